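"""Synthetic corpora and gene-set collections with planted structure.

The corpus generator emulates a comorbidity literature query: every article
carries the "Comorbidity" MeSH tag, contains the index disease with a given
prevalence, and mentions each planted co-disease with a conditional
probability depending on whether the index disease is present (the lift
``p_given_index / p_given_not_index`` is what the mining pipeline should
recover). Background diseases appear independently of the index. Diseases
are sampled independently per article given the index status — the mining
statistics only see pairwise margins, so higher-order dependence would be
invisible anyway.

The gene-set generator plants "cores": gene groups shared by exactly a
declared subset of diseases, plus per-set private genes, so the
multimorbidity table of the downstream analysis is known by construction.

All randomness flows through one :class:`numpy.random.Generator` seeded from
a single integer; equal seeds give byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import SpecError
from .genesets import GeneSetCollection
from .medline import Article, Corpus

__all__ = ["PlantedDisease", "CorpusSpec", "GeneSetSpec", "simulate_corpus", "simulate_genesets"]

#: Leading digit keeping synthetic PMIDs clear of real ones (real PMIDs are
#: currently well below 9e8).
_PMID_BASE = 900_000_000


@dataclass(frozen=True)
class PlantedDisease:
    """A co-disease with index-conditional occurrence probabilities."""

    disease: str
    p_given_index: float
    p_given_not_index: float


@dataclass(frozen=True)
class CorpusSpec:
    n_articles: int
    index_prevalence: float
    planted: tuple[PlantedDisease, ...] = ()
    background: tuple[tuple[str, float], ...] = ()
    seed: int = 0
    index_disease: str = "Alzheimer Disease"
    comorbidity_tag: str = "Comorbidity"

    def validate(self) -> None:
        if self.n_articles < 0:
            raise SpecError("n_articles must be >= 0")
        probs = [self.index_prevalence]
        probs += [p for pl in self.planted for p in (pl.p_given_index, pl.p_given_not_index)]
        probs += [p for _, p in self.background]
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise SpecError("all probabilities must lie in [0, 1]")
        names = [pl.disease for pl in self.planted] + [d for d, _ in self.background]
        if self.index_disease in names:
            raise SpecError("planted/background diseases must differ from the index disease")
        if len(names) != len(set(names)):
            raise SpecError("duplicate disease names in spec")


@dataclass(frozen=True)
class GeneSetSpec:
    diseases: tuple[str, ...]
    universe_size: int
    cores: tuple[tuple[frozenset[str], int], ...] = ()
    per_set_private: int = 0
    seed: int = 0

    @property
    def n_diseases(self) -> int:
        return len(self.diseases)

    def validate(self) -> None:
        if self.n_diseases == 0:
            raise SpecError("at least one disease required")
        declared = set(self.diseases)
        for subset, n in self.cores:
            if n < 0:
                raise SpecError("core sizes must be >= 0")
            if not subset <= declared:
                raise SpecError(f"core subset {sorted(subset)} references undeclared diseases")
        if self.per_set_private < 0:
            raise SpecError("per_set_private must be >= 0")
        needed = sum(n for _, n in self.cores) + self.per_set_private * self.n_diseases
        if needed > self.universe_size:
            raise SpecError(f"universe exhausted: need {needed} genes, have {self.universe_size}")


def simulate_corpus(spec: CorpusSpec) -> Corpus:
    """Generate a MEDLINE-style corpus per the spec; deterministic under seed."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_articles
    has_index = rng.random(n) < spec.index_prevalence
    columns: list[tuple[str, np.ndarray]] = []
    for pl in spec.planted:
        p = np.where(has_index, pl.p_given_index, pl.p_given_not_index)
        columns.append((pl.disease, rng.random(n) < p))
    for disease, p in spec.background:
        columns.append((disease, rng.random(n) < p))

    articles = []
    for i in range(n):
        headings = [spec.comorbidity_tag]
        if has_index[i]:
            headings.append(spec.index_disease)
        headings.extend(d for d, col in columns if col[i])
        articles.append(Article(pmid=str(_PMID_BASE + i + 1), mesh_headings=headings))
    provenance = (
        f"synthetic comorbidity corpus: n={n}, index={spec.index_disease!r}, "
        f"prevalence={spec.index_prevalence}, seed={spec.seed}"
    )
    return Corpus(articles=articles, provenance=provenance)


def simulate_genesets(spec: GeneSetSpec) -> GeneSetCollection:
    """Generate gene sets with planted shared cores; deterministic under seed.

    Each core's genes are placed in exactly that core's diseases and nowhere
    else; private genes are disjoint across sets. The first declared disease
    is the index.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    width = max(5, len(str(spec.universe_size)))
    pool = [f"G{g + 1:0{width}d}" for g in rng.permutation(spec.universe_size)]
    cursor = 0
    sets: dict[str, set[str]] = {d: set() for d in spec.diseases}
    for subset, n_shared in spec.cores:
        genes = pool[cursor : cursor + n_shared]
        cursor += n_shared
        for d in subset:
            sets[d].update(genes)
    for d in spec.diseases:
        genes = pool[cursor : cursor + spec.per_set_private]
        cursor += spec.per_set_private
        sets[d].update(genes)
    return GeneSetCollection(sets=sets, index_disease=spec.diseases[0])
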