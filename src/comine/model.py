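"""Model/Results facade over the comorbidity-mining pipeline.

:class:`ComorbidityModel` is built from a corpus, a disease lexicon and an
index disease; :meth:`ComorbidityModel.fit` runs co-occurrence counting and
exact Fisher testing and returns a :class:`ComorbidityResults` carrying the
ranked co-occurrence table, the per-disease contingency counts and
p-values, significance calls, and a ``summary()`` report.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Literal

import pandas as pd

from .cooccur import CooccurrenceResult, count_pairs, top_k
from .errors import UnknownDiseaseError
from .fisher import (
    DEFAULT_ALPHA,
    Alternative,
    ComorbidityResult,
    ContingencyCounts,
    Convention,
    comorbidity_significance,
)
from .lexicon import DiseaseLexicon, build_lexicon, normalize_term, read_descriptor_tsv
from .medline import Corpus, disease_set, parse_medline

__all__ = ["ComorbidityModel", "ComorbidityResults"]

logger = logging.getLogger(__name__)


class ComorbidityModel:
    """Literature comorbidity analysis for one index disease.

    Parameters
    ----------
    corpus : Corpus
        MeSH-indexed articles, typically the result of a comorbidity query.
    lexicon : DiseaseLexicon
        The disease-matching dictionary.
    index_disease : str
        Any spelling that normalizes to a lexicon entry.
    """

    def __init__(self, corpus: Corpus, lexicon: DiseaseLexicon, index_disease: str):
        self.corpus = corpus
        self.lexicon = lexicon
        canonical = lexicon.entries.get(normalize_term(index_disease))
        if canonical is None:
            raise UnknownDiseaseError(f"index disease {index_disease!r} not in lexicon")
        self.index_disease = canonical
        # one pass over the MeSH indices; reused by fit()
        self._disease_sets = [disease_set(a, lexicon) for a in corpus.articles]

    @classmethod
    def from_files(
        cls,
        corpus_path: str | Path,
        lexicon_path: str | Path,
        index_disease: str,
        excluded_categories: tuple[str, ...] = ("Animal Diseases",),
    ) -> "ComorbidityModel":
        """Build from a MEDLINE file and a ``term<TAB>category`` TSV."""
        with open(lexicon_path, encoding="utf-8") as fh:
            lexicon = build_lexicon(read_descriptor_tsv(fh), excluded_categories)
        with open(corpus_path, encoding="utf-8") as fh:
            corpus = parse_medline(fh, provenance=str(corpus_path))
        return cls(corpus, lexicon, index_disease)

    def fit(
        self,
        alpha: float = DEFAULT_ALPHA,
        alternative: Alternative = "greater",
        convention: Convention = "remainder",
        correction: Literal[None, "bh"] = None,
    ) -> "ComorbidityResults":
        """Rank co-occurring diseases and test comorbidity significance.

        The default ``remainder`` convention forms the exact 2x2 partition
        of the corpus (both / co-only / index-only / neither), which is the
        correct Fisher table for self-consistent corpus counts; ``margins``
        and ``direct`` reproduce alternative published assemblies of the
        four counts and remain selectable for sensitivity analysis.
        """
        cooc = count_pairs(self.corpus, self.lexicon, self.index_disease)
        idx = self.index_disease
        n_total = len(self.corpus)
        pairs: list[tuple[str, ContingencyCounts]] = []
        for r in cooc:
            n_both = r.p_each_pair
            n_cd = sum(1 for s in self._disease_sets if r.co_disease in s and idx not in s)
            n_idx = sum(1 for s in self._disease_sets if idx in s and r.co_disease not in s)
            pairs.append(
                (
                    r.co_disease,
                    ContingencyCounts(
                        n_both=n_both,
                        n_cd_only=n_cd,
                        n_idx_only=n_idx,
                        n_total=n_total,
                        convention=convention,
                    ),
                )
            )
        tests = comorbidity_significance(pairs, alpha=alpha, alternative=alternative, correction=correction)
        logger.info(
            "corpus=%d articles, p_all=%d, co-occurring=%d, significant=%d",
            n_total,
            cooc[0].p_all if cooc else 0,
            len(cooc),
            sum(t.significant for t in tests),
        )
        return ComorbidityResults(self, cooc, tests, alpha, alternative, convention)


class ComorbidityResults:
    """Fitted comorbidity analysis: rankings, p-values, significance calls."""

    def __init__(
        self,
        model: ComorbidityModel,
        cooccurrence_results: list[CooccurrenceResult],
        test_results: list[ComorbidityResult],
        alpha: float,
        alternative: Alternative,
        convention: Convention,
    ):
        self.model = model
        self.cooccurrence_results = cooccurrence_results
        self.test_results = test_results
        self.alpha = alpha
        self.alternative = alternative
        self.convention = convention

        self.n_articles = len(model.corpus)
        self.p_all = cooccurrence_results[0].p_all if cooccurrence_results else 0
        self.n_cooccurring = len(cooccurrence_results)
        self.n_significant = sum(t.significant for t in test_results)

        self.cooccurrence = pd.DataFrame(
            [
                {
                    "co_disease": r.co_disease,
                    "p_each_pair": r.p_each_pair,
                    "p_all": r.p_all,
                    "sort_ratio": r.sort_ratio,
                }
                for r in cooccurrence_results
            ],
            columns=["co_disease", "p_each_pair", "p_all", "sort_ratio"],
        )
        self.comorbidity = pd.DataFrame(
            [
                {
                    "co_disease": t.co_disease,
                    "n_both": t.counts.n_both,
                    "n_cd_only": t.counts.n_cd_only,
                    "n_idx_only": t.counts.n_idx_only,
                    "n_total": t.counts.n_total,
                    "p_value": t.p_value,
                    "significant": t.significant,
                }
                for t in test_results
            ],
            columns=[
                "co_disease",
                "n_both",
                "n_cd_only",
                "n_idx_only",
                "n_total",
                "p_value",
                "significant",
            ],
        )

    @property
    def pvalues(self) -> pd.Series:
        return self.comorbidity.set_index("co_disease")["p_value"]

    @property
    def significant(self) -> pd.Series:
        return self.comorbidity.set_index("co_disease")["significant"]

    def top(self, k: int = 5) -> pd.DataFrame:
        """Top-k co-occurring diseases by sort ratio (ties alphabetical)."""
        rows = top_k(self.cooccurrence_results, k) if self.cooccurrence_results else []
        return pd.DataFrame(
            [
                {
                    "co_disease": r.co_disease,
                    "p_each_pair": r.p_each_pair,
                    "p_all": r.p_all,
                    "sort_ratio": round(r.sort_ratio, 4),
                }
                for r in rows
            ],
            columns=["co_disease", "p_each_pair", "p_all", "sort_ratio"],
        )

    def summary(self, k: int = 5) -> str:
        """Human-readable report of the fitted analysis."""
        lines = [
            "Comorbidity mining results",
            "=" * 62,
            f"Index disease:        {self.model.index_disease}",
            f"Articles in corpus:   {self.n_articles}",
            f"Pairing articles:     {self.p_all} (index + >=1 co-disease)",
            f"Co-occurring diseases:{self.n_cooccurring:>6}",
            f"Significant (p < {self.alpha:g}): {self.n_significant}",
            f"Fisher test:          {self.alternative}, convention={self.convention}",
            "-" * 62,
            f"Top {min(k, self.n_cooccurring)} by sort ratio:",
        ]
        top = self.top(k)
        pmap = dict(zip(self.comorbidity["co_disease"], self.comorbidity["p_value"]))
        sigmap = dict(zip(self.comorbidity["co_disease"], self.comorbidity["significant"]))
        for _, row in top.iterrows():
            name = row["co_disease"]
            star = " *" if sigmap.get(name, False) else ""
            lines.append(
                f"  {name:<32} {row['p_each_pair']:>5} /{row['p_all']:>6}  "
                f"ratio={row['sort_ratio']:.4f}  p={pmap.get(name, float('nan')):.2e}{star}"
            )
        lines.append("-" * 62)
        lines.append("* significant at the configured threshold")
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"<ComorbidityResults: {self.n_cooccurring} co-occurring, "
            f"{self.n_significant} significant, n={self.n_articles}>"
        )
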