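"""Index-disease / co-disease co-occurrence counting and sort-ratio ranking.

For an index disease D and a corpus of MeSH-indexed articles, each
co-occurring disease C gets two counts:

* ``p_each_pair`` — articles whose MeSH index contains both D and C;
* ``p_all``       — articles containing D together with at least one other
  lexicon disease (the pairing denominator, shared by all C).

The ranking statistic is the sort ratio ``p_each_pair / p_all``, the
fraction of D-pairing articles that mention C. Ratios are kept at full
precision; reports round to four decimals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import IO

from .errors import UnknownDiseaseError
from .lexicon import DiseaseLexicon, normalize_term
from .medline import Corpus, disease_set

__all__ = ["CooccurrenceResult", "sort_ratio", "count_pairs", "top_k", "write_cooccurrence_tsv"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CooccurrenceResult:
    co_disease: str
    p_each_pair: int
    p_all: int

    @property
    def sort_ratio(self) -> float:
        return sort_ratio(self.p_each_pair, self.p_all)


def sort_ratio(p_each_pair: int, p_all: int) -> float:
    """Exact quotient p_each_pair / p_all; domain error when p_all == 0."""
    if p_all <= 0:
        raise ZeroDivisionError("sort ratio undefined: p_all is zero")
    if not 0 <= p_each_pair <= p_all:
        raise ValueError(f"p_each_pair={p_each_pair} outside [0, p_all={p_all}]")
    return p_each_pair / p_all


def count_pairs(
    corpus: Corpus, lexicon: DiseaseLexicon, index_disease: str
) -> list[CooccurrenceResult]:
    """Count all index/co-disease pairs and rank by sort ratio.

    Sorted by sort ratio descending, ties broken alphabetically by
    co-disease. Returns an empty list (with a logged warning) when no
    article pairs the index disease with another lexicon disease.

    Raises
    ------
    UnknownDiseaseError
        If ``index_disease`` is not a lexicon entry.
    """
    key = normalize_term(index_disease)
    canonical = lexicon.entries.get(key)
    if canonical is None:
        raise UnknownDiseaseError(f"index disease {index_disease!r} not in lexicon")

    p_all = 0
    pair_counts: dict[str, int] = {}
    for article in corpus.articles:
        diseases = disease_set(article, lexicon)
        if canonical not in diseases or len(diseases) < 2:
            continue
        p_all += 1
        for co in diseases:
            if co != canonical:
                pair_counts[co] = pair_counts.get(co, 0) + 1

    if p_all == 0:
        logger.warning(
            "no article pairs %r with another lexicon disease; empty result", canonical
        )
        return []
    results = [
        CooccurrenceResult(co_disease=co, p_each_pair=n, p_all=p_all)
        for co, n in pair_counts.items()
    ]
    results.sort(key=lambda r: (-r.sort_ratio, r.co_disease))
    return results


def top_k(results: list[CooccurrenceResult], k: int) -> list[CooccurrenceResult]:
    """First k results in ranking order (ratio desc, then alphabetical)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > len(results):
        logger.warning("requested top %d of %d results; returning all", k, len(results))
    ordered = sorted(results, key=lambda r: (-r.sort_ratio, r.co_disease))
    return ordered[:k]


def write_cooccurrence_tsv(results: list[CooccurrenceResult], stream: IO[str]) -> None:
    """Report: co_disease, p_each_pair, p_all, sort_ratio (4 dp)."""
    stream.write("co_disease\tp_each_pair\tp_all\tsort_ratio\n")
    for r in results:
        stream.write(f"{r.co_disease}\t{r.p_each_pair}\t{r.p_all}\t{r.sort_ratio:.4f}\n")
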