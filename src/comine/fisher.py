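"""Exact Fisher tests for literature comorbidity, robust to p ~ 1e-300.

The comorbidity corpus yields four counts per index/co-disease pair:

(i)   ``n_both``     — articles indexed with both diseases;
(ii)  ``n_cd_only``  — articles with the co-disease but not the index disease;
(iii) ``n_idx_only`` — articles with the index disease but not the co-disease;
(iv)  ``n_total``    — all articles in the comorbidity corpus.

Three conventions assemble these into a 2x2 table:

* ``margins``   — counts (ii) and (iii) are used directly as the two
  hypergeometric margins over a population of size (iv): cells
  ``(a, b-a, c-a, N-b-c+a)``. This is the convention calibrated against the
  published comorbidity tables, and it is the exact test whenever the
  marginal counts are inclusive of the overlap.
* ``remainder`` — cells ``(a, b, c, N-a-b-c)``: the exact single-partition
  table when counts (ii)/(iii) already exclude the overlap, as the Boolean
  queries above define them. This is the default for corpus-derived counts.
* ``direct``    — cells ``(a, b, c, N)``: count (iv) dropped in verbatim as
  the d-cell. Kept selectable for sensitivity analysis; it inflates the
  table total and is anticonservative when the index disease is common.

P-values are computed by accumulating hypergeometric log-probabilities
(log-gamma terms) with log-sum-exp, so tails down to 1e-300 come back
without underflow.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from typing import IO, Iterable, Literal, Sequence

import numpy as np
from scipy.special import gammaln, logsumexp
from scipy.stats import false_discovery_control

from .errors import DegenerateTableError, InconsistentCountsError, OracleScaleError

__all__ = [
    "ContingencyCounts",
    "ComorbidityResult",
    "assemble_table",
    "fisher_exact_pvalue",
    "fisher_exact_log_pvalue",
    "fisher_bruteforce_oracle",
    "comorbidity_significance",
    "write_comorbidity_tsv",
    "DEFAULT_ALPHA",
]

Alternative = Literal["greater", "less", "two_sided"]
Convention = Literal["direct", "remainder", "margins"]

#: Genome-wide style significance threshold used for comorbidity calls.
DEFAULT_ALPHA = 5.0e-8

# Relative slack when comparing point probabilities for the two-sided rule;
# tables whose probability exceeds the observed one by less than this factor
# still count as "as extreme".
_TWO_SIDED_SLACK = 1e-7


@dataclass(frozen=True)
class ContingencyCounts:
    """The four literature counts for one index/co-disease pair."""

    n_both: int
    n_cd_only: int
    n_idx_only: int
    n_total: int
    convention: Convention = "margins"

    def __post_init__(self) -> None:
        for name in ("n_both", "n_cd_only", "n_idx_only", "n_total"):
            if getattr(self, name) < 0:
                raise InconsistentCountsError(f"{name} is negative")
        if self.convention not in ("direct", "remainder", "margins"):
            raise InconsistentCountsError(f"unknown convention {self.convention!r}")


@dataclass(frozen=True)
class ComorbidityResult:
    co_disease: str
    counts: ContingencyCounts
    p_value: float
    significant: bool


def assemble_table(counts: ContingencyCounts) -> tuple[int, int, int, int]:
    """Assemble the 2x2 cells (a, b, c, d) under the counts' convention.

    Raises
    ------
    InconsistentCountsError
        If the convention produces a negative cell.
    """
    a, b, c, n = counts.n_both, counts.n_cd_only, counts.n_idx_only, counts.n_total
    if counts.convention == "direct":
        cells = (a, b, c, n)
    elif counts.convention == "remainder":
        cells = (a, b, c, n - a - b - c)
    else:  # margins
        cells = (a, b - a, c - a, n - b - c + a)
    if min(cells) < 0:
        raise InconsistentCountsError(
            f"counts {counts} produce negative cell under {counts.convention!r}: {cells}"
        )
    return cells


def _support_logpmf(a: int, b: int, c: int, d: int) -> tuple[np.ndarray, np.ndarray]:
    """Hypergeometric support and log-pmf for the a-cell at fixed margins."""
    N = a + b + c + d
    r1, c1 = a + b, a + c
    lo = max(0, r1 + c1 - N)
    hi = min(r1, c1)
    x = np.arange(lo, hi + 1)
    # log C(c1, x) + log C(N-c1, r1-x) - log C(N, r1), via log-gamma
    lpmf = (
        _lcomb(c1, x)
        + _lcomb(N - c1, r1 - x)
        - _lcomb(N, r1)
    )
    return x, lpmf


def _lcomb(n: int | np.ndarray, k: np.ndarray) -> np.ndarray:
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def _validate_cells(cells: Sequence[int]) -> tuple[int, int, int, int]:
    if len(cells) != 4:
        raise ValueError("expected 4 cells")
    a, b, c, d = (int(v) for v in cells)
    if min(a, b, c, d) < 0:
        raise InconsistentCountsError(f"negative cell in {cells}")
    if a + b + c + d == 0:
        raise DegenerateTableError("all-zero 2x2 table")
    return a, b, c, d


def fisher_exact_log_pvalue(cells: Sequence[int], alternative: Alternative = "greater") -> float:
    """Natural log of the exact Fisher p-value (log-space throughout)."""
    a, b, c, d = _validate_cells(cells)
    x, lpmf = _support_logpmf(a, b, c, d)
    # tails spanning the whole support are exactly 1 — skip float summation
    if alternative == "greater" and a <= int(x[0]):
        return 0.0
    if alternative == "less" and a >= int(x[-1]):
        return 0.0
    if alternative == "greater":
        sel = x >= a
    elif alternative == "less":
        sel = x <= a
    elif alternative == "two_sided":
        la = float(lpmf[x == a][0])
        sel = lpmf <= la + math.log1p(_TWO_SIDED_SLACK)
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return min(0.0, float(logsumexp(lpmf[sel])))


def fisher_exact_pvalue(cells: Sequence[int], alternative: Alternative = "greater") -> float:
    """Exact Fisher p-value on a 2x2 table.

    One-sided ``greater`` is the enrichment tail P(X >= a) of the a-cell's
    hypergeometric distribution at the table's margins; ``two_sided`` sums
    every table whose point probability does not exceed the observed one
    (relative slack 1e-7). Accurate down to ~1e-300.
    """
    return float(math.exp(fisher_exact_log_pvalue(cells, alternative)))


def fisher_bruteforce_oracle(cells: Sequence[int], alternative: Alternative = "greater") -> Fraction:
    """Exact-rational Fisher p-value by full enumeration (test oracle).

    Enumerates every table with the observed margins using
    :class:`fractions.Fraction`, so the result is exact. Restricted to
    totals N <= 200 to keep enumeration honest and cheap.
    """
    a, b, c, d = _validate_cells(cells)
    N = a + b + c + d
    if N > 200:
        raise OracleScaleError(f"oracle limited to N <= 200, got {N}")
    r1, c1 = a + b, a + c
    lo, hi = max(0, r1 + c1 - N), min(r1, c1)
    denom = math.comb(N, r1)
    pmf = {
        x: Fraction(math.comb(c1, x) * math.comb(N - c1, r1 - x), denom)
        for x in range(lo, hi + 1)
    }
    if alternative == "greater":
        return sum(p for x, p in pmf.items() if x >= a)
    if alternative == "less":
        return sum(p for x, p in pmf.items() if x <= a)
    if alternative == "two_sided":
        cutoff = pmf[a] * (Fraction(10**7 + 1, 10**7))
        return min(Fraction(1), sum(p for p in pmf.values() if p <= cutoff))
    raise ValueError(f"unknown alternative {alternative!r}")


def comorbidity_significance(
    pairs: Iterable[tuple[str, ContingencyCounts]],
    alpha: float = DEFAULT_ALPHA,
    alternative: Alternative = "greater",
    correction: Literal[None, "bh"] = None,
) -> list[ComorbidityResult]:
    """Exact Fisher p-values and significance calls for many pairs.

    Significance is the strict inequality ``p < alpha`` (or adjusted p when
    ``correction="bh"`` requests Benjamini-Hochberg). Output sorted by
    p-value ascending, ties alphabetical.
    """
    if not 0.0 < alpha <= 1.0:
        raise ValueError(f"alpha must be in (0, 1], got {alpha}")
    pairs = list(pairs)
    pvals = [fisher_exact_pvalue(assemble_table(counts), alternative) for _, counts in pairs]
    crit = pvals
    if correction == "bh" and pvals:
        crit = list(false_discovery_control(pvals, method="bh"))
    results = [
        ComorbidityResult(co_disease=name, counts=counts, p_value=p, significant=q < alpha)
        for (name, counts), p, q in zip(pairs, pvals, crit)
    ]
    results.sort(key=lambda r: (r.p_value, r.co_disease))
    return results


def write_comorbidity_tsv(results: Iterable[ComorbidityResult], stream: IO[str]) -> None:
    """Report: the four counts, p-value (3 significant digits), significance."""
    stream.write("co_disease\tn_both\tn_cd_only\tn_idx_only\tn_total\tp_value\tsignificant\n")
    for r in results:
        c = r.counts
        stream.write(
            f"{r.co_disease}\t{c.n_both}\t{c.n_cd_only}\t{c.n_idx_only}\t{c.n_total}\t"
            f"{r.p_value:.2e}\t{str(r.significant).lower()}\n"
        )
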