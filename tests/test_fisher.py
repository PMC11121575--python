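"""Contingency assembly, log-space Fisher tests and the enumeration oracle."""

import math

import numpy as np
import pytest
from scipy.stats import hypergeom

from comine.errors import (
    DegenerateTableError,
    InconsistentCountsError,
    OracleScaleError,
)
from comine.fisher import (
    ComorbidityResult,
    ContingencyCounts,
    assemble_table,
    comorbidity_significance,
    fisher_bruteforce_oracle,
    fisher_exact_log_pvalue,
    fisher_exact_pvalue,
)

from conftest import SIGNIFICANT_TABLE2, TABLE2


def random_tables(n, max_total, seed):
    """Random non-degenerate 2x2 tables with total <= max_total."""
    rng = np.random.default_rng(seed)
    tables = []
    while len(tables) < n:
        cells = tuple(int(v) for v in rng.integers(0, max_total // 4 + 1, size=4))
        if sum(cells) == 0 or sum(cells) > max_total:
            continue
        a, b, c, d = cells
        if (a + b == 0 or c + d == 0) and (a + c == 0 or b + d == 0):
            continue
        tables.append(cells)
    return tables


class TestAssembleTable:
    def test_direct_passes_total_through(self):
        counts = ContingencyCounts(142, 220, 1066, 125_924, convention="direct")
        assert assemble_table(counts) == (142, 220, 1066, 125_924)

    def test_remainder_subtracts_other_cells(self):
        counts = ContingencyCounts(142, 220, 1066, 125_924, convention="remainder")
        assert assemble_table(counts) == (142, 220, 1066, 124_496)

    def test_margins_uses_counts_as_margins(self):
        counts = ContingencyCounts(142, 220, 1066, 125_924, convention="margins")
        assert assemble_table(counts) == (142, 78, 924, 124_780)

    def test_negative_cell_is_inconsistent(self):
        with pytest.raises(InconsistentCountsError):
            assemble_table(ContingencyCounts(1, 0, 0, 0, convention="remainder"))
        with pytest.raises(InconsistentCountsError):
            assemble_table(ContingencyCounts(5, 2, 9, 100, convention="margins"))
        with pytest.raises(InconsistentCountsError):
            ContingencyCounts(-1, 0, 0, 0)


class TestFisherExact:
    def test_tiny_table_equals_enumerated_sixth(self):
        # margins (2,2|2,2): 3 tables, only a=2 as extreme; C(2,2)C(2,0)/C(4,2)=1/6
        assert fisher_exact_pvalue((2, 0, 0, 2), "greater") == pytest.approx(1 / 6, rel=1e-12)

    def test_minimum_of_support_has_unit_tail(self):
        assert fisher_exact_pvalue((0, 5, 7, 11), "greater") == 1.0

    def test_symmetric_table_two_sided_is_one(self):
        assert fisher_exact_pvalue((1, 1, 1, 1), "two_sided") == pytest.approx(1.0)

    def test_degenerate_table_rejected(self):
        with pytest.raises(DegenerateTableError):
            fisher_exact_pvalue((0, 0, 0, 0), "greater")

    def test_unknown_alternative_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_pvalue((1, 2, 3, 4), "both")

    def test_extreme_tail_has_no_underflow(self):
        """A deep tail comes back as a finite log, far below float underflow."""
        logp = fisher_exact_log_pvalue((500, 0, 0, 500_000), "greater")
        assert -6000 < logp < -600
        assert fisher_exact_pvalue((500, 0, 0, 500_000), "greater") == 0.0  # below float range

    def test_matches_scipy_survival_function(self):
        """Independent route: scipy's hypergeometric sf on moderate tables."""
        for a, b, c, d in random_tables(50, 500, seed=7):
            ours = fisher_exact_pvalue((a, b, c, d), "greater")
            N, K, n = a + b + c + d, a + b, a + c
            ref = float(hypergeom.sf(a - 1, N, K, n))
            assert ours == pytest.approx(ref, rel=1e-9, abs=1e-300)

    def test_greater_tail_decreases_in_a_at_fixed_margins(self):
        r1, c1, N = 20, 30, 100
        ps = []
        for a in range(0, min(r1, c1) + 1):
            b, c = r1 - a, c1 - a
            d = N - a - b - c
            if d < 0:
                break
            ps.append(fisher_exact_pvalue((a, b, c, d), "greater"))
        assert all(p1 > p2 for p1, p2 in zip(ps, ps[1:]))

    def test_discrete_complement_identity(self):
        """greater + less = 1 + point probability, on random tables."""
        for a, b, c, d in random_tables(40, 300, seed=11):
            g = fisher_exact_pvalue((a, b, c, d), "greater")
            l = fisher_exact_pvalue((a, b, c, d), "less")
            N, K, n = a + b + c + d, a + b, a + c
            point = float(hypergeom.pmf(a, N, K, n))
            assert g + l == pytest.approx(1.0 + point, rel=1e-9)

    def test_log_and_linear_scales_agree(self):
        for cells in random_tables(40, 200, seed=3):
            p = fisher_exact_pvalue(cells, "greater")
            logp = fisher_exact_log_pvalue(cells, "greater")
            if p > 1e-10:
                assert math.log(p) == pytest.approx(logp, abs=1e-9)


class TestOracle:
    def test_enumerated_sixth(self):
        assert fisher_bruteforce_oracle((2, 0, 0, 2), "greater") == pytest.approx(1 / 6)

    def test_symmetric_two_sided_is_one(self):
        assert fisher_bruteforce_oracle((1, 1, 1, 1), "two_sided") == 1

    def test_scale_limit(self):
        with pytest.raises(OracleScaleError):
            fisher_bruteforce_oracle((100, 100, 100, 100), "greater")

    @pytest.mark.parametrize("alternative", ["greater", "less", "two_sided"])
    def test_logspace_agrees_with_exact_enumeration(self, alternative):
        for cells in random_tables(60, 100, seed=29):
            exact = float(fisher_bruteforce_oracle(cells, alternative))
            ours = fisher_exact_pvalue(cells, alternative)
            assert ours == pytest.approx(exact, rel=1e-10)


class TestComorbiditySignificance:
    def _pairs(self, convention="margins"):
        return [
            (name, ContingencyCounts(a, b, c, n, convention=convention))
            for name, (a, b, c, n, _) in TABLE2.items()
        ]

    def test_published_rows_reproduced_under_margins_convention(self):
        results = comorbidity_significance(self._pairs(), alpha=5e-8, alternative="greater")
        by_name = {r.co_disease: r for r in results}
        for name, (*_, expected_p) in TABLE2.items():
            assert by_name[name].p_value == pytest.approx(expected_p, rel=0.05)
        assert {r.co_disease for r in results if r.significant} == SIGNIFICANT_TABLE2
        # sorted by p ascending
        ps = [r.p_value for r in results]
        assert ps == sorted(ps)

    def test_alpha_one_flags_everything(self):
        results = comorbidity_significance(self._pairs(), alpha=1.0)
        assert all(r.significant for r in results)

    def test_empty_input_gives_empty_output(self):
        assert comorbidity_significance([]) == []

    def test_alpha_domain(self):
        with pytest.raises(ValueError):
            comorbidity_significance(self._pairs(), alpha=0.0)

    def test_bh_correction_is_monotone_and_conservative(self):
        raw = comorbidity_significance(self._pairs(), alpha=5e-8)
        adj = comorbidity_significance(self._pairs(), alpha=5e-8, correction="bh")
        flagged_raw = {r.co_disease for r in raw if r.significant}
        flagged_adj = {r.co_disease for r in adj if r.significant}
        assert flagged_adj <= flagged_raw

    def test_strict_inequality_at_threshold(self):
        counts = ContingencyCounts(2, 0, 0, 2, convention="direct")
        p = fisher_exact_pvalue(assemble_table(counts), "greater")
        [res] = comorbidity_significance([("x", counts)], alpha=p)
        assert isinstance(res, ComorbidityResult)
        assert not res.significant  # p < alpha is strict
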