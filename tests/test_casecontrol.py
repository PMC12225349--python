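"""Contingency analysis: chi-square, Cramer's V, pairwise decomposition, ORs."""

import math

import numpy as np
import pytest
from scipy.stats.contingency import association

from cprvent.casecontrol import (
    build_tables,
    case_control,
    case_control_all,
    chi_square,
    cramers_v,
    cramers_v_label,
    odds_ratio,
    pairwise_decomposition,
)
from cprvent.datasets import lifeguard_ventilation_counts
from cprvent.events import ContingencyTable, ValidationError


def table(counts, rows=None, cols=None):
    counts = np.asarray(counts)
    rows = rows or tuple(f"r{i}" for i in range(counts.shape[0]))
    cols = cols or tuple(f"c{i}" for i in range(counts.shape[1]))
    return ContingencyTable(tuple(rows), tuple(cols), counts)


def chi2_oracle(counts):
    """Literal sum((O - E)^2 / E)."""
    counts = np.asarray(counts, dtype=float)
    n = counts.sum()
    expected = np.outer(counts.sum(1), counts.sum(0)) / n
    return ((counts - expected) ** 2 / expected).sum()


class TestBuildTables:
    def test_study_counts_shape_and_marginals(self):
        tables = build_tables(lifeguard_ventilation_counts())
        gr = tables[("green", "red")]
        assert [list(r) for r in gr.counts] == [[0, 125], [6, 49], [24, 28]]
        assert gr.col_totals.tolist() == [30, 202]
        assert tables[("green", "amber")].col_totals.tolist() == [30, 149]
        assert tables[("amber", "red")].col_totals.tolist() == [149, 202]

    def test_zero_everywhere_still_builds(self):
        import pandas as pd

        zeros = pd.DataFrame(0, index=["T0", "T1", "T2"], columns=["green", "amber", "red"])
        tables = build_tables(zeros)
        assert all(t.n == 0 for t in tables.values())

    def test_missing_category_column_rejected(self):
        import pandas as pd

        counts = pd.DataFrame({"green": [1, 2, 3]}, index=["T0", "T1", "T2"])
        with pytest.raises(ValidationError, match="amber"):
            build_tables(counts)


class TestChiSquare:
    def test_proportional_rows_give_zero(self):
        res = chi_square(table([[10, 20], [20, 40]]))
        assert res.statistic == pytest.approx(0)
        assert res.p == pytest.approx(1)

    def test_green_amber_overall(self):
        """3x2 table: statistic ~10.47, df 2, p rounds to 0.005."""
        res = chi_square(table([[0, 22], [6, 53], [24, 74]]))
        assert res.statistic == pytest.approx(10.47, abs=0.01)
        assert res.df == 2
        assert round(res.p, 3) == 0.005

    def test_transposition_invariance(self, rng):
        counts = rng.integers(1, 50, size=(2, 2))
        a = chi_square(table(counts))
        b = chi_square(table(counts.T))
        assert a.statistic == pytest.approx(b.statistic)
        assert a.p == pytest.approx(b.p)

    def test_zero_marginal_rejected(self):
        with pytest.raises(ValidationError, match="marginal"):
            chi_square(table([[0, 0], [5, 7]]))
        with pytest.raises(ValidationError, match="N = 0"):
            chi_square(table([[0, 0], [0, 0]]))

    def test_matches_brute_force_oracle_up_to_4x4(self, rng):
        for r in (2, 3, 4):
            for c in (2, 3, 4):
                for _ in range(5):
                    counts = rng.integers(1, 40, size=(r, c))
                    res = chi_square(table(counts))
                    assert res.statistic == pytest.approx(chi2_oracle(counts))
                    assert res.df == (r - 1) * (c - 1)

    def test_p_approximates_permutation_null(self, rng):
        """Monte-Carlo check against the conditional-margins null."""
        counts = np.array([[12, 8], [6, 16]])
        res = chi_square(table(counts))
        row_tot, col_tot, n = counts.sum(1), counts.sum(0), counts.sum()
        labels = np.repeat([0, 1], row_tot)
        hits = 0
        reps = 4000
        for _ in range(reps):
            perm = rng.permutation(labels)
            a = perm[: col_tot[0]].sum()
            sim = np.array(
                [[col_tot[0] - a, row_tot[0] - (col_tot[0] - a)],
                 [a, row_tot[1] - a]]
            )
            hits += chi2_oracle(sim) >= res.statistic - 1e-12
        assert res.p == pytest.approx(hits / reps, abs=0.03)


class TestCramersV:
    @pytest.mark.parametrize(
        "counts,expected",
        [
            ([[0, 22], [6, 53], [24, 74]], 0.24),  # green vs amber, overall
            ([[0, 125], [6, 49], [24, 28]], 0.55),  # green vs red, overall
            ([[22, 125], [53, 49], [74, 28]], 0.50),  # amber vs red, overall
            ([[0, 125], [24, 28]], 0.61),  # green vs red, T0 vs T2
        ],
    )
    def test_printed_effect_sizes(self, counts, expected):
        v, _ = cramers_v(table(counts))
        assert round(v, 2) == expected

    def test_diagonal_2x2_is_one(self):
        v, label = cramers_v(table([[10, 0], [0, 10]]))
        assert v == pytest.approx(1.0)
        assert label == "Large"

    def test_independent_table_is_zero(self):
        v, label = cramers_v(table([[10, 20], [20, 40]]))
        assert v == pytest.approx(0.0)
        assert label == "Negligible"

    def test_matches_scipy_association(self, rng):
        for _ in range(10):
            counts = rng.integers(1, 60, size=(3, 2))
            v, _ = cramers_v(table(counts))
            assert v == pytest.approx(association(counts, method="cramer", correction=False))

    def test_label_bands(self):
        assert cramers_v_label(0.05) == "Negligible"
        assert cramers_v_label(0.15) == "Small"
        assert cramers_v_label(0.35) == "Medium"
        assert cramers_v_label(0.55) == "Large"


class TestPairwiseDecomposition:
    def test_green_red_pairwise_values(self):
        tab = table([[0, 125], [6, 49], [24, 28]], rows=("T0", "T1", "T2"),
                    cols=("green", "red"))
        results = pairwise_decomposition(tab)
        by_pair = {r.exposures: r for r in results}
        assert round(by_pair[("T0", "T1")].cramers_v, 2) == 0.28
        assert round(by_pair[("T0", "T2")].cramers_v, 2) == 0.61
        assert round(by_pair[("T1", "T2")].cramers_v, 2) == 0.39
        assert all(r.significant for r in results)

    def test_amber_red_t1_t2(self):
        tab = table([[22, 125], [53, 49], [74, 28]], rows=("T0", "T1", "T2"),
                    cols=("amber", "red"))
        by_pair = {r.exposures: r for r in pairwise_decomposition(tab)}
        assert round(by_pair[("T1", "T2")].cramers_v, 2) == 0.21
        assert by_pair[("T1", "T2")].significant  # p = 0.002 < 0.0167

    def test_identical_rows_not_significant(self):
        tab = table([[10, 20], [10, 20], [10, 20]], rows=("T0", "T1", "T2"))
        for res in pairwise_decomposition(tab):
            assert res.chi2.p == pytest.approx(1)
            assert not res.significant

    def test_zero_marginal_subtable_flagged(self):
        tab = table([[0, 10], [0, 20], [5, 5]], rows=("T0", "T1", "T2"))
        by_pair = {r.exposures: r for r in pairwise_decomposition(tab)}
        assert by_pair[("T0", "T1")].chi2 is None
        assert math.isnan(by_pair[("T0", "T1")].cramers_v)
        assert by_pair[("T0", "T2")].chi2 is not None


class TestOddsRatio:
    def test_unit_table(self):
        res = odds_ratio(table([[1, 1], [1, 1]]))
        assert res.value == pytest.approx(1.0)

    def test_cross_product(self):
        # T2 (24, 28) over T1 (6, 49): (24*49)/(28*6) = 7.0
        res = odds_ratio(table([[24, 28], [6, 49]]))
        assert res.value == pytest.approx(7.0)
        assert not res.corrected

    def test_scale_invariance_narrows_ci(self):
        small = odds_ratio(table([[4, 6], [3, 8]]))
        big = odds_ratio(table([[40, 60], [30, 80]]))
        assert big.value == pytest.approx(small.value)
        assert (big.ci_high - big.ci_low) < (small.ci_high - small.ci_low)

    def test_zero_cell_gets_haldane_correction(self):
        res = odds_ratio(table([[0, 125], [24, 28]]))
        assert res.corrected
        assert res.value == pytest.approx((0.5 * 28.5) / (125.5 * 24.5))

    def test_zero_line_undefined(self):
        res = odds_ratio(table([[0, 0], [5, 7]]))
        assert not res.defined
        assert math.isnan(res.value)

    def test_woolf_ci_formula(self):
        res = odds_ratio(table([[24, 28], [6, 49]]))
        se = math.sqrt(1 / 24 + 1 / 28 + 1 / 6 + 1 / 49)
        assert res.ci_low == pytest.approx(7.0 * math.exp(-1.96 * se), rel=1e-3)
        assert res.ci_high == pytest.approx(7.0 * math.exp(1.96 * se), rel=1e-3)


class TestFullAnalysis:
    def test_case_control_all_on_study_counts(self):
        results = case_control_all(lifeguard_ventilation_counts())
        assert set(results) == {("green", "amber"), ("green", "red"), ("amber", "red")}
        overall = {pair: round(res.cramers_v, 2) for pair, res in results.items()}
        assert overall == {("green", "amber"): 0.24, ("green", "red"): 0.55,
                           ("amber", "red"): 0.50}
        assert results[("green", "red")].v_label == "Large"
        assert results[("amber", "red")].v_label == "Medium"

    def test_invariants_on_random_tables(self, rng):
        for _ in range(20):
            counts = rng.integers(1, 50, size=(3, 2))
            res = case_control(table(counts, rows=("T0", "T1", "T2")))
            assert 0 <= res.cramers_v <= 1
            for pw in res.pairwise:
                assert pw.chi2 is None or 0 <= pw.chi2.p <= 1
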