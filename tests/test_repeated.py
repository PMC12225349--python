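"""Repeated-measures machinery: routing, omnibus tests, effect sizes."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cprvent.events import ValidationError
from cprvent.repeated import (
    bonferroni,
    cohens_d_paired,
    compare,
    compare_variables,
    effect_size_label,
    friedman_bonferroni,
    friedman_exact_p,
    friedman_statistic,
    rm_anova_bonferroni,
    rosenthal_r,
    route_test,
    wilcoxon_exact_p,
    _rm_anova,
)


def friedman_oracle(mat):
    """Hand rank-sum Friedman chi-square (no ties assumed)."""
    n, k = mat.shape
    ranks = np.argsort(np.argsort(mat, axis=1), axis=1) + 1
    rank_sums = ranks.sum(axis=0)
    return 12.0 / (n * k * (k + 1)) * np.sum(rank_sums**2) - 3 * n * (k + 1)


class TestRouting:
    def test_skewed_data_routes_nonparametric(self, rng):
        mat = np.exp(rng.normal(0, 2.5, size=(10, 3))) ** 2
        # verify the premise: Shapiro rejects for this draw
        assert any(stats.shapiro(col).pvalue < 0.05 for col in mat.T)
        assert route_test(mat) == "nonparametric"

    def test_degenerate_ties_route_nonparametric(self):
        mat = np.tile([1.0, 2.0, 3.0], (6, 1))
        mat[:, 0] = 1.0  # constant column: normality untestable
        assert route_test(mat) == "nonparametric"

    def test_large_normal_draws_route_parametric_mostly(self, rng):
        hits = sum(
            route_test(rng.normal(50, 5, size=(80, 3))) == "parametric"
            for _ in range(100)
        )
        # each column passes Shapiro w.p. 0.95 -> all three ~0.857
        assert 70 <= hits <= 97

    def test_unequal_pairing_rejected(self):
        with pytest.raises(ValidationError):
            route_test({"T0": [1, 2, 3], "T1": [1, 2], "T2": [1, 2, 3]})


class TestEffectSizes:
    def test_label_bands(self):
        assert effect_size_label(0.19) == "Trivial"
        assert effect_size_label(0.2) == "Small"
        assert effect_size_label(0.5) == "Moderate"
        assert effect_size_label(0.8) == "Large"
        assert effect_size_label(1.29) == "Large"
        assert effect_size_label(1.3) == "Very large"

    def test_cohens_d_flags_zero_variance(self):
        x = np.array([1.0, 2.0, 3.0])
        d = cohens_d_paired(x, x)
        assert math.isnan(d.value)
        assert d.label == "Undefined"

    def test_cohens_d_unit_by_construction(self, rng):
        diff = rng.normal(0, 1, 30)
        diff = (diff - diff.mean()) / diff.std(ddof=1)  # mean 0, sd 1
        x = rng.normal(50, 5, 30)
        d = cohens_d_paired(x + diff + 1.0, x)  # differences: mean 1, sd 1
        assert d.value == pytest.approx(1.0)
        assert d.label == "Large"

    def test_rosenthal_r_formula(self):
        r = rosenthal_r(2.0, 20)
        assert r.value == pytest.approx(2 / math.sqrt(20))
        assert r.label == "Small"
        assert rosenthal_r(-2.0, 20).value == r.value  # sign-invariant
        assert rosenthal_r(0.0, 20).label == "Trivial"

    def test_bonferroni_monotone_and_capped(self, rng):
        for p in rng.uniform(0, 1, 50):
            adj = bonferroni(p)
            assert adj >= p
            assert adj <= 1


class TestFriedman:
    def test_identical_columns_degenerate(self):
        mat = np.tile([3.0, 1.0, 4.0, 1.0], (3, 1)).T
        res = friedman_bonferroni(mat)
        assert res.statistic == 0
        assert res.p == 1
        assert res.degenerate
        assert all(e.p_adjusted == 1 for e in res.pairwise)

    def test_strictly_ordered_n4_statistic_is_8(self):
        mat = np.array([[1, 2, 3], [4, 5, 6], [7, 8, 9], [1.5, 2.5, 3.5]])
        assert friedman_statistic(mat) == pytest.approx(8.0)

    def test_statistic_matches_hand_oracle(self, rng):
        mat = rng.normal(size=(8, 3))
        assert friedman_statistic(mat) == pytest.approx(friedman_oracle(mat))

    def test_monotone_transform_invariance(self, rng):
        mat = rng.normal(size=(7, 3))
        assert friedman_statistic(mat) == pytest.approx(
            friedman_statistic(np.exp(mat))
        )

    def test_exact_p_matches_naive_enumeration(self, rng):
        """Exhaustive permutation oracle, n=4 subjects, continuous data."""
        mat = rng.normal(size=(4, 3))
        observed = friedman_oracle(mat)
        perms = list(itertools.permutations(range(3)))
        hits = total = 0
        for assignment in itertools.product(perms, repeat=4):
            permuted = np.vstack([mat[i, list(p)] for i, p in enumerate(assignment)])
            hits += friedman_oracle(permuted) >= observed - 1e-12
            total += 1
        assert friedman_exact_p(mat) == pytest.approx(hits / total)

    def test_pairwise_carries_rosenthal_r(self, rng):
        mat = rng.normal(size=(10, 3)) + np.array([0, 1.0, 2.0])
        res = friedman_bonferroni(mat)
        assert res.family == "nonparametric"
        for entry in res.pairwise:
            assert entry.effect.kind == "rosenthal_r"
            assert 0 <= entry.effect.value
            assert entry.p_adjusted >= entry.p_raw


class TestWilcoxon:
    def test_exact_p_matches_sign_flip_enumeration(self, rng):
        """2^n sign-flip oracle on tie-free differences, n=5."""
        x = rng.normal(size=5)
        y = x + rng.normal(0.8, 1.0, size=5)
        diff = x - y
        ranks = stats.rankdata(np.abs(diff))
        w_obs = ranks[diff > 0].sum()
        total_rank = ranks.sum()
        ws = [
            sum(r for r, s in zip(ranks, signs) if s)
            for signs in itertools.product([False, True], repeat=5)
        ]
        mean_w = total_rank / 2
        p_oracle = np.mean([abs(w - mean_w) >= abs(w_obs - mean_w) - 1e-12 for w in ws])
        assert wilcoxon_exact_p(x, y) == pytest.approx(p_oracle)


class TestRmAnova:
    def test_identical_columns_degenerate(self):
        mat = np.tile([3.0, 1.0, 4.0, 1.0], (3, 1)).T
        res = rm_anova_bonferroni(mat)
        assert res.degenerate
        assert res.statistic == 0
        assert res.p == 1

    def test_location_invariance(self, rng):
        mat = rng.normal(size=(10, 3)) + np.array([0, 0.7, 1.2])
        a = rm_anova_bonferroni(mat)
        b = rm_anova_bonferroni(mat + 100.0)
        assert a.statistic == pytest.approx(b.statistic)
        assert a.p == pytest.approx(b.p)
        for ea, eb in zip(a.pairwise, b.pairwise):
            assert ea.effect.value == pytest.approx(eb.effect.value)

    def test_two_condition_f_equals_t_squared(self, rng):
        mat = rng.normal(size=(12, 2)) + np.array([0, 0.5])
        f, p_f = _rm_anova(mat)
        t_res = stats.ttest_rel(mat[:, 0], mat[:, 1])
        assert f == pytest.approx(t_res.statistic**2)
        assert p_f == pytest.approx(t_res.pvalue)

    def test_cross_check_against_pingouin(self, rng):
        pingouin = pytest.importorskip("pingouin")
        mat = rng.normal(size=(10, 3)) + np.array([0, 0.5, 1.0])
        f, p = _rm_anova(mat)
        frame = pd.DataFrame(
            {
                "y": mat.ravel(),
                "subject": np.repeat(np.arange(10), 3),
                "cond": np.tile(["T0", "T1", "T2"], 10),
            }
        )
        pg = pingouin.rm_anova(data=frame, dv="y", within="cond", subject="subject")
        assert f == pytest.approx(float(pg["F"].iloc[0]))
        assert p == pytest.approx(float(pg["p_unc"].iloc[0]))

    def test_pairwise_carries_cohens_d(self, rng):
        mat = rng.normal(size=(10, 3)) + np.array([0, 1.0, 2.0])
        res = rm_anova_bonferroni(mat)
        for entry in res.pairwise:
            assert entry.effect.kind == "cohens_d"


class TestCompareIntegration:
    def test_compare_routes_by_normality(self, rng):
        normal = rng.normal(50, 5, size=(30, 3))
        assert compare(normal).family in ("parametric", "nonparametric")
        skewed = np.exp(rng.normal(0, 2.5, size=(10, 3))) ** 2
        assert compare(skewed).family == "nonparametric"

    def test_compare_variables_pivots_by_pair(self, rng):
        rows = []
        for pair in ("P1", "P2", "P3", "P4", "P5"):
            for j, test in enumerate(("T0", "T1", "T2")):
                rows.append(
                    {"pair_id": pair, "test_id": test,
                     "cpr_quality": float(rng.normal(40 + 10 * j, 5))}
                )
        results = compare_variables(pd.DataFrame(rows), ["cpr_quality"])
        (res,) = results
        assert res.variable == "cpr_quality"
        assert len(res.pairwise) == 3
        assert {e.pair for e in res.pairwise} == {("T0", "T1"), ("T0", "T2"), ("T1", "T2")}

    def test_unbalanced_design_rejected(self):
        frame = pd.DataFrame(
            {"pair_id": ["P1", "P1", "P1", "P2"], "test_id": ["T0", "T1", "T2", "T0"],
             "x": [1.0, 2, 3, 4]}
        )
        with pytest.raises(ValidationError):
            compare_variables(frame, ["x"])
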