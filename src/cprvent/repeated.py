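"""Three-test repeated-measures comparisons with effect sizes.

Each quantitative session variable is measured at three exposure levels
(T0, T1, T2) on the same subjects (rescuer pairs by default), giving
k = 3 related samples.  The comparison machinery is normality-routed:

* if every column passes Shapiro-Wilk at alpha = 0.05, a one-way
  repeated-measures ANOVA is used, followed by pairwise paired t tests
  with Bonferroni correction (p x 3, capped at 1) and Cohen's d for
  paired data as the effect size;
* otherwise the Friedman test on within-subject ranks is used, followed
  by pairwise Wilcoxon signed-rank tests (normal approximation, Pratt
  zero handling) with the same Bonferroni correction and Rosenthal's
  r = |z| / sqrt(N) as the effect size.

Effect sizes carry the conventional magnitude labels: < 0.2 trivial,
0.2-0.5 small, 0.5-0.8 moderate, 0.8-1.3 large, >= 1.3 very large.

Rosenthal's N is, by default, the total number of observations across
the two related samples (2 x pairs); the literature is split, so
``rosenthal_n="n"`` switches to N = pairs.

For very small designs (n <= 6 subjects) an exact Friedman p-value is
available by enumerating all (k!)^n equally likely within-subject
orderings of the ranks.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.anova import AnovaRM

from .events import TEST_LABELS, ValidationError

PAIR_LABELS = (("T0", "T1"), ("T0", "T2"), ("T1", "T2"))

EFFECT_BANDS = (
    (0.2, "Trivial"),
    (0.5, "Small"),
    (0.8, "Moderate"),
    (1.3, "Large"),
    (math.inf, "Very large"),
)


def effect_size_label(value: float) -> str:
    """Magnitude label for d or r: <0.2 Trivial ... >=1.3 Very large."""
    if math.isnan(value):
        return "Undefined"
    for upper, label in EFFECT_BANDS:
        if abs(value) < upper:
            return label
    return "Very large"


@dataclass(frozen=True)
class EffectSize:
    value: float
    kind: Literal["cohens_d", "rosenthal_r"]
    label: str
    note: str = ""


@dataclass(frozen=True)
class PairwiseEntry:
    pair: tuple[str, str]
    statistic: float
    p_raw: float
    p_adjusted: float
    effect: EffectSize


@dataclass(frozen=True)
class ComparisonResult:
    variable: str
    family: Literal["parametric", "nonparametric"]
    omnibus_name: str
    statistic: float
    p: float
    pairwise: tuple[PairwiseEntry, ...] = ()
    degenerate: bool = False
    note: str = ""


def _as_matrix(samples: Mapping[str, Sequence[float]] | pd.DataFrame | np.ndarray) -> np.ndarray:
    """Coerce paired per-test samples to an (n_subjects, 3) matrix."""
    if isinstance(samples, pd.DataFrame):
        missing = [t for t in TEST_LABELS if t not in samples.columns]
        if missing:
            raise ValidationError(f"missing test column(s): {', '.join(missing)}")
        mat = samples[list(TEST_LABELS)].to_numpy(dtype=float)
    elif isinstance(samples, Mapping):
        lengths = {len(v) for v in samples.values()}
        if len(lengths) > 1:
            raise ValidationError("paired samples must have equal length per test")
        missing = [t for t in TEST_LABELS if t not in samples]
        if missing:
            raise ValidationError(f"missing test column(s): {', '.join(missing)}")
        mat = np.column_stack([np.asarray(samples[t], dtype=float) for t in TEST_LABELS])
    else:
        mat = np.asarray(samples, dtype=float)
    if mat.ndim != 2 or mat.shape[1] != len(TEST_LABELS):
        raise ValidationError(f"expected an (n, {len(TEST_LABELS)}) paired matrix")
    if np.isnan(mat).any():
        raise ValidationError("paired samples contain missing values")
    return mat


def bonferroni(p: float, m: int = 3) -> float:
    """p x m, capped at 1."""
    return min(1.0, p * m)


def route_test(
    samples: Mapping[str, Sequence[float]] | pd.DataFrame | np.ndarray,
    alpha: float = 0.05,
) -> Literal["parametric", "nonparametric"]:
    """Choose the test family by per-column Shapiro-Wilk normality.

    Parametric iff normality is not rejected for any test column at
    ``alpha``.  Degenerate columns (constant values, n < 3) make the
    Shapiro-Wilk statistic undefined and route to the nonparametric
    family.
    """
    mat = _as_matrix(samples)
    if mat.shape[0] < 3:
        return "nonparametric"
    for col in mat.T:
        if np.ptp(col) == 0:
            return "nonparametric"
        if stats.shapiro(col).pvalue < alpha:
            return "nonparametric"
    return "parametric"


# ---------------------------------------------------------------------------
# Effect sizes


def cohens_d_paired(x: Sequence[float], y: Sequence[float]) -> EffectSize:
    """Cohen's d for paired data: |mean(x - y)| / sd(x - y), sample sd.

    Undefined (NaN, flagged) when the differences have zero spread.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValidationError("paired samples must have equal length")
    diff = x - y
    sd = diff.std(ddof=1)
    if sd == 0:
        return EffectSize(float("nan"), "cohens_d", "Undefined", "zero-variance differences")
    d = abs(diff.mean()) / sd
    return EffectSize(float(d), "cohens_d", effect_size_label(d))


def rosenthal_r(z: float, n_obs: int) -> EffectSize:
    """Rosenthal's r = |z| / sqrt(N) for a rank-test normal approximation.

    ``n_obs`` is the total number of observations N; for a paired design
    the conventional choice is 2 x pairs.
    """
    if n_obs < 2:
        raise ValidationError(f"n_obs must be >= 2, got {n_obs}")
    r = abs(z) / math.sqrt(n_obs)
    return EffectSize(float(r), "rosenthal_r", effect_size_label(r))


# ---------------------------------------------------------------------------
# Friedman route


def _friedman_chi2(mat: np.ndarray) -> tuple[float, int]:
    """Tie-corrected Friedman chi-square via scipy; 0 when every row is tied."""
    k = mat.shape[1]
    if np.all(np.ptp(mat, axis=1) == 0):
        return 0.0, k - 1
    res = stats.friedmanchisquare(*mat.T)
    return float(res.statistic), k - 1


def friedman_statistic(mat: np.ndarray) -> float:
    """Friedman chi-square on within-subject ranks (tie-corrected)."""
    stat, _ = _friedman_chi2(np.asarray(mat, dtype=float))
    return stat


def friedman_exact_p(mat: np.ndarray) -> float:
    """Exact Friedman p by enumerating all (k!)^n within-subject orderings.

    Under the null every ordering of each subject's values is equally
    likely; the p-value is the fraction of orderings whose statistic is
    >= the observed one.  Feasible only for small n (k = 3, n <= ~8).
    """
    n, k = mat.shape
    if math.factorial(k) ** n > 2_000_000:
        raise ValidationError("exact Friedman enumeration infeasible for this n")
    observed, _ = _friedman_chi2(mat)
    perms = list(itertools.permutations(range(k)))
    count = 0
    total = 0
    for assignment in itertools.product(range(len(perms)), repeat=n):
        permuted = np.vstack([mat[i, list(perms[a])] for i, a in enumerate(assignment)])
        stat, _ = _friedman_chi2(permuted)
        count += stat >= observed - 1e-12
        total += 1
    return count / total


def _wilcoxon_z(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Wilcoxon signed-rank (normal approximation, Pratt zeros).

    Returns (W statistic, z, two-sided p); degenerate all-zero
    differences give (0, 0, 1).
    """
    if np.all(x == y):
        return 0.0, 0.0, 1.0
    res = stats.wilcoxon(x, y, zero_method="pratt", correction=False, method="approx")
    return float(res.statistic), float(res.zstatistic), float(res.pvalue)


def wilcoxon_exact_p(x: Sequence[float], y: Sequence[float]) -> float:
    """Exact two-sided signed-rank p-value (small n, no tied differences).

    Enumerative counterpart of the normal-approximation route used in
    :func:`friedman_bonferroni`; intended for small designs where the
    exhaustive null distribution is available.
    """
    res = stats.wilcoxon(np.asarray(x, float), np.asarray(y, float), method="exact")
    return float(res.pvalue)


def friedman_bonferroni(
    samples: Mapping[str, Sequence[float]] | pd.DataFrame | np.ndarray,
    *,
    variable: str = "",
    rosenthal_n: Literal["2n", "n"] = "2n",
    exact: bool = False,
) -> ComparisonResult:
    """Friedman omnibus plus Bonferroni-corrected pairwise Wilcoxon tests.

    Pairwise p-values are multiplied by 3 and capped at 1; each pairwise
    entry carries Rosenthal's r computed from the Wilcoxon z.  With
    ``exact=True`` (small n only) the omnibus p comes from the exhaustive
    within-subject permutation distribution instead of the chi-square
    approximation.
    """
    mat = _as_matrix(samples)
    n = mat.shape[0]
    if n < 2:
        raise ValidationError("need at least 2 subjects")

    degenerate = bool(np.all(np.ptp(mat, axis=1) == 0))
    if degenerate:
        statistic, p = 0.0, 1.0
    else:
        statistic, _ = _friedman_chi2(mat)
        if exact:
            p = friedman_exact_p(mat)
        else:
            p = float(stats.chi2.sf(statistic, mat.shape[1] - 1))

    n_obs = 2 * n if rosenthal_n == "2n" else n
    pairwise = []
    for a, b in PAIR_LABELS:
        ia, ib = TEST_LABELS.index(a), TEST_LABELS.index(b)
        w, z, p_raw = _wilcoxon_z(mat[:, ia], mat[:, ib])
        pairwise.append(
            PairwiseEntry(
                pair=(a, b),
                statistic=w,
                p_raw=p_raw,
                p_adjusted=bonferroni(p_raw),
                effect=rosenthal_r(z, n_obs),
            )
        )
    return ComparisonResult(
        variable=variable,
        family="nonparametric",
        omnibus_name="friedman",
        statistic=statistic,
        p=p,
        pairwise=tuple(pairwise),
        degenerate=degenerate,
        note="all-tied data" if degenerate else "",
    )


# ---------------------------------------------------------------------------
# RM-ANOVA route


def _rm_anova(mat: np.ndarray) -> tuple[float, float]:
    """One-way repeated-measures F and p via statsmodels AnovaRM."""
    n, k = mat.shape
    frame = pd.DataFrame(
        {
            "value": mat.ravel(),
            "subject": np.repeat(np.arange(n), k),
            "condition": np.tile(np.array(TEST_LABELS[:k]), n),
        }
    )
    table = AnovaRM(frame, "value", "subject", within=["condition"]).fit().anova_table
    return float(table["F Value"].iloc[0]), float(table["Pr > F"].iloc[0])


def rm_anova_bonferroni(
    samples: Mapping[str, Sequence[float]] | pd.DataFrame | np.ndarray,
    *,
    variable: str = "",
) -> ComparisonResult:
    """Repeated-measures ANOVA plus Bonferroni-corrected paired t tests.

    Each pairwise entry carries Cohen's d for paired data.  Data with no
    within-subject variance at all are flagged degenerate (F = 0, p = 1).
    """
    mat = _as_matrix(samples)
    if mat.shape[0] < 2:
        raise ValidationError("need at least 2 subjects")

    degenerate = bool(np.all(np.ptp(mat, axis=1) == 0))
    if degenerate:
        statistic, p = 0.0, 1.0
    else:
        statistic, p = _rm_anova(mat)

    pairwise = []
    for a, b in PAIR_LABELS:
        ia, ib = TEST_LABELS.index(a), TEST_LABELS.index(b)
        x, y = mat[:, ia], mat[:, ib]
        if np.ptp(x - y) == 0 and np.all(x == y):
            t_stat, p_raw = 0.0, 1.0
        else:
            t_res = stats.ttest_rel(x, y)
            t_stat, p_raw = float(t_res.statistic), float(t_res.pvalue)
            if math.isnan(t_stat):  # zero-variance non-zero differences
                t_stat, p_raw = math.inf, 0.0
        pairwise.append(
            PairwiseEntry(
                pair=(a, b),
                statistic=t_stat,
                p_raw=p_raw,
                p_adjusted=bonferroni(p_raw),
                effect=cohens_d_paired(x, y),
            )
        )
    return ComparisonResult(
        variable=variable,
        family="parametric",
        omnibus_name="rm_anova",
        statistic=statistic,
        p=p,
        pairwise=tuple(pairwise),
        degenerate=degenerate,
        note="no within-subject variance" if degenerate else "",
    )


def compare(
    samples: Mapping[str, Sequence[float]] | pd.DataFrame | np.ndarray,
    *,
    variable: str = "",
    alpha: float = 0.05,
    rosenthal_n: Literal["2n", "n"] = "2n",
) -> ComparisonResult:
    """Normality-routed comparison: RM-ANOVA or Friedman as appropriate."""
    family = route_test(samples, alpha)
    if family == "parametric":
        return rm_anova_bonferroni(samples, variable=variable)
    return friedman_bonferroni(samples, variable=variable, rosenthal_n=rosenthal_n)


def compare_variables(
    metrics: pd.DataFrame,
    variables: Sequence[str],
    *,
    unit: Literal["pair", "participant"] = "pair",
    rosenthal_n: Literal["2n", "n"] = "2n",
) -> list[ComparisonResult]:
    """Run the routed comparison for each variable of a session-metrics frame.

    ``metrics`` must contain ``pair_id``, ``test_id`` and the requested
    variable columns (one row per session).  The unit of analysis is the
    rescuer pair; ``unit="participant"`` is accepted for data recorded
    per participant (the pivot key is whatever identifier column the
    frame carries).
    """
    key = "pair_id" if unit == "pair" else "participant_id"
    if key not in metrics.columns:
        raise ValidationError(f"metrics frame lacks column {key!r}")
    results = []
    for var in variables:
        wide = metrics.pivot(index=key, columns="test_id", values=var)
        if wide.isna().any().any():
            raise ValidationError(f"unbalanced design for {var!r}: missing cells")
        results.append(compare(wide, variable=var, rosenthal_n=rosenthal_n))
    return results


def comparison_to_dict(result: ComparisonResult) -> dict:
    """JSON-serialisable view of a ComparisonResult."""
    return {
        "variable": result.variable,
        "family": result.family,
        "omnibus": {
            "name": result.omnibus_name,
            "statistic": result.statistic,
            "p": result.p,
        },
        "degenerate": result.degenerate,
        "note": result.note,
        "pairwise": [
            {
                "pair": f"{e.pair[0]} vs {e.pair[1]}",
                "statistic": e.statistic,
                "p_raw": e.p_raw,
                "p_adjusted": e.p_adjusted,
                "effect_size": {
                    "value": None if math.isnan(e.effect.value) else e.effect.value,
                    "kind": e.effect.kind,
                    "label": e.effect.label,
                    "note": e.effect.note,
                },
            }
            for e in result.pairwise
        ],
    }
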