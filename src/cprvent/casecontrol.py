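"""Case-control analysis of ventilation categories across training exposure.

The analysis sample is the pooled set of effective ventilations from all
tests, each labelled with its colour category (green/amber/red) and the
rescuer's training exposure at the time it was performed (T0 = no
training, T1 = one session, T2 = two sessions).  For each pair of
categories a 3x2 contingency table (exposure x category) is analysed:

* Pearson chi-square WITHOUT continuity correction, df = (r-1)(c-1);
* Cramer's V = sqrt(chi2 / (N * (min(r, c) - 1))), labelled by the
  conventional bands 0.1-0.3 small, 0.3-0.5 medium, >= 0.5 large;
* pairwise 2x2 decomposition over exposure pairs, significance declared
  when the raw p falls below the Bonferroni-adjusted threshold
  alpha / 3 = 0.0167;
* odds ratios via the cross-product with Woolf (log-normal) 95%
  confidence intervals, applying the Haldane-Anscombe +0.5 correction
  to every cell when any cell is zero (flagged in the output).

No Yates correction is applied anywhere: the uncorrected statistic is
the one whose effect sizes match the standard Cramer's V definition on
small tables, and corrected and uncorrected versions differ materially
at these sample sizes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency

from .events import ContingencyTable, TEST_LABELS, ValidationError

PAIRWISE_ALPHA = 0.05 / 3  # Bonferroni-adjusted threshold for 3 comparisons

CATEGORY_PAIRS = (("green", "amber"), ("green", "red"), ("amber", "red"))
EXPOSURE_PAIRS = (("T0", "T1"), ("T0", "T2"), ("T1", "T2"))

V_BANDS = ((0.1, "Negligible"), (0.3, "Small"), (0.5, "Medium"), (math.inf, "Large"))


def cramers_v_label(v: float) -> str:
    """Magnitude label: 0.1-0.3 Small, 0.3-0.5 Medium, >=0.5 Large.

    Values below 0.1 fall outside the named bands and are reported as
    "Negligible" rather than rounded up to Small.
    """
    for upper, label in V_BANDS:
        if v < upper:
            return label
    return "Large"


@dataclass(frozen=True)
class Chi2Result:
    statistic: float
    df: int
    p: float
    low_expected: bool  # any expected cell count < 5


@dataclass(frozen=True)
class OddsRatioResult:
    """Cross-product OR with Woolf 95% CI.

    ``orientation`` records which row/column served as reference;
    ``corrected`` flags the Haldane-Anscombe +0.5 adjustment.
    """

    value: float
    ci_low: float
    ci_high: float
    corrected: bool
    orientation: str
    defined: bool = True


@dataclass(frozen=True)
class PairwiseCaseControl:
    exposures: tuple[str, str]
    table: ContingencyTable
    chi2: Chi2Result | None
    cramers_v: float
    v_label: str
    significant: bool
    odds_ratio: OddsRatioResult | None
    note: str = ""


@dataclass(frozen=True)
class ContingencyResult:
    """Full analysis of one category-pair table across the three exposures."""

    table: ContingencyTable
    chi2: Chi2Result
    cramers_v: float
    v_label: str
    pairwise: tuple[PairwiseCaseControl, ...]


def build_tables(
    counts: pd.DataFrame | Mapping[str, Mapping[str, int]],
) -> dict[tuple[str, str], ContingencyTable]:
    """Build the three category-pair tables from per-test category counts.

    ``counts`` is indexed by test label (T0/T1/T2) with columns
    green/amber/red — the output shape of ``classify_all``.  Returns one
    3x2 table (exposures x categories) per unordered category pair.
    """
    frame = pd.DataFrame(counts)
    missing = [t for t in TEST_LABELS if t not in frame.index]
    if missing:
        raise ValidationError(f"missing exposure row(s): {', '.join(missing)}")
    tables = {}
    for a, b in CATEGORY_PAIRS:
        for col in (a, b):
            if col not in frame.columns:
                raise ValidationError(f"missing category column {col!r}")
        tables[(a, b)] = ContingencyTable(
            rows=TEST_LABELS,
            cols=(a, b),
            counts=frame.loc[list(TEST_LABELS), [a, b]].to_numpy(),
        )
    return tables


def chi_square(table: ContingencyTable) -> Chi2Result:
    """Pearson chi-square without continuity correction.

    Raises when a marginal row or column is all zero (the statistic is
    undefined); flags (not rejects) tables with expected counts < 5.
    """
    if table.n == 0:
        raise ValidationError("empty table: N = 0")
    if np.any(table.row_totals == 0) or np.any(table.col_totals == 0):
        raise ValidationError("zero marginal row/column: chi-square undefined")
    statistic, p, df, expected = chi2_contingency(table.counts, correction=False)
    return Chi2Result(
        statistic=float(statistic),
        df=int(df),
        p=float(p),
        low_expected=bool(np.any(expected < 5)),
    )


def cramers_v(table: ContingencyTable) -> tuple[float, str]:
    """Cramer's V = sqrt(chi2 / (N * (min(r, c) - 1))) with its label."""
    res = chi_square(table)
    r, c = table.counts.shape
    v = math.sqrt(res.statistic / (table.n * (min(r, c) - 1)))
    return v, cramers_v_label(v)


def odds_ratio(
    table: ContingencyTable,
    *,
    reference_row: str | None = None,
    reference_col: str | None = None,
) -> OddsRatioResult:
    """Cross-product odds ratio of a 2x2 table with Woolf 95% CI.

    The cell layout is oriented so the reference row/column (by default
    the last of each: higher exposure and second category) lands in the
    denominator; the orientation string records the choice.  When any
    cell is zero the Haldane-Anscombe +0.5 correction is applied to all
    cells (flagged); if an entire row or column of the uncorrected table
    is zero the OR is undefined.
    """
    if table.counts.shape != (2, 2):
        raise ValidationError("odds ratio requires a 2x2 table")
    rows = list(table.rows)
    cols = list(table.cols)
    if reference_row and reference_row != rows[-1]:
        rows.reverse()
    if reference_col and reference_col != cols[-1]:
        cols.reverse()
    counts = ContingencyTable(tuple(rows), tuple(cols), table.to_frame().loc[rows, cols].to_numpy()).counts
    a, b = counts[0]
    c, d = counts[1]
    orientation = f"odds of {cols[0]} vs {cols[1]}, {rows[0]} relative to {rows[1]}"
    if (a == 0 and b == 0) or (c == 0 and d == 0) or (a == 0 and c == 0) or (b == 0 and d == 0):
        return OddsRatioResult(
            value=float("nan"),
            ci_low=float("nan"),
            ci_high=float("nan"),
            corrected=False,
            orientation=orientation,
            defined=False,
        )
    corrected = bool(np.any(counts == 0))
    if corrected:
        a, b, c, d = (x + 0.5 for x in (a, b, c, d))
    value = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return OddsRatioResult(
        value=float(value),
        ci_low=float(value * math.exp(-1.959963984540054 * se)),
        ci_high=float(value * math.exp(1.959963984540054 * se)),
        corrected=corrected,
        orientation=orientation,
    )


def pairwise_decomposition(
    table: ContingencyTable,
    *,
    alpha: float = PAIRWISE_ALPHA,
    reference_row: str = "T0",
) -> tuple[PairwiseCaseControl, ...]:
    """Decompose a 3x2 exposure table into the three 2x2 exposure pairs.

    Each sub-table gets an uncorrected chi-square, Cramer's V and an
    odds ratio; significance is declared iff the raw p is below the
    Bonferroni-adjusted threshold (0.0167 for three comparisons).
    Sub-tables with a zero marginal are flagged undefined rather than
    dropped.
    """
    if len(table.rows) != 3:
        raise ValidationError("pairwise decomposition requires 3 exposure rows")
    results = []
    for pair in EXPOSURE_PAIRS:
        sub = table.subtable(list(pair))
        ref = reference_row if reference_row in pair else pair[0]
        try:
            chi2 = chi_square(sub)
            v, v_label = cramers_v(sub)
            significant = chi2.p < alpha
            note = ""
        except ValidationError as exc:
            results.append(
                PairwiseCaseControl(
                    exposures=pair,
                    table=sub,
                    chi2=None,
                    cramers_v=float("nan"),
                    v_label="Undefined",
                    significant=False,
                    odds_ratio=None,
                    note=str(exc),
                )
            )
            continue
        results.append(
            PairwiseCaseControl(
                exposures=pair,
                table=sub,
                chi2=chi2,
                cramers_v=v,
                v_label=v_label,
                significant=significant,
                odds_ratio=odds_ratio(sub, reference_row=ref),
                note=note,
            )
        )
    return tuple(results)


def case_control(table: ContingencyTable, *, alpha: float = PAIRWISE_ALPHA) -> ContingencyResult:
    """Full analysis of one 3x2 exposure-by-category table."""
    chi2 = chi_square(table)
    v, v_label = cramers_v(table)
    return ContingencyResult(
        table=table,
        chi2=chi2,
        cramers_v=v,
        v_label=v_label,
        pairwise=pairwise_decomposition(table, alpha=alpha),
    )


def case_control_all(
    counts: pd.DataFrame | Mapping[str, Mapping[str, int]],
    *,
    alpha: float = PAIRWISE_ALPHA,
) -> dict[tuple[str, str], ContingencyResult]:
    """Run the case-control analysis for every category pair."""
    return {
        pair: case_control(tab, alpha=alpha) for pair, tab in build_tables(counts).items()
    }


def _or_to_dict(o: OddsRatioResult | None) -> dict | None:
    if o is None:
        return None
    return {
        "value": None if math.isnan(o.value) else o.value,
        "ci95": None if math.isnan(o.value) else [o.ci_low, o.ci_high],
        "haldane_anscombe": o.corrected,
        "orientation": o.orientation,
        "defined": o.defined,
    }


def result_to_dict(result: ContingencyResult) -> dict:
    """JSON-serialisable view of a ContingencyResult."""
    return {
        "rows": list(result.table.rows),
        "cols": list(result.table.cols),
        "counts": result.table.counts.tolist(),
        "chi_square": {
            "statistic": result.chi2.statistic,
            "df": result.chi2.df,
            "p": result.chi2.p,
            "low_expected": result.chi2.low_expected,
        },
        "cramers_v": result.cramers_v,
        "v_label": result.v_label,
        "pairwise": [
            {
                "exposures": list(p.exposures),
                "counts": p.table.counts.tolist(),
                "chi_square": None
                if p.chi2 is None
                else {"statistic": p.chi2.statistic, "df": p.chi2.df, "p": p.chi2.p},
                "cramers_v": None if math.isnan(p.cramers_v) else p.cramers_v,
                "v_label": p.v_label,
                "significant_at_0.0167": p.significant,
                "odds_ratio": _or_to_dict(p.odds_ratio),
                "note": p.note,
            }
            for p in result.pairwise
        ],
    }
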