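"""Human-readable report rendering.

Markdown tables in the shape practitioners expect from this kind of
study: a session-variable table with "median (Q1-Q3)" cells and the
pairwise p-values with effect-size labels, and contingency blocks with
"N (%)" cells.  Percentages are rendered to 0 decimal places and effect
sizes to 2, matching conventional display precision; machine outputs
(CSV/JSON) keep full precision.
"""

from __future__ import annotations

import math
from typing import Mapping, Sequence

import pandas as pd

from .casecontrol import ContingencyResult
from .events import TEST_LABELS
from .repeated import ComparisonResult

VARIABLE_LABELS = {
    "mean_depth": "Mean depth (mm)",
    "mean_rate": "Mean rate (CC/min)",
    "no_flow_time_s": "No flow time (s)",
    "no_flow_pct": "No flow time (%)",
    "n_ventilations": "Number of total V",
    "pct_effective": "Effective V (%)",
    "mean_volume": "Mean volume (mL)",
    "mean_insufflation_time": "Mean insufflation time (s)",
    "cc_quality": "CC quality (%)",
    "v_quality": "V quality (%)",
    "cpr_quality": "CPR quality (%)",
}


def _fmt(value: float, decimals: int) -> str:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return "-"
    return f"{value:.{decimals}f}"


def _median_iqr_cell(median: float, q1: float, q3: float, decimals: int) -> str:
    return f"{_fmt(median, decimals)} ({_fmt(q1, decimals)}-{_fmt(q3, decimals)})"


def _markdown_table(header: Sequence[str], rows: Sequence[Sequence[str]]) -> str:
    lines = ["| " + " | ".join(header) + " |", "|" + "|".join("---" for _ in header) + "|"]
    lines += ["| " + " | ".join(row) + " |" for row in rows]
    return "\n".join(lines)


def render_session_table(
    summary: pd.DataFrame,
    comparisons: Mapping[str, ComparisonResult] | None = None,
    decimals: int = 0,
) -> str:
    """Render the per-test summary (output of ``summarize_group``).

    One row per variable, "median (Q1-Q3)" per test, plus — when
    comparisons are supplied — a column of Bonferroni-adjusted pairwise
    p-values with effect sizes, e.g. ``T0 vs T1 = 0.016 (0.88 Large)``.
    """
    comparisons = comparisons or {}
    header = ["Variable"] + [f"{t} median (Q1-Q3)" for t in TEST_LABELS] + ["Pairwise p (effect)"]
    rows = []
    for var in summary.index:
        dec = 2 if var == "mean_insufflation_time" else decimals
        cells = [VARIABLE_LABELS.get(var, var)]
        for t in TEST_LABELS:
            cells.append(
                _median_iqr_cell(
                    summary.loc[var, (t, "median")],
                    summary.loc[var, (t, "q1")],
                    summary.loc[var, (t, "q3")],
                    dec,
                )
            )
        comp = comparisons.get(var)
        if comp is None:
            cells.append("-")
        else:
            parts = []
            for entry in comp.pairwise:
                eff = entry.effect
                eff_txt = (
                    f" ({_fmt(eff.value, 2)} {eff.label})"
                    if not math.isnan(eff.value)
                    else ""
                )
                parts.append(
                    f"{entry.pair[0]} vs {entry.pair[1]} = {_fmt(entry.p_adjusted, 3)}{eff_txt}"
                )
            cells.append("; ".join(parts))
        rows.append(cells)
    return _markdown_table(header, rows)


def render_case_control(results: Mapping[tuple[str, str], ContingencyResult]) -> str:
    """Render the case-control blocks with "N (%)" cells.

    Percentages are within-column (share of that category's total across
    exposure levels).  Each block lists the overall chi-square p and
    Cramer's V, then the pairwise decomposition with significance at the
    Bonferroni-adjusted threshold 0.0167 and odds ratios with 95% CIs.
    """
    blocks = []
    for (cat_a, cat_b), res in results.items():
        tab = res.table
        col_totals = tab.col_totals
        header = ["Exposure"] + [
            f"{c.capitalize()} ventilation (N = {int(n)})" for c, n in zip(tab.cols, col_totals)
        ]
        rows = []
        for i, row_label in enumerate(tab.rows):
            cells = [row_label]
            for j in range(len(tab.cols)):
                count = int(tab.counts[i, j])
                pct = 100.0 * count / col_totals[j] if col_totals[j] else 0.0
                cells.append(f"{count} ({pct:.0f}%)")
            rows.append(cells)
        lines = [
            f"### {cat_a.capitalize()} vs {cat_b.capitalize()}",
            "",
            _markdown_table(header, rows),
            "",
            f"Overall: chi-square = {res.chi2.statistic:.2f}, df = {res.chi2.df}, "
            f"p = {res.chi2.p:.3g}; Cramer's V = {res.cramers_v:.2f} ({res.v_label})",
            "",
        ]
        for pw in res.pairwise:
            if pw.chi2 is None:
                lines.append(f"- {pw.exposures[0]} vs {pw.exposures[1]}: undefined ({pw.note})")
                continue
            star = " *" if pw.significant else ""
            or_txt = ""
            if pw.odds_ratio is not None and pw.odds_ratio.defined:
                o = pw.odds_ratio
                flag = ", +0.5 correction" if o.corrected else ""
                or_txt = f"; OR = {o.value:.2f} ({o.ci_low:.2f}-{o.ci_high:.2f}{flag})"
            lines.append(
                f"- {pw.exposures[0]} vs {pw.exposures[1]}: p = {pw.chi2.p:.3g}{star}, "
                f"V = {pw.cramers_v:.2f} ({pw.v_label}){or_txt}"
            )
        lines.append("")
        blocks.append("\n".join(lines))
    note = (
        "\\* significant at the Bonferroni-adjusted threshold p < 0.0167 (0.05/3). "
        "N: absolute frequency; (%): share of the category total."
    )
    return "\n".join(blocks) + note + "\n"
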