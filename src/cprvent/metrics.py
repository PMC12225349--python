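"""Per-test session summaries and composite CPR quality scores.

Composite scores (all percentages in [0, 100]):

* compression quality = mean of the percentages of compressions with
  correct depth, correct recoil and correct rate;
* ventilation quality = percentage of effective ventilations classified
  green (volume 500-600 mL and insufflation time 0.85-1.15 s);
* CPR quality = (compression quality + ventilation quality) / 2.

"Correct rate" is ambiguous between a per-compression judgement and a
session-level one, so both are offered: ``rate_mode="per-compression"``
(default) scores each compression's instantaneous rate against the
guideline band of 100-120/min, while ``rate_mode="session-mean"``
scores 100 if the session's mean rate lies in the band and 0 otherwise.

No-flow time is the part of the test with no compression activity: the
session duration minus the union of per-compression occupancy intervals,
where a compression at instantaneous rate r occupies 60/r seconds.  It
is reported both in seconds and as a percentage of the test duration.

Group summaries use the median and interquartile range with the
inclusive linear-interpolation quartile convention (numpy's default),
so reported IQRs are exactly reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .classify import ClassificationThresholds, DEFAULT_THRESHOLDS, classify
from .events import SessionRecord, ValidationError, VentilationEvent

RATE_BAND = (100.0, 120.0)  # guideline compressions/min

SUMMARY_VARIABLES = [
    "mean_depth",
    "mean_rate",
    "no_flow_time_s",
    "no_flow_pct",
    "n_ventilations",
    "pct_effective",
    "mean_volume",
    "mean_insufflation_time",
    "cc_quality",
    "v_quality",
    "cpr_quality",
]


def _check_pct(value: float, name: str) -> float:
    if not 0.0 <= value <= 100.0:
        raise ValidationError(f"{name} must be in [0, 100], got {value}")
    return float(value)


def cc_quality(
    pct_correct_depth: float,
    pct_correct_recoil: float,
    pct_correct_rate: float,
) -> float:
    """Compression quality: mean of the three per-component percentages."""
    return (
        _check_pct(pct_correct_depth, "pct_correct_depth")
        + _check_pct(pct_correct_recoil, "pct_correct_recoil")
        + _check_pct(pct_correct_rate, "pct_correct_rate")
    ) / 3.0


def v_quality(
    events: Sequence[VentilationEvent],
    thresholds: ClassificationThresholds = DEFAULT_THRESHOLDS,
) -> float:
    """Ventilation quality: percentage of green ventilations.

    Defined as 0 for an empty sample (no effective ventilations).
    """
    events = [ev for ev in events if ev.effective]
    if not events:
        return 0.0
    n_green = sum(1 for ev in events if classify(ev, thresholds).label == "green")
    return 100.0 * n_green / len(events)


def cpr_quality(cc: float, v: float) -> float:
    """Overall CPR quality: mean of compression and ventilation quality."""
    return (_check_pct(cc, "cc quality") + _check_pct(v, "v quality")) / 2.0


@dataclass(frozen=True)
class SessionMetrics:
    """Summary of one session; compression-derived fields are NaN when the
    session contains no compressions."""

    pair_id: str
    test_id: str
    mean_depth: float
    mean_rate: float
    no_flow_time_s: float
    no_flow_pct: float
    n_ventilations: int
    pct_effective: float
    mean_volume: float
    mean_insufflation_time: float
    cc_quality: float
    v_quality: float
    cpr_quality: float


def _no_flow_ms(record: SessionRecord) -> float:
    """Session duration minus the union of compression-occupancy intervals."""
    intervals = sorted(
        (cp.t_start, min(cp.t_start + cp.occupied_ms, record.duration))
        for cp in record.compressions
    )
    occupied = 0.0
    current_end = -math.inf
    for start, end in intervals:
        if start > current_end:
            occupied += end - start
            current_end = end
        elif end > current_end:
            occupied += end - current_end
            current_end = end
    return record.duration - occupied


def summarize_session(
    record: SessionRecord,
    thresholds: ClassificationThresholds = DEFAULT_THRESHOLDS,
    *,
    rate_mode: str = "per-compression",
) -> SessionMetrics:
    """Compute the per-session summary row.

    Ventilation means are over effective ventilations only; the
    ventilation count is the effective count, matching the inclusion
    rule of the analysis sample.
    """
    if rate_mode not in ("per-compression", "session-mean"):
        raise ValidationError(f"unknown rate_mode {rate_mode!r}")

    comps = record.compressions
    if comps:
        depths = np.array([c.depth for c in comps])
        rates = np.array([c.instantaneous_rate for c in comps])
        mean_depth = float(depths.mean())
        mean_rate = float(rates.mean())
        pct_depth = 100.0 * np.mean([c.correct_depth for c in comps])
        pct_recoil = 100.0 * np.mean([c.correct_recoil for c in comps])
        if rate_mode == "per-compression":
            pct_rate = 100.0 * np.mean([c.correct_rate for c in comps])
        else:
            pct_rate = 100.0 if RATE_BAND[0] <= mean_rate <= RATE_BAND[1] else 0.0
        cc = cc_quality(pct_depth, pct_recoil, pct_rate)
    else:
        mean_depth = mean_rate = float("nan")
        cc = float("nan")

    effective = record.effective_ventilations
    n_total = len(record.ventilations)
    pct_effective = 100.0 * len(effective) / n_total if n_total else 0.0
    if effective:
        mean_volume = float(np.mean([ev.volume for ev in effective]))
        mean_time = float(np.mean([ev.insufflation_s for ev in effective]))
    else:
        mean_volume = mean_time = float("nan")

    v = v_quality(effective, thresholds)
    cpr = cpr_quality(cc, v) if not math.isnan(cc) else float("nan")

    no_flow_ms = _no_flow_ms(record)
    return SessionMetrics(
        pair_id=record.pair_id,
        test_id=record.test_id,
        mean_depth=mean_depth,
        mean_rate=mean_rate,
        no_flow_time_s=no_flow_ms / 1000.0,
        no_flow_pct=100.0 * no_flow_ms / record.duration,
        n_ventilations=len(effective),
        pct_effective=pct_effective,
        mean_volume=mean_volume,
        mean_insufflation_time=mean_time,
        cc_quality=cc,
        v_quality=v,
        cpr_quality=cpr,
    )


def metrics_frame(metrics: Iterable[SessionMetrics]) -> pd.DataFrame:
    """Stack session summaries into one row per (pair, test)."""
    return pd.DataFrame([vars(m) for m in metrics])


def summarize_group(
    metrics: Iterable[SessionMetrics],
    variables: Sequence[str] = tuple(SUMMARY_VARIABLES),
) -> pd.DataFrame:
    """Median and IQR (Q1-Q3) per variable per test.

    Returns a frame indexed by variable with a (test, statistic)
    MultiIndex on the columns, statistic in {median, q1, q3}.  Raises if
    any test label present has no sessions for a requested variable.
    """
    frame = metrics_frame(metrics)
    if frame.empty:
        raise ValidationError("no session metrics to summarize")
    pieces: dict[tuple[str, str], dict[str, float]] = {}
    for test_id, group in frame.groupby("test_id", sort=True):
        for var in variables:
            values = group[var].to_numpy(dtype=float)
            values = values[~np.isnan(values)]
            if values.size == 0:
                raise ValidationError(f"no data for {var!r} in test {test_id}")
            q1, med, q3 = np.percentile(values, [25, 50, 75])
            pieces.setdefault((str(test_id), "median"), {})[var] = med
            pieces.setdefault((str(test_id), "q1"), {})[var] = q1
            pieces.setdefault((str(test_id), "q3"), {})[var] = q3
    out = pd.DataFrame(pieces).loc[list(variables)]
    out.columns = pd.MultiIndex.from_tuples(out.columns, names=["test", "stat"])
    return out.sort_index(axis=1)
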