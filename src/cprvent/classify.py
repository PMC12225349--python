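"""Three-tier (green/amber/red) classification of bag-mask ventilations.

A ventilation is judged on two axes jointly: insufflated volume and
insufflation time.  *Green* ventilations sit inside the reference bands
(volume 500-600 mL and insufflation time 0.85-1.15 s, i.e. close to the
guideline target of ~1 s); *amber* ventilations deviate slightly but stay
within a wider tolerance box (400-700 mL and 0.55-1.45 s); *red*
ventilations fall outside the tolerance box on either axis.

All interval bounds are closed.  The red rules are strict inequalities
(volume < 400 or > 700 mL, time < 0.55 or > 1.45 s), so a value exactly
on an amber boundary is amber, never red; green bounds are inclusive for
symmetry.  The rules are evaluated with green-first precedence: green,
then red, else amber — the three outcomes partition the (volume, time)
plane.

Thresholds are data, not code: alternative guideline bands load from a
small JSON file (see :meth:`ClassificationThresholds.from_json`).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .events import SessionRecord, TEST_LABELS, ValidationError, VentilationEvent

CATEGORIES = ("green", "amber", "red")


@dataclass(frozen=True)
class Interval:
    """A closed interval [lower, upper]."""

    lower: float
    upper: float

    def __post_init__(self) -> None:
        if self.lower > self.upper:
            raise ValidationError(f"interval lower {self.lower} > upper {self.upper}")

    def contains(self, x: float) -> bool:
        return self.lower <= x <= self.upper

    def covers(self, other: "Interval") -> bool:
        return self.lower <= other.lower and other.upper <= self.upper


def _as_interval(value: Interval | tuple[float, float]) -> Interval:
    if isinstance(value, Interval):
        return value
    return Interval(*value)


@dataclass(frozen=True)
class ClassificationThresholds:
    """Green and amber bands for volume (mL) and insufflation time (s).

    Invariant: the green box is nested inside the amber box on both axes,
    so the green/amber/red rules partition the plane.
    """

    green_vol: Interval = field(default=Interval(500.0, 600.0))
    green_time: Interval = field(default=Interval(0.85, 1.15))
    amber_vol: Interval = field(default=Interval(400.0, 700.0))
    amber_time: Interval = field(default=Interval(0.55, 1.45))

    def __post_init__(self) -> None:
        for name in ("green_vol", "green_time", "amber_vol", "amber_time"):
            object.__setattr__(self, name, _as_interval(getattr(self, name)))
        if not self.amber_vol.covers(self.green_vol):
            raise ValidationError("green volume band must lie within the amber band")
        if not self.amber_time.covers(self.green_time):
            raise ValidationError("green time band must lie within the amber band")

    @classmethod
    def from_json(cls, path: str | Path) -> "ClassificationThresholds":
        """Load bands from JSON: ``{"green_vol": [500, 600], ...}``."""
        payload = json.loads(Path(path).read_text(encoding="utf-8"))
        kwargs = {
            key: Interval(*payload[key])
            for key in ("green_vol", "green_time", "amber_vol", "amber_time")
            if key in payload
        }
        return cls(**kwargs)

    def to_json(self, path: str | Path) -> None:
        payload = {
            key: [getattr(self, key).lower, getattr(self, key).upper]
            for key in ("green_vol", "green_time", "amber_vol", "amber_time")
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n", encoding="utf-8")


DEFAULT_THRESHOLDS = ClassificationThresholds()


@dataclass(frozen=True)
class VentilationCategory:
    """The assigned colour label plus the rule that fired."""

    label: str
    reason: str


def classify_volume_time(
    volume: float,
    time_s: float,
    thresholds: ClassificationThresholds = DEFAULT_THRESHOLDS,
) -> VentilationCategory:
    """Classify a (volume mL, insufflation time s) pair.

    Green iff both values sit in the green bands; red iff either value
    falls strictly outside the amber bands; amber otherwise.
    """
    if volume < 0:
        raise ValidationError(f"volume must be >= 0 mL, got {volume}")
    if time_s < 0:
        raise ValidationError(f"insufflation time must be >= 0 s, got {time_s}")
    t = thresholds
    if t.green_vol.contains(volume) and t.green_time.contains(time_s):
        return VentilationCategory("green", "volume and insufflation time in green bands")
    if volume < t.amber_vol.lower:
        return VentilationCategory("red", f"volume < {t.amber_vol.lower:g} mL")
    if volume > t.amber_vol.upper:
        return VentilationCategory("red", f"volume > {t.amber_vol.upper:g} mL")
    if time_s < t.amber_time.lower:
        return VentilationCategory("red", f"insufflation time < {t.amber_time.lower:g} s")
    if time_s > t.amber_time.upper:
        return VentilationCategory("red", f"insufflation time > {t.amber_time.upper:g} s")
    return VentilationCategory("amber", "within amber bands but outside green")


def classify(
    event: VentilationEvent,
    thresholds: ClassificationThresholds = DEFAULT_THRESHOLDS,
) -> VentilationCategory:
    """Classify one ventilation event (time converted from ms to s)."""
    return classify_volume_time(event.volume, event.insufflation_s, thresholds)


@dataclass(frozen=True)
class CategoryCounts:
    """Per-test category counts over the effective-ventilation sample."""

    table: pd.DataFrame  # index: test labels, columns: green/amber/red
    n_excluded: int  # ineffective ventilations left out of the sample

    @property
    def n_included(self) -> int:
        return int(self.table.to_numpy().sum())

    def proportions(self) -> pd.DataFrame:
        totals = self.table.sum(axis=1)
        return self.table.div(totals.where(totals > 0, 1), axis=0)


def classify_all(
    records: Iterable[SessionRecord],
    thresholds: ClassificationThresholds = DEFAULT_THRESHOLDS,
) -> CategoryCounts:
    """Count green/amber/red ventilations per test across sessions.

    Only effective ventilations are included, matching the inclusion rule
    of the analysis sample; the number of excluded (ineffective) events
    is tallied rather than silently dropped.
    """
    counts = pd.DataFrame(0, index=list(TEST_LABELS), columns=list(CATEGORIES))
    excluded = 0
    for session in records:
        for ev in session.ventilations:
            if not ev.effective:
                excluded += 1
                continue
            category = classify(ev, thresholds)
            counts.loc[session.test_id, category.label] += 1
    return CategoryCounts(table=counts, n_excluded=excluded)


def classification_frame(
    records: Iterable[SessionRecord],
    thresholds: ClassificationThresholds = DEFAULT_THRESHOLDS,
) -> pd.DataFrame:
    """Per-event classification table (one row per effective ventilation).

    Columns: pair_id, participant_id, test_id, t_start_ms, volume_ml,
    insufflation_s, category, reason.  Used for scatter-style exports of
    volume vs insufflation time coloured by category.
    """
    rows: list[Mapping[str, object]] = []
    for session in records:
        for ev in session.effective_ventilations:
            cat = classify(ev, thresholds)
            rows.append(
                {
                    "pair_id": ev.pair_id,
                    "participant_id": ev.participant_id,
                    "test_id": ev.test_id,
                    "t_start_ms": ev.t_start,
                    "volume_ml": ev.volume,
                    "insufflation_s": ev.insufflation_s,
                    "category": cat.label,
                    "reason": cat.reason,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "pair_id",
            "participant_id",
            "test_id",
            "t_start_ms",
            "volume_ml",
            "insufflation_s",
            "category",
            "reason",
        ],
    )
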