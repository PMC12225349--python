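"""Synthetic 30:2 CPR sessions with the statistical structure of manikin data.

The generator emulates a two-minute resuscitation test by a rescuer
pair: five initial rescue breaths (drowning protocol), then repeated
cycles of 30 chest compressions followed by 2 ventilations, truncated
at the test duration.  Ventilation volumes and insufflation times, and
compression rates and depths, are drawn independently per event from
lognormal distributions parameterised by a median and interquartile
range — the summary statistics this kind of study reports — via
:func:`lognormal_from_median_iqr`.

Three built-in exposure profiles reflect the typical evolution across a
ventilation-focused training programme: untrained rescuers squeeze the
bag fast and hard (T0: median volume 639 mL, insufflation time 0.48 s),
while trained ones approach the guideline ~1 s squeeze with smaller
volumes (T1: 452 mL / 0.91 s; T2: 531 mL / 0.94 s).  Because a slower
squeeze lengthens each ventilation interlude, the timing constants
(inter-breath gap 1.5 s, compression-to-ventilation pause 2.0 s) make
the untrained profile fit 5 full cycles (15 ventilations) and the
trained profiles 4 (13 ventilations) in the two minutes — the
characteristic drop in ventilation count with training.

Reproducibility: a single study seed fans out to per-session substreams
keyed by a stable hash of (pair_id, test_id), so any one session can be
regenerated independently of generation order.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .events import (
    CompressionRecord,
    SessionRecord,
    TEST_LABELS,
    ValidationError,
    VentilationEvent,
)

Z75 = float(stats.norm.ppf(0.75))  # ~0.6744897501960817

DEPTH_BAND = (50.0, 60.0)  # mm, guideline depth
RATE_BAND = (100.0, 120.0)  # compressions/min


def lognormal_from_median_iqr(median: float, q1: float, q3: float) -> tuple[float, float]:
    """Lognormal (mu, sigma) whose median and IQR match the targets.

    mu = ln(median); sigma = ln(q3/q1) / (2 * z_0.75).  The fitted
    distribution has the target median exactly; its quartile ratio
    Q3/Q1 equals q3/q1 exactly, so the IQR matches whenever the summary
    comes from an approximately lognormal sample.  A degenerate summary
    (q1 = median = q3) yields sigma = 0, a point mass.
    """
    if not (0 < q1 <= median <= q3):
        raise ValidationError(
            f"need 0 < q1 <= median <= q3, got ({median}, {q1}, {q3})"
        )
    return float(np.log(median)), float(np.log(q3 / q1) / (2 * Z75))


def _sample_lognormal(
    rng: np.random.Generator, median: float, q1: float, q3: float, size: int
) -> np.ndarray:
    mu, sigma = lognormal_from_median_iqr(median, q1, q3)
    if sigma == 0:
        return np.full(size, median, dtype=float)
    return rng.lognormal(mean=mu, sigma=sigma, size=size)


@dataclass(frozen=True)
class TestProfile:
    """Event-level distribution parameters for one exposure level.

    Volume (mL), insufflation time (s), compression rate (/min) and
    depth (mm) are each given as (median, (Q1, Q3)); the lognormal fit
    reproduces the median exactly and the IQR distributionally.
    ``p_effective`` is the probability the manikin captures a
    ventilation as effective; ``p_correct_recoil`` the per-compression
    probability of full chest recoil (the one compression-quality
    component not derivable from rate or depth).
    """

    __test__ = False  # not a pytest class despite the name

    test_id: str
    volume_median: float
    volume_iqr: tuple[float, float]
    time_median: float
    time_iqr: tuple[float, float]
    rate_median: float
    rate_iqr: tuple[float, float]
    depth_median: float
    depth_iqr: tuple[float, float]
    p_effective: float = 1.0
    p_correct_recoil: float = 0.8
    inter_breath_gap: float = 1.5  # s between consecutive ventilations
    compression_pause: float = 2.0  # s hands-off transition after a block

    def __post_init__(self) -> None:
        if self.test_id not in TEST_LABELS:
            raise ValidationError(f"unknown test_id {self.test_id!r}")
        for name in ("volume", "time", "rate", "depth"):
            med = getattr(self, f"{name}_median")
            q1, q3 = getattr(self, f"{name}_iqr")
            if not (0 < q1 <= med <= q3):
                raise ValidationError(f"{name}: need 0 < Q1 <= median <= Q3")
        for p in (self.p_effective, self.p_correct_recoil):
            if not 0 <= p <= 1:
                raise ValidationError("probabilities must be in [0, 1]")
        if self.inter_breath_gap < 0 or self.compression_pause < 0:
            raise ValidationError("timing constants must be non-negative")


#: Built-in exposure profiles (see module docstring for the rationale).
DEFAULT_PROFILES: dict[str, TestProfile] = {
    "T0": TestProfile(
        "T0",
        volume_median=639, volume_iqr=(593, 717),
        time_median=0.48, time_iqr=(0.41, 0.59),
        rate_median=122, rate_iqr=(116, 127),
        depth_median=56, depth_iqr=(52, 61),
        p_correct_recoil=0.5,
    ),
    "T1": TestProfile(
        "T1",
        volume_median=452, volume_iqr=(317, 519),
        time_median=0.91, time_iqr=(0.73, 1.21),
        rate_median=115, rate_iqr=(106, 120),
        depth_median=53, depth_iqr=(50, 55),
        p_correct_recoil=0.85,
    ),
    "T2": TestProfile(
        "T2",
        volume_median=531, volume_iqr=(488, 618),
        time_median=0.94, time_iqr=(0.82, 1.03),
        rate_median=113, rate_iqr=(108, 120),
        depth_median=54, depth_iqr=(50, 56),
        p_correct_recoil=0.85,
    ),
}


@dataclass(frozen=True)
class StudyDesign:
    """Protocol constants of the simulated study."""

    n_pairs: int = 5
    duration_s: float = 120.0
    initial_breaths: int = 5
    compressions_per_cycle: int = 30
    breaths_per_cycle: int = 2
    between_pair_sd: float = 0.0  # lognormal-scale random pair effect

    def __post_init__(self) -> None:
        for name in ("n_pairs", "initial_breaths", "compressions_per_cycle", "breaths_per_cycle"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if self.duration_s <= 0:
            raise ValidationError("duration_s must be positive")
        if self.between_pair_sd < 0:
            raise ValidationError("between_pair_sd must be >= 0")

    @property
    def duration_ms(self) -> int:
        return int(round(self.duration_s * 1000))


DEFAULT_DESIGN = StudyDesign()


def session_rng(seed: int, pair_id: str, test_id: str) -> np.random.Generator:
    """Per-session substream: seed fan-out by stable hash of the session key."""
    key = zlib.crc32(f"{pair_id}|{test_id}".encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([seed, key]))


def sample_ventilation_values(
    profile: TestProfile, n: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Draw n (volume mL, insufflation time s) pairs from the profile."""
    volumes = _sample_lognormal(rng, profile.volume_median, *profile.volume_iqr, size=n)
    times = _sample_lognormal(rng, profile.time_median, *profile.time_iqr, size=n)
    return volumes, times


def simulate_test(
    profile: TestProfile,
    design: StudyDesign = DEFAULT_DESIGN,
    *,
    seed: int = 0,
    pair_id: str = "P1",
    participant_id: str | None = None,
    rng: np.random.Generator | None = None,
) -> SessionRecord:
    """Simulate one session on the 30:2 timeline.

    The clock starts at 0 and advances through: ``initial_breaths``
    ventilations (each occupying its insufflation time plus the
    inter-breath gap), then cycles of ``compressions_per_cycle``
    compressions (each occupying one beat at its sampled instantaneous
    rate), a hands-off pause, and ``breaths_per_cycle`` ventilations.
    An event is emitted only if it finishes within the test duration;
    the timeline stops at the first event that does not fit.
    """
    if rng is None:
        rng = session_rng(seed, pair_id, profile.test_id)
    participant_id = participant_id or f"{pair_id}a"
    duration_ms = design.duration_ms

    pair_shift = (
        float(rng.normal(0.0, design.between_pair_sd)) if design.between_pair_sd else 0.0
    )
    vol_factor = float(np.exp(pair_shift))

    ventilations: list[VentilationEvent] = []
    compressions: list[CompressionRecord] = []
    t_ms = 0.0

    def emit_breaths(n: int) -> bool:
        """Append up to n breaths; False when the test clock runs out."""
        nonlocal t_ms
        volumes, times = sample_ventilation_values(profile, n, rng)
        for vol, t_s in zip(volumes * vol_factor, times):
            insufflation_ms = int(round(t_s * 1000))
            start = int(round(t_ms))
            if start + insufflation_ms > duration_ms:
                return False
            ventilations.append(
                VentilationEvent(
                    pair_id=pair_id,
                    participant_id=participant_id,
                    test_id=profile.test_id,
                    t_start=start,
                    insufflation_time=insufflation_ms,
                    volume=float(vol),
                    effective=bool(rng.random() < profile.p_effective),
                )
            )
            t_ms += insufflation_ms + profile.inter_breath_gap * 1000
        return True

    def emit_compressions(n: int) -> bool:
        nonlocal t_ms
        rates = _sample_lognormal(rng, profile.rate_median, *profile.rate_iqr, size=n)
        depths = _sample_lognormal(rng, profile.depth_median, *profile.depth_iqr, size=n)
        for rate, depth in zip(rates, depths):
            beat_ms = 60_000.0 / rate
            start = int(round(t_ms))
            if t_ms + beat_ms > duration_ms:
                return False
            compressions.append(
                CompressionRecord(
                    pair_id=pair_id,
                    test_id=profile.test_id,
                    t_start=start,
                    depth=float(depth),
                    instantaneous_rate=float(rate),
                    correct_depth=bool(DEPTH_BAND[0] <= depth <= DEPTH_BAND[1]),
                    correct_recoil=bool(rng.random() < profile.p_correct_recoil),
                    correct_rate=bool(RATE_BAND[0] <= rate <= RATE_BAND[1]),
                )
            )
            t_ms += beat_ms
        return True

    alive = emit_breaths(design.initial_breaths)
    while alive:
        if not emit_compressions(design.compressions_per_cycle):
            break
        t_ms += profile.compression_pause * 1000
        alive = emit_breaths(design.breaths_per_cycle)

    return SessionRecord(
        pair_id=pair_id,
        test_id=profile.test_id,
        ventilations=tuple(ventilations),
        compressions=tuple(compressions),
        duration=duration_ms,
    )


def simulate_study(
    profiles: Mapping[str, TestProfile] | None = None,
    design: StudyDesign = DEFAULT_DESIGN,
    *,
    seed: int = 0,
) -> tuple[list[SessionRecord], dict]:
    """Simulate the full study: every pair at every exposure level.

    Returns the sessions (n_pairs x 3 tests) plus a truth record with
    the generating parameters, for parameter-recovery checks.
    """
    profiles = dict(profiles) if profiles is not None else dict(DEFAULT_PROFILES)
    missing = [t for t in TEST_LABELS if t not in profiles]
    if missing:
        raise ValidationError(f"missing profile(s) for: {', '.join(missing)}")
    sessions = []
    for i in range(1, design.n_pairs + 1):
        pair_id = f"P{i}"
        for test_id in TEST_LABELS:
            sessions.append(
                simulate_test(
                    profiles[test_id], design, seed=seed, pair_id=pair_id
                )
            )
    truth = {
        "seed": seed,
        "design": asdict(design),
        "profiles": {t: asdict(p) for t, p in profiles.items()},
    }
    return sessions, truth


# ---------------------------------------------------------------------------
# Profile / design (de)serialisation


def load_profiles(path: str | Path) -> dict[str, TestProfile]:
    """Load per-test profiles from JSON ({test_id: {field: value, ...}})."""
    payload = json.loads(Path(path).read_text(encoding="utf-8"))
    profiles = {}
    for test_id, fields in payload.items():
        fields = dict(fields)
        fields.setdefault("test_id", test_id)
        for key in ("volume_iqr", "time_iqr", "rate_iqr", "depth_iqr"):
            if key in fields:
                fields[key] = tuple(fields[key])
        profiles[test_id] = TestProfile(**fields)
    return profiles


def save_profiles(profiles: Mapping[str, TestProfile], path: str | Path) -> None:
    payload = {t: asdict(p) for t, p in profiles.items()}
    Path(path).write_text(json.dumps(payload, indent=2) + "\n", encoding="utf-8")


def load_design(path: str | Path) -> StudyDesign:
    payload = json.loads(Path(path).read_text(encoding="utf-8"))
    return StudyDesign(**payload)
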