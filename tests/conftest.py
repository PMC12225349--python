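import numpy as np
import pytest

from cprvent.events import CompressionRecord, SessionRecord, VentilationEvent


def make_ventilation(
    volume,
    time_s,
    *,
    pair_id="P1",
    participant_id="P1a",
    test_id="T0",
    t_start=0,
    effective=True,
):
    return VentilationEvent(
        pair_id=pair_id,
        participant_id=participant_id,
        test_id=test_id,
        t_start=t_start,
        insufflation_time=int(round(time_s * 1000)),
        volume=volume,
        effective=effective,
    )


def make_session(vol_time_pairs, *, pair_id="P1", test_id="T0", compressions=(),
                 effective=None, duration=120_000):
    effective = effective or [True] * len(vol_time_pairs)
    vents = [
        make_ventilation(
            vol, t, pair_id=pair_id, test_id=test_id, t_start=3000 * i, effective=eff
        )
        for i, ((vol, t), eff) in enumerate(zip(vol_time_pairs, effective))
    ]
    return SessionRecord(
        pair_id=pair_id,
        test_id=test_id,
        ventilations=tuple(vents),
        compressions=tuple(compressions),
        duration=duration,
    )


def make_compression(t_start, *, rate=120.0, depth=55.0, pair_id="P1", test_id="T0",
                     correct_depth=True, correct_recoil=True, correct_rate=True):
    return CompressionRecord(
        pair_id=pair_id,
        test_id=test_id,
        t_start=t_start,
        depth=depth,
        instantaneous_rate=rate,
        correct_depth=correct_depth,
        correct_recoil=correct_recoil,
        correct_rate=correct_rate,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240801)


@pytest.fixture
def random_sessions(rng):
    """A small randomized but valid study for round-trip style tests."""
    sessions = []
    for pair in ("P1", "P2"):
        for test in ("T0", "T1", "T2"):
            n = int(rng.integers(3, 9))
            vents = [
                VentilationEvent(
                    pair_id=pair,
                    participant_id=f"{pair}a",
                    test_id=test,
                    t_start=int(3000 * i + rng.integers(0, 500)),
                    insufflation_time=int(rng.integers(200, 1800)),
                    volume=float(np.round(rng.uniform(150, 900), 1)),
                    effective=bool(rng.random() < 0.9),
                )
                for i in range(n)
            ]
            comps = [
                CompressionRecord(
                    pair_id=pair,
                    test_id=test,
                    t_start=int(30_000 + 500 * i),
                    depth=float(np.round(rng.uniform(35, 70), 1)),
                    instantaneous_rate=float(np.round(rng.uniform(80, 140), 1)),
                    correct_depth=bool(rng.random() < 0.7),
                    correct_recoil=bool(rng.random() < 0.7),
                    correct_rate=bool(rng.random() < 0.7),
                )
                for i in range(int(rng.integers(5, 40)))
            ]
            sessions.append(
                SessionRecord(
                    pair_id=pair,
                    test_id=test,
                    ventilations=tuple(vents),
                    compressions=tuple(comps),
                )
            )
    return sessions
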