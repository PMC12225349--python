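"""Built-in example data.

Small published-style summary inputs that the analysis modules accept
directly, so the case-control machinery can be exercised without raw
event files.
"""

from __future__ import annotations

import pandas as pd

from .events import ContingencyTable


def lifeguard_ventilation_counts() -> pd.DataFrame:
    """Category counts of 381 effective bag-mask ventilations.

    From a two-session ventilation-focused training programme for
    lifeguard students (10 rescuers in 5 pairs, two-minute 30:2 tests):
    each effective ventilation was classified green/amber/red by its
    volume and insufflation time, at three exposure levels — before
    training (T0, 147 ventilations), after one session (T1, 108) and
    after two sessions (T2, 126).

    Returns a frame indexed by exposure level with columns
    green/amber/red, suitable for :func:`cprvent.casecontrol.build_tables`.
    """
    return pd.DataFrame(
        {
            "green": [0, 6, 24],
            "amber": [22, 53, 74],
            "red": [125, 49, 28],
        },
        index=["T0", "T1", "T2"],
    )


def lifeguard_green_red_table() -> ContingencyTable:
    """The green-vs-red exposure table of the same sample (3x2)."""
    counts = lifeguard_ventilation_counts()
    return ContingencyTable(
        rows=("T0", "T1", "T2"),
        cols=("green", "red"),
        counts=counts[["green", "red"]].to_numpy(),
    )
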