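"""Event data model and file I/O for manikin CPR sessions.

A resuscitation test is a two-minute run of the adult 30:2 protocol
(30 chest compressions alternating with 2 bag-mask ventilations),
preceded by 5 initial rescue breaths as used for drowning victims.
Each test is performed by a rescuer pair and repeated at three exposure
levels: before training (T0), after one training session (T1) and after
two sessions (T2).

Two event kinds are recorded with millisecond timestamps relative to the
start of the test:

* a *ventilation*: one bag squeeze, characterised by the insufflated
  volume (mL) and the insufflation time (ms), plus a flag saying whether
  the manikin registered it as effective;
* a *compression*: one chest compression, characterised by depth (mm),
  instantaneous rate (compressions/min) and per-compression correctness
  flags for depth, recoil and rate.

Both kinds are serialised in a single long-format CSV dialect (UTF-8,
comma separated, one header row)::

    pair_id,participant_id,test_id,event_type,t_start_ms,insufflation_ms,
    volume_ml,effective,depth_mm,rate_cpm,correct_depth,correct_recoil,
    correct_rate

Cells that do not apply to an event type are left empty; booleans are
written as 0/1 so files survive locale round trips. Times are kept as
integer milliseconds throughout and converted to seconds only at
computation boundaries.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

TEST_LABELS = ("T0", "T1", "T2")
"""Exposure labels: pre-training, after one session, after two sessions."""

CSV_COLUMNS = [
    "pair_id",
    "participant_id",
    "test_id",
    "event_type",
    "t_start_ms",
    "insufflation_ms",
    "volume_ml",
    "effective",
    "depth_mm",
    "rate_cpm",
    "correct_depth",
    "correct_recoil",
    "correct_rate",
]

DEFAULT_TEST_DURATION_MS = 120_000


class SchemaError(ValueError):
    """The file header does not match the documented dialect."""


class ValidationError(ValueError):
    """A field value violates a model invariant."""


@dataclass(frozen=True)
class RowError:
    """A malformed CSV row, reported with its 1-based line number."""

    line: int
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"line {self.line}: {self.message}"


class EventParseError(ValueError):
    """Raised when strict reading encounters malformed rows."""

    def __init__(self, errors: Sequence[RowError]):
        self.errors = list(errors)
        preview = "; ".join(str(e) for e in self.errors[:5])
        more = "" if len(self.errors) <= 5 else f" (+{len(self.errors) - 5} more)"
        super().__init__(f"{len(self.errors)} malformed row(s): {preview}{more}")


def _check_test_id(test_id: str) -> None:
    if test_id not in TEST_LABELS:
        raise ValidationError(
            f"unknown test_id {test_id!r}; allowed labels: {', '.join(TEST_LABELS)}"
        )


@dataclass(frozen=True)
class VentilationEvent:
    """One insufflation delivered with the self-inflating bag.

    Parameters
    ----------
    t_start : int
        Offset from the start of the test, in milliseconds.
    insufflation_time : int
        Duration of the bag squeeze, in milliseconds.
    volume : float
        Insufflated volume, in mL.
    effective : bool
        Whether the manikin captured the ventilation as effective; only
        effective ventilations enter the analysis sample.
    """

    pair_id: str
    participant_id: str
    test_id: str
    t_start: int
    insufflation_time: int
    volume: float
    effective: bool = True

    def __post_init__(self) -> None:
        _check_test_id(self.test_id)
        if self.t_start < 0:
            raise ValidationError(f"t_start must be >= 0 ms, got {self.t_start}")
        if self.insufflation_time < 0:
            raise ValidationError(
                f"insufflation_time must be >= 0 ms, got {self.insufflation_time}"
            )
        if self.volume < 0:
            raise ValidationError(f"volume must be >= 0 mL, got {self.volume}")

    @property
    def insufflation_s(self) -> float:
        """Insufflation time in seconds."""
        return self.insufflation_time / 1000.0


@dataclass(frozen=True)
class CompressionRecord:
    """One chest compression with its instantaneous quality flags."""

    pair_id: str
    test_id: str
    t_start: int
    depth: float
    instantaneous_rate: float
    correct_depth: bool = False
    correct_recoil: bool = False
    correct_rate: bool = False

    def __post_init__(self) -> None:
        _check_test_id(self.test_id)
        if self.t_start < 0:
            raise ValidationError(f"t_start must be >= 0 ms, got {self.t_start}")
        if self.depth < 0:
            raise ValidationError(f"depth must be >= 0 mm, got {self.depth}")
        if self.instantaneous_rate <= 0:
            raise ValidationError(
                f"instantaneous_rate must be > 0/min, got {self.instantaneous_rate}"
            )

    @property
    def occupied_ms(self) -> float:
        """Time the compression occupies: one beat at the instantaneous rate."""
        return 60_000.0 / self.instantaneous_rate


@dataclass(frozen=True)
class SessionRecord:
    """All events of one rescuer pair in one test.

    Events are kept time-ordered; every contained event must carry the
    session's ``pair_id`` and ``test_id`` and finish within ``duration``.
    """

    pair_id: str
    test_id: str
    ventilations: tuple[VentilationEvent, ...] = ()
    compressions: tuple[CompressionRecord, ...] = ()
    duration: int = DEFAULT_TEST_DURATION_MS

    def __post_init__(self) -> None:
        _check_test_id(self.test_id)
        if self.duration <= 0:
            raise ValidationError("session duration must be positive")
        object.__setattr__(self, "ventilations", tuple(self.ventilations))
        object.__setattr__(self, "compressions", tuple(self.compressions))
        for ev in self.ventilations:
            if ev.pair_id != self.pair_id or ev.test_id != self.test_id:
                raise ValidationError(
                    f"ventilation ({ev.pair_id},{ev.test_id}) does not belong to "
                    f"session ({self.pair_id},{self.test_id})"
                )
            if ev.t_start + ev.insufflation_time > self.duration:
                raise ValidationError(
                    f"ventilation at {ev.t_start} ms overruns the session "
                    f"duration of {self.duration} ms"
                )
        for cp in self.compressions:
            if cp.pair_id != self.pair_id or cp.test_id != self.test_id:
                raise ValidationError(
                    f"compression ({cp.pair_id},{cp.test_id}) does not belong to "
                    f"session ({self.pair_id},{self.test_id})"
                )
            if cp.t_start > self.duration:
                raise ValidationError(
                    f"compression at {cp.t_start} ms lies outside the session"
                )
        for events in (self.ventilations, self.compressions):
            starts = [e.t_start for e in events]
            if any(b < a for a, b in zip(starts, starts[1:])):
                raise ValidationError("event t_start values must be non-decreasing")

    @property
    def effective_ventilations(self) -> tuple[VentilationEvent, ...]:
        """Ventilations captured as effective — the analysis sample."""
        return tuple(ev for ev in self.ventilations if ev.effective)


# ---------------------------------------------------------------------------
# CSV reading / writing


def _parse_bool(raw: str, column: str) -> bool:
    if raw in ("0", "1"):
        return raw == "1"
    raise ValidationError(f"{column} must be 0 or 1, got {raw!r}")


def _parse_row(row: dict[str, str], line: int) -> VentilationEvent | CompressionRecord:
    kind = row["event_type"]
    if kind == "ventilation":
        return VentilationEvent(
            pair_id=row["pair_id"],
            participant_id=row["participant_id"],
            test_id=row["test_id"],
            t_start=int(row["t_start_ms"]),
            insufflation_time=int(row["insufflation_ms"]),
            volume=float(row["volume_ml"]),
            effective=_parse_bool(row["effective"], "effective"),
        )
    if kind == "compression":
        return CompressionRecord(
            pair_id=row["pair_id"],
            test_id=row["test_id"],
            t_start=int(row["t_start_ms"]),
            depth=float(row["depth_mm"]),
            instantaneous_rate=float(row["rate_cpm"]),
            correct_depth=_parse_bool(row["correct_depth"], "correct_depth"),
            correct_recoil=_parse_bool(row["correct_recoil"], "correct_recoil"),
            correct_rate=_parse_bool(row["correct_rate"], "correct_rate"),
        )
    raise ValidationError(f"unknown event_type {kind!r}")


def read_events(
    path: str | Path,
    *,
    duration: int = DEFAULT_TEST_DURATION_MS,
    collect_errors: bool = False,
) -> list[SessionRecord] | tuple[list[SessionRecord], list[RowError]]:
    """Read the long-format event CSV into :class:`SessionRecord` objects.

    Rows are grouped into one session per ``(pair_id, test_id)``.  No row
    is silently dropped: every malformed row is reported with its line
    number, either by raising :class:`EventParseError` (default) or, with
    ``collect_errors=True``, by returning ``(sessions, errors)``.

    Raises
    ------
    SchemaError
        If a required column is missing from the header.
    EventParseError
        If any row is malformed and ``collect_errors`` is False.
    """
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        missing = [c for c in CSV_COLUMNS if c not in header]
        if missing:
            raise SchemaError(f"missing required column(s): {', '.join(missing)}")
        errors: list[RowError] = []
        groups: dict[tuple[str, str], dict[str, list]] = {}
        for line, row in enumerate(reader, start=2):
            try:
                event = _parse_row(row, line)
            except (ValidationError, ValueError, KeyError) as exc:
                errors.append(RowError(line, str(exc)))
                continue
            key = (event.pair_id, event.test_id)
            bucket = groups.setdefault(key, {"v": [], "c": []})
            if isinstance(event, VentilationEvent):
                bucket["v"].append(event)
            else:
                bucket["c"].append(event)

    if errors and not collect_errors:
        raise EventParseError(errors)

    sessions = [
        SessionRecord(
            pair_id=pair_id,
            test_id=test_id,
            ventilations=tuple(sorted(b["v"], key=lambda e: e.t_start)),
            compressions=tuple(sorted(b["c"], key=lambda e: e.t_start)),
            duration=duration,
        )
        for (pair_id, test_id), b in sorted(groups.items())
    ]
    if collect_errors:
        return sessions, errors
    return sessions


def _bool_cell(value: bool) -> str:
    return "1" if value else "0"


def write_events(records: Iterable[SessionRecord], path: str | Path) -> None:
    """Write sessions to the long-format event CSV (round-trip safe)."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(CSV_COLUMNS)
        for session in records:
            merged: list[tuple[int, int, object]] = [
                (ev.t_start, 0, ev) for ev in session.ventilations
            ] + [(cp.t_start, 1, cp) for cp in session.compressions]
            for _, _, event in sorted(merged, key=lambda t: (t[0], t[1])):
                if isinstance(event, VentilationEvent):
                    writer.writerow(
                        [
                            event.pair_id,
                            event.participant_id,
                            event.test_id,
                            "ventilation",
                            event.t_start,
                            event.insufflation_time,
                            f"{event.volume:g}",
                            _bool_cell(event.effective),
                            "",
                            "",
                            "",
                            "",
                            "",
                        ]
                    )
                else:
                    writer.writerow(
                        [
                            event.pair_id,
                            "",
                            event.test_id,
                            "compression",
                            event.t_start,
                            "",
                            "",
                            "",
                            f"{event.depth:g}",
                            f"{event.instantaneous_rate:g}",
                            _bool_cell(event.correct_depth),
                            _bool_cell(event.correct_recoil),
                            _bool_cell(event.correct_rate),
                        ]
                    )


# ---------------------------------------------------------------------------
# Contingency tables


@dataclass(frozen=True)
class ContingencyTable:
    """A labelled count matrix (exposure levels x outcome categories)."""

    rows: tuple[str, ...]
    cols: tuple[str, ...]
    counts: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.shape != (len(self.rows), len(self.cols)):
            raise ValidationError(
                f"counts shape {counts.shape} does not match labels "
                f"({len(self.rows)}x{len(self.cols)})"
            )
        if not np.issubdtype(counts.dtype, np.integer):
            if not np.all(np.equal(np.mod(counts, 1), 0)):
                raise ValidationError("counts must be integers")
            counts = counts.astype(np.int64)
        if np.any(counts < 0):
            raise ValidationError("counts must be non-negative")
        object.__setattr__(self, "rows", tuple(self.rows))
        object.__setattr__(self, "cols", tuple(self.cols))
        object.__setattr__(self, "counts", counts.astype(np.int64))

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    @property
    def row_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def col_totals(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def subtable(self, rows: Sequence[str]) -> "ContingencyTable":
        """Restrict to a subset of exposure rows (for pairwise decomposition)."""
        idx = [self.rows.index(r) for r in rows]
        return ContingencyTable(tuple(rows), self.cols, self.counts[idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.rows), columns=list(self.cols))


def read_contingency_table(path: str | Path) -> ContingencyTable:
    """Load a labelled count matrix from JSON or CSV.

    JSON layout: ``{"rows": [...], "cols": [...], "counts": [[...], ...]}``.
    CSV layout: header ``,col1,col2,...`` then one row label + counts per line.
    """
    path = Path(path)
    if path.suffix.lower() == ".json":
        payload = json.loads(path.read_text(encoding="utf-8"))
        try:
            rows, cols, counts = payload["rows"], payload["cols"], payload["counts"]
        except (KeyError, TypeError) as exc:
            raise SchemaError(f"contingency JSON missing key: {exc}") from exc
        return ContingencyTable(tuple(rows), tuple(cols), np.asarray(counts))
    frame = pd.read_csv(path, index_col=0)
    return ContingencyTable(
        tuple(str(r) for r in frame.index),
        tuple(str(c) for c in frame.columns),
        frame.to_numpy(),
    )


def write_contingency_table(table: ContingencyTable, path: str | Path) -> None:
    """Write a count matrix as JSON (``.json``) or CSV (anything else)."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        payload = {
            "rows": list(table.rows),
            "cols": list(table.cols),
            "counts": table.counts.tolist(),
        }
        path.write_text(json.dumps(payload, indent=2) + "\n", encoding="utf-8")
    else:
        table.to_frame().to_csv(path)
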