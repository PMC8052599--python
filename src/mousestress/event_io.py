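"""Reading, validating and writing mouse event logs and self-report tables.

The raw observational unit is a 30-minute recording of pointer samples at
approximately 125 Hz (one sample every ~8 ms).  Each sample carries a
timestamp in integer milliseconds since recording start, integer pixel
coordinates (screen convention: origin top-left, y increasing downward;
only coordinate differences are ever used downstream) and an event kind:
``move``, ``click`` or ``wheel``.

File formats (all UTF-8, comma-delimited, LF):

* event log: header ``t_ms,x,y,kind``, one row per event;
* self-reports: header ``subject_id,recording_id,started_at,valence,arousal``
  with ISO-8601 date-times;
* subject covariates: header starting ``subject_id,age,gender,...``.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from datetime import datetime
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "EventKind",
    "MouseEvent",
    "EventLog",
    "SelfReport",
    "ParseError",
    "ValidationError",
    "read_event_log",
    "write_event_log",
    "detect_tracking_error",
    "read_self_reports",
    "write_self_reports",
    "read_covariates",
    "write_covariates",
    "NOMINAL_SAMPLE_INTERVAL_MS",
    "NOMINAL_RECORDING_MINUTES",
]

#: Sampling interval of the recorder (~125 Hz).
NOMINAL_SAMPLE_INTERVAL_MS = 8
#: Nominal length of one recording window.
NOMINAL_RECORDING_MINUTES = 30

EVENT_LOG_HEADER = "t_ms,x,y,kind"
SELF_REPORT_HEADER = "subject_id,recording_id,started_at,valence,arousal"


class ParseError(ValueError):
    """A file did not conform to the documented dialect."""


class ValidationError(ValueError):
    """A value violated a domain invariant."""


class EventKind(str, Enum):
    MOVE = "move"
    CLICK = "click"
    WHEEL = "wheel"


_VALID_KINDS = frozenset(k.value for k in EventKind)


@dataclass(frozen=True)
class MouseEvent:
    """One pointer sample: time (ms since recording start), pixel position, kind."""

    t: int
    x: int
    y: int
    kind: EventKind

    def __post_init__(self) -> None:
        if self.t < 0:
            raise ValidationError(f"timestamp must be >= 0, got {self.t}")


@dataclass
class EventLog:
    """An ordered sequence of pointer samples from one 30-minute recording.

    Events are held columnar (``t``/``x``/``y`` int64 arrays, ``kind`` a
    unicode array) because a full recording has ~225,000 of them; the
    ``events`` property materializes :class:`MouseEvent` objects on demand.
    File order is preserved; validation is a separate step
    (:func:`detect_tracking_error`).  Calendar time lives only in
    ``started_at``; event timestamps are relative milliseconds.
    """

    subject_id: str
    recording_id: str
    t: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    x: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    y: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    kind: np.ndarray = field(default_factory=lambda: np.empty(0, dtype="U5"))
    started_at: datetime | None = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=np.int64)
        self.x = np.asarray(self.x, dtype=np.int64)
        self.y = np.asarray(self.y, dtype=np.int64)
        self.kind = np.asarray(self.kind, dtype="U5")
        if not (len(self.t) == len(self.x) == len(self.y) == len(self.kind)):
            raise ValidationError("event columns must have equal length")
        if len(self.t) and self.t.min() < 0:
            raise ValidationError("timestamps must be >= 0")
        if len(self.kind) and not np.isin(self.kind, list(_VALID_KINDS)).all():
            bad = self.kind[~np.isin(self.kind, list(_VALID_KINDS))][0]
            raise ValidationError(f"unknown event kind {bad!r}")

    def __len__(self) -> int:
        return len(self.t)

    @property
    def events(self) -> list[MouseEvent]:
        return [
            MouseEvent(int(ti), int(xi), int(yi), EventKind(ki))
            for ti, xi, yi, ki in zip(self.t, self.x, self.y, self.kind)
        ]

    @classmethod
    def from_events(
        cls,
        subject_id: str,
        recording_id: str,
        events: Sequence[MouseEvent],
        started_at: datetime | None = None,
    ) -> "EventLog":
        return cls(
            subject_id,
            recording_id,
            np.array([e.t for e in events], dtype=np.int64),
            np.array([e.x for e in events], dtype=np.int64),
            np.array([e.y for e in events], dtype=np.int64),
            np.array([e.kind.value for e in events], dtype="U5"),
            started_at,
        )

    def arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """Columnar view ``(t, x, y, kind)``."""
        return self.t, self.x, self.y, self.kind


@dataclass(frozen=True)
class SelfReport:
    """A twice-daily affect self-report on 7-point valence/arousal scales."""

    subject_id: str
    recording_id: str
    valence: int
    arousal: int
    started_at: datetime | None = None

    def __post_init__(self) -> None:
        for name, v in (("valence", self.valence), ("arousal", self.arousal)):
            if not (isinstance(v, (int, np.integer)) and 1 <= v <= 7):
                raise ValidationError(f"{name} must be an integer in 1..7, got {v!r}")

    @property
    def weekday(self) -> str:
        """Mon..Fri, or 'weekend' (Saturday and Sunday pooled)."""
        if self.started_at is None:
            raise ValidationError("weekday undefined without started_at")
        names = ["Mon", "Tue", "Wed", "Thu", "Fri"]
        wd = self.started_at.weekday()
        return names[wd] if wd < 5 else "weekend"

    @property
    def daytime(self) -> str:
        """'morning' (before noon) or 'afternoon'."""
        if self.started_at is None:
            raise ValidationError("daytime undefined without started_at")
        return "morning" if self.started_at.hour < 12 else "afternoon"


def read_event_log(
    path: str | Path | io.TextIOBase,
    subject_id: str | None = None,
    recording_id: str | None = None,
    started_at: datetime | None = None,
) -> EventLog:
    """Parse an event-log file into an :class:`EventLog`.

    Rows are returned in file order; nothing is reordered or dropped
    (tracking-error detection is a separate step).  Identifiers default to
    the file stem split on ``__`` (``<subject>__<recording>.csv``).

    Raises
    ------
    ParseError
        On a bad header, a malformed row (with its line number) or an
        unknown event kind.
    """
    if isinstance(path, (str, Path)):
        p = Path(path)
        if subject_id is None or recording_id is None:
            parts = p.stem.split("__", 1)
            subject_id = subject_id or parts[0]
            recording_id = recording_id or (parts[1] if len(parts) > 1 else p.stem)
        handle = p.open("r", encoding="utf-8", newline="")
        close = True
    else:
        handle, close = path, False
        subject_id = subject_id or "unknown"
        recording_id = recording_id or "unknown"
    try:
        header = handle.readline().rstrip("\n").rstrip("\r")
        if header != EVENT_LOG_HEADER:
            raise ParseError(
                f"bad event-log header: expected {EVENT_LOG_HEADER!r}, got {header!r}"
            )
        try:
            df = pd.read_csv(
                handle,
                names=["t_ms", "x", "y", "kind"],
                dtype={"t_ms": np.int64, "x": np.int64, "y": np.int64, "kind": str},
                header=None,
            )
        except (ValueError, pd.errors.ParserError) as exc:
            raise ParseError(f"malformed event-log row: {exc}") from exc
    finally:
        if close:
            handle.close()

    kinds = df["kind"].to_numpy(dtype="U16")
    bad = ~np.isin(kinds, list(_VALID_KINDS))
    if bad.any():
        i = int(np.flatnonzero(bad)[0])
        raise ParseError(f"unknown event kind {kinds[i]!r} at line {i + 2}")
    t = df["t_ms"].to_numpy()
    if (t < 0).any():
        raise ParseError(f"negative timestamp at line {int(np.flatnonzero(t < 0)[0]) + 2}")
    return EventLog(
        subject_id,
        recording_id,
        t,
        df["x"].to_numpy(),
        df["y"].to_numpy(),
        kinds.astype("U5"),
        started_at,
    )


def write_event_log(log: EventLog, path: str | Path) -> None:
    """Write ``log`` in the documented dialect; round-trips exactly."""
    df = pd.DataFrame({"t_ms": log.t, "x": log.x, "y": log.y, "kind": log.kind})
    with Path(path).open("w", encoding="utf-8", newline="\n") as fh:
        fh.write(EVENT_LOG_HEADER + "\n")
        df.to_csv(fh, header=False, index=False, lineterminator="\n")


def detect_tracking_error(log: EventLog) -> bool:
    """True iff the timestamp sequence is invalid.

    A log is a tracking error iff any timestamp strictly decreases, or two
    move events share a timestamp — either makes a movement's duration zero
    or negative and hence its speed undefined.
    """
    t, kind = log.t, log.kind
    if len(t) < 2:
        return False
    dt = np.diff(t)
    if (dt < 0).any():
        return True
    both_moves = (kind[1:] == "move") & (kind[:-1] == "move")
    return bool(((dt == 0) & both_moves).any())


# ---------------------------------------------------------------------------
# Self-report and covariate tables


def read_self_reports(path: str | Path) -> list[SelfReport]:
    df = pd.read_csv(path)
    expected = SELF_REPORT_HEADER.split(",")
    if list(df.columns) != expected:
        raise ParseError(f"bad self-report header: expected {expected}, got {list(df.columns)}")
    reports = []
    for i, row in enumerate(df.itertuples(index=False)):
        if pd.isna(row.valence) or pd.isna(row.arousal):
            raise ValidationError(f"missing valence/arousal at line {i + 2}")
        reports.append(
            SelfReport(
                str(row.subject_id),
                str(row.recording_id),
                int(row.valence),
                int(row.arousal),
                datetime.fromisoformat(str(row.started_at)),
            )
        )
    return reports


def write_self_reports(reports: Iterable[SelfReport], path: str | Path) -> None:
    rows = [
        {
            "subject_id": r.subject_id,
            "recording_id": r.recording_id,
            "started_at": r.started_at.isoformat() if r.started_at else "",
            "valence": r.valence,
            "arousal": r.arousal,
        }
        for r in reports
    ]
    pd.DataFrame(rows, columns=SELF_REPORT_HEADER.split(",")).to_csv(path, index=False)


def read_covariates(path: str | Path) -> pd.DataFrame:
    """Read the per-subject covariate table, indexed by ``subject_id``."""
    df = pd.read_csv(path, dtype={"subject_id": str})
    if "subject_id" not in df.columns:
        raise ParseError("covariate table must have a subject_id column")
    return df.set_index("subject_id")


def write_covariates(df: pd.DataFrame, path: str | Path) -> None:
    df.reset_index().to_csv(path, index=False)
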