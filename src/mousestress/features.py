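"""Trajectory segmentation, speed/accuracy statistics, filters, aggregation.

A *trajectory* is a contiguous run of move events terminated by a click or
wheel.  Two statistics are computed per trajectory:

* **speed** — summed Euclidean step length (pixels) divided by the
  trajectory duration (seconds): path length over time, not net
  displacement over time;
* **accuracy** — the share of time steps at which the movement direction
  stayed the same on both axes.  With per-step deltas (Δx_t, Δy_t), the
  indicator eqdir_t is 1 iff sign(Δx_t) = sign(Δx_{t−1}) and
  sign(Δy_t) = sign(Δy_{t−1}) (sign ∈ {−1, 0, +1}); accuracy is the mean of
  eqdir over all comparisons.  Accuracy 1 means the direction was never
  altered, 0 that it was altered at every step.  A pause (zero delta)
  between equal-direction steps counts as two changes: direction passes
  through 0.

Both are averaged, unweighted, over the retained trajectories of a
recording.  Retention applies the duration window (inclusive, default
1–10 s); recordings themselves are retained only if they have movement, a
valid timestamp sequence, and at least ``min_trajectories`` trajectories.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .event_io import EventKind, EventLog, MouseEvent, ValidationError, detect_tracking_error

__all__ = [
    "Trajectory",
    "RecordingFeatures",
    "FilterConfig",
    "ExclusionReport",
    "DegenerateFeatureError",
    "Standardizer",
    "segment_trajectories",
    "trajectory_speed",
    "trajectory_accuracy",
    "recording_features",
    "apply_exclusions",
    "standardize_features",
    "features_to_frame",
    "frame_to_features",
    "write_features",
    "read_features",
]

FEATURES_HEADER = [
    "subject_id",
    "recording_id",
    "n_trajectories",
    "speed",
    "accuracy",
    "click_prop",
    "wheel_prop",
    "weekday",
    "daytime",
]


class DegenerateFeatureError(ValueError):
    """A feature column has zero variance and cannot be standardized."""


@dataclass(frozen=True)
class FilterConfig:
    """Retention rules: trajectory duration window and recording minimum.

    Defaults: trajectories kept if their duration lies in [1 s, 10 s]
    (inclusive); recordings kept if they retain at least 10 trajectories.
    """

    min_duration_s: float = 1.0
    max_duration_s: float = 10.0
    min_trajectories: int = 10

    def __post_init__(self) -> None:
        if not (0 < self.min_duration_s < self.max_duration_s):
            raise ValidationError("need 0 < min_duration_s < max_duration_s")
        if self.min_trajectories < 1:
            raise ValidationError("min_trajectories must be >= 1")


@dataclass
class Trajectory:
    """One segmented movement: move samples plus the terminating click/wheel.

    Positions are held as arrays (``t`` in ms, ``x``/``y`` in px) covering
    every event in the segment, terminal included; ``events`` materializes
    them as :class:`MouseEvent` objects on demand.
    """

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    terminal_kind: EventKind

    @property
    def duration_s(self) -> float:
        return float(self.t[-1] - self.t[0]) / 1000.0

    @property
    def path_length_px(self) -> float:
        dx = np.diff(self.x)
        dy = np.diff(self.y)
        return float(np.sqrt(dx * dx + dy * dy).sum())

    @property
    def n_steps(self) -> int:
        return len(self.t) - 1

    @property
    def events(self) -> list[MouseEvent]:
        kinds = [EventKind.MOVE] * (len(self.t) - 1) + [self.terminal_kind]
        return [
            MouseEvent(int(ti), int(xi), int(yi), k)
            for ti, xi, yi, k in zip(self.t, self.x, self.y, kinds)
        ]


@dataclass
class RecordingFeatures:
    """Per-recording aggregates entering the stress regression."""

    subject_id: str
    recording_id: str
    n_trajectories: int
    speed: float
    accuracy: float
    click_prop: float
    wheel_prop: float
    weekday: str | None = None
    daytime: str | None = None


@dataclass
class ExclusionReport:
    """Bookkeeping of the three sequential recording filters.

    Rules are applied in order — no movement, tracking error, too few
    trajectories — and each recording is counted under the first rule it
    trips, so the counts are mutually exclusive and
    ``n_retained = n_raw − (n_no_movement + n_tracking_error +
    n_too_few_trajectories)`` holds by construction.
    """

    n_raw: int
    n_no_movement: int
    n_tracking_error: int
    n_too_few_trajectories: int
    excluded_subjects: list[str] = field(default_factory=list)

    @property
    def n_excluded(self) -> int:
        return self.n_no_movement + self.n_tracking_error + self.n_too_few_trajectories

    @property
    def n_retained(self) -> int:
        return self.n_raw - self.n_excluded


def segment_trajectories(log: EventLog, cfg: FilterConfig | None = None) -> list[Trajectory]:
    """Split a validated log into duration-filtered trajectories.

    Each trajectory begins at the first move event after the previous
    click/wheel (or the log start) and ends at the next click/wheel,
    inclusive.  Trajectories whose duration falls outside
    ``[cfg.min_duration_s, cfg.max_duration_s]`` are dropped.  Every
    click/wheel terminates at most one trajectory and no move event belongs
    to two trajectories (the segmentation is a partition of the move runs).

    Raises :class:`~mousestress.event_io.ValidationError` if timestamps
    decrease anywhere — such logs must be removed by the tracking-error
    filter before segmentation.
    """
    cfg = cfg or FilterConfig()
    t, x, y, kind = log.arrays()
    if len(t) >= 2 and (np.diff(t) < 0).any():
        raise ValidationError(
            f"log {log.recording_id!r} has decreasing timestamps; "
            "run tracking-error validation first"
        )
    term_idx = np.flatnonzero(kind != "move")
    out: list[Trajectory] = []
    prev = -1
    for j in term_idx:
        start = prev + 1
        prev = j
        if j - start < 1:  # terminal with no preceding move
            continue
        dur = (t[j] - t[start]) / 1000.0
        if cfg.min_duration_s <= dur <= cfg.max_duration_s:
            out.append(
                Trajectory(t[start : j + 1], x[start : j + 1], y[start : j + 1], EventKind(kind[j]))
            )
    return out


def trajectory_speed(traj: Trajectory) -> float:
    """Mean movement speed: path length (px) over duration (s)."""
    if traj.duration_s <= 0:
        raise ValidationError("trajectory duration must be positive")
    return traj.path_length_px / traj.duration_s


def trajectory_accuracy(traj: Trajectory) -> float | None:
    """Share of steps whose direction matched the previous step on both axes.

    Returns ``None`` when the trajectory has fewer than two displacement
    steps — accuracy is undefined there and the trajectory is skipped in
    the recording mean (it still counts toward the trajectory-count
    filter).
    """
    dx = np.diff(traj.x)
    dy = np.diff(traj.y)
    if len(dx) < 2:
        return None
    sx = np.sign(dx)
    sy = np.sign(dy)
    eqdir = (sx[1:] == sx[:-1]) & (sy[1:] == sy[:-1])
    return float(eqdir.mean())


def recording_features(log: EventLog, cfg: FilterConfig | None = None) -> RecordingFeatures | None:
    """Aggregate one validated log to recording-level features.

    Speed and accuracy are unweighted means over the retained trajectories;
    click/wheel proportions are shares of retained trajectories by terminal
    kind.  Returns ``None`` when no trajectory survives the duration filter
    (the recording is then removable by the count filter).
    """
    cfg = cfg or FilterConfig()
    trajs = segment_trajectories(log, cfg)
    if not trajs:
        return None
    speeds = [trajectory_speed(tr) for tr in trajs]
    accs = [a for a in (trajectory_accuracy(tr) for tr in trajs) if a is not None]
    kinds = [tr.terminal_kind for tr in trajs]
    n = len(trajs)
    started = log.started_at
    weekday = daytime = None
    if started is not None:
        names = ["Mon", "Tue", "Wed", "Thu", "Fri"]
        weekday = names[started.weekday()] if started.weekday() < 5 else "weekend"
        daytime = "morning" if started.hour < 12 else "afternoon"
    return RecordingFeatures(
        subject_id=log.subject_id,
        recording_id=log.recording_id,
        n_trajectories=n,
        speed=float(np.mean(speeds)),
        accuracy=float(np.mean(accs)) if accs else np.nan,
        click_prop=sum(k == EventKind.CLICK for k in kinds) / n,
        wheel_prop=sum(k == EventKind.WHEEL for k in kinds) / n,
        weekday=weekday,
        daytime=daytime,
    )


def apply_exclusions(
    logs: Iterable[EventLog], cfg: FilterConfig | None = None
) -> tuple[list[RecordingFeatures], ExclusionReport]:
    """Filter recordings and return retained features plus the audit report.

    Rules, applied sequentially with first-hit counting:

    1. *no movement* — the log contains no move events;
    2. *tracking error* — invalid timestamps
       (:func:`~mousestress.event_io.detect_tracking_error`);
    3. *too few trajectories* — fewer than ``cfg.min_trajectories``
       trajectories survive the duration filter.

    Subjects whose every recording was excluded are listed in the report.
    """
    cfg = cfg or FilterConfig()
    retained: list[RecordingFeatures] = []
    n_raw = n_empty = n_err = n_few = 0
    subjects_seen: dict[str, int] = {}
    for log in logs:
        n_raw += 1
        subjects_seen.setdefault(log.subject_id, 0)
        _, _, _, kind = log.arrays()
        if not (kind == "move").any():
            n_empty += 1
            continue
        if detect_tracking_error(log):
            n_err += 1
            continue
        feats = recording_features(log, cfg)
        if feats is None or feats.n_trajectories < cfg.min_trajectories:
            n_few += 1
            continue
        retained.append(feats)
        subjects_seen[log.subject_id] += 1
    excluded_subjects = sorted(s for s, n in subjects_seen.items() if n == 0)
    report = ExclusionReport(n_raw, n_empty, n_err, n_few, excluded_subjects)
    return retained, report


# ---------------------------------------------------------------------------
# Standardization


@dataclass(frozen=True)
class Standardizer:
    """A reusable center/scale transform (empirical mean, sample sd, ddof=1)."""

    mean: dict[str, float]
    sd: dict[str, float]

    def transform(self, df: pd.DataFrame) -> pd.DataFrame:
        out = df.copy()
        for c in self.mean:
            out[c] = (df[c] - self.mean[c]) / self.sd[c]
        return out

    def inverse(self, df: pd.DataFrame) -> pd.DataFrame:
        out = df.copy()
        for c in self.mean:
            out[c] = df[c] * self.sd[c] + self.mean[c]
        return out


def standardize_features(
    rows: Sequence[RecordingFeatures] | pd.DataFrame,
    columns: Sequence[str] = ("speed", "accuracy"),
) -> tuple[pd.DataFrame, Standardizer]:
    """Center and scale the named columns, pooled over all recordings.

    Uses the empirical mean and *sample* standard deviation (ddof=1) of
    each column; returns the standardized frame and the fitted transform
    for reuse on new data.  Raises :class:`DegenerateFeatureError` on a
    constant column.
    """
    df = rows if isinstance(rows, pd.DataFrame) else features_to_frame(rows)
    if len(df) < 2:
        raise ValidationError("need at least 2 rows to standardize")
    mean, sd = {}, {}
    for c in columns:
        m = float(df[c].mean())
        s = float(df[c].std(ddof=1))
        if not np.isfinite(s) or s == 0.0:
            raise DegenerateFeatureError(f"column {c!r} has zero variance")
        mean[c], sd[c] = m, s
    scaler = Standardizer(mean, sd)
    return scaler.transform(df), scaler


# ---------------------------------------------------------------------------
# Features table I/O


def features_to_frame(rows: Sequence[RecordingFeatures]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "subject_id": r.subject_id,
                "recording_id": r.recording_id,
                "n_trajectories": r.n_trajectories,
                "speed": r.speed,
                "accuracy": r.accuracy,
                "click_prop": r.click_prop,
                "wheel_prop": r.wheel_prop,
                "weekday": r.weekday,
                "daytime": r.daytime,
            }
            for r in rows
        ],
        columns=FEATURES_HEADER,
    )


def frame_to_features(df: pd.DataFrame) -> list[RecordingFeatures]:
    return [
        RecordingFeatures(
            str(r.subject_id),
            str(r.recording_id),
            int(r.n_trajectories),
            float(r.speed),
            float(r.accuracy),
            float(r.click_prop),
            float(r.wheel_prop),
            None if pd.isna(r.weekday) else str(r.weekday),
            None if pd.isna(r.daytime) else str(r.daytime),
        )
        for r in df.itertuples(index=False)
    ]


def write_features(rows: Sequence[RecordingFeatures], path: str | Path) -> None:
    features_to_frame(rows).to_csv(path, index=False)


def read_features(path: str | Path) -> list[RecordingFeatures]:
    return frame_to_features(pd.read_csv(path, dtype={"subject_id": str, "recording_id": str}))
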