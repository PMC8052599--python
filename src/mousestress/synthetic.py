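"""Synthetic mouse-movement studies with known ground truth.

The generator emulates the statistical structure the analysis assumes so
every pipeline stage is testable without real recordings:

* **Trajectory level** — a step process at ~125 Hz moving from a start
  point toward a target with a constant integer base step (so the
  noiseless path is perfectly monotone).  Neuromotor noise is emulated by
  a *jitter* probability: per step and per axis, with probability
  ``jitter`` the displacement sign is drawn at random instead of following
  the direct-to-target direction.  Expected extracted accuracy is a
  strictly decreasing function of jitter; extracted speed equals the
  realized (pixel-quantized) nominal speed.
* **Study level** — subject intercepts alpha_i ~ Normal(mu_alpha,
  sigma_alpha); per recording, standardized (speed, accuracy) targets from
  a bivariate normal (independent by default); the stress bit from the
  logistic model Bernoulli(invlogit(alpha_i + b1*s + b2*a + b3*s*a)).
  Valence/arousal self-reports are drawn uniformly from the circumplex
  cells consistent with the stress bit.  ``mu_alpha`` defaults to the
  value solving a 10.1% marginal stress prevalence by quadrature.
* **Raw mode** — the (speed, accuracy) targets are realized as event
  streams: speed by a linear map to pixels/second, accuracy through a
  monotone jitter calibration curve estimated once per run by simulation.
  Optional corruption (no-movement, tracking-error, sparse recordings)
  exercises the exclusion filters.

Identical seeds produce identical studies in every mode.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime, timedelta
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import expit

from .event_io import EventKind, EventLog, MouseEvent, SelfReport, ValidationError
from .features import RecordingFeatures

__all__ = [
    "TrajectoryParams",
    "StudyParams",
    "GroundTruth",
    "StudyData",
    "generate_trajectory",
    "generate_study",
    "generate_covariates",
    "solve_intercept_mean",
    "EXCLUSION_CALIBRATION_RATES",
]

#: Corruption rates (no-movement, tracking-error, sparse) calibrated so a
#: 2029-recording study loses ≈(5, 92, 200) recordings to the three filters.
EXCLUSION_CALIBRATION_RATES = (0.003, 0.045, 0.10)

_SCREEN = (1920, 1080)
_STRESS_CELLS = [(v, a) for v in (1, 2, 3) for a in (5, 6, 7)]
_NONSTRESS_CELLS = [
    (v, a) for v in range(1, 8) for a in range(1, 8) if not (v < 4 and a > 4)
]
# linear maps from standardized targets to raw trajectory parameters
_SPEED_BASE_PX_S = 400.0
_SPEED_SD_PX_S = 120.0
_SPEED_FLOOR_PX_S = 60.0
_ACC_BASE = 0.75
_ACC_SD = 0.08


@dataclass(frozen=True)
class TrajectoryParams:
    """Parameters of one simulated movement."""

    start: tuple[int, int]
    target: tuple[int, int]
    nominal_speed: float
    jitter: float
    duration_s: float = 2.0
    sample_interval_ms: int = 8
    terminal_kind: EventKind = EventKind.CLICK

    def __post_init__(self) -> None:
        if not (0.0 <= self.jitter <= 1.0):
            raise ValidationError("jitter must be in [0, 1]")
        if self.nominal_speed <= 0 or self.duration_s <= 0:
            raise ValidationError("nominal_speed and duration_s must be positive")


def _trajectory_arrays(
    p: TrajectoryParams, rng: np.random.Generator, t0: int = 0
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, float]:
    """Simulate one trajectory; returns (t, x, y, kind, realized_speed).

    The base step is the per-sample displacement toward the target rounded
    to integer pixels (positions are screen pixels), so the realized speed
    is the quantized ``|base_step| / interval``; with ``jitter == 0`` the
    path is exactly monotone on both axes.
    """
    dt = p.sample_interval_ms
    n_steps = max(2, int(round(p.duration_s * 1000.0 / dt)))
    d = np.array(p.target, dtype=float) - np.array(p.start, dtype=float)
    dist = np.hypot(*d)
    u = d / dist if dist > 0 else np.array([1.0, 0.0])
    step_mag = p.nominal_speed * dt / 1000.0
    base = np.round(u * step_mag).astype(np.int64)
    if base[0] == 0 and base[1] == 0:
        base[np.argmax(np.abs(u))] = 1 if u[np.argmax(np.abs(u))] >= 0 else -1
    # expected step magnitude: sign flips preserve it, but a deviation on a
    # zero base axis injects a 1 px component
    m = float(np.hypot(*base))
    if base[0] == 0 or base[1] == 0:
        m = (1.0 - p.jitter) * m + p.jitter * float(np.sqrt(m * m + 1.0))
    realized_speed = m / dt * 1000.0

    steps = np.tile(base, (n_steps, 1))
    if p.jitter > 0:
        deviate = rng.random((n_steps, 2)) < p.jitter
        signs = rng.choice((-1, 1), size=(n_steps, 2))
        mag = np.maximum(np.abs(base), 1)
        steps = np.where(deviate, signs * mag, steps)
    pos = np.empty((n_steps + 1, 2), dtype=np.int64)
    pos[0] = p.start
    pos[1:] = np.asarray(p.start) + np.cumsum(steps, axis=0)
    t = t0 + dt * np.arange(n_steps + 1, dtype=np.int64)
    kind = np.full(n_steps + 1, "move", dtype="U5")
    kind[-1] = p.terminal_kind.value
    return t, pos[:, 0], pos[:, 1], kind, realized_speed


def generate_trajectory(p: TrajectoryParams, rng: np.random.Generator) -> list[MouseEvent]:
    """Simulate one movement ending in a click/wheel, as event objects."""
    t, x, y, kind, _ = _trajectory_arrays(p, rng)
    return [
        MouseEvent(int(ti), int(xi), int(yi), EventKind(ki))
        for ti, xi, yi, ki in zip(t, x, y, kind)
    ]


def solve_intercept_mean(
    prevalence: float,
    betas: tuple[float, float, float],
    sigma_alpha: float,
    feature_corr: float = 0.0,
    n_nodes: int = 21,
) -> float:
    """Population intercept giving the target marginal stress prevalence.

    Integrates invlogit(alpha + b1*s + b2*a + b3*s*a) over alpha ~
    Normal(mu, sigma_alpha) and standardized (s, a) by Gauss-Hermite
    quadrature, and solves for mu.  Deterministic.
    """
    if not (0.0 < prevalence < 1.0):
        raise ValidationError("prevalence must be in (0, 1)")
    nodes, weights = np.polynomial.hermite_e.hermegauss(n_nodes)
    w = weights / weights.sum()
    b1, b2, b3 = betas
    s = nodes[:, None]
    a_ind = nodes[None, :]
    a = feature_corr * s + np.sqrt(1 - feature_corr**2) * a_ind
    lin_sa = b1 * s + b2 * a + b3 * s * a  # (n, n)
    w_sa = w[:, None] * w[None, :]

    def marginal(mu: float) -> float:
        lin = mu + sigma_alpha * nodes[:, None, None] + lin_sa[None, :, :]
        probs = expit(lin)
        return float(np.einsum("i,jk,ijk->", w, w_sa, probs))

    return float(optimize.brentq(lambda m: marginal(m) - prevalence, -25.0, 10.0))


@dataclass
class GroundTruth:
    """Everything the generator knows: the oracle for recovery tests."""

    true_betas: tuple[float, float, float]
    mu_alpha: float
    sigma_alpha: float
    subjects: pd.DataFrame  # subject_id, alpha, is_outlier
    recordings: pd.DataFrame  # per-recording targets, stress prob/bit, corruption
    jitter_calibration: pd.DataFrame | None = None  # jitter grid -> mean accuracy


@dataclass
class StudyData:
    """Output of :func:`generate_study`: inputs for the pipeline + truth."""

    mode: str
    reports: list[SelfReport]
    truth: GroundTruth
    features: list[RecordingFeatures] | None = None  # direct mode
    logs: list[EventLog] | None = None  # raw mode


@dataclass(frozen=True)
class StudyParams:
    """Study-level generative settings.

    Defaults mirror the field-study conditions: 70 subjects, ~26
    recordings each (rounded Normal(26.13, 14.33), clipped to 1..70), true
    interaction effect −0.32 with null main effects, 10.1% marginal stress
    prevalence, subject heterogeneity sigma_alpha = 1 on the logit scale.
    ``corruption_rates`` (no-movement, tracking-error, sparse) default to
    zero; see :data:`EXCLUSION_CALIBRATION_RATES` for the exclusion-filter
    calibration.
    """

    seed: int
    n_subjects: int = 70
    recordings_mean: float = 26.13
    recordings_sd: float = 14.33
    true_betas: tuple[float, float, float] = (0.0, 0.0, -0.32)
    prevalence: float = 0.101
    intercept_mean: float | None = None  # solved from prevalence when None
    intercept_sd: float = 1.0
    feature_corr: float = 0.0
    mode: Literal["direct", "raw"] = "direct"
    corruption_rates: tuple[float, float, float] = (0.0, 0.0, 0.0)
    min_trajectories: int = 10
    trajectories_mean: int = 16
    n_outlier_subjects: int = 0
    outlier_accuracy_shift: float = -4.0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValidationError("need at least 2 subjects")
        if sum(self.corruption_rates) >= 1.0:
            raise ValidationError("corruption rates must sum below 1")
        if self.mode not in ("direct", "raw"):
            raise ValidationError(f"unknown mode {self.mode!r}")
        if self.intercept_mean is None and not (0 < self.prevalence < 1):
            raise ValidationError("prevalence must be in (0, 1)")


def _random_datetime(rng: np.random.Generator) -> datetime:
    """A study-window timestamp: weekdays ~20% each, weekend ~1%, AM 52%."""
    base = datetime(2021, 2, 1)  # a Monday
    week = int(rng.integers(0, 7))
    if rng.random() < 0.01:
        day = int(rng.integers(5, 7))
    else:
        day = int(rng.integers(0, 5))
    if rng.random() < 0.52:
        hour = int(rng.integers(9, 11))
    else:
        hour = int(rng.integers(14, 16))
    minute = int(rng.integers(0, 60))
    return base + timedelta(days=7 * week + day, hours=hour, minutes=minute)


def _draw_affect(stress: int, rng: np.random.Generator) -> tuple[int, int]:
    cells = _STRESS_CELLS if stress else _NONSTRESS_CELLS
    v, a = cells[int(rng.integers(0, len(cells)))]
    return v, a


def _calibrate_jitter(rng: np.random.Generator, n_per_point: int = 40) -> pd.DataFrame:
    """Mean extracted accuracy on a jitter grid (simulation, once per run)."""
    from .features import Trajectory, trajectory_accuracy

    grid = np.linspace(0.0, 1.0, 21)
    means = []
    for j in grid:
        accs = []
        for _ in range(n_per_point):
            angle = rng.uniform(0, 2 * np.pi)
            start = (960, 540)
            target = (
                int(start[0] + 4000 * np.cos(angle)),
                int(start[1] + 4000 * np.sin(angle)),
            )
            p = TrajectoryParams(start, target, _SPEED_BASE_PX_S, float(j), duration_s=2.0)
            t, x, y, kind, _ = _trajectory_arrays(p, rng)
            acc = trajectory_accuracy(Trajectory(t, x, y, EventKind.CLICK))
            if acc is not None:
                accs.append(acc)
        means.append(float(np.mean(accs)))
    return pd.DataFrame({"jitter": grid, "accuracy": means})


def _jitter_for_accuracy(target_acc: float, cal: pd.DataFrame) -> float:
    """Invert the monotone-decreasing calibration curve by interpolation."""
    acc = cal["accuracy"].to_numpy()
    jit = cal["jitter"].to_numpy()
    # enforce monotone decrease before inverting (simulation noise)
    acc = np.minimum.accumulate(acc)
    target = float(np.clip(target_acc, acc[-1], acc[0]))
    return float(np.interp(target, acc[::-1], jit[::-1]))


def _raw_recording(
    subject_id: str,
    recording_id: str,
    s_target: float,
    a_target: float,
    n_traj: int,
    cal: pd.DataFrame,
    rng: np.random.Generator,
    started_at: datetime,
    corruption: str,
) -> tuple[EventLog, float, float]:
    """Realize one recording as an event stream; returns (log, speed, jitter)."""
    nominal_speed = max(_SPEED_FLOOR_PX_S, _SPEED_BASE_PX_S + _SPEED_SD_PX_S * s_target)
    acc_target = _ACC_BASE + _ACC_SD * a_target
    jitter = _jitter_for_accuracy(acc_target, cal)

    ts, xs, ys, ks = [], [], [], []
    t_cursor = 0
    for _ in range(n_traj):
        duration = float(rng.uniform(1.3, 6.0))
        start = (int(rng.integers(100, _SCREEN[0] - 100)), int(rng.integers(100, _SCREEN[1] - 100)))
        angle = rng.uniform(0, 2 * np.pi)
        target = (
            int(start[0] + 40000 * np.cos(angle)),
            int(start[1] + 40000 * np.sin(angle)),
        )
        terminal = EventKind.WHEEL if rng.random() < 0.25 else EventKind.CLICK
        p = TrajectoryParams(start, target, nominal_speed, jitter, duration, terminal_kind=terminal)
        t, x, y, kind, _ = _trajectory_arrays(p, rng, t0=t_cursor)
        ts.append(t)
        xs.append(x)
        ys.append(y)
        ks.append(kind)
        t_cursor = int(t[-1] + rng.integers(200, 2000))

    t = np.concatenate(ts)
    x = np.concatenate(xs)
    y = np.concatenate(ys)
    kind = np.concatenate(ks)

    if corruption == "tracking_error":
        move_idx = np.flatnonzero(kind == "move")
        i = int(rng.choice(move_idx[1:]))
        if rng.random() < 0.5:
            t = t.copy()
            t[i] = t[i - 1]  # duplicate move timestamp
        else:
            t = t.copy()
            t[i] = max(0, t[i - 1] - int(rng.integers(1, 50)))  # decreasing step
    log = EventLog(subject_id, recording_id, t, x, y, kind, started_at)
    return log, nominal_speed, jitter


def generate_study(p: StudyParams) -> StudyData:
    """Generate a full multi-subject study with complete ground truth.

    In ``direct`` mode the standardized (speed, accuracy) targets are
    emitted as the feature table; in ``raw`` mode they are realized as
    event streams (clean recordings carry at least ``min_trajectories``
    trajectories) for the feature pipeline to process.  Corrupted
    recordings, when enabled, trip exactly one exclusion rule each.
    """
    rng = np.random.default_rng(p.seed)
    mu_alpha = (
        p.intercept_mean
        if p.intercept_mean is not None
        else solve_intercept_mean(p.prevalence, p.true_betas, p.intercept_sd, p.feature_corr)
    )
    b1, b2, b3 = p.true_betas
    alphas = mu_alpha + p.intercept_sd * rng.standard_normal(p.n_subjects)
    subject_ids = [f"s{i:03d}" for i in range(p.n_subjects)]
    outliers = set(subject_ids[: p.n_outlier_subjects])

    cal = _calibrate_jitter(rng) if p.mode == "raw" else None

    n_rec = np.clip(
        np.round(rng.normal(p.recordings_mean, p.recordings_sd, p.n_subjects)), 1, 70
    ).astype(int)

    r0, r1, r2 = p.corruption_rates
    reports: list[SelfReport] = []
    features: list[RecordingFeatures] = []
    logs: list[EventLog] = []
    rec_rows = []

    for i, sid in enumerate(subject_ids):
        for k in range(n_rec[i]):
            rid = f"{sid}_r{k:03d}"
            u = rng.random()
            if u < r0:
                corruption = "no_movement"
            elif u < r0 + r1:
                corruption = "tracking_error"
            elif u < r0 + r1 + r2:
                corruption = "sparse"
            else:
                corruption = "clean"

            s = rng.standard_normal()
            a_ind = rng.standard_normal()
            a = p.feature_corr * s + np.sqrt(1 - p.feature_corr**2) * a_ind
            if sid in outliers:
                a += p.outlier_accuracy_shift
            prob = float(expit(alphas[i] + b1 * s + b2 * a + b3 * s * a))
            stress = int(rng.random() < prob)
            val, aro = _draw_affect(stress, rng)
            started = _random_datetime(rng)
            weekday = (
                ["Mon", "Tue", "Wed", "Thu", "Fri"][started.weekday()]
                if started.weekday() < 5
                else "weekend"
            )
            daytime = "morning" if started.hour < 12 else "afternoon"
            reports.append(SelfReport(sid, rid, val, aro, started))

            speed_raw = jitter = np.nan
            if p.mode == "direct":
                wheel = float(rng.beta(2.0, 6.0))
                features.append(
                    RecordingFeatures(
                        subject_id=sid,
                        recording_id=rid,
                        n_trajectories=int(rng.poisson(p.trajectories_mean - p.min_trajectories))
                        + p.min_trajectories,
                        speed=float(s),
                        accuracy=float(a),
                        click_prop=1.0 - wheel,
                        wheel_prop=wheel,
                        weekday=weekday,
                        daytime=daytime,
                    )
                )
            else:
                if corruption == "no_movement":
                    n_ev = int(rng.integers(1, 4))
                    t = np.cumsum(rng.integers(500, 5000, n_ev)).astype(np.int64)
                    pos = rng.integers(0, 1000, (n_ev, 2)).astype(np.int64)
                    kinds = rng.choice(["click", "wheel"], n_ev).astype("U5")
                    logs.append(EventLog(sid, rid, t, pos[:, 0], pos[:, 1], kinds, started))
                else:
                    if corruption == "sparse":
                        n_traj = int(rng.integers(1, p.min_trajectories))
                    else:
                        n_traj = p.min_trajectories + int(
                            rng.poisson(max(1, p.trajectories_mean - p.min_trajectories))
                        )
                    log, speed_raw, jitter = _raw_recording(
                        sid, rid, s, a, n_traj, cal, rng, started, corruption
                    )
                    logs.append(log)

            rec_rows.append(
                {
                    "subject_id": sid,
                    "recording_id": rid,
                    "speed_target": float(s),
                    "accuracy_target": float(a),
                    "p_stress": prob,
                    "stress": stress,
                    "valence": val,
                    "arousal": aro,
                    "corruption": corruption,
                    "nominal_speed_px_s": speed_raw,
                    "jitter": jitter,
                }
            )

    truth = GroundTruth(
        true_betas=p.true_betas,
        mu_alpha=float(mu_alpha),
        sigma_alpha=p.intercept_sd,
        subjects=pd.DataFrame(
            {
                "subject_id": subject_ids,
                "alpha": alphas,
                "is_outlier": [s in outliers for s in subject_ids],
            }
        ),
        recordings=pd.DataFrame(rec_rows),
        jitter_calibration=cal,
    )
    return StudyData(
        mode=p.mode,
        reports=reports,
        truth=truth,
        features=features if p.mode == "direct" else None,
        logs=logs if p.mode == "raw" else None,
    )


def generate_covariates(n_subjects: int, seed: int | np.random.Generator) -> pd.DataFrame:
    """Per-subject covariate table with field-study marginals.

    Age uniform 20–61; gender dummy (1 = male) with 46% female; education
    dummy (1 = university degree) at 59%; sport/nutrition small counts;
    alcohol and smoking on their 1–4 categorical scales; big-five traits
    on 1–10.  Indexed by ``subject_id``; deterministic given the seed.
    """
    if n_subjects < 1:
        raise ValidationError("n_subjects must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    df = pd.DataFrame(
        {
            "subject_id": [f"s{i:03d}" for i in range(n_subjects)],
            "age": rng.integers(20, 62, n_subjects),
            "gender": (rng.random(n_subjects) < 0.54).astype(int),
            "education": (rng.random(n_subjects) < 0.59).astype(int),
            "sport": rng.integers(0, 11, n_subjects),
            "nutrition": rng.integers(0, 9, n_subjects),
            "alcohol": rng.integers(1, 5, n_subjects),
            "smoking": rng.integers(1, 5, n_subjects),
            "openness": rng.integers(1, 11, n_subjects),
            "conscientiousness": rng.integers(1, 11, n_subjects),
            "extraversion": rng.integers(1, 11, n_subjects),
            "agreeableness": rng.integers(1, 11, n_subjects),
            "neuroticism": rng.integers(1, 11, n_subjects),
        }
    ).set_index("subject_id")
    return df


def save_study(study: StudyData, out_dir: str | Path) -> None:
    """Write a study in the pipeline's text formats (plus the truth tables)."""
    from .event_io import write_self_reports
    from .features import write_features

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_self_reports(study.reports, out / "self_reports.csv")
    if study.features is not None:
        write_features(study.features, out / "features.csv")
    if study.logs is not None:
        from .event_io import write_event_log

        logdir = out / "logs"
        logdir.mkdir(exist_ok=True)
        for log in study.logs:
            write_event_log(log, logdir / f"{log.subject_id}__{log.recording_id}.csv")
    study.truth.subjects.to_csv(out / "truth_subjects.csv", index=False)
    study.truth.recordings.to_csv(out / "truth_recordings.csv", index=False)
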