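"""Circumplex encoding of affect self-reports into stress outcomes.

Following the circumplex model of affect, acute stress is the combination
of low valence and high arousal.  On 7-point scales with neutral midpoint
4, the dichotomous outcome is::

    stress = 1  iff  valence < 4 and arousal > 4        (else 0)

Of the 49 (valence, arousal) cells, exactly the 9 with valence in {1,2,3}
and arousal in {5,6,7} encode stress.  A discrete severity-like measure
used in sensitivity analyses is ``arousal − valence + 6`` (range 0–12);
note it is not equivalent to the dichotomy — e.g. (valence 4, arousal 7)
and (valence 2, arousal 5) both score 9 but only the latter is stress.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

from .event_io import SelfReport, ValidationError
from .features import RecordingFeatures, features_to_frame

__all__ = [
    "StressObservation",
    "DataIntegrityError",
    "encode_stress",
    "encode_discrete_stress",
    "join_observations",
    "observations_to_frame",
    "write_observations",
    "read_observations",
]

OBSERVATIONS_HEADER = [
    "subject_id",
    "recording_id",
    "stress",
    "valence",
    "arousal",
    "discrete_stress",
    "speed",
    "accuracy",
    "click_prop",
    "wheel_prop",
    "weekday",
    "daytime",
]


class DataIntegrityError(ValueError):
    """Duplicate or inconsistent keys while joining tables."""


def _check_scale(name: str, v: int) -> None:
    if not (isinstance(v, int) and 1 <= v <= 7):
        raise ValidationError(f"{name} must be an integer in 1..7, got {v!r}")


def encode_stress(valence: int, arousal: int) -> int:
    """Dichotomous stress: 1 iff valence < 4 and arousal > 4 (both strict)."""
    _check_scale("valence", valence)
    _check_scale("arousal", arousal)
    return int(valence < 4 and arousal > 4)


def encode_discrete_stress(valence: int, arousal: int) -> int:
    """Discrete stress measure ``arousal − valence + 6`` in 0..12."""
    _check_scale("valence", valence)
    _check_scale("arousal", arousal)
    return arousal - valence + 6


@dataclass
class StressObservation:
    """One joined row of the regression data set."""

    subject_id: str
    recording_id: str
    stress: int
    valence: int
    arousal: int
    discrete_stress: int
    features: RecordingFeatures


def join_observations(
    reports: Sequence[SelfReport],
    feats: Sequence[RecordingFeatures],
) -> tuple[list[StressObservation], list[SelfReport], list[RecordingFeatures]]:
    """Inner-join self-reports with recording features on (subject, recording).

    Returns ``(observations, unmatched_reports, unmatched_features)`` so
    nothing is silently dropped.  Duplicate keys on either side raise
    :class:`DataIntegrityError`.
    """
    def key(o) -> tuple[str, str]:
        return (o.subject_id, o.recording_id)

    rmap: dict[tuple[str, str], SelfReport] = {}
    for r in reports:
        if key(r) in rmap:
            raise DataIntegrityError(f"duplicate self-report key {key(r)}")
        rmap[key(r)] = r
    fmap: dict[tuple[str, str], RecordingFeatures] = {}
    for f in feats:
        if key(f) in fmap:
            raise DataIntegrityError(f"duplicate feature key {key(f)}")
        fmap[key(f)] = f

    obs = [
        StressObservation(
            subject_id=k[0],
            recording_id=k[1],
            stress=encode_stress(rmap[k].valence, rmap[k].arousal),
            valence=rmap[k].valence,
            arousal=rmap[k].arousal,
            discrete_stress=encode_discrete_stress(rmap[k].valence, rmap[k].arousal),
            features=fmap[k],
        )
        for k in rmap
        if k in fmap
    ]
    unmatched_reports = [r for k, r in rmap.items() if k not in fmap]
    unmatched_feats = [f for k, f in fmap.items() if k not in rmap]
    return obs, unmatched_reports, unmatched_feats


def observations_to_frame(obs: Sequence[StressObservation]) -> pd.DataFrame:
    """Long-form observations table (one row per recording)."""
    fdf = features_to_frame([o.features for o in obs])
    df = pd.DataFrame(
        {
            "subject_id": [o.subject_id for o in obs],
            "recording_id": [o.recording_id for o in obs],
            "stress": [o.stress for o in obs],
            "valence": [o.valence for o in obs],
            "arousal": [o.arousal for o in obs],
            "discrete_stress": [o.discrete_stress for o in obs],
        }
    )
    for c in ("speed", "accuracy", "click_prop", "wheel_prop", "weekday", "daytime"):
        df[c] = fdf[c].to_numpy()
    return df[OBSERVATIONS_HEADER]


def write_observations(obs: Sequence[StressObservation], path: str | Path) -> None:
    observations_to_frame(obs).to_csv(path, index=False)


def read_observations(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"subject_id": str, "recording_id": str})
    missing = [c for c in OBSERVATIONS_HEADER if c not in df.columns]
    if missing:
        raise DataIntegrityError(f"observations table missing columns {missing}")
    return df
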