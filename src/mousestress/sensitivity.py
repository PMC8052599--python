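"""Robustness checks: filter settings, model variants, outcome encodings.

``run_grid`` re-runs the full estimate over a cartesian grid of
processing and modelling choices — trajectory-count minimum, maximum
trajectory duration, control blocks / varying slopes, outcome encoding,
and optional subject exclusions — recording the interaction coefficient
(posterior mean and 95% HPDI) per cell.  Cells are independent and
reproducible: each gets the seed ``base_seed + a stable hash of its
settings``.  A failing cell is recorded, not fatal to the grid.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .encoding import join_observations
from .event_io import EventLog, SelfReport, ValidationError
from .features import FilterConfig, RecordingFeatures, apply_exclusions
from .model import ModelSpec, PriorSpec, SamplerConfig, fit, hpdi

__all__ = ["SensitivityGrid", "run_grid", "flag_outlier_subjects", "cell_seed"]

_VARIANTS = (
    "base",
    "varying_slopes",
    "+mouse_events",
    "+sociodemographics",
    "+health",
    "+personality",
)


@dataclass(frozen=True)
class SensitivityGrid:
    """Axes of the robustness grid (all nonempty)."""

    min_trajectories_values: tuple[int, ...] = (10,)
    max_duration_values: tuple[float, ...] = (10.0,)
    model_variants: tuple[str, ...] = ("base",)
    outcome_variants: tuple[str, ...] = ("stress",)
    subject_exclusion_sets: tuple[tuple[str, ...], ...] = ((),)

    def __post_init__(self) -> None:
        if not all(
            (
                self.min_trajectories_values,
                self.max_duration_values,
                self.model_variants,
                self.outcome_variants,
                self.subject_exclusion_sets,
            )
        ):
            raise ValidationError("every grid axis must be nonempty")
        bad = set(self.model_variants) - set(_VARIANTS)
        if bad:
            raise ValidationError(f"unknown model variants {sorted(bad)}")

    def cells(self):
        for mt in self.min_trajectories_values:
            for md in self.max_duration_values:
                for var in self.model_variants:
                    for out in self.outcome_variants:
                        for excl in self.subject_exclusion_sets:
                            yield (mt, md, var, out, tuple(excl))


def cell_seed(base_seed: int, cell: tuple) -> int:
    """Deterministic per-cell seed: base seed plus a stable settings hash."""
    digest = zlib.crc32(repr(cell).encode("utf-8"))
    return int((base_seed + digest) % (2**31 - 1))


def _spec_for(variant: str, outcome: str) -> ModelSpec:
    if variant == "base":
        return ModelSpec(outcome=outcome)
    if variant == "varying_slopes":
        return ModelSpec(outcome=outcome, varying_slopes=True)
    return ModelSpec(outcome=outcome, controls=(variant.lstrip("+"),))


def run_grid(
    reports: Sequence[SelfReport],
    grid: SensitivityGrid,
    sampler: SamplerConfig,
    logs: Sequence[EventLog] | None = None,
    features: Sequence[RecordingFeatures] | None = None,
    covariates: pd.DataFrame | None = None,
    priors: PriorSpec | None = None,
) -> pd.DataFrame:
    """Run every grid cell and return a long-form results table.

    Provide ``logs`` to let filter axes re-run segmentation, or
    ``features`` for a feature-level grid (then only the trajectory-count
    minimum can vary; a non-default maximum duration needs raw logs).
    One row per cell: settings, the interaction coefficient's posterior
    mean and 95% HPDI, diagnostics, or the recorded error.
    """
    if (logs is None) == (features is None):
        raise ValidationError("provide exactly one of logs or features")
    rows = []
    for cell in grid.cells():
        mt, md, variant, outcome, excl = cell
        seed = cell_seed(sampler.seed, cell)
        row = {
            "min_trajectories": mt,
            "max_duration_s": md,
            "variant": variant,
            "outcome": outcome,
            "excluded_subjects": ";".join(excl),
            "seed": seed,
        }
        try:
            if logs is not None:
                cfg = FilterConfig(min_duration_s=1.0, max_duration_s=md, min_trajectories=mt)
                feats, _ = apply_exclusions(logs, cfg)
            else:
                if md != 10.0:
                    raise ValidationError("varying max duration needs raw logs")
                feats = [f for f in features if f.n_trajectories >= mt]
            feats = [f for f in feats if f.subject_id not in excl]
            reps = [r for r in reports if r.subject_id not in excl]
            obs, _, _ = join_observations(reps, feats)
            spec = _spec_for(variant, outcome)
            cfg_sampler = SamplerConfig(
                seed=seed,
                n_chains=sampler.n_chains,
                n_warmup=sampler.n_warmup,
                n_sampling=sampler.n_sampling,
                target_accept=sampler.target_accept,
                max_treedepth=sampler.max_treedepth,
                rhat_threshold=sampler.rhat_threshold,
            )
            summary = fit(obs, spec, priors=priors, sampler=cfg_sampler, covariates=covariates)
            draws = summary.draws_of("b_speed_x_accuracy")
            lo, hi = hpdi(draws, 0.95)
            row.update(
                n_obs=len(obs),
                beta3_mean=float(draws.mean()),
                beta3_hpdi_low=lo,
                beta3_hpdi_high=hi,
                rhat_max=max(summary.diagnostics["rhat"].values()),
                n_divergent=summary.diagnostics["n_divergent"],
                error="",
            )
        except Exception as exc:  # cell failures are data, not crashes
            row.update(
                n_obs=np.nan,
                beta3_mean=np.nan,
                beta3_hpdi_low=np.nan,
                beta3_hpdi_high=np.nan,
                rhat_max=np.nan,
                n_divergent=np.nan,
                error=f"{type(exc).__name__}: {exc}",
            )
        rows.append(row)
    return pd.DataFrame(rows)


def flag_outlier_subjects(
    features: Sequence[RecordingFeatures] | pd.DataFrame, rule: float = 2.0
) -> list[str]:
    """Subjects whose mean accuracy is unusually low.

    Flags subjects whose mean recording accuracy lies below the pooled
    mean minus ``rule`` pooled standard deviations (pooled over all
    recordings).  The threshold is parameterized; 2 SD is the default.
    """
    from .features import features_to_frame

    df = features if isinstance(features, pd.DataFrame) else features_to_frame(features)
    if df["subject_id"].nunique() < 2:
        raise ValidationError("need at least 2 subjects")
    pooled_mean = float(df["accuracy"].mean())
    pooled_sd = float(df["accuracy"].std(ddof=1))
    cut = pooled_mean - rule * pooled_sd
    per_subject = df.groupby("subject_id")["accuracy"].mean()
    return sorted(per_subject.index[per_subject < cut].astype(str))
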