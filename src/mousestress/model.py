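"""Hierarchical Bayesian regression of stress on mouse speed and accuracy.

The primary model is a varying-intercept logistic regression::

    stress_ik ~ Bernoulli(logit^-1(alpha_i + b1*speed_ik + b2*accuracy_ik
                                     + b3*speed_ik*accuracy_ik + controls))
    alpha_i = mu_alpha + sigma_alpha * z_i,     z_i ~ Normal(0, 1)

for subject i and recording k.  Speed and accuracy enter centered and
scaled by their pooled empirical mean and sample standard deviation, so
the interaction coefficient b3 reads off the speed-accuracy trade-off: a
negative b3 means that fast-but-inaccurate or slow-but-accurate movement
raises the odds of stress.  Sensitivity variants swap the outcome for
valence, arousal or the discrete stress score under a Poisson-log link,
add control blocks, or add subject-varying slopes on speed and accuracy.

Estimation is full MCMC with the in-package No-U-Turn Sampler
(:mod:`mousestress.nuts`), 4 chains of 1000 warm-up + 1000 retained
iterations by default, under weakly informative priors (Normal(0, 2.5) on
coefficients and the population intercept, half-Student-t(3, 2.5) on group
standard deviations).  Convergence is a hard gate: split-R-hat above the
threshold or any post-warmup divergence raises :class:`ConvergenceError`.
Posteriors are summarized by the mean and the 95% highest posterior
density interval (HPDI) — the shortest interval holding the mass.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import arviz as az
import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

from .encoding import StressObservation, observations_to_frame
from .event_io import ValidationError
from .features import Standardizer

__all__ = [
    "ModelSpec",
    "PriorSpec",
    "SamplerConfig",
    "PosteriorSummary",
    "ConvergenceError",
    "DegenerateDataError",
    "fit",
    "hpdi",
    "odds_change",
    "partial_dependence",
    "participation_bias_test",
    "CONTROL_BLOCKS",
]


class ConvergenceError(RuntimeError):
    """MCMC did not converge; carries the offending diagnostics."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class DegenerateDataError(ValueError):
    """The data cannot identify the model (single subject, constant outcome...)."""


#: Control blocks selectable in :class:`ModelSpec.controls`.
CONTROL_BLOCKS = (
    "mouse_events",       # click/wheel proportions
    "weekday",            # indicators vs Monday
    "daytime",            # morning dummy
    "sociodemographics",  # age, gender, education
    "health",             # sport, nutrition, alcohol, smoking
    "personality",        # big five
)

_POISSON_OUTCOMES = ("valence", "arousal", "discrete_stress")


@dataclass(frozen=True)
class ModelSpec:
    """What to regress on what.

    ``outcome='stress'`` uses a Bernoulli-logit likelihood; ``valence``,
    ``arousal`` and ``discrete_stress`` use Poisson-log (sensitivity
    variants).  ``controls`` lists blocks from :data:`CONTROL_BLOCKS`.
    ``varying_slopes`` adds independent subject-level slopes on speed and
    accuracy (non-centered, each with its own half-t group sd).
    """

    outcome: str = "stress"
    controls: tuple[str, ...] = ()
    varying_slopes: bool = False

    def __post_init__(self) -> None:
        if self.outcome not in ("stress",) + _POISSON_OUTCOMES:
            raise ValidationError(f"unknown outcome {self.outcome!r}")
        bad = set(self.controls) - set(CONTROL_BLOCKS)
        if bad:
            raise ValidationError(f"unknown control blocks {sorted(bad)}")


@dataclass(frozen=True)
class PriorSpec:
    """Weakly informative priors (all scales > 0, configurable)."""

    coef_scale: float = 2.5
    intercept_scale: float = 2.5
    group_sd_scale: float = 2.5
    group_sd_df: float = 3.0

    def __post_init__(self) -> None:
        for v in (self.coef_scale, self.intercept_scale, self.group_sd_scale, self.group_sd_df):
            if v <= 0:
                raise ValidationError("prior scales and df must be positive")


@dataclass(frozen=True)
class SamplerConfig:
    """MCMC configuration; the seed is required and logged with results."""

    seed: int
    n_chains: int = 4
    n_warmup: int = 1000
    n_sampling: int = 1000
    target_accept: float = 0.9
    max_treedepth: int = 10
    rhat_threshold: float = 1.01
    algorithm: str = "nuts"

    def __post_init__(self) -> None:
        if min(self.n_chains, self.n_warmup, self.n_sampling) <= 0:
            raise ValidationError("chain/iteration counts must be positive")


@dataclass
class PosteriorSummary:
    """Draws and summaries of a fitted model.

    ``params`` maps each scalar parameter name to a ``(chains, draws)``
    array; subject intercepts (and, if present, subject slopes) are held
    as ``(chains, draws, n_subjects)`` arrays.
    """

    params: dict[str, np.ndarray]
    alpha: np.ndarray
    subjects: list[str]
    spec: ModelSpec
    priors: PriorSpec
    sampler: SamplerConfig
    scaler: Standardizer | None
    diagnostics: dict
    slope_speed: np.ndarray | None = None
    slope_accuracy: np.ndarray | None = None
    fixed_names: list[str] = field(default_factory=list)

    def draws_of(self, name: str) -> np.ndarray:
        return self.params[name].reshape(-1)

    def mean(self, name: str) -> float:
        return float(self.draws_of(name).mean())

    def hpdi_of(self, name: str, mass: float = 0.95) -> tuple[float, float]:
        return hpdi(self.draws_of(name), mass)

    def table(self, mass: float = 0.95) -> pd.DataFrame:
        """Summary table: parameter, mean, hpdi_low, hpdi_high, rhat, ess."""
        rows = []
        for name in self.params:
            lo, hi = self.hpdi_of(name, mass)
            rows.append(
                {
                    "parameter": name,
                    "mean": self.mean(name),
                    "hpdi_low": lo,
                    "hpdi_high": hi,
                    "rhat": self.diagnostics["rhat"].get(name, np.nan),
                    "ess": self.diagnostics["ess"].get(name, np.nan),
                }
            )
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Design-matrix assembly


def _as_frame(data) -> pd.DataFrame:
    if isinstance(data, pd.DataFrame):
        return data.copy()
    if len(data) and isinstance(data[0], StressObservation):
        return observations_to_frame(data)
    raise ValidationError("data must be a DataFrame or a list of StressObservation")


def _control_columns(
    df: pd.DataFrame, blocks: Sequence[str], covariates: pd.DataFrame | None
) -> pd.DataFrame:
    """Assemble control columns: continuous ones centered and scaled,
    categorical ones as indicator contrasts against the first level."""
    out = {}

    def zscore(x: pd.Series) -> np.ndarray:
        v = x.to_numpy(dtype=float)
        s = v.std(ddof=1)
        return (v - v.mean()) / (s if s > 0 else 1.0)

    if "mouse_events" in blocks:
        out["b_click_prop"] = zscore(df["click_prop"])
        out["b_wheel_prop"] = zscore(df["wheel_prop"])
    if "weekday" in blocks:
        levels = ["Mon", "Tue", "Wed", "Thu", "Fri", "weekend"]
        for lv in levels[1:]:
            out[f"b_weekday_{lv}"] = (df["weekday"] == lv).to_numpy(dtype=float)
    if "daytime" in blocks:
        out["b_daytime_morning"] = (df["daytime"] == "morning").to_numpy(dtype=float)

    needs_cov = {"sociodemographics", "health", "personality"} & set(blocks)
    if needs_cov:
        if covariates is None:
            raise ValidationError(f"blocks {sorted(needs_cov)} need a covariate table")
        cov = covariates.loc[df["subject_id"].astype(str)]
        if "sociodemographics" in blocks:
            out["b_age"] = zscore(cov["age"])
            out["b_gender_male"] = cov["gender"].to_numpy(dtype=float)
            out["b_education_univ"] = cov["education"].to_numpy(dtype=float)
        if "health" in blocks:
            out["b_sport"] = zscore(cov["sport"])
            out["b_nutrition"] = zscore(cov["nutrition"])
            for var in ("alcohol", "smoking"):
                vals = cov[var].to_numpy()
                for lv in (2, 3, 4):
                    out[f"b_{var}_{lv}"] = (vals == lv).astype(float)
        if "personality" in blocks:
            for trait in (
                "openness",
                "conscientiousness",
                "extraversion",
                "agreeableness",
                "neuroticism",
            ):
                out[f"b_{trait}"] = zscore(cov[trait])
    return pd.DataFrame(out, index=df.index)


# ---------------------------------------------------------------------------
# Log posterior


def _make_logp_grad(
    y: np.ndarray,
    X: np.ndarray,
    subj: np.ndarray,
    n_subjects: int,
    family: str,
    priors: PriorSpec,
    varying_slopes: bool,
    speed: np.ndarray | None,
    acc: np.ndarray | None,
):
    """Return (logp_grad, dim, unpack) for the flat parameter vector.

    Layout: [mu_alpha, beta (p), log_sigma_alpha, z (M)]
    plus, with varying slopes, [log_sigma_s, log_sigma_a, zs (M), za (M)].
    Group sds are sampled on the log scale (Jacobian included).
    """
    n, p = X.shape
    M = n_subjects
    s_int2 = priors.intercept_scale**2
    s_coef2 = priors.coef_scale**2
    nu = priors.group_sd_df
    s_sd2 = priors.group_sd_scale**2

    i_mu = 0
    i_beta = slice(1, 1 + p)
    i_ls = 1 + p
    i_z = slice(2 + p, 2 + p + M)
    dim = 2 + p + M
    if varying_slopes:
        i_lss = dim
        i_lsa = dim + 1
        i_zs = slice(dim + 2, dim + 2 + M)
        i_za = slice(dim + 2 + M, dim + 2 + 2 * M)
        dim = dim + 2 + 2 * M

    def half_t_logp_grad(ls: float) -> tuple[float, float]:
        sig2 = np.exp(2.0 * ls)
        lp = -(nu + 1) / 2 * np.log1p(sig2 / (nu * s_sd2)) + ls
        dlp = -(nu + 1) * sig2 / (nu * s_sd2 + sig2) + 1.0
        return lp, dlp

    def logp_grad(theta: np.ndarray) -> tuple[float, np.ndarray]:
        mu = theta[i_mu]
        beta = theta[i_beta]
        ls = theta[i_ls]
        z = theta[i_z]
        sigma = np.exp(ls)
        eta = mu + sigma * z[subj] + X @ beta
        if varying_slopes:
            ss = np.exp(theta[i_lss])
            sa = np.exp(theta[i_lsa])
            zs = theta[i_zs]
            za = theta[i_za]
            eta = eta + ss * zs[subj] * speed + sa * za[subj] * acc

        if family == "bernoulli":
            ll = float(np.dot(y, eta) - np.logaddexp(0.0, eta).sum())
            g_eta = y - expit(eta)
        else:  # poisson
            lam = np.exp(np.minimum(eta, 30.0))
            ll = float(np.dot(y, eta) - lam.sum())
            g_eta = y - lam

        lp_ht, g_ht = half_t_logp_grad(ls)
        lp = (
            ll
            - 0.5 * mu * mu / s_int2
            - 0.5 * float(beta @ beta) / s_coef2
            - 0.5 * float(z @ z)
            + lp_ht
        )
        grad = np.empty_like(theta)
        ge_by_subj = np.bincount(subj, weights=g_eta, minlength=M)
        grad[i_mu] = g_eta.sum() - mu / s_int2
        grad[i_beta] = X.T @ g_eta - beta / s_coef2
        grad[i_z] = sigma * ge_by_subj - z
        grad[i_ls] = sigma * float(ge_by_subj @ z) + g_ht

        if varying_slopes:
            lp_s, g_s = half_t_logp_grad(theta[i_lss])
            lp_a, g_a = half_t_logp_grad(theta[i_lsa])
            lp += lp_s + lp_a - 0.5 * float(zs @ zs) - 0.5 * float(za @ za)
            gs_subj = np.bincount(subj, weights=g_eta * speed, minlength=M)
            ga_subj = np.bincount(subj, weights=g_eta * acc, minlength=M)
            grad[i_zs] = ss * gs_subj - zs
            grad[i_za] = sa * ga_subj - za
            grad[i_lss] = ss * float(gs_subj @ zs) + g_s
            grad[i_lsa] = sa * float(ga_subj @ za) + g_a
        return lp, grad

    def unpack(draws: np.ndarray) -> dict:
        sigma = np.exp(draws[..., i_ls])
        out = {
            "mu": draws[..., i_mu],
            "beta": draws[..., i_beta],
            "sigma": sigma,
            "alpha": draws[..., i_mu, None] + sigma[..., None] * draws[..., i_z],
        }
        if varying_slopes:
            out["sigma_slope_speed"] = np.exp(draws[..., i_lss])
            out["sigma_slope_accuracy"] = np.exp(draws[..., i_lsa])
            out["slope_speed"] = out["sigma_slope_speed"][..., None] * draws[..., i_zs]
            out["slope_accuracy"] = out["sigma_slope_accuracy"][..., None] * draws[..., i_za]
        return out

    return logp_grad, dim, unpack


# ---------------------------------------------------------------------------
# Fitting


def fit(
    data,
    spec: ModelSpec | None = None,
    priors: PriorSpec | None = None,
    sampler: SamplerConfig | None = None,
    covariates: pd.DataFrame | None = None,
    standardize: bool = True,
) -> PosteriorSummary:
    """Fit the hierarchical regression by NUTS and summarize the posterior.

    Parameters
    ----------
    data
        Observations table (``observations_to_frame`` layout) or a list of
        :class:`~mousestress.encoding.StressObservation`.
    standardize
        Center/scale speed and accuracy by their pooled mean and sample sd
        before forming the interaction (the default and the intended use;
        pass ``False`` only for data already on the standardized scale).

    Raises
    ------
    DegenerateDataError
        Fewer than two subjects, or a constant outcome.
    ConvergenceError
        Any monitored split-R-hat above the threshold, or any post-warmup
        divergence.
    """
    from .nuts import sample_nuts

    spec = spec or ModelSpec()
    priors = priors or PriorSpec()
    if sampler is None:
        raise ValidationError("a SamplerConfig with an explicit seed is required")

    df = _as_frame(data)
    subjects = sorted(df["subject_id"].astype(str).unique())
    if len(subjects) < 2:
        raise DegenerateDataError("need at least 2 subjects for a varying intercept")
    subj_index = {s: i for i, s in enumerate(subjects)}
    subj = df["subject_id"].astype(str).map(subj_index).to_numpy(dtype=np.int64)

    scaler = None
    if standardize:
        from .features import standardize_features

        zdf, scaler = standardize_features(df, columns=("speed", "accuracy"))
        speed = zdf["speed"].to_numpy(dtype=float)
        acc = zdf["accuracy"].to_numpy(dtype=float)
    else:
        speed = df["speed"].to_numpy(dtype=float)
        acc = df["accuracy"].to_numpy(dtype=float)

    fixed = pd.DataFrame(
        {
            "b_speed": speed,
            "b_accuracy": acc,
            "b_speed_x_accuracy": speed * acc,
        },
        index=df.index,
    )
    ctrl = _control_columns(df, spec.controls, covariates)
    Xdf = pd.concat([fixed, ctrl], axis=1)
    X = Xdf.to_numpy(dtype=float)
    fixed_names = list(Xdf.columns)

    family = "bernoulli" if spec.outcome == "stress" else "poisson"
    y = df[spec.outcome].to_numpy(dtype=float)
    if family == "bernoulli" and len(np.unique(y)) < 2:
        raise DegenerateDataError("outcome has zero variance (all stress identical)")

    logp_grad, dim, unpack = _make_logp_grad(
        y, X, subj, len(subjects), family, priors, spec.varying_slopes, speed, acc
    )

    seeds = np.random.SeedSequence(sampler.seed).spawn(sampler.n_chains)
    chains = []
    warm_div = 0
    for c in range(sampler.n_chains):
        rng = np.random.default_rng(seeds[c])
        init = 0.1 * rng.standard_normal(dim)
        res = sample_nuts(
            logp_grad,
            init,
            sampler.n_warmup,
            sampler.n_sampling,
            rng,
            target_accept=sampler.target_accept,
            max_treedepth=sampler.max_treedepth,
        )
        chains.append(res)
        warm_div += res.n_warmup_divergent
    draws = np.stack([c.draws for c in chains])  # (chains, draws, dim)
    divergent = np.stack([c.divergent for c in chains])

    un = unpack(draws)
    params: dict[str, np.ndarray] = {"intercept": un["mu"]}
    for j, name in enumerate(fixed_names):
        params[name] = un["beta"][..., j]
    params["sigma_subject"] = un["sigma"]
    if spec.varying_slopes:
        params["sigma_slope_speed"] = un["sigma_slope_speed"]
        params["sigma_slope_accuracy"] = un["sigma_slope_accuracy"]

    rhat, ess = {}, {}
    for name, arr in params.items():
        rhat[name] = float(az.rhat(arr))
        ess[name] = float(az.ess(arr))
    alpha_rhat = float(np.nanmax(az.rhat(az.convert_to_dataset(un["alpha"])).x.values))
    diagnostics = {
        "rhat": rhat,
        "ess": ess,
        "alpha_rhat_max": alpha_rhat,
        "n_divergent": int(divergent.sum()),
        "n_warmup_divergent": int(warm_div),
        "step_size": [c.step_size for c in chains],
        "mean_tree_depth": float(np.mean([c.tree_depth.mean() for c in chains])),
        "seed": sampler.seed,
    }

    worst = max(max(rhat.values()), alpha_rhat)
    if worst > sampler.rhat_threshold:
        raise ConvergenceError(
            f"split-R-hat {worst:.4f} exceeds {sampler.rhat_threshold}", diagnostics
        )
    if divergent.any():
        raise ConvergenceError(
            f"{int(divergent.sum())} post-warmup divergent transitions", diagnostics
        )

    return PosteriorSummary(
        params=params,
        alpha=un["alpha"],
        subjects=subjects,
        spec=spec,
        priors=priors,
        sampler=sampler,
        scaler=scaler,
        diagnostics=diagnostics,
        slope_speed=un.get("slope_speed"),
        slope_accuracy=un.get("slope_accuracy"),
        fixed_names=fixed_names,
    )


# ---------------------------------------------------------------------------
# Posterior summaries


def hpdi(draws: np.ndarray, mass: float = 0.95) -> tuple[float, float]:
    """Highest posterior density interval by the shortest-sorted-window rule.

    The interval is the narrowest contiguous window of the sorted draws
    containing ``ceil(mass * n)`` of them.  Requires at least 100 draws.
    """
    x = np.sort(np.asarray(draws, dtype=float).reshape(-1))
    n = x.size
    if not (0.0 < mass < 1.0):
        raise ValidationError("mass must be in (0, 1)")
    if n < 100:
        raise ValidationError(f"need >= 100 draws for an HPDI, got {n}")
    m = int(np.ceil(mass * n))
    widths = x[m - 1 :] - x[: n - m + 1]
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + m - 1])


def odds_change(
    summary: PosteriorSummary, delta_speed: float, delta_accuracy: float
) -> float:
    """Multiplicative change in stress odds for a move of (ds, da) SD units.

    exp of the posterior-mean change in the linear predictor from (0, 0) to
    (``delta_speed``, ``delta_accuracy``), main effects plus interaction.
    Logistic models only.
    """
    if summary.spec.outcome != "stress":
        raise ValidationError("odds_change is defined for the logistic model only")
    d = (
        summary.mean("b_speed") * delta_speed
        + summary.mean("b_accuracy") * delta_accuracy
        + summary.mean("b_speed_x_accuracy") * delta_speed * delta_accuracy
    )
    return float(np.exp(d))


def partial_dependence(
    summary: PosteriorSummary,
    speed_grid: np.ndarray | None = None,
    accuracy_grid: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Model-implied stress probability over a speed x accuracy grid.

    At each grid point (s, a), averages inverse-logit(alpha_i + b1*s +
    b2*a + b3*s*a) over posterior draws and subjects (subject-varying
    slopes included when fitted).  Default grid: -2 SD to +2 SD, 21 points
    per axis.  Returns ``(speed_grid, accuracy_grid, surface)`` with
    ``surface[i, j]`` at ``(speed_grid[i], accuracy_grid[j])``.
    """
    if summary.spec.outcome != "stress":
        raise ValidationError("partial dependence on the probability scale needs the logistic model")
    s_grid = np.linspace(-2, 2, 21) if speed_grid is None else np.asarray(speed_grid, float)
    a_grid = np.linspace(-2, 2, 21) if accuracy_grid is None else np.asarray(accuracy_grid, float)
    alpha = summary.alpha.reshape(-1, summary.alpha.shape[-1])  # (K, M)
    b1 = summary.params["b_speed"].reshape(-1)
    b2 = summary.params["b_accuracy"].reshape(-1)
    b3 = summary.params["b_speed_x_accuracy"].reshape(-1)
    us = (
        summary.slope_speed.reshape(-1, alpha.shape[1])
        if summary.slope_speed is not None
        else None
    )
    ua = (
        summary.slope_accuracy.reshape(-1, alpha.shape[1])
        if summary.slope_accuracy is not None
        else None
    )
    surface = np.empty((s_grid.size, a_grid.size))
    for i, s in enumerate(s_grid):
        for j, a in enumerate(a_grid):
            lin = alpha + (b1 * s + b2 * a + b3 * s * a)[:, None]
            if us is not None:
                lin = lin + us * s + ua * a
            surface[i, j] = expit(lin).mean()
    return s_grid, a_grid, surface


def participation_bias_test(
    stress_few: int,
    n_few: int,
    stress_many: int,
    n_many: int,
    correction: bool = True,
) -> tuple[float, float]:
    """Pearson chi-square (df=1) comparing stress rates between subjects
    with few and many recordings.

    Defaults to the Yates continuity correction.  Returns ``(chi_square,
    p_value)``.  Raises on an empty margin (the test is undefined there).
    """
    counts = (stress_few, n_few, stress_many, n_many)
    if any(c < 0 for c in counts):
        raise ValidationError("counts must be nonnegative")
    if stress_few > n_few or stress_many > n_many:
        raise ValidationError("stress counts cannot exceed totals")
    table = np.array(
        [[stress_few, n_few - stress_few], [stress_many, n_many - stress_many]], dtype=float
    )
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValidationError("chi-square test undefined: empty margin")
    res = stats.chi2_contingency(table, correction=correction)
    return float(res.statistic), float(res.pvalue)
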