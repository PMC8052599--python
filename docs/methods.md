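# Methods

## The measurement model

A recording is ~30 minutes of pointer samples at a nominal 125 Hz (8 ms
intervals), each an integer-millisecond timestamp, integer pixel
coordinates and an event kind (move, click, wheel). A *trajectory* is a
contiguous run of moves ending at the next click or wheel, inclusive; the
segmentation is a partition — every terminal event closes at most one
trajectory and no move belongs to two. Trajectories shorter than 1 s or
longer than 10 s are discarded (bounds inclusive): the short ones are
ballistic fragments, the long ones contain idle phases.

Two statistics summarize each trajectory:

* **speed** — summed Euclidean step length divided by duration (px/s).
  Path length, not net displacement: a back-and-forth movement is fast
  even if it goes nowhere.
* **accuracy** — the mean of the per-step indicator `eqdir`, which is 1
  when the sign of the displacement is unchanged on *both* axes relative
  to the previous step (sign ∈ {−1, 0, +1}). Accuracy 1 means the
  direction was never corrected; 0, corrected at every step. More
  corrective sub-movements — the behavioral signature of neuromotor
  noise — lower it.

Conventions that the definition leaves open, and how this package fixes
them:

* *Zero displacements.* sign(0) = 0 and `eqdir` compares sign pairs for
  equality, so a pause followed by a resumption in the same direction
  counts as two direction changes. This is parameter-free and purely
  local; the alternative (ignoring zero steps) would need a pause-length
  convention.
* *Sampling.* Comparisons are made between consecutive move-event deltas
  at the native sample rate; nothing is resampled.
* *Degenerate trajectories.* With fewer than two displacement steps
  accuracy is undefined; such trajectories are skipped in the recording
  mean but still count toward the trajectory-count filter (their speed is
  defined).

Recording-level speed and accuracy are unweighted means over retained
trajectories, alongside the click/wheel terminal proportions and
weekday/daytime metadata. Recordings are excluded sequentially — no move
events at all; invalid timestamps (any strictly decreasing step, or two
move events sharing a timestamp, either of which makes a speed
undefined); fewer than 10 retained trajectories — with first-hit
counting, so the exclusion report's categories are mutually exclusive and
sum exactly to raw − retained.

## Stress encoding

Acute stress follows the circumplex model of affect: on 7-point scales
with neutral midpoint 4, `stress = 1` iff valence < 4 and arousal > 4
(both strict). Exactly 9 of the 49 affect cells qualify. The discrete
sensitivity measure `arousal − valence + 6` (0–12) deliberately conflates
states the dichotomy separates; it is provided for the Poisson sensitivity
models and should be read with that caveat.

## The regression model

With speed and accuracy centered and scaled by their pooled empirical mean
and *sample* standard deviation (ddof = 1; pooling over all retained
recordings, no per-subject grouping), the primary model is a
varying-intercept logistic regression of the stress bit on speed,
accuracy, and their product. Centering makes the interaction coefficient
directly interpretable: a negative β₃ means opposite-signed excursions of
speed and accuracy (the trade-off) raise the stress odds, and
`exp(β₁Δs + β₂Δa + β₃ΔsΔa)` is the posterior-mean odds factor of a
(Δs, Δa) move in SD units.

Priors are weakly informative and configurable: Normal(0, 2.5) on
coefficients and the population intercept (logit scale), half-Student-t(3,
2.5) on group standard deviations. Subject intercepts are parameterized
non-centered (α_i = μ_α + σ_α z_i) for sampler geometry. Optional control
blocks enter as standardized continuous columns or first-level-reference
indicator contrasts (weekday vs Monday, alcohol/smoking vs category 1).
The varying-slopes variant adds independent subject slopes on speed and
accuracy, each with its own half-t scale; slope–intercept correlations are
not modeled — the variant exists as a robustness probe, and the
correlated version would buy generality the rest of the package never
uses.

Sensitivity outcomes (valence, arousal, discrete stress) swap the
likelihood for Poisson-log with the same linear predictor.

## Estimation

Sampling is full MCMC with an in-package No-U-Turn Sampler: leapfrog
integration with dynamic path doubling, slice selection among valid
states, Stan-style warm-up (dual-averaging step size toward a 0.9 target
acceptance statistic; diagonal mass matrix re-estimated over doubling
windows with shrinkage toward unit scale), and an energy-error threshold
of 1000 for flagging divergences. Defaults are 4 chains × (1000 warm-up +
1000 retained); chains are seeded independently from one required,
logged seed and are deterministic given it.

Convergence is a hard gate, not a warning: any post-warmup divergence or
any rank-normalized split-R̂ above the threshold raises an error carrying
the diagnostics (R̂/ESS via arviz). The default threshold is 1.01,
appropriate at the default draw count. At deliberately reduced iteration
counts (e.g. 500+500 replicate sweeps) the R̂ *estimator's* own noise
floor sits near 1.01–1.02, so such runs should pass an explicit threshold
of 1.02–1.03; the recovery and sensitivity suites do exactly that. This
is a property of the diagnostic at small sample sizes, not of the
posterior.

The 95% HPDI is computed by the shortest-sorted-window rule on pooled
post-warmup draws (the narrowest contiguous window of sorted draws
holding ⌈0.95 n⌉ of them), requiring at least 100 draws; it matches an
exhaustive window scan exactly and is shorter than the equal-tailed
interval for skewed posteriors. Partial dependence averages
logit⁻¹(α_i + β₁s + β₂a + β₃sa) over posterior draws and subjects on a
±2 SD grid; at the origin it equals the posterior mean of logit⁻¹(α_i) by
construction.

The participation-bias check is a df-1 Pearson χ² on the 2×2 table of
stress counts for subjects with few (≤10) versus many recordings, with
the Yates continuity correction by default (the uncorrected statistic is
available via a flag); on the published counts (6/43 vs 188/1986) the
corrected statistic is 0.53 (p = .47) where the uncorrected one would be
0.98.

## Sensitivity grid

`run_grid` crosses trajectory-count minima, maximum durations (raw logs
required, since re-filtering needs re-segmentation), model variants,
outcome encodings and subject-exclusion sets, fitting each cell with seed
`base_seed + crc32(settings)` so cells are independent yet reproducible;
cell failures are recorded rows, not crashes. Low-accuracy subjects are
flagged when their mean accuracy falls below the pooled mean minus a
configurable multiple (default 2) of the pooled standard deviation.

## The synthetic-study generator

The generator emulates the statistical structure the analysis assumes,
with complete ground truth.

**Trajectory level.** A movement is a constant integer base step toward a
target (the per-sample displacement rounded to pixels), so the noiseless
path is exactly monotone and extracted accuracy is exactly 1. Neuromotor
noise is a per-step, per-axis probability `jitter` of drawing the axis
sign at random instead of following the target direction. Sign flips
preserve step magnitude, so extracted speed equals the pixel-quantized
nominal speed (recorded as ground truth; a deviation on a zero base axis
injects a 1 px component, accounted for in expectation). Expected
accuracy is strictly decreasing in jitter — per active axis the
probability of an unchanged sign between consecutive steps is
(1 − j/2)² + (j/2)², decreasing on [0, 1].

**Study level.** Subject intercepts are Normal(μ_α, σ_α); per recording,
standardized (speed, accuracy) targets are bivariate normal (independent
by default, correlation exposed as a stress-test knob); the stress bit is
Bernoulli from the logistic model itself, so generator and fitter are
mutual oracles. Defaults mirror the field-study conditions: 70 subjects;
recordings per subject rounded Normal(26.13, 14.33) clipped to [1, 70];
true effects (0, 0, −0.32); marginal prevalence 10.1%, with μ_α solved by
Gauss–Hermite quadrature given σ_α; σ_α = 1.0 on the logit scale as a
realistic between-subject heterogeneity.

Valence/arousal are drawn uniformly from the circumplex cells consistent
with the stress bit. Two consequences are documented rather than hidden:
the Poisson sensitivity outcomes have a known generative mismatch (affect
carries no information beyond the dichotomy), and the share of subjects
whose *average* affect falls in the stress quadrant saturates near ~12%
(within-cell valence–arousal covariance is positive, disfavoring the
quadrant), below the ~17% seen in real panels where affect varies
continuously. Passing tests therefore demonstrate recovery of the
dichotomous-stress estimand, not realism of the affect marginals.

**Raw mode** realizes the standardized targets as event streams: speed by
a linear map (400 + 120·s px/s, floored at 60), accuracy via a monotone
jitter-calibration curve estimated once per run by simulation (21-point
jitter grid × 40 trajectories) and inverted by interpolation — the
forward map from jitter to extracted accuracy has no closed form once
pixel quantization enters. Clean recordings carry at least the
trajectory-count minimum; optional corruption plants recordings that trip
exactly one exclusion rule each (no move events; a duplicated or
decreased move timestamp; too few trajectories), at rates
(0.003, 0.045, 0.10) calibrated so a 2029-recording study loses about
(6, 91, 203) recordings to the three filters. Identical seeds give
byte-identical studies in every mode.

Covariate tables reproduce the field panel's marginals (ages 20–61, 46%
female, 59% university-educated, categorical health scales, big-five
traits on 1–10) for exercising the control blocks; they carry no signal.

## Problem sizes used in the shipped checks

Simulation-based recovery runs 20 replicate studies at the full
field-study scale (70 × ~26) with 4 × (500 + 500) iterations — posterior
means recover the generating interaction to well within ±0.1 with
nominal HPDI coverage. Unit-level fits use 25–40 subjects and 2 chains of
a few hundred iterations each; the null-coverage suite (20 replicates,
true effects zero) runs at the default study scale. These sizes were
chosen so the whole suite completes in minutes while keeping every
statistical claim at the scale it is made about.

## Known limitations

* Observational estimand: the model measures association; nothing here
  supports causal claims about stress and motor behavior.
* The generator does not model task semantics, Fitts'-law timing, pauses
  within trajectories, or keyboard interplay; accuracy realism is limited
  to the jitter mechanism.
* Stress severity is out of scope — the outcome is a dichotomy by design.
* The NUTS implementation is single-threaded dense numpy; it is sized for
  ~10²–10³ parameters and ~10³–10⁴ observations, ample here but not a
  general-purpose PPL.
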