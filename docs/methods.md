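# Methods

## Model

`latentshift` models a longitudinal cognitive score (one row per visit)
as a population decline curve evaluated on a subject-specific *disease
time* scale plus structured subject-level deviations:

    y_ij = θ( t_ij + d_i + s_i ) + x_i,0 + x_i,BM(t_ij) + ε_ij,
    θ(t) = l · exp( t / exp(g) ) + v.

Disease time is study time plus a fixed stage offset `d_i = X_s,i β_s`
(group dummies and optional stage covariates) plus a random shift
`s_i ~ N(0, τ²)`. The exponential family encodes two assumptions about
pathological cognitive aging: a stable pre-disease level (`v` is the left
asymptote as disease time → −∞) and a monotone, accelerating decline for
`l > 0`. The family is overparametrized — rescaling `l` by
`exp(−a/exp(g))` and shifting all stage parameters by `a` leaves the
curve unchanged — so the reference group's stage offset is structurally
fixed at zero: disease month 0 is, by convention, the average baseline
stage of the cognitively normal group. A linear-in-time family
(`θ(t) = l·t + v`, no `g`) is provided for cross-checks against ordinary
linear mixed models.

Subject-level deviations decompose into a random starting level
`x_i,0 ~ N(0, σ₀²)`, a Brownian-motion process with covariance
`σ_BM²·min(t, t′)` indexed by *study* time (so the baseline level is
carried entirely by `x_i,0`; indexing by disease time would make the
covariance depend on the latent shift and destroy the joint-normal
formulation), and i.i.d. noise `ε ~ N(0, σ²)`. The shift and starting
level are coupled through `Cov(s_i, x_i,0) = ρ σ₀²`: subjects further
along the timeline than their group's average may also sit
systematically above or below the curve.

Covariate effects can act on three channels: stage (`s`, months), rate
(`g`, log time-scale) and level (`v`, score units). Continuous stage
covariates are mean-centered on reference-group values so the timeline
origin keeps its meaning; indicator covariates are left uncentered.
Missing covariates are handled complete-case per fitted model. Subjects
with a single visit are retained (they still inform the level and the
variance components).

## Estimation

The marginal likelihood of a subject integrates a Gaussian whose mean is
nonlinear in `s_i` over the shift distribution. Three likelihood objects
are distinguished:

* **Shift-conditional likelihood** (`nll_conditional`): Gaussian with
  mean `θ(t + d_i + s) + (ρσ₀²/τ²)·s` and covariance
  `C − (ρσ₀²)²/τ²·J`, where `C` is the process covariance. The linear
  random effects (starting level, Brownian values) are integrated exactly
  here, so all inner problems are one-dimensional in the shift.
* **Laplace approximate marginal**: the conditional-plus-prior criterion
  at the per-subject shift mode, plus half the log of the one-dimensional
  curvature there. This is the objective `fit_ml` minimizes — jointly
  over the fixed effects and the transformed variance components — and
  the −2·log-likelihood it reports. It is exact for the linear-in-time
  family.
* **Exact marginal** (`nll_exact_marginal`, `exact_neg2ll`): adaptive
  Gauss–Hermite quadrature (≥ 30 nodes, centered and scaled at the
  per-subject mode, with a wide fixed-grid fallback if the mode curvature
  is not positive). Exposed as a diagnostic and used as the oracle in
  tests; it is not the fitting objective.

`fit_ml` first runs a classical two-step warm-up — a penalized nonlinear
least-squares update of fixed effects and shift modes (`pnls_step`)
alternated with a linear mixed-effects variance update on the model
linearized about the modes (`lme_step`) — accepting iterations only while
they improve the Laplace marginal, and then polishes all parameters with
a bounded quasi-Newton method using an analytic gradient (envelope
identity at the shift mode; implicit derivative of the mode for the
log-curvature term; verified against finite differences in the test
suite). The pure two-step fixed point was found to be materially biased
for this model on simulated cohorts: the joint-mode criterion omits the
curvature term of the marginal integral, and that term varies strongly
with the fixed effects because cohort members sit on very different parts
of the exponential (near-flat for cognitively normal subjects, steep in
dementia). The Laplace objective restores the missing term; parameter
recovery and the linear-family equivalence with a reference linear
mixed model follow directly.

Numerical choices:

* Variance components are estimated as `log τ²`, `log σ_BM²`, `log σ₀²`,
  `log σ²` and `atanh` of the implied shift–level correlation
  `r = ρσ₀/τ`, guaranteeing validity of every iterate; `ρ` is recovered
  for reporting. Log-variances are bounded below at −30 (pinned with a
  warning); the shift SD is capped at 300 months, beyond which the
  timeline loses meaning and the (τ², ρ, σ₀²) direction becomes a flat
  ridge for weakly nonlinear curves.
* Group stage offsets are bounded to (−240, 480) months: outside that
  window the exponential is numerically flat and a sparse group's offset
  can drift without bound.
* The inner shift mode is found by a dense grid over ±4τ (41 points
  during fitting, 201 for prediction) followed by safeguarded Newton
  refinement with steps clamped to the grid spacing; the grid makes the
  search global (the profile likelihood in `s` can be multimodal under
  the exponential mean), the refinement makes it smooth for the outer
  quasi-Newton iteration.
* Arguments of `exp` are clipped at ±50 to survive optimizer excursions.
* Initialization: the level starts at the reference group's mean baseline
  score; group offsets are obtained by mapping group mean baseline scores
  through the inverse of a candidate curve over a coarse (l, exp(g))
  grid; noise and level variances split the residual variance; the
  Brownian rate comes from lag-1 residual increments; τ² starts at
  (24 months)².
* Degrees of freedom count every free fixed effect plus the five variance
  parameters; AIC = −2LL + 2·df and BIC = −2LL + ln(N)·df with N the
  total observation count and natural logarithm (the convention pinned by
  reproducing published AIC/BIC pairs from their −2LL and df).

Degenerate regimes worth knowing about: with a flat outcome (`l ≈ 0`),
the triple (l, g, v) is ridge-degenerate — a huge-time-scale exponential
is numerically a small linear trend — so only the fitted trajectory (not
`v̂` itself) is identified; and in the linear-family limit, (τ², ρ, σ₀²)
collapse to a single identifiable intercept variance
`l²τ² + 2lρσ₀² + σ₀²`, which is why the linear-family cross-check fixes
τ² (negligible) and ρ = 0. `fit_ml` accepts a `fix_variance` option for
such designs.

## Prediction and validation

Random effects are predicted as posterior modes under the ML estimates:
the shift by the global 1-D search, the starting level and Brownian
values by exact Gaussian conditioning given the shift (for linear-
Gaussian components the mode equals the mean). A subject's predicted
disease month at study time `t` is `t + d_i + ŝ_i`. Trajectory forecasts
add the Brownian conditional mean, which is linear interpolation between
the visit-time modes (anchored at zero at study time 0) and constant
beyond the last visit (martingale property).

For staging subjects from baseline information only — the situation of a
patient entering a trial — `predict_stage_baseline` uses either the fixed
effects alone (group plus stage covariates such as baseline biomarkers)
or additionally the baseline score via a single-visit posterior mode;
`holdout_prediction_errors` scores the implied trajectory forecasts
against held-out visits by mean squared error and median absolute error,
with baseline visits excluded by default since they informed the staging.

Two downstream analyses assess whether the fitted timeline is meaningful
beyond the score it was fitted on: an OLS regression of time since
reported symptom onset on predicted disease time (t-test p-value; plus
the slope-one least-squares intercept, i.e. the mean difference, for
age-at-onset comparisons), and a comparison of two random-intercept-
and-slope linear mixed models for a secondary longitudinal outcome — one
cubic B-spline trajectory (3 df + intercept) per baseline group over
study time versus a single trajectory over predicted disease time, fitted
by ML on the identical complete-case observations with the package's own
marginal-Gaussian machinery. With five groups the fixed-effect df are
5·4 = 20 versus 4; adding two random-effect variances, their covariance
and the residual gives total df 24 versus 8. The 3-df cubic basis places
boundary knots at the observed min/max with no interior knots (the
convention under which a cubic basis plus intercept has exactly 4 df);
groups with fewer than four distinct times get a reduced basis with a
warning.

## Forward selection

Candidate moves are single (covariate, parameter) additions over the
pool, evaluated in deterministic order (pool order, then g before s
before v). At each step all candidates are fitted (warm-started from the
incumbent, new coefficient at zero) and the largest AIC improvement is
accepted; the search stops when no candidate improves AIC, and the final
model is the minimum-BIC model among the accepted chain including the
base. Failed candidate fits are skipped and recorded. Multi-level factors
must be pre-encoded as dummy columns; each column is one move.

## Synthetic cohorts

The simulator draws directly from the generative model and is the test
bed for everything above. Defaults describe a cohort shaped like a large
observational AD study — they are package choices, not estimates from any
real dataset:

* 2,000 subjects in five baseline strata (25 / 5 / 20 / 30 / 20 %),
  stage offsets (29, 42, 88, 136) months;
* curve `l = 1`, `exp(g) = 45` months, `v = 9` score points, which places
  the group baseline means near 10 / 11 / 11.5 / 16 / 29.5 points on a
  0–85 scale;
* shift SD τ = 24 months; level SD 2 points; Brownian rate 0.08
  points²/month (SD ≈ 2 points at four years); noise SD 2.5 points;
  shift–level correlation 0.3;
* visits scheduled at months 0, 6, 12, 18, 24, 36, 48 with independent
  60 % retention per post-baseline visit (≈ 4.6 visits per subject);
  baseline is always observed; dropout is non-informative by design;
* demographic covariates (age, sex, education) drawn independently of the
  latent stage; stage-informative baseline biomarkers can be added as
  affine functions of the true baseline disease month plus noise.

A single generator seeded once per call drives all draws; the returned
truth tables (per-subject latents, per-visit mean/Brownian/noise
components) reconstruct the dataset bit-for-bit.

What passing tests on these cohorts do and do not show: the generator
matches the model exactly, so recovery results demonstrate correctness of
the estimation machinery, not robustness to the misspecifications real
cohorts carry (informative dropout, floor/ceiling effects of bounded
scales, practice effects, non-Gaussian noise, stage-dependent covariate
distributions). Staging accuracy is strongly stage-dependent — shifts of
near-flat early-stage trajectories are mostly prior-shrunken, while
late-stage trajectories pin the shift to within a few months — so
cohort-level staging correlations depend on the group mix.

## Known limitations

* One outcome at a time; no joint multivariate progression model.
* The warp is a pure shift: no subject-level rate (time-scaling) random
  effect.
* Point estimates with likelihood-based model comparison only; no
  standard errors are reported yet, and no REML or Bayesian posterior.
* Bimodally distributed biomarkers (e.g., amyloid measures) are poorly
  described by a single trajectory over disease time; the timescale
  comparison will legitimately favor per-group models there.
* Model output is not clipped to the score range of bounded scales.
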