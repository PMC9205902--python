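# Methods

`adapt2state` models trial-by-trial visuomotor adaptation of 3D reaching
movements with linear-Gaussian state-space models, fits them hierarchically
across experimental runs with a Bayesian sampler, and relates the fitted
noise structure to adaptation rate through the steady-state Kalman gain.
This note records the model, the numerical choices, what the synthetic data
emulate, and the known limitations.

## The adaptation model

On step `n` (a trial, or an 8-trial epoch) of run `j` in perturbation plane
`p`, the measured movement angle is

    y_jp(n) = C x_jp(n) + eps_u,      eps_u ~ N(0, sigma_u_jp)

with hidden planning state `x`. In the two-state variant `x` has a slow and
a fast component and `C = [1, 1]`; in the single-state variant `x` is a
scalar. The state learns from the experienced error
`e_jp(n) = p(n) - y_jp(n)`, where `p(n)` is the perturbation magnitude
(30 deg during the perturbation phase, 0 otherwise):

    x_jp(n+1) = A_jp x_jp(n) + B_jp e_jp(n) + eps_x,
    eps_x ~ N(0, sigma_x_jp)  per state component,

with `A = diag(a_s, a_f)`, `B = (b_s, b_f)'` and ordering constraints
`a_s > a_f > 0` (slow retains more) and `b_f > b_s > 0` (fast learns more).
`sigma_x` and `sigma_u` are standard deviations in degrees; *planning
variability* and *measurement variability* are their squares. The state
starts at `x(1) = 0`: the first perturbed observation is unadapted, matching
a baseline-start design. Retention values >= 1 are allowed in simulation but
rejected by the closed-form asymptote `y* = p G / (1 + G)`,
`G = sum_states b / (1 - a)`, which requires strict forgetting.

Positive angles are compensatory: `e = p - y` shrinks as adaptation
proceeds.

## Steady-state Kalman gain

For an optimal learner the weight given to the experienced error depends on
the two noise sources. With planning variance `vx` and measurement variance
`vu`, the steady-state variance of the state estimate is
`sigma_X+^2 = (-vx + sqrt(vx^2 + 4 vx vu)) / 2` (implemented in a
rationalised form, `2 vx vu / (vx + sqrt(vx^2 + 4 vx vu))`, to avoid
catastrophic cancellation when `vu << vx`), and

    K = (sigma_X+^2 + vx) / (sigma_X+^2 + vu + vx)  in [0, 1].

`K` is computed per posterior draw from the sampled noise scales, so its
posterior uncertainty is available downstream. API inputs are variances
(names end in `_var`) to prevent SD/variance unit mistakes.

## Hierarchical structure and priors

Every subject-level parameter is drawn from a per-plane population normal,
e.g. `a_s_jp ~ N(mu_{a_s,p}, sigma_{a_s})`, with the population SD shared
across planes. Hyper-priors are wide: retention means `N(1, 9)` and
learning-rate means `N(0, 9)` (mean, SD), retention/learning population SDs
half-Cauchy(0, 5), and both the means and SDs of the noise scales
half-Cauchy(0, 15). Runs from the same subject in different planes are
treated as independent (no shared per-subject offsets). The per-run
(non-hierarchical) fit applies these hyper-priors directly to the
subject-level parameters.

## Sampler

No probabilistic-programming backend is used; the sampler is purpose-built
for this model family and fully seeded:

- **Likelihood.** Hidden states are marginalised analytically. Because `e`
  is computed from the *observed* angle, conditioning on the data makes the
  dynamics linear with a known input, and the exact marginal likelihood is
  a 2-state (or 1-state) Kalman filter; the one-step-ahead predictive terms
  are retained per observation for WAIC. Filters are numba-compiled scalar
  loops.
- **Subject-level updates.** Component-wise adaptive Metropolis sweeps
  (acceptance-rate-tuned step sizes, target 0.27, frozen after warmup) plus
  one joint Metropolis move per iteration whose proposal covariance is the
  running warmup covariance scaled by 2.38^2 / d (Haario-style). Ordering
  constraints are enforced by proposal rejection, so every retained draw
  satisfies them exactly. Chains start from per-run EM point estimates
  (with small jitter): a shared heuristic start mixes too slowly into runs
  whose parameters sit far from the population centre.
- **Hyper-parameter updates.** Univariate slice sampling of each population
  mean and SD. Two additional group moves per parameter counter the
  centred-hierarchy "funnel": a *translate* move shifting a plane's
  subject values together with their population mean, and a *scale* move
  rescaling deviations together with the population SD (an exact Metropolis
  move carrying its `c^(R+1)` Jacobian).
- **Truncation constants.** The subject-level normals are truncated by the
  ordering constraints; their normalising constants (which depend weakly on
  the hypers) are ignored in the hyper updates. This matches the behaviour
  of constrained-parameter declarations in standard HMC tooling without an
  explicit truncation correction.
- **Defaults.** 4 chains, 1000 warmup + 1000 retained iterations, 5
  component sweeps per iteration. Convergence is monitored with split
  R-hat and ESS (via arviz) on the population means (hierarchical) or
  run-averaged subject parameters (per-run); a fit with max R-hat above
  1.05 carries a warning and a `converged: false` flag. All randomness
  derives from one `SeedSequence` split per chain; identical inputs give
  bit-identical draws.

WAIC is computed on the deviance scale, `-2 (lppd - p_waic)` with `p_waic`
the summed posterior variance of the pointwise log-likelihood (sample
variance with `n - 1`); an arviz cross-check agrees to ~1e-4 relative. RMS
residuals compare each observed series against the posterior-mean
*noise-free forward simulation* (the model's fitted curve), averaging the
deterministic trajectory over up to 400 thinned posterior draws. The
"null value probability" of a hyper-parameter difference is the two-sided
tail credibility `2 min(P(delta<0), P(delta>0))`, capped at 1.

## EM baseline

The comparison fitter is a generic constrained linear-dynamical-system EM:
Kalman filter + RTS smoother E-step (with lag-one covariances), closed-form
M-step for the diagonal retention matrix, learning-rate vector, pooled
planning variance (shared by both states) and measurement variance, then a
projection onto the constraint set — a likelihood-invariant slow/fast
relabelling when the ordering flips, followed by small-margin clipping.
Without projection EM's monotonicity guarantee holds and its fixed points
are stationary points of the marginal likelihood (verified numerically);
with projection a rare decrease is possible and the trace exposes it.
Default initialisation: `a_s = 0.95, a_f = 0.5, b_s = 0.05, b_f = 0.2`,
noise scales from first-difference residuals.

## Synthetic data

**Surrogate runs.** Each run's true parameters are drawn from normal
distributions reflecting typical epoch-level human values — `a_s ~
N(0.93, 0.03)`, `a_f ~ N(0.55, 0.2)`, `b_s ~ N(0.06, 0.04)`, `b_f ~
N(0.18, 0.08)`, planning variability `~ N(1.5, 1)` deg^2, measurement
variability `~ N(6, 3)` deg^2 — re-drawn (rejection, not clipping, to stay
unbiased within the admissible region) until the ordering and positivity
constraints hold. The default schedule is the experiment's block design at
epoch granularity: 15 baseline / 30 perturbation / 30 washout epochs
(75 steps; 8 trials per epoch), with a trial-level variant (600 steps)
available. A *correlated* variant draws the noise variances first, computes
`K`, and sets `b_s = 0.3 K` exactly (re-drawing `b_f` until `b_f > b_s`),
for testing whether fitting pipelines recover — or spuriously introduce —
parameter correlations.

Because variances are drawn on the variance scale but the hierarchy lives
on the SD scale, two related population summaries exist: the variability
*at the population mean*, `mu_sigma^2` (reported by the validation
pipeline), and the population-*mean* variability
`mu_sigma^2 + sd_pop^2` (the `E[X^2]` identity; available as
`PosteriorResult.population_variability_draws`). The first understates
the generating mean by the dispersion term, the second rides on the
right-skewed `sd_pop^2` posterior; recovery comparisons are cleanest on
the SD scale of the hyper-parameter itself, where the transform bias is
below 1.5%. The positivity truncation of the variance draws shifts their
true mean a few percent above the nominal 1.5 / 6 deg^2.

**3D reaches.** Synthetic centre-out trials to the corners of a 10 cm cube:
a stationary hold, a minimum-jerk longitudinal profile, and an injected
aiming angle defined on the *measurement scale* — the lateral deviation in
the perturbed plane equals `tan(theta)` times the longitudinal distance up
to half the centre-to-target distance, then blends smoothly back to the
target. (A rigid in-plane rotation of an out-of-plane cube diagonal would
*not* measure back as the rotation angle under the half-distance angle
definition; defining the injection on the measurement scale makes
round-trip tests exact for every target.) Position noise is smooth
(spline-interpolated Gaussian knots, marginal SD = `noise_sd`): per-sample
white noise at 100 Hz would put the hold-phase speed far above the 3 cm/s
onset threshold, which real tremor does not. These are geometric fixtures:
no biomechanics, no feedback corrections, no failed trials.

What passing tests on these data do show: the preprocessing chain is
geometrically correct (signs, planes, normalisation, baseline correction),
and the fitting machinery recovers parameters generated by the model class
it assumes. What they do not show: robustness to model misspecification,
online feedback corrections within movements, or real kinematic noise.

## Preprocessing conventions

Onset is the first sample whose finite-difference speed exceeds 3 cm/s and
stays above it for a configurable dwell (default 3 samples); trial end is
the first sample inside the target sphere (default radius 0.75 cm). The
onset-to-end window is linearly resampled at 50 equally spaced times.
The lateral axis is the unit vector orthogonal to the centre-to-target
direction within the perturbation plane (`t_hat x n_hat`), signed so that
compensation of a counterclockwise perturbation is positive. Baseline mean
profiles are computed per subject x block x *target* (per-target because
mean curvature is target-specific) and subtracted pointwise. The adaptation
angle is `atan2(d_half, target_dist / 2)` with `d_half` interpolated at the
first crossing of half the centre-to-target distance; it reduces to the
true rigid-rotation angle for straight re-aimed in-plane paths. Epochs
average 8 consecutive trials that visit each target exactly once and must
not straddle phase boundaries.

## Problem sizes for validation

The validation protocol runs at desk scale: hyper-parameter recovery uses
20 runs of 75 epochs; correlation recovery uses 40 runs. For the
correlation datasets the runs are generated and fitted at trial level
(600 steps), the granularity of the original validation design: at 75
epochs per run the per-run posteriors of `b_s` and `K` are broad enough
that hierarchical shrinkage plus regression attenuation (posterior-mean
estimates act as error-laden regressors) suppress the fitted slope to
roughly 0.13 regardless of run count, whereas trial-level runs retain most
of the imposed coupling. Even at trial level the recovered slope sits
somewhat below the generating 0.3 — attenuated by shrinkage of per-run
`b_s`, posterior uncertainty in `K`, and the `b_f > b_s` constraint
squeezing high-`b_s` runs — and the uncorrelated variant's slope CI
contains 0. This attenuation is a property of regressing shrunk point
estimates, not a sampler defect; it is strongest when the population
spread of `K` is small relative to per-run posterior width.

## Known limitations

- The model is strictly step-discrete; no within-movement control.
- Point estimates for regressions are posterior means; alternatives
  (medians, draws-based regressions) are not exposed.
- EM provides no standard errors.
- The sampler is specialised to these two model variants; it is not a
  general-purpose PPL, and very long series (>> 10^3 steps) would need
  retuned sweep counts.
- Single-state fits initialise from moment heuristics rather than EM.
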