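# Methods

`coverstate` estimates latent plant-cover proportions from visually
determined ordinal cover-class records. This note documents the model, the
synthetic-data generator, the sampler, and the numerical and design choices
behind them.

## The observation model: an ordinal-beta likelihood

Within a quadrat, the continuous cover proportion `p` is modelled as beta
distributed with mean `mu` and dispersion `delta`:

    p ~ Beta(mu * phi, (1 - mu) * phi),   phi = (1 - delta) / delta,

so that `Var(p) = delta * mu * (1 - mu)`. `delta` in (0, 1) is
interpretable either as the intra-quadrat spatial correlation of plant
occupancy or, when small, as the uncertainty of a visual cover estimate.
An observer records the ordinal class `Y` whose interval
`(d_{Y-1}, d_Y]` contains `p`, so

    Pr(Y | mu, delta) = I_{d_Y}(a, b) - I_{d_{Y-1}}(a, b),

where `I_x(a, b)` is the regularized incomplete beta function (the beta
CDF). The default cut points are `{0, 0.01, 0.1, 0.25, 0.5, 0.75, 1}`,
giving six classes; class 1 additionally contains `p = 0`, i.e.
non-detection is folded into the lowest class rather than modelled as a
separate zero state. Classes are left-open/right-closed — relevant only to
the simulator's binning, since boundary points carry no probability under
the continuous model.

## The state-space model

For quadrats arranged on a line, surveyed at calendar years placed on a
unit-spaced time grid of `T` steps (unobserved years stay on the grid):

* latent trend — second-order random walk on the logit scale:
  `theta_t | theta_{t-1}, theta_{t-2} ~ Normal(2 theta_{t-1} - theta_{t-2},
  sigma_T^2)` for `t >= 3`; `theta_1, theta_2 ~ Normal(0, 2.5^2)`. This
  AR(2) form with coefficients (2, −1) penalises curvature, not level
  changes, so sustained trends are cheap and the extrapolation variance
  grows over unobserved years.
* spatial effects — at each *observed* occasion `t`, a first-order random
  walk across adjacent quadrats: `r_{t,q} - r_{t,q-1} ~ Normal(0,
  sigma_R^2)`, anchored by `r_{t,1} ~ Normal(0, 2.5^2)` and then centred
  to sum to zero within the occasion so the effects cannot absorb the
  temporal intercept. Centering is a deterministic transform of the free
  effects (the prior lives on the uncentred values), keeping the density
  proper. Effects at unobserved steps would be entirely prior-determined
  and are not instantiated.
* observation — `Y_{t,q}` has the ordinal-beta distribution with
  `mu_{t,q} = logit^{-1}(theta_t + r_{t,q})` and a single `delta` shared
  by all cells of a fit.
* priors — `sigma_T, sigma_R ~ HalfNormal(0, 2.5^2)`;
  `delta ~ Uniform(0, 1)` (the dispersion is a bounded parameter and the
  data inform it strongly; a flat prior adds nothing to the log density on
  its support). The 2.5 scale is weakly informative on the logit scale,
  where ±5 already spans cover 0.01–0.99.

Derived quantities: `phi_t = logit^{-1}(theta_t)` is the overall expected
cover proportion, reported as the posterior median and central 95%
interval per grid step (`overall_cover_curve`).

## Synthetic data

`simulator.SimConfig` defaults encode the benchmark recovery scenario:
10 sequential quadrats × 15 survey occasions, `theta_1 = -6` (about 0.25%
cover), drift 0.3 and innovation sd 0.5 per step on the logit scale, a
time-invariant spatial random walk with sd 0.5 started at `r_1 = 0`, and
`delta = 0.05`. Class labels are produced by drawing `p` from the beta
distribution per cell and binning at the cut points, which is
distributionally identical to drawing from the closed-form class
probabilities (tested by a chi-square comparison of both routes).

Two generator variants exist because the benchmark is deliberately
misspecified relative to the fitted model:

* `variant="paper"` (default) — first-order random walk with drift for the
  trend and one time-invariant spatial profile. Fitting the AR(2)/per-
  occasion model to such data is a robustness exercise; recovered scale
  parameters need not equal the generating ones exactly.
* `variant="model"` — second-order trend differences and an independent,
  centred spatial walk per occasion, matching the fitted model; used for
  parameter-recovery and coverage tests, where credible intervals should
  cover the generating values at roughly nominal rates.

`make_real_like` emulates the structure of a long-term survey: a sparse
calendar of observed years (e.g. 20 surveys across 1957–2017) on a full
annual grid, with whole years unobserved. What the generator does *not*
emulate: zero-inflation (true absence as a separate state), observer
misclassification, 2-D quadrat layouts, and temporal changes in the
spatial profile beyond what the chosen variant implies. Passing tests
therefore validate the estimator under the model's own assumptions — they
do not certify robustness to detection failure or misclassified field
records.

## Inference

The posterior is sampled with the package's own multinomial No-U-Turn
sampler (dual-averaging step-size adaptation, Stan-style windowed
adaptation of a diagonal metric, divergence threshold 1000 on the
Hamiltonian error). The joint density sampled is exactly the model
density above, re-expressed over free coordinates:

* `theta` is sampled in *centred* form at surveyed grid steps: the
  likelihood informs each such `theta_t` individually, and centred
  coordinates are then far better conditioned than innovation
  (non-centred) coordinates, which turn the trend into a long correlated
  ribbon. Unobserved grid steps carry no likelihood, and given the
  surveyed values their trend states are exactly Gaussian under the AR(2)
  prior — they are therefore sampled as standardised conditional-bridge
  residuals (`theta_gap = A theta_surveyed + sigma_T R^{-1} w`, with `A`
  and the Cholesky factor `R` precomputed from the second-difference
  precision matrix). The residuals decouple from the data entirely, which
  removes both the dense gap correlations and the gap-side `sigma_T`
  funnel. For an empty panel (prior sampling) plain innovations are used,
  since without any likelihood anchoring the centred form cannot traverse
  the `sigma_T` funnel.
* spatial effects are always non-centred (standardised increments scaled
  by `sigma_R`): one ordinal observation per cell leaves them
  prior-dominated.
* `log sigma_T`, `log sigma_R`, `logit delta` with the corresponding
  Jacobians.

Gradients are hand-assembled reverse-mode passes through these linear
transforms. The derivative of the incomplete beta function with respect
to its shape parameters has no closed form; it is taken by forward
differences (step 1e-4 on the linear predictor) sharing the central
evaluation. Gradient error only shapes the Hamiltonian proposal — the
accept/reject step uses the exact density — so the invariant distribution
is untouched. The per-cell likelihood loop is JIT-compiled around scipy's
own C `betainc` when numba is available, with an equivalent vectorised
numpy fallback.

Defaults copy the benchmark protocol: 4 chains, 1000 warmup + 1000
retained draws, acceptance target 0.85. On the benchmark panel the
posterior summaries are indistinguishable across targets 0.8–0.99, and
they agree with an independent JAGS implementation of the same model on a
small test panel to well within Monte-Carlo error. A chain that ends with
more than 10% divergent draws — occasionally a chain's adaptation settles
inside the scale-parameter funnel — is deterministically rerun on a
reserved seed stream with the target raised to 0.95, then 0.99; residual
non-convergence is reported, never suppressed.

Convergence is summarised by the classic split-chain Gelman–Rubin
statistic (each chain halved; `sqrt(((n-1)/n W + B/n) / W)`), which
matches `arviz.rhat(..., method="split")` to machine precision; values
below 1.1 are taken as converged, checked over `delta`, both sigmas,
every `theta_t` and every centred spatial effect. Percentiles throughout
(summaries, credible curves, rootogram bounds) use linear interpolation
between order statistics.

## Posterior predictive checks

One replicate panel is drawn per retained posterior draw by sampling each
observed cell from its ordinal-beta distribution at that draw's
parameters. A rootogram per occasion compares observed per-class counts
with the replicate mean and the 5th–95th percentile band; plots use a
square-root count axis. Because counts are discrete, the empirical
percentile band is conservative at tied integers — the realised
flag rate of a well-specified model sits somewhat *below* the nominal
10%, and the calibration test bounds it accordingly.
`ppc_discrepancy_report` lists every (occasion, class) cell whose
observed count leaves the band.

## Problem sizes used by the test suite

The suite fits the benchmark panel once at the full protocol (4 chains ×
(1000 + 1000)); the across-seed dispersion average uses four additional
panels at 2 chains × (500 + 500), and the ten-replicate coverage study
uses 2 chains × (300 + 300) — posterior means of the three scale
parameters are stable to ~0.001–0.01 under these reductions, far inside
the tolerances being checked, and the shorter runs keep the whole suite
at desk scale. The JAGS cross-check and the real-data application are not
part of the suite: the former lives outside the package, the latter
requires the externally published survey dataset (readable via
`read_panel(..., recode="field6", absent="class1")`).

## Known limitations

* No zero-inflation or misclassification component: sites where true
  absence matters will bias `delta` upward (it absorbs excess class-1
  mass as intra-quadrat correlation).
* Spatial structure is one-dimensional by construction; 2-D layouts would
  need a different neighbourhood prior (e.g. CAR).
* The dispersion is shared across occasions and quadrats within a fit.
* Long unobserved spans are extrapolated by the AR(2) prior alone; their
  credible bands widen quadratically and should be read as model-based
  extrapolation, not evidence.
* Occasional divergent chains on small or weakly informative panels are
  handled by the escalation rerun; if divergences persist at target 0.99
  the fit is flagged and should be treated as unreliable.
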