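# Methods

## Data model

Each subject `i` carries a latent linear trajectory
`Y*_i(t) = U_i1 + U_i2 t + beta_age Age_i` with
`(U_i1, U_i2) ~ MVN(mu, G)`, observed with i.i.d. Gaussian error
`sigma^2` at scheduled exam times, and an event hazard
`h_i(t) = h_0(t) exp{gamma Y*_i(t) + alpha_1 Age_i + alpha_2 Sex_i}`.
Follow-up is `T_i = min(S_i, C_i)` with event flag `delta_i`; censoring
`C ~ Uniform(25, 30)` years with an administrative cut-off at 30 years.
All times are years from the first exam; intervals in counting-process
tables are half-open `(start, stop]` with events at `stop` and the risk
set at `t` defined by `start < t <= stop`.

Default generation parameters emulate a Framingham-style panel: 6 exams
at 0, 4, ..., 20 years; random-effect means (4.250, 0.250) and covariance
`G = [[0.29, -0.00465], [-0.00465, 0.00032]]` (log-triglyceride scale);
residual variance 0.1161 (a 0.396 variant reflects noisier assays);
survival coefficients 0.050 per year of age and -0.500 for female sex;
baseline age ~ Normal(43.3, 9.58^2) truncated to (25, 75), 51.2% female.
Two values are not dictated by the emulated cohort and are explicit
knobs: the age coefficient *inside* the trajectory (default 0.050, the
same magnitude as the survival age effect) and the Weibull shape
(default `nu = 1.5`; `nu = 1` gives the Exponential).  The baseline scale
`lambda` is never set directly in studies; it is calibrated by
common-random-number bisection so the realized censoring fraction hits a
target (10/50/90%) within ±0.02.

## Closed-form event times

The generator inverts the plug-in cumulative hazard

    H(t) = lambda * t^nu * exp{X'beta + gamma (U1 + U2 t)} = -log M,
    M ~ Uniform(0, 1),

whose solution is `T = (nu / (gamma U2)) W0(c A)` with
`c = gamma U2 / nu` and
`A = (-log M / (lambda e^{X'beta + gamma U1}))^{1/nu}`, `W0` the
principal Lambert branch.  When `|c|` falls below 1e-10 the analytic
limit (the plain Weibull inverse CDF `T = A`) is used; when
`c A < -1/e` (possible for `gamma U2 < 0`, where the hazard decays) the
cumulative hazard is bounded below `-log M` and the latent event time is
`+inf` — the subject ends censored.  Every finite draw satisfies the
defining identity to 1e-10, verified against a brute-force root-finder
in the test suite.

Note a deliberate asymmetry: this plug-in form is *not* the integral of
the hazard `h(t)` above (the integral of an exponential-in-t hazard has
an extra Lambert-type structure).  The joint-model likelihood integrates
the hazard properly.  The mismatch is retained by design — the
simulation grids are defined by the plug-in scheme, and the upward bias
of the joint ML estimator observed on those grids is partly attributable
to it.  A second, self-consistent scheme ("rizopoulos" in
`ScenarioConfig.generation_scheme`) draws event times by bisection on the
exactly integrated hazard, making the joint model correctly specified;
it is used for the n = 1000, 90%-censoring comparisons.

## Estimators

**TDCM.** Observed measurements enter a counting-process Cox model by
strict last-value-carried-forward: measurement `Y_ij` covers
`(t_ij, t_{i,j+1}]`, the final interval ends at `T_i`, and a measurement
coincident with the event time is not used.  With measurement error in
the covariate the estimate is attenuated toward zero; quantifying that
attenuation is the point of the comparison.

**TSA** (ordinary regression calibration).  Stage 1 fits the linear
mixed model by marginal maximum likelihood on all subjects; stage 2 runs
the Cox model on intervals broken at every distinct event time, the
covariate being the empirical-Bayes predicted trajectory evaluated at
each break, so each risk set sees every at-risk subject's prediction at
that event time.  Wald inference comes from the stage-2 partial
likelihood only; first-stage uncertainty is intentionally not
propagated (that understatement of the SE is itself one of the method's
documented properties).  Event-time breakpoints (rather than exam-time
breakpoints) are used because the predicted values are needed exactly at
event times.

**Cox engine.**  Newton–Raphson from zero with step-halving on the
Breslow partial likelihood (Efron available), convergence at max |score|
<= 1e-8, SEs from the inverse observed information.  A converged score
with a coefficient beyond ±15 is re-flagged as non-converged (monotone
likelihood).  The engine is validated against brute-force risk-set
enumeration and, on time-constant covariates, against an independent
proportional-hazards implementation.

**LME.**  Marginal ML with the fixed effects profiled out by GLS at
every variance-parameter evaluation; `G` is optimized through its
Cholesky factor with log diagonal, `sigma^2` on the log scale.  All
per-subject algebra reduces to 2x2 Woodbury identities, vectorized
across subjects.  Two quasi-Newton starts (moment-based and perturbed)
guard against local optima; REML is available behind a flag.  ML is the
default for consistency with the joint likelihood.  Baseline age is
included as a fixed covariate by default (matching the generator), with
a flag to drop it.

**MLA.**  Weibull shared-parameter joint model.  Per subject the
likelihood integrates longitudinal density x survival density x
random-effect prior over `(U1, U2)`:2-D tensor Gauss–Hermite (default 9
nodes per dimension, 15 as the strict setting) standardized by the
subject's *longitudinal* posterior (adaptive centering), which makes the
`gamma = 0` case exact and keeps 9 nodes accurate to ~1e-10 against
dense-grid integration.  The inner cumulative hazard uses 15-point
Gauss–Kronrod after the substitution `u = T w^2`, which removes the
`u^{nu-1}` derivative singularity at zero (without it the quadrature
error is ~1e-4 per subject at `nu = 1.5`).  Optimization is hybrid:

1. an ECM phase on quadrature atoms frozen at the initial centering
   (closed-form updates for `mu`, `G`, `sigma^2`; conditional
   quasi-Newton for the survival block plus `beta_age`), exactly
   monotone in the atom-approximated log-likelihood — 5 iterations by
   default, a cap being configurable (EM alone crawls on this model:
   the coupling information lives almost entirely in the E-step);
2. quasi-Newton (L-BFGS) with *analytic* gradients via Fisher's identity
   on fixed-center quadrature, diagonally preconditioned (the raw
   parameters differ by orders of magnitude in curvature), with centers
   refreshed between cycles until the iterate is stationary.

Standard errors come from the observed information computed as the
central-difference Jacobian of the analytic score; positivity of
`lambda, nu, sigma^2` is enforced by log parameterization and `G` by its
Cholesky factor.  Convergence is certified by the score statistic
`s' I^{-1} s < 0.01` at the reported optimum rather than by optimizer
bookkeeping (bounded line searches can report abnormal exits at a
perfectly good optimum; L-BFGS-B's bounded line search can even stall,
so box constraints are imposed as a smooth quadratic penalty instead).

**BSJM.**  Same structure with a constant baseline hazard `lam0`, which
gives the cumulative hazard the closed form
`lam0 e^{const} (e^{gamma U2 T} - 1)/(gamma U2)`.  Priors: normal(0, 100)
on `gamma`, `alpha`, `beta_age` and the random-effect means;
Wishart(Q^{-1} = I, v = 2) on the random-effects precision;
inverse-gamma(0.01, 0.01) on `sigma^2`; gamma(0.01, 0.01) on `lam0` —
diffuse stand-ins, all overridable.  Updates are conjugate wherever the
survival term permits (`sigma^2`, the precision of `G`, `mu`, and —
because of the closed-form exposure — `lam0`); random effects and the
regression scalars use random-walk Metropolis with step sizes adapted
toward 20–40% acceptance during burn-in only and frozen afterwards.
The reference protocol (4 chains, 101,000 iterations, burn-in 1,000,
thinning 50) is the default configuration; studies use much shorter
chains.  Split-chain Gelman–Rubin and an initial-positive-sequence ESS
are computed per parameter; R-hat > 1.1 on `gamma` is recorded as a
warning in the result, not raised.  The sampler is validated three ways:
prior reproduction with the likelihood switched off (using proper
finite-moment priors, since the diffuse defaults have none), conjugate
agreement with the ML mixed model when the survival block is disabled,
and a total-variation comparison (<= 0.05) of the `gamma` posterior
against a dense-grid posterior on a tiny dataset with everything else
fixed at truth.

## Study harness

A scenario fixes scheme x n x censoring x gamma x sigma^2; replicate
seeds spawn deterministically from the scenario seed, `lambda` is
calibrated once per scenario and cached, and only converged fits enter
the aggregates (the count is reported).  Reported metrics: mean
estimate, mean model SE *and* empirical SD (the single "SE" of summary
tables is ambiguous between the two), 95% Wald coverage, bias, MSE, and
— under the null — Type I error at two-sided 0.05.  MSE is computed by
its standard definition.

## Problem sizes

Monte-Carlo sizes in the shipped tests and in `scripts/acceptance.py`
are chosen for a single desk CPU: Type I error from 250–300 replicates
(null fits take ~0.15 s); mean-estimate cells from 220–250 replicates
for TSA/TDCM and 30–40 for the joint model (~3 s per joint fit at
n = 100); the n = 1000 / 90% censoring scheme from 16–20 TSA/TDCM and
5–6 joint-model replicates (~35 s per joint fit at n = 1000).  The
acceptance bands scale accordingly (±2 Monte-Carlo SEs of the run
actually performed).  At these sizes every comparison is reproducible
end-to-end in minutes; anyone wanting publication-scale precision can
raise `replicates` in the scenario configuration.

A finding worth stating plainly, because the two generation schemes were
built to expose it: under the self-consistent scheme (where the joint
model is correctly specified) the joint ML estimate of the link is
approximately unbiased and the two-step estimate overshoots slightly at
high censoring, whereas under the plug-in scheme the joint ML estimate
is biased away from the truth and the two-step estimate is nearly
unbiased.  Which estimator "wins" a simulation comparison of this kind
is therefore partly a property of the generator, not only of the
estimators — the acceptance script computes both cells so the contrast
can be reproduced directly.

## What the generator does and does not emulate

The synthetic panels reproduce the exam cadence, biomarker scale,
covariate marginals, censoring pattern and event-rate regimes of a
mid-century cardiovascular cohort.  They do not contain: missing exams
other than by death/censoring truncation, assay batch effects or serial
correlation beyond the random line, informative censoring, tied event
times, or non-linear trajectories.  Passing tests therefore certify the
estimators under exactly these idealized conditions; on real data the
linearity and non-informative-censoring assumptions are the first things
to check.

## Known limitations

* Trajectories are linear only; quadratic/spline forms are out of scope.
* The two-step variant fitted on risk sets only (risk-set regression
  calibration) is not implemented; the ordinary variant is.
* The Bayesian model's baseline hazard is constant (a Weibull option
  exists but is off by default), and its grid-scale operating
  characteristics are not benchmarked — MCMC at study scale is
  computationally prohibitive and convergence on small replicates is not
  guaranteed; its correctness rests on the oracle suite above.
* TSA standard errors ignore first-stage uncertainty by construction.
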