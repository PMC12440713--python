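# Methods

## Structural model

Phenobarbital disposition in dogs is described by a one-compartment model
with first-order oral absorption and an enzyme-turnover autoinduction
mechanism. The state is (Ad, Ac, Enz): depot amount (mg), central amount
(mg) and a relative pool of metabolizing enzymes (dimensionless):

    dAd/dt  = -ka · Ad
    dAc/dt  =  ka · Ad − (CL/V) · Enz · Ac
    dEnz/dt =  Kenz − Kenz · (1 − Cc/(Cc + IC50)) · Enz,   Cc = Ac/V

Enzyme production and degradation rate constants are equal (`Kenz`), so the
drug-free steady state is exactly Enz = 1. The drug inhibits enzyme
*degradation* with half-maximal effect at `IC50`; chronic exposure therefore
accumulates enzyme and raises the apparent clearance over the first ~2 weeks
of therapy, reproducing the clinical observation that concentrations peak
early and then settle lower under constant dosing. Degradation is modelled
as first order in Enz (the standard turnover form); a zero-order reading of
the mechanism would not admit a finite drug-free steady state, which the
model requires.

All disposition parameters are apparent (confounded with oral
bioavailability F); doses enter the depot in full. Units are fixed: hours,
mg, L, mg/L (1 mg/L = 1 µg/mL).

Covariates enter clearance as

    CL/F = CL_pop · (WT/20)^0.75 · (AGE/5)^beta_age,

an allometric weight term with fixed exponent 3/4 and a power age term
centred at the population medians (20 kg, 5 y). Volume scales linearly with
weight, V = 20 L · WT/20. Sex (an exponential term on CL/F) is supported for
covariate searches but is absent from the final model.

### Default parameters

| parameter  | value  | units | status |
|------------|--------|-------|--------|
| ka         | 0.6    | 1/h   | fixed (literature; a 0.61 h⁻¹ variant circulates — 0.6 is used consistently and is configurable) |
| V_ref      | 20.0   | L     | fixed (literature) |
| CL_pop     | 0.015  | L/h   | estimated |
| beta_age   | −0.15  | —     | estimated |
| Kenz       | 0.15   | 1/h   | estimated |
| IC50       | 1.77   | mg/L  | estimated |
| omega_CL   | 0.3    | —     | assumed (not reported with the final model; ≈30% CV log-normal IIV on CL/F, typical of canine TDM) |
| sigma_add  | 2.0    | mg/L  | assumed (additive residual SD; same caveat) |

Useful closed forms: at steady state the dosing rate balances induced
elimination, dose/τ = CL · (1 + Css/IC50) · Css, so the interval-average
concentration is the positive root of a quadratic; the steady-state enzyme
pool is 1 + Css/IC50. For the 20 kg / 5 y dog on 100 mg q12h this gives
Css ≈ 30.49 mg/L and Enz ≈ 18.2, with ODE-simulated trough/peak
≈ 28.7 / 31.6 mg/L. Because elimination grows with concentration, exposure
scales roughly with √dose once Css ≫ IC50.

## Numerical integration

Two integrators share the same right-hand side:

* a reference path (`pbpop.model.simulate_profile`) using SciPy's
  stiff-capable LSODA with rtol 1e-8 / atol 1e-10, restarted at every dose
  event so the depot discontinuity is never interpolated across;
* a fixed-step classical Runge–Kutta integrator on a shared time grid
  (`pbpop._ode.integrate_grid`), vectorized across individuals, used
  wherever thousands of profiles are needed (likelihood evaluation,
  replicate simulation, Monte Carlo dosing). The system is non-stiff (rate
  constants ≤ ka = 0.6 h⁻¹), so at the default step of 0.5 h the relative
  error against the reference path is ~1e-6, and ~1.5e-5 at 1 h (both
  verified in tests, along with the Bateman closed form in the no-induction
  limit and mass conservation with elimination disabled).

Concentrations recorded at a dose time are taken *before* the dose
(predose/trough convention, matching clinical TDM sampling). Dose and
observation times must fall on the integration grid.

## Estimation

Interindividual variability is a single log-normal random effect on CL/F,
so each subject's marginal likelihood is a one-dimensional integral. It is
evaluated by two-pass adaptive Gauss–Hermite quadrature: a first pass on
prior-scaled nodes (√2·ω·x_k) locates the conditional mode and curvature
from a local parabola, a second pass re-centres the rule there. With 16
nodes (default) the OFV is stable to <0.01 units against 32- and 64-node
rules, and it matches brute-force Monte Carlo integration on a small cohort
within Monte Carlo error. This deterministic scheme replaces the stochastic
EM (SAEM) used by commercial tools; with one random effect it is exact up
to quadrature error and fully reproducible.

The OFV (−2 log marginal likelihood) is minimized with L-BFGS-B over
log-transformed positive parameters (CL_pop, Kenz, IC50, ω, σ; covariate
exponents on the identity scale), finite-difference gradients (step 1e-5),
and box bounds that keep the ODE well conditioned. Initial values:
CL_pop 0.01, Kenz 0.1, IC50 1, beta_age 0, ω 0.3, σ 2. Non-finite
likelihoods (pathological parameter corners) return a large penalty rather
than NaN.

Standard errors come from the observed Fisher information: a central
finite-difference Hessian of −log L at the optimum on the transformed scale
(relative step 1e-4), inverted and mapped to the natural scale by the delta
method; RSE% = 100·SE/|estimate|. Wald tests are two-sided normal
approximations. During stepwise covariate screening the Wald SE for the
candidate coefficient uses the 1-D profile curvature only — a deliberate
approximation adequate for screening, not for reporting.

Covariate selection follows forward inclusion (OFV drop ≥ 3.84, 1 df,
p < 0.05, plus Wald p < 0.05 for the added coefficient) and backward
elimination (removal must cost ≥ 6.63 units, p < 0.01), with strict `>=`
conventions at the thresholds. The fixed-exponent allometric weight term
adds no estimated coefficient, so only the LRT gate applies to it. The
corrected BIC uses the hybrid penalty: subject-level parameters (CL_pop,
covariate betas, ω) × log N_subjects; observation-level parameters (Kenz,
IC50, σ) × log N_obs — reducing to the classical BIC when every subject
contributes one observation.

Individual (MAP / empirical-Bayes) estimates maximize
log p(y|η) + log φ(η; 0, ω²) by iterated parabolic refinement on a
shrinking η-grid (three rounds, accuracy ≪ 1e-3), vectorized across
subjects. With no observations the estimate is the prior mode η = 0; MAP
estimates are always shrunk toward zero relative to the unpenalized
optimum.

### Identifiability of the turnover parameters

The likelihood has a soft ridge along which (CL_pop, IC50) rise together
with Kenz falling: steady-state data constrain mainly CL/IC50 (since
dose/τ ≈ CL·Css²/IC50 when Css ≫ IC50), and only the pre-steady-state
samples separate the pair. With sparse designs, realizations of the
maximum-likelihood estimate can travel far along this ridge while staying
within ordinary likelihood fluctuation of the truth; the rich
48/168/672 h design narrows but does not eliminate it. When all subjects
share the same three sampling times, the induction transient is
essentially just-identified from three population-mean values, and some
noise realizations are best fit by the Kenz → ∞ quasi-steady-state limit
(instantaneous enzyme equilibrium, leaving only CL/IC50 identified). This
is a property of the design, not of the optimizer or the integrator:
refits from distant starting points reach the same optimum, its OFV is
genuinely below the one at the generating values (by an amount consistent
with ordinary chi-square deviance), and the OFV is unchanged under a 25×
finer integration step. Parameter-recovery experiments on such designs
should therefore be read per-parameter: the age exponent and the
variance/error components are recovered reliably; CL_pop, IC50 and Kenz
individually carry design-limited uncertainty far larger than a
linearized Fisher-information analysis of a real, staggered-time clinical
dataset would suggest.

## Synthetic data

The generator emulates a steady-state TDM study in client-owned dogs:

* demographics: truncated normal age (target 5.4 ± 3.5 y, bounds 0.3–16)
  and weight (21.3 ± 14.0 kg, bounds 2–70), with the parent (µ, σ) solved
  by moment matching so the *realized* truncated moments hit the targets;
  sex Bernoulli(0.57 male);
* regimens: mg/kg q12h oral dosing, optionally rounded to achievable
  combinations of 100/40/15 mg tablets and their halves (clinical doses
  span roughly 2.5–5.5 mg/kg);
* sampling: the sparse clinical rule draws one predose sample per dog at a
  dosing time between day 20 and day 40, with 20% of dogs contributing a
  second sample (~1.2 samples/dog, matching the ~121 samples per 100 dogs
  structure); a rich variant samples every dog at 48, 168 and 672 h for
  turnover identifiability;
* error: log-normal IIV on CL/F (ω = 0.3 default), additive Gaussian assay
  noise (σ = 2 mg/L default), truncation of negative draws at zero with a
  below-LLOQ flag, and an LLOQ of 1.1 mg/L whose default policy excludes
  censored observations from estimation (a "flag" policy retains them,
  marked MDV = 1).

What the generator does *not* emulate: dropout, co-medication, breed or
neuter-status effects, interoccasion variability, dose-adherence noise, and
assay proportional error. Passing recovery tests therefore demonstrate
correctness of the estimation machinery under the model's own assumptions,
not robustness to real-world model misspecification.

## Dose-regimen simulation

Regimens are three-phase plans (loading events, an optional q12h
progression block, long-term maintenance) in mg/kg. The recommendation
grid is stratified by weight (<10, 10–25, >25 kg) and age (≤1, 1–7, ≥7 y);
boundary conventions are half-open as listed. Phase hand-offs: loading at
t = 0 (the repeated-loading cell doses at 0 and 24 h), progression q12h
from 24 h (48 h after a repeated load) for 5 days, maintenance thereafter;
cells without progression start maintenance at 24 h.

Monte Carlo evaluation draws covariates uniformly within the stratum
(open-ended ranges capped at 60 kg / 0.3–15 y), applies log-normal IIV on
CL/F (ω = 0.3 default — the cohort ω is not separately reported, so the
synthetic default is reused), simulates 60 days, and computes the
probability of target attainment: the fraction of subjects whose
final-interval predose (trough) concentration lies within 15–45 mg/L.
Trough evaluation is the default because predose sampling is the clinical
convention; a stricter whole-interval variant is available. Residual assay
error is excluded from PTA (the target concerns true exposure). A PTA of
90% is the acceptance bar for recommending a regimen. Under these
assumptions the minimal qualifying maintenance dose for the central
stratum (10–25 kg, 1–7 y) is ~3 mg/kg q12h — below the recommended
5 mg/kg, which attains >99%; the recommendation's headroom is consistent
with its clinical provenance.

## Diagnostics

* Validation metrics: ME = mean(pred−obs) in mg/L, MRE = 100·mean of
  relative errors, RMSE = 100·√(mean squared relative error)
  (the radical is applied — the name and the percent scale require it).
  Both a-priori (η = 0, covariates only) and MAP-updated modes are
  computed; the MAP mode re-predicts the observations used for the update,
  i.e. an in-sample shrinkage summary.
* NPDE: K simulated replicates per dataset; per-subject decorrelation by
  the Cholesky factor of the empirical simulation covariance; ranks mapped
  through the inverse normal CDF, ties broken by seeded uniform jitter,
  probabilities clipped to [1/2K, 1−1/2K]. Under a correct model NPDE are
  iid N(0, 1).
* VPC: predose observations binned by weight tertile (configurable);
  observed 5/50/95th percentiles overlaid on the 90% envelope of the same
  percentiles across simulated replicates; optional prediction correction
  rescales each value by bin-median-over-own population prediction. Output
  is plot-ready tabular data; rendering is left to the caller's plotting
  tool.

## Problem sizes and reproducibility

Every stochastic routine takes an explicit seed and is deterministic given
it. The test suite and the acceptance script run at deliberately chosen
scales: parameter recovery at n = 100 dogs (the study's cohort size) with
the rich design; PTA at n = 1,000 profiles (the study's simulation size);
quadrature/MC cross-checks on 3-subject toys with 4×10⁴ draws; NPDE/VPC
null checks at K = 120–400 replicates; stepwise-selection simulations on
12–20 dog cohorts with a reduced 2-point design and partially fixed
structural parameters. Null-behaviour assertions are calibrated to ~3
standard errors at their own sample sizes.

## Known limitations

* One compartment, additive error only; no proportional-error or
  multi-compartment variants.
* A single random effect (CL/F); ω on other parameters and interoccasion
  variability are out of scope.
* The stepwise Wald screen uses profile curvature, ignoring parameter
  correlations.
* The (CL, IC50, Kenz) ridge limits turnover-parameter precision under the
  supported sampling designs (see above).
* LLOQ handling is exclusion or flagging; no censored-likelihood (M3)
  treatment.
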