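# Methods

## Disease model

Three mutually exclusive states: *Out of hospital* (OUT), *In hospital*
(HOSP, admission for heart failure, stroke or myocardial infarction),
and *Death* (DEAD, absorbing). Four transitions: OUT→HOSP, OUT→DEAD,
HOSP→OUT, HOSP→DEAD. The Markov assumption is relaxed with a
clock-reset (semi-Markov) time scale — each transition hazard depends on
time since entry into the current state, so history enters through the
current sojourn.

Each transition is modelled with a flexible parametric
(Royston–Parmar) survival model: the log cumulative cause-specific
hazard is a natural (restricted) cubic spline in log sojourn time plus a
linear predictor,

    ln H(t|x) = γ0 + γ1 u + γ2 v1(u) + γ3 v2(u) + β'x,   u = ln t,

where the restricted truncated-power terms `v_j` make the spline linear
beyond the boundary knots — which is also the model's extrapolation
behaviour beyond the observed follow-up (Weibull-like in the tail).
"Four knots" is interpreted as 2 boundary knots at the extremes of the
log uncensored event times plus 2 internal knots at the 33rd/67th
percentiles (configurable via `n_knots`; with `n_knots=2` the model is
exactly Weibull). Competing transitions censor one another at the
shared sojourn time (cause-specific likelihood); administrative
censoring contributes `−H` terms only. Ties need no correction in the
continuous-time likelihood.

Estimation maximizes the right-censored log likelihood
`Σ d_i[ln(ds/du) − u_i + η_i] − exp(η_i)` (η = s(u) + β'x) by BFGS with
the analytic gradient, initialized at the nested Weibull fit
(γ2 = γ3 = 0), and polished with damped Newton steps using the analytic
Hessian; the covariance of θ̂ = (γ, β) is the inverse observed
information. Convergence tolerance 1e-8 on the relative likelihood
change, 500 iterations maximum. Continuous covariates (age/10,
propensity) are centered before fitting and the centers are stored in
the fit, so evaluation is self-contained. Monotonicity of s(u) is
*monitored, not constrained*: a fit with ds/du < 0 anywhere on the
event-time range is flagged, and hazard evaluations clip at zero with a
warning. Fits with fewer events than parameters are flagged as
unreliable (relevant for in-hospital death, the rarest transition).

Adjustment covariates: age per 10 years, sex, clinical profile
(Multisource Comorbidity Score bands good 0–4 / intermediate 5–14 /
poor ≥15, entered as dummies), a propensity score, and treatment.
The propensity score is an explicit adjustment covariate, standing in
for the high-dimensional propensity score used with real claims data
(variable selection itself is out of scope).

## Synthetic cohort generator

The generator emulates a regional claims cohort of triple-therapy
initiators aged ≥ 40 (index dates spread over a 4-year window,
administrative end of observation giving ≤ 52 months ≙ 1,583 days of
follow-up). Defaults, configurable in `GeneratorConfig`:

* **Covariates** — age ~ Normal(68, 11) truncated at 40; 47% male;
  clinical profile good/intermediate/poor = 70/25/5% (no published
  marginal distribution exists; these are plausible placeholders).
* **Treatment assignment** — logistic on centered covariates with
  coefficients making single-pill users younger, more often male and
  healthier; the intercept is calibrated by root-finding on a fixed
  internal reference sample (seed 0, n = 20,000) so the marginal
  single-pill share is 0.31 regardless of the cohort drawn later. The
  recorded propensity is the true assignment probability jittered on
  the logit scale (SD 0.30) — a proxy for an estimated score.
* **Event histories** — competing cause-specific Weibull hazards with
  clock reset, i.e. a deliberately *different* baseline family from the
  spline used in fitting (a mild mis-specification stress test; exact
  recovery tests instead simulate from a fitted spline model).
  Baselines (per year since state entry, at reference covariates):
  OUT→HOSP shape 1.05 scale 0.07; OUT→DEAD shape 1.15 scale 0.030;
  HOSP→OUT shape 0.90 scale 28 (≈ 12-day stays); HOSP→DEAD shape 1.0
  scale 1.2 (≈ 4% in-hospital deaths). With the covariate effects this
  yields ≈ 10%/yr hospitalization and ≈ 4%/yr mortality — plausible for
  a treated hypertensive cohort of this age. Treatment log hazard
  ratios default to ln(0.91), ln(0.79), ln(1.09), ln(0.88).
* **Costs** — hospital days draw Gamma daily costs
  (mean 602.01, SD 684.00 €/day; a d-day stay is drawn exactly as
  Gamma(d·k, θ) by summability); out-of-hospital days accrue per-patient
  daily rates for CV outpatient care (Gamma mean 0.15, SD 0.33) and
  drugs (Gamma mean 0.54 single-pill / 0.52 two-pill, SD 0.35, with
  small log-linear covariate effects creating the confounding the
  adjusted drug-cost model must remove). SD = 0 degenerates to a point
  mass.
* **Reproducibility** — every per-patient quantity comes from a
  dedicated RNG substream keyed by (seed, patient id, purpose); growing
  the cohort or simulating more patients never perturbs existing ones.

Simultaneous competing event times within 1e-9 days resolve to death
(conservative); the same rule is applied in the microsimulation.

What the generator does *not* emulate: treatment switching, calendar
effects, emigration as a separate censoring cause (merged into
administrative censoring), true claims coding, or any real covariate
joint distribution. Passing tests therefore demonstrate correctness of
the *machinery* under the assumed data-generating structure, not
validity of conclusions about any real population.

## Cost model

Hospitalization and outpatient daily costs: per-patient daily rate
(total / person-days in the state), averaged across patients with
positive person-days, with SD and SE across patients; a category with no
person-days is flagged missing rather than silently zero. Daily drug
cost: Gamma GLM with log link (standard for right-skewed costs; an
identity-link Gaussian fallback exists for additive-noise
configurations) on strategy + covariates; patients with zero
out-of-hospital days are excluded (logged). Adjusted per-strategy means
are g-computation averages of per-patient predictions with strategy set
to each level; SEs by the delta method on the GLM coefficient
covariance.

## Microsimulation

Each patient is simulated under both strategies from an identical
substream (common random numbers), so paired differences are purely
parameter-driven and the identical-parameters null gives ΔC = ΔE = 0
exactly. Sojourns are drawn by inversion: E ~ Exp(1), solve H(t|x) = E.
On the log-time axis the spline equation is closed-form outside the
boundary knots and solved by Brent's method inside them (tolerance well
below 1e-6 days); if H at the remaining horizon is below E the sojourn
is censored at the horizon.

Lifetime horizon: min(70 years after index, age 110) — the analysis
horizon is "lifetime" but an explicit cap keeps the integral finite;
age enters hazards fixed at its index value (no in-simulation aging, a
stated limitation of the approach). Life-years accrue in OUT and HOSP;
drug + outpatient daily costs accrue in OUT, the hospitalization per
diem in HOSP. Discounting is continuous with force δ = ln(1 + r),
r = 3%/yr by default, applied by exact integration
`(e^(−δt1) − e^(−δt2))/δ` over each sojourn segment.

## Decision analysis

Increments are single-pill minus two-pill means over the simulated
cohort. ICER = ΔC/ΔE with cost-effectiveness-plane classification
(dominant / dominated / trade-off NE / trade-off SW / indifferent at
1e-12 tolerance); ratios are reported numerically even in the dominant
quadrant alongside the label. NMB = λΔE − ΔC at the reference
willingness-to-pay λ = €23,000/LY; the CEAC grid is €0–100,000 by
€1,000. Subgroups: sex, age bands 40–64 / 65–80 / >80, clinical
profile; stratum results aggregate back to the overall increments by
patient-count weighting (tested identity).

## Probabilistic sensitivity analysis

Per sample: transition coefficient vectors are drawn from
MVN(θ̂, Σ̂) per transition (Cholesky, with a tiny-jitter fallback for
semi-definite Σ̂; an all-zero Σ̂ short-circuits to the point estimate);
draws with a negative hazard anywhere on the fitted event-time range
are redrawn (up to 100 attempts, counts logged). Cost means are drawn
from method-of-moments Gammas — by default on the **SE of the mean**
(parameter uncertainty), with an SD mode available since published
summaries often print patient-level SDs. Each sample re-simulates a
fixed patient subsample (default 2,000) with common random numbers
across samples, isolating parameter uncertainty. Default 1,000 samples.
95% CIs are the 2.5th/97.5th percentiles of the per-sample increments
(exact order statistics of the stored vector); the marginal ICER is the
ratio of across-sample mean increments. Hazard and cost parameters are
sampled independently.

## Short-horizon validation

Model adequacy is checked by re-simulating with the horizon capped at
the 52-month observation window (undiscounted) and comparing against
quantities estimated directly from the data: the adjusted difference in
restricted mean survival time via leave-one-out jackknife
pseudo-observations of the Kaplan–Meier RMST regressed on treatment +
covariates, and the adjusted total-cost difference via a linear model.
Robust (HC1 sandwich) variances are used for both regressions —
pseudo-observations are dependent, and costs are heteroscedastic.
Agreement is flagged when the simulated point estimate falls inside the
observed 95% CI. The Kaplan–Meier/RMST estimator is implemented
directly in numpy because the jackknife needs thousands of cheap
refits; it is cross-checked against an independent survival library in
the test suite.

## Problem sizes and numerical choices

Parameter-recovery experiments run at n = 20,000 patients with 52-month
censoring (≈ 4,000 hospitalization, ≈ 2,200 out-of-hospital death and
≈ 170 in-hospital death events), which puts the Wald CI half-width for
the recovered treatment HRs near 5–10% — adequate to pin each HR to its
truth. The test suite uses a shared 4,000-patient fixture and
sub-sampled microsimulations (hundreds of patients, lifetime horizon;
the spline-truth recovery property runs 6 replicates at n = 15,000) —
sizes chosen to keep the full suite fast while leaving every assertion
comfortably powered. Root-finding tolerances: 1e-12 on log time for
sojourn inversion; optimizer tolerances as above. Degenerate inputs
(zero hazards, zero SDs, empty strata, zero events, single-patient cost
categories) are either handled exactly or rejected with named errors —
see the test suite.

## Known limitations

* Lifetime extrapolation rests on the spline's log-linear tail beyond
  52 months of data; no external life-table calibration is attempted.
* No treatment switching, no QALY/utility weighting (no quality-of-life
  data in the source setting), no time-varying covariates or frailty.
* The generator's covariate distributions and baseline hazards are
  plausible defaults, not estimates from any real cohort; headline
  numbers produced on synthetic data (life expectancy ~12–13 years at
  mean age 68, dominance of the single pill) are structural
  consequences of the configured truth, not clinical findings.
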