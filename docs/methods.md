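# Methods

## Model and estimators

The package estimates prognosis parameters for cancer survivors that can
be written as smooth functionals H(X(t), X(t+Δ)) of a process X solving

    X(t) = X(0) + ∫₀ᵗ F(X(s)) dA(s),

where A is a q-vector of cumulative hazard coefficients and F is a p×q
matrix function.  Three systems are shipped:

| system   | state        | integrators                | dynamics                                  |
|----------|--------------|----------------------------|-------------------------------------------|
| survival | S            | all-cause hazard           | dS = −S dA                                 |
| rmrl     | (S, R)       | all-cause hazard, time     | dS = −S dA, dR = S dt                      |
| cif      | (S, C^c, C^o)| cause-specific hazards     | dS = −S(dA^c+dA^o), dC^c = S dA^c, dC^o = S dA^o |

The plug-in estimator substitutes the Nelson–Aalen estimate Â (pooled or
cause-specific, with censored subjects contributing only to the at-risk
counts) and solves the resulting difference equation forward over the
event grid, evaluating all coefficients at the state of the previous
grid point.  For the survival system this reproduces Kaplan–Meier
exactly; for the cif system, the Aalen–Johansen cumulative incidences.

The covariance path V̂(t) of the root-n residual follows the companion
recursion

    V̂ ← V̂ + Σⱼ {V̂ ∇Fⱼᵀ + ∇Fⱼ V̂} ΔÂʲ + n F Δ[B] Fᵀ,

with quadratic covariation increments Δ[B]ᵢⱼ = ΔÂⁱ ΔÂʲ (zero for any
entry involving the time component).  A cross-covariance recursion
anchored at V̂(t, t) = V̂(t) propagates V̂(t, s) ← (I + Σⱼ ∇Fⱼ ΔÂʲ) V̂(t, s−)
over (t, t+Δ], and the covariance of H(X̂(t), X̂(t+Δ)) is the delta-method
sandwich of ∇H with the 2p×2p block matrix of V̂(t), V̂(t, t+Δ), V̂(t+Δ).
X(0) is a known constant in every shipped system, so V̂(0) = 0.

### Dual computation

Every parameter's variance is computed twice on every call: through the
generic machinery above, and through its closed form (the scalar
survival-variance recursion and Kaplan–Meier-ratio formula for
conditional survival, the block quadratic form for RMRL, and the
explicit a(t)/b(t) gradient vectors for the four cause-specific
transforms).  The two routes are asserted to agree to 1e-10; a failure
raises immediately rather than returning numbers.  This is the strongest
internal check available on the recursion implementations and is never
switched off.

## Numerical choices

* **Time (Lebesgue) integrators.**  Systems with a dt term (RMRL) are
  driven on the union of the event grid and a regular mesh
  (`mesh_step`, default 0.01 years).  The time component's increment is
  the spacing since the previous grid point, so time integrals of step
  integrands telescope exactly and R̂ is the exact integral of the
  Kaplan–Meier step function regardless of the mesh.
* **Exact transport of the continuous covariance part.**  Between jumps
  the covariance recursion is a linear ODE in V̂.  Its dt contribution is
  applied as the one-step transport (I + ∇F_time·h) V̂ (I + ∇F_time·h)ᵀ
  rather than the first-order Euler increment.  Because ∇F_time is
  state-independent and nilpotent for every shipped system, this
  transport is the *exact* solution of the defining equation over the
  step and composes exactly across steps, making the covariance path
  independent of the mesh to float precision.  Plain Euler would leave
  an O(mesh) residual (about 0.1–1% of the R-variance at the default
  mesh) that halving the mesh would expose.
* **Ties.**  Simultaneous deaths at s are pooled, ΔÂ = dN/Y with dN
  possibly > 1; subjects censored exactly at s stay in Y(s).  Under ties
  the quadratic-covariation increment (ΔÂ)² is used as the normative
  definition; the familiar ∫(1/Y)dÂ identity coincides with it only for
  singleton jumps and is asserted in tests on tie-free data only.
* **Right-continuity and evaluation.**  X̂ and V̂ are right-continuous
  step paths; evaluation at any t reads the last grid point ≤ t (with a
  1e-9-year tolerance absorbing float noise in mesh multiples).  Between
  the last event and the end of follow-up the paths are constant (the
  product-limit convention), so curves may be evaluated there.
* **Undefined regions.**  Any base time where a transform denominator
  vanishes — Ŝ(t) = 0 late in follow-up, no other-cause events in the
  window for the risk ratio, Ŝ(t) = Ŝ(t+Δ) for the death proportion —
  is flagged in the curve's `undefined_mask` instead of raising, since
  late-time degeneracy is routine at registry scale.
* **Confidence intervals.**  Wald on the natural scale by default
  (estimate ± 1.96·SE with the plug-in SE), clipped to the parameter's
  logical range ([0,1] for probabilities, [0,Δ] for RMRL); log and
  log–log scales are available.  Curves over t use pointwise intervals;
  simultaneous bands are out of scope.

## Population contrasts

Expected survival uses the Ederer I construction: each subject is
matched by (age at diagnosis, sex, calendar year of diagnosis) to a
population individual whose hazard follows the rate table on unit
attained-age × calendar-year cells, each individual curve and its
running integral are integrated in closed form per cell, and the curves
are averaged.  Conditional population quantities CS_g and RMRL_g are
computed from this marginal average curve (not by re-matching among
population survivors at t; the distinction matters only when the age mix
of survivors shifts, and the marginal convention is the one used with
registry rate tables).  Ages or years beyond the table carry the
boundary cell's rate forward with a warning (configurable to a hard
error).  Population curves carry zero sampling variance — they derive
from national tables — so contrast intervals reflect cohort uncertainty
only: var(ratio) = var_c / CS_g², var(difference) = var_c.  Rate tables
published as yearly death probabilities q are converted to hazards with
−log(1−q) by the reader.

## Synthetic data and what passing tests show

The generator emulates a registry cohort: latent cause-specific death
times with constant or piecewise-constant hazards (defaults: cancer
0.3/yr, other causes 0.1/yr — a cohort with substantial early cancer
mortality), independent exponential censoring (default rate 0.1/yr),
administrative censoring at 18 years, and demographics (age at diagnosis
uniform on [30, 60), sex balanced, diagnosis years 2001–2015) drawn
independently of survival.  An optional age-dependent hazard multiplier
exercises the Ederer I matching.  Because the law is
piecewise-exponential, every parameter has an exact closed-form truth
(`simulate.truth`), which the tests verify against numerical quadrature.

What this emulates well: right censoring, competing causes, realistic
event counts and at-risk decay.  What it does not: covariate-dependent
hazards beyond the optional age multiplier, informative censoring,
delayed entry, period effects in the rate table, or cause-of-death
misclassification.  Passing tests therefore demonstrate the correctness
of the estimators and their variances under independent censoring — the
assumption the method itself makes — not robustness to its violation.

Test and validation problem sizes were chosen so the full statistical
suite exercises each claim at meaningful power while completing in a few
minutes: oracle equivalences on cohorts up to n = 200, Greenwood
agreement at n = 500, truth recovery and null contrasts at n = 2000, and
interval coverage over 1000 replicates of n = 300.

## Known limitations

* Only the Nelson–Aalen estimator drives the plug-in; additive-hazards
  regression integrators are not implemented.
* No left truncation or time-dependent covariates.
* The crossing-time report's "pessimistic" time is the crossing of the
  pointwise lower 95% confidence curve — on a rising curve the only
  plotted object that crosses later than the estimate.  A bootstrap
  percentile of the crossing time would be an alternative; it is noted,
  not implemented.
* Non-monotone estimated curves report the first crossing with a
  warning; the report's logic presumes the true curve improves
  monotonically.
* Excess-hazard (relative survival) decompositions, Ederer II and
  Hakulinen expected survival, and covariate-stratified prediction are
  out of scope.
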