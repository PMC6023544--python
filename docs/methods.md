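# Methods

This note documents the statistical models the package implements, the
synthetic-data generators that stand in for the unavailable laboratory and
semi-field data, and the numerical and design choices a maintainer would
want to know about.

## Quasi-likelihood GLM engine

All stages fit Poisson (log link) or binomial (logit link) GLMs by IRLS and
convert them to quasi-likelihood inference with the Pearson dispersion
`φ̂ = X²/(n − p)`. Coefficient covariance is `φ̂ (XᵀWX)⁻¹`; nested models
are compared with the analysis-of-deviance quasi-F statistic
`F = [(D_red − D_full)/(df_red − df_full)] / φ̂`, with `φ̂` and the
denominator df taken from the larger model of the pair. One deliberate
exception: in the time-course stage, the 1-df test collapsing the two
highest-RH cells at 25 °C takes its dispersion from the *collapsed* model,
so its denominator df is that model's residual df (113 on 120
observations). This matches the df convention of the published analysis
this stage reconstructs; the standard larger-model convention would give
112.

Numerics: IRLS starts from `μ₀ = y + 0.5` (Poisson) or `(y + ½)/(n + 1)`
(binomial) projected onto the design on the link scale; convergence is a
relative deviance change below 1e-8 within 100 iterations. If the
statsmodels IRLS path diverges (it can overflow when a segmented-basis
candidate pins a cell near zero), a damped step-halving IRLS computes the
same estimate; both paths report the plain exponential-family
log-likelihood at dispersion 1, which is the quantity the breakpoint search
profiles. Rank-deficient designs raise an error naming the aliased columns
rather than silently dropping them — the factorial designs here must be
constructed correctly, and silent dropping hides bugs. Linear predictors
exceeding ±30 at convergence attach a separation warning to the fit.
p-values are reported at full precision with no multiplicity adjustment.

## Stage 1: factorial analysis

RH levels with zero total conidia across all cadavers (80% and 85% by
construction) are removed before modelling. Temperature enters as a
continuous covariate centered at 19 °C (the mid-range of the 13–25 °C
design), giving each RH group an intercept and a slope: 6 parameters for
the full {90}, {95}, {100} grouping on 120 cadavers, hence residual df 114.
Two tests are reported: collapsing {95, 100} against the full grouping
(2 df) and the common temperature slope against an intercept-only model
(1 df, denominator 118). Capilliconidia proportions use the per-cadaver
total as binomial trials; cadavers with zero total have no defined
proportion and are excluded (with their count reported), which is why the
proportion tests run on fewer df than the count tests.

## Stage 2: segmented discharge curve

The "maximal" linear predictor is one free intercept per RH × temperature
cell (3 × 2 = 6) plus two slopes shared across cells on the broken-stick
basis `s₁ = min(t, ψ)`, `s₂ = (t − ψ)₊` — 8 parameters on 120 records,
residual df 112. The breakpoint is profiled on a fixed grid (default
4.5–35.5 h in 0.1 h steps): the profile log-likelihood is piecewise smooth
in ψ with kinks at the design times, so a grid argmax is robust and
auditable where smooth optimizers are not; ties break toward the smallest
candidate. Profiling uses the pure Poisson likelihood (dispersion 1);
dispersion is then re-estimated at ψ̂ for the quasi-Poisson tests. A single
common breakpoint is fitted across all cells, matching the single reported
discharge window. Candidates whose fit fails are dropped from the argmax
with a warning. `discharge_window` summarizes a fit as (onset, plateau):
the largest design time before ψ̂ whose largest fitted mean is still below
one conidium, and ψ̂ itself.

## Stage 3: response surface and decision support

Duration covariates count hours *strictly above* the thresholds (RH > 90%,
T > 21 °C) in a 24 h window ending at the destructive-sampling time, at the
logger's hourly resolution, so they are integers in [0, 24]. The surface is
linear with interaction (4 parameters), not quadratic: on 28 weekly
observations this yields the sequential ladder F(1,26), F(1,25), F(1,24)
for warm hours, humid hours and interaction — a 6-parameter quadratic would
be inconsistent with that df sequence. Sequential (type-I) tests are
reported in the order warm hours, humid hours, interaction. Iso-probability
contours solve `logit p = η` for one covariate with the other fixed; the
equation is linear in the free variable with effective slope
`β_free + β_int · fixed`. A non-positive effective slope returns an
explicit "non-increasing surface" infeasible result, and an out-of-range
solution an infeasible result that still carries the unconstrained root
(negative roots mean the probability target is already exceeded at zero
hours). The count-to-category scale maps 0 → zero, 1–500 → low,
> 500 → high; the printed scale's boundaries ("low >1 and <500") are
internally inconsistent, and this convention keeps the categories
exhaustive with an unambiguous binary sporulation indicator.

## Diagnostics

Half-normal plots order the absolute deviance residuals against quantiles
`Φ⁻¹((i + n − 1/8)/(2n + ½))`. Envelopes simulate `n_sim = 99` response
vectors from the fitted means under the *plain* Poisson/binomial family —
not inflated by `φ̂` — refit the same design to each, and take per-position
empirical quantiles at `(1 ± level)/2` and the median. Simulating at
dispersion 1 is deliberate: overdispersion then shows up as observed
residuals escaping the envelope, which is what makes the display useful as
a quasi-model check; the corresponding limitation is that a well-fitting
quasi model with large `φ̂` will also flag points.

## Synthetic-data generators

The generators define the study conditions for every test; none of the raw
data behind the original analyses are available.

**Calibration.** The default response surface is the unique 4-parameter
logistic surface through four anchors: the two published 0.9-probability
contour points (6 humid h, 10 warm h) and (15 humid h, 6 warm h), plus
(0, 0) → 0.01 and (24, 24) → 0.999 to pin the surface away from the
contour. Solving the 4×4 linear system in logit space gives
β₀ = −4.595, β_RH = 0.325, β_T = 0.594, β_int = −0.0183. The negative
interaction implied by these anchors makes the surface decrease very
slightly in humid hours once warm hours exceed ≈17.7 (a dip below 1e-3 in
probability at the 0.999 plateau); the surface is exactly monotone in warm
hours everywhere. The shape tests assert exactly that.

**Factorial assay** (20 combinations × 10 cadavers): counts at 80/85% RH
are identically zero. Elsewhere the per-cadaver total is gamma-Poisson:
`total ~ Poisson(Z μ)`, `Z ~ Gamma(k, mean 1)`, `log μ = a_RH + b_RH (T − 19)`,
giving negative-binomial variance `μ + μ²/k` — any mean-correct generator
is admissible for quasi-likelihood fitting, and the moment identity
`var/mean = 1 + μ/k` is what the dispersion-recovery tests check. The
capilliconidia share is binomial with a logit linear in temperature per RH
level. Defaults (`a = {3.2, 4.0, 4.2}`, `b = {0.10, 0.12, 0.12}`, `k = 2`)
reproduce the qualitative factorial pattern: counts and capilliconidia
proportion rise with temperature, ≥95% RH beats 90%, and the proportion at
90% RH is flat in temperature (its logit slope defaults to 0, which is why
the temperature slope is per-RH-level rather than a scalar). They are
configuration, not estimates of the original data.

**Time course** (3 RH × 2 temperatures × 5 durations × 4 replicates = 120
records, each an experimental unit pooling four cadavers): broken-stick log
mean with true breakpoint ψ = 10 h (midpoint of the published 8–12 h
discharge window) and a flat second segment (b₂ = 0; discharge plateaus).
The baseline `a = −7` and pre-break slope `b₁ = 1.3` keep the 4 h mean
below 0.5 conidia (no discharge in the first hours) while plateaus reach
roughly 150–650 conidia per unit, a sharp enough rise for the breakpoint to
be recoverable within the published window in ≥90% of replicates — the
recovery rate the generator is required to support. The frailty shape is
`k = 8`: the sum of four independent per-cadaver Gamma(2) frailties, i.e.
the factorial assay's cadaver-level overdispersion aggregated to the unit
level.

**Semi-field trials** (28 weeks × 10 cadavers; 28 weeks is what the
published residual df 24/25/26 for the 4/3/2-parameter ladder implies):
each week gets a 24 h hourly weather window, `T(t) = 21 + 5 sin(2π(t−9)/24)
+ shift + N(0, 1)` with RH in opposite phase (mean 90, amplitude 7, clipped
to [0, 100]). Week-level shifts are laid out on an evenly spaced grid over
±7 °C (temperature, in week order) and ±8% RH (independently permuted), so
the realized (H_RH, H_T) covariates sweep the full [0, 24]² square on every
seed the way fifteen months of seasons would — an i.i.d. draw could leave
the corners uncovered and the interaction unidentifiable. Sporulation is
binomial with the calibrated surface's probability at the week's
covariates.

**What passing tests do and do not show.** The generators are mean- and
design-faithful but idealized: no missing logger hours, no within-window
autocorrelation beyond the diel cycle, no spatial leaf-microclimate
variation, frailties independent across cadavers, and quasi-Poisson fits
face negative-binomial (not arbitrary) overdispersion. Recovery results on
these data demonstrate that the estimators are implemented correctly and
are consistent under the assumed structure — not that the original field
system satisfies that structure.

## Problem sizes and determinism

Recovery suites use 100 replicates for the breakpoint (grid of 311
candidate fits each), 200 for the surface/contour recovery, 200 outer
replicates of 99-simulation envelopes for diagnostics coverage, and 2000
null replicates for the F-test size check. Contour-recovery summaries
average the feasible (in-[0, 24]) solutions; fits whose 0.9 contour falls
below zero hours are reported infeasible-with-root and excluded. Every
stochastic component takes an explicit seed; the pipeline writes a manifest
with SHA-256 hashes of its inputs, and identical configuration reproduces
byte-identical outputs.
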