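# Methods

## Problem and model

Neonates lose weight after birth — typically 4–8% of birth weight, reaching a
minimum (the *nadir*) around days 2–3 — before regaining it around days 4–6.
When birth weight is measured a day or more after delivery, as is common for
home births visited by field workers, the measurement sits near the nadir and
understates the weight at delivery. Population prevalences of
small-for-gestational-age (SGA, weight-for-GA below the 10th percentile of a
sex-specific standard) and low birth weight (LBW, <2500 g) computed from such
measurements are inflated. The package recalibrates each measured weight back
to time t = 0 at delivery, imputes birth weight for births with no
measurement, and re-estimates the prevalences with multiple imputation.

The recalibration is an empirical-Bayes transfer between two cohorts:

1. **Training (longitudinal) cohort.** Daily weights on days 0–10 for a few
   hundred surviving singleton babies, first weight within 6 h of delivery.
   A linear mixed model is fitted by REML (`statsmodels MixedLM`):

       Y_ij = x_ij'β + u0_i + u1_i·t_ij + e_ij,

   with fixed effects for parity (first-birth indicator), maternal education
   and age, infant sex, and gestational age with a linear spline knot at 40
   weeks; per-baby random intercept u0 (g) and slope u1 (g/day);
   Var(u0, u1) = G (2×2), Var(e) = σ². G and σ² are the transferred
   quantities.

2. **Application cohort.** One weight per live birth at postnatal age t (or
   none). A mixed model of the observed weight with a per-woman random
   intercept and fixed effects — natural cubic spline in maternal age (4 df),
   education, neonatal-death indicator, sex, preterm and multiple-birth
   indicators, first-birth indicator, and age-at-measurement terms (linear in
   days plus a linear spline knot at day 3) — yields for each record the
   prediction at its own t (ŵ_it) and at t = 0 (ŵ_i0).

3. **Empirical Bayes combination.** With v_i = G11 + G12·t_i (the covariance
   between the random part of weight at delivery and at t_i),

       λ_i = v_i/(v_i + σ²),
       w̃_i0 = ŵ_i0 + λ_i·(w_it − ŵ_it),
       Var(w̃_i0) = (G11 + σ²) − v_i²/(v_i + σ²).

   m predictive draws from N(w̃_i0, Var(w̃_i0)) form the imputation datasets.

### The shrinkage denominator

The exact conditional distribution of weight(0) given weight(t) under the
random-intercept + slope model has denominator
Var(w_t) = G11 + 2·G12·t + G22·t² + σ², not v + σ². The package implements
the shrinkage form above as its primary operation and ships
`oracle_conditional_normal` (exact bivariate-normal conditioning) alongside;
the two coincide exactly when t = 0 or when G12 = G22 = 0, and the test suite
quantifies the gap elsewhere. With the slope variance G22 small relative to
G11 (the empirical situation: weight level varies across babies far more than
its day-to-day drift), the difference is a fraction of a percent of the
shrinkage weight.

Two numerical guards: when G12 < 0 and t is large, v can go negative; λ is
then clamped to 0 with a warning, so the estimate degrades to the
covariate-only prediction ŵ_i0. When G12 > 0 pushes v above G11, the printed
variance expression can go slightly negative; it is clamped at 0.

## Missing-weight imputation

Weights are missing for a non-random subset (in the emulated setting ~12%,
concentrated in neonatal deaths — ~62% missing — and preterm births). A
random-forest regression (scikit-learn, 500 trees by default) of the
recalibrated birth weight on sex, gestational age, multiple/singleton,
survival status, first-birth indicator, maternal education and age is
trained once per imputation index k on recalibrated draw k (m parallel
forests, preserving between-imputation variability; a mean-trained
single-forest mode is available). A stochastic draw is the forest prediction
plus a residual resampled from the out-of-bag residual pool — distribution-
free, though it ignores heteroscedasticity; per-tree sampling would be the
alternative. Records missing any required covariate are excluded with exact
bookkeeping (imputed + excluded = missing). All draws are floored at 300 g.

Forest prediction gaps attenuate rare binary effects: with ~1.6% multiples,
a −659 g generating deficit is recovered at roughly −600 g, and a −324 g
neonatal-death deficit at roughly −220 g. This attenuation is inherent to
ensemble averaging with rare splits and is reflected in the test tolerances.

## Trajectory analytics

Per-baby descriptive statistics extend the observed daily weights to a dense
curve from delivery: a natural cubic interpolating spline through the
(time, weight) points, evaluated on a 0.01-day grid over [0, 10]. The birth
weight for the return criterion is the curve's value at t = 0 (the short
extrapolation from the first measurement, taken within 6 h); the nadir is
the grid argmin (ties broken earliest); the return time is the first
post-nadir time the curve regains the delivery weight, censored at the
window end otherwise. The probability of not yet having returned is the
Kaplan–Meier product-limit estimator (lifelines), censored babies
contributing risk time to day 10.

A GCV-chosen smoothing spline was rejected for the curve builder: on
synthetic truth it oversmooths the ~4% nadir dip (recovered loss ~2.9%,
nadir shifted ~0.1–0.15 d late), while the interpolating spline recovers the
nadir time essentially unbiased. The cost of interpolation is a small
noise-driven bias elsewhere: with 30 g measurement noise the apparent
minimum is ~10–15 g deeper than the true one (relative loss overstated by
~0.4 percentage points) and the measured median return time runs ~0.1 d
late, with slightly fewer censored babies than the generating fraction
(noise lets slow regainers cross the threshold just inside the window).
These biases are documented in the test tolerances.

## Classification and reporting

Size-for-GA uses a pluggable percentile table (sex, GA, p03/p10/p50/p90)
with linear interpolation in GA; weights exactly at the 10th or 90th
percentile are AGA (closed interval); GA outside the table's range
[22+0, 44+6] weeks is explicitly unclassifiable. The packaged default table
is **synthetic** — a Gompertz median curve (asymptote 4650 g, rate 0.1184/wk,
inflection 31 wk, female factor 0.955) with normal proportional spread
(CV 12.5%), in the right range for a South-Asian cohort — because no
published extrapolated standard covering that range is publicly available;
real analyses must supply their own table. LBW/VLBW use strict <2500 g /
<1500 g. Two GA band schemes are provided (default: term ≥37 to <45 wk;
alternate: term 37–42 plus post-term 42–45, with "very preterm" naming).

Prevalences use a Wald 95% CI on the reporting scale (the large-sample
regime the method targets; Wilson available for boundary cases), pooled
across the m completed datasets with Rubin's rules
(T = W + (1 + 1/m)B, t reference with ν = (m−1)(1 + W/((1+1/m)B))²).
The comparison table contrasts measured weights taken <72 h after delivery
with the multiply-imputed estimates; relative change is reported unsigned,
absolute difference signed (imputed − measured), display rounding 1 dp.
The neonatal mortality rate counts lost-to-follow-up births as survivors
(the reference category of the survival definition; a toggle inverts this).
The heaping index is the percent of weights exactly at a target value
(default 4500 g) among weights within ±250 g of it.

## Synthetic-data generator

The generator emulates the documented structure of the two cohorts so every
stage is testable with known truth. Per-baby latent trajectory: log-linear
decline to the nadir, log-linear regain to birth weight, then linear growth
at 30 g/day; observed weight = trajectory + N(0, 30 g) (digital-scale-order
noise). Parameter distributions (right-skewed, median-parameterised):

| quantity | distribution | default calibration |
|---|---|---|
| nadir time | log-normal | median 2.1 d, σ_log 0.07 |
| relative loss at nadir | logit-normal | median 4.3%, σ_logit 0.35 |
| regain interval Δ | log-normal | solved from: median return 4.5 d among returners, 84/457 never returning in 10 d |
| birth weight | normal, covariate mean | intercept 2810 g; sex +85, first birth −100, GA spline +110/+30 g/wk (knot 40), multiples −659, neonatal death −324, residual SD 350 g, floor 500 g |
| measurement age (application) | log-normal mixture | facility (58.1%): median 11.5 h, σ_log 1.2; home: median 30 h, σ_log 2.3 — giving overall median ≈15.2 h and ≈8% beyond day 10 |

The Δ distribution's (μ, σ) are solved in closed form so that, with the
nadir at its median, P(nadir + Δ > 10) equals the never-return fraction and
the conditional median among returners maps onto the 4.5-day target.

The missing-weight mechanism is a logistic model in survival status
(log-odds +2.6 for deaths), preterm birth (+0.33), nulliparity (+0.15) and
education (+0.02/yr) with intercept −2.25, calibrated to ~12.4% missing
overall, ~62% among deaths and ~11% among survivors. Missingness depends on
covariates and survival only — conditionally independent of the weight —
so downstream missing-not-at-random behaviour is attributable entirely to
the covariate–weight correlation. Small independent covariate missingness
(sex 0.3%, parity 0.5%, survival 0.14%, education 0.1%) exercises the
exclusion bookkeeping. Women contribute 1 + Poisson(0.38) births each.

A separate mode (`simulate_lmm_training_cohort`) generates repeated weights
directly from the random-intercept + slope linear model with configured
G (default diag-dominant, G11 = 160 000 g², G22 = 400 g²/day²,
G12 = −1600 g²/day) and residual SD 50 g: the fitted model is then correctly
specified, which is the only setting in which "recovering the generating
G and σ²" is well-posed. Variance-component recovery is assessed across 20
seeds at 457 babies × 11 visits as the median relative error: G11 and σ²
within 15%; fixed effects within 10%, assessed on the intercept and the
below-40-week GA slope — the coefficients whose generating magnitude is
large relative to their sampling SE at n = 457 (a 2 g/yr education effect
has a ~5 g SE; relative error is not meaningful there). These tolerances
are repository constants in the acceptance tests.

What the generator does **not** emulate: cluster-randomised intervention
arms or spatial structure, secular trends between the two cohorts' eras,
digit preference/heaping (weights are continuous; the heaping index is
exercised on constructed fixtures), gestational-age measurement error,
within-pair correlation of twins beyond the shared woman intercept, and any
dependence of the trajectory shape on SGA status (growth-restricted babies
may lose weight differently). Passing tests therefore demonstrate internal
consistency of the method under its own assumptions, not field validity.

## Numerical choices and problem sizes

- REML throughout (toggleable to ML); optimizers tried in order lbfgs →
  powell → nelder-mead, since profiled surfaces with weakly identified
  variance components (most women contribute one birth) make gradient
  methods fragile. Exactly-constant training data short-circuits to a
  degenerate zero-variance fit flagged singular.
- Constant fixed-effect columns in the application model (no multiples
  sampled, or all measurements on one side of the time knot) are dropped
  from the design rather than left to make it singular.
- Grid resolution 0.01 d (~15 min) for nadir/return searches; ties earliest.
- Times are converted hours → days at module boundaries; every interface
  documents its unit.
- Test and acceptance runs use reduced problem sizes chosen for stable
  statistics: application cohorts of 1 200–20 000 births (full scale
  31 116), forests of 50–200 trees (default 500), 20 seeds for stochastic
  recovery. The training cohort always runs at its natural size (457).
- One global seed spawns per-stage substreams (`numpy SeedSequence`), so
  stages rerun in isolation and identical configs give byte-identical
  artifacts.

## Known limitations

- The transfer of (G, σ²) across cohorts is assumed, not checked; nothing
  in the package can detect a training/application mismatch.
- The application model's linear-plus-knot time trend only approximates the
  nadir-shaped population curve, leaving a residual bias of a few tens of
  grams for measurements near the nadir (reduced ~2–3-fold from the raw
  bias in the synthetic evaluation).
- The Box-1-style shrinkage denominator is implemented as specified rather
  than the exact conditional variance; the oracle quantifies the difference.
- OOB-residual draws assume exchangeable residuals across the covariate
  space.
- Prevalence CIs ignore the uncertainty of the transferred variance
  components and of the growth standard itself.
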