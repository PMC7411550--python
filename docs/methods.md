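# Methods

## Study design implemented

The package implements a time-stratified case-crossover analysis of daily
ICU admission counts against dichotomous dust-storm exposure. The design
compares each location with itself within a fixed calendar stratum, which
removes time-invariant confounding (hospital catchment, population) and,
through weekday-matched control days, day-of-week effects, by construction.

A stratum is a ZIP × year × calendar-quarter cell containing at least one
dust day. Control days sit at ±28k days from each dust day inside the same
quarter; 28 is a multiple of 7, so controls inherit the dust day's weekday,
and bidirectional sampling yields two or three controls for any dust date
(three when the date lies within 28 days of one quarter edge). Follow-up
days +1..+5 after every index day enter the stratum so that lagged effects
are estimable; a mid-quarter dust date therefore produces the canonical
18-day stratum (3 index days × 6). Follow-up days crossing the quarter or
year boundary are retained and carry the covariates of their true dates.
Multiple storms in one cell merge into a single stratum, and lag
indicators are computed against the full dust-day table, so one day may
carry several nonzero lags when storms fall less than six days apart.

## Conditional quasi-Poisson estimation

Conditioning the stratum-intercept Poisson model on stratum totals leaves
the multinomial likelihood

    l(b) = sum_s [ sum_i y_si x'_si b − Y_s log sum_i exp(x'_si b) ].

We maximise it directly (Newton–Raphson, start b = 0, step-halving on
likelihood decrease, convergence at max |gradient| < 1e-8, 50-iteration
cap) rather than fitting thousands of stratum dummies; the two estimators
share the same maximiser, which the test suite verifies against a
stratum-dummy Poisson fit to 1e-6. Strata with zero total count or a
single day contribute nothing and are dropped before fitting.

Numerical choices:

* Nuisance spline blocks are QR-orthonormalised before entering the
  design. The truncated-power natural-spline basis is exact but badly
  conditioned at 8 df per year over a 16-year span; orthonormalisation
  changes the column span not at all and the dust-lag coefficients not at
  all, while keeping the information matrix well conditioned. Columns are
  further rescaled to unit norm inside the optimiser and mapped back.
* Aliasing is detected on the within-stratum-centred design (the
  conditional likelihood sees only within-stratum contrasts) by greedy
  rank-revealing orthogonalisation at tolerance 1e-8, with the dust lags
  ordered first so collinear confounder columns, not exposure columns, are
  dropped. The pruning is repeated after non-informative strata are
  removed, since their removal can re-introduce collinearity. Dropped
  columns are reported as aliased, never silently zeroed.
* Complete separation is detected two ways: the within-sample linear
  predictor spread exceeding 30 during iteration, or a converged solution
  in which one day absorbs its stratum's entire count with fitted
  probability 1 − 1e-6 (a boundary/monotone likelihood).
* Dispersion is the Pearson statistic over N − G − p degrees of freedom,
  where G is the number of informative strata (the absorbed intercepts);
  it is used as estimated, without flooring at 1, per quasi-likelihood
  convention. When the residual df is nonpositive (saturated toy fits) the
  dispersion falls back to 1 with a logged warning.
* Inference is Wald throughout: per-lag percent increases
  100·(exp(b)−1), uniform-weight window contrasts with variance c'Vc, and
  a joint chi-square test over all lag coefficients.

PM2.5 and ozone enter linearly at lag 0; their lag and functional form are
otherwise unconstrained choices, and the linear form is the simplest
defensible default. The date spline df is 8 × (number of distinct calendar
years in the fitted rows).

## Scenario scaling

A dichotomous dust-day log relative risk is extrapolated to a hypothetical
severe storm by assuming log-linearity in the PM10 contrast: with
dust-day elevation Δ = 47.8 µg/m³ and target concentration T,
p → 100·(exp(log(1+p/100)·T/Δ) − 1) applied to the centre and both CI
bounds. The transform is monotone in T, continuous at p = 0, and reduces
to the identity at T = Δ. Scaling the published rounded inputs reproduces
the published projections at printed precision for the centre and upper
bound; the lower bound differs in the last digit (3.4 vs 3.3) because the
original was evidently scaled before rounding.

## Dust–meteorology contrasts

The contrast of each environment variable on dust days is estimated with a
linear mixed model — fixed dust indicator plus a seasonal natural spline
on date (8 df/year), random intercept per stratum — fitted by REML via
statsmodels MixedLM. This stage is a standard fit contract, not novel
computation, so a library routine is used; the degenerate zero-variance
limit is checked against OLS as an oracle. Reported p-values are floored
at 1e-300 rather than printed as zero.

## Synthetic data generator

The generator emulates the four inputs with the statistical structure the
analysis assumes. Defaults are the study's operating points where stated,
chosen once otherwise:

* **Storm calendar** — storms per ZIP-year 1.0; month weights bimodal with
  the July–August peak and a secondary April bump
  (2,2,3,6,4,3,10,10,4,2,2,2 before normalisation); begin hours
  afternoon-peaked (rounded N(14.5, 2.5), clipped to 0–23). Timing is
  generated for fixture realism but unused by the daily-resolution
  analysis.
* **Geometry** — ZIP footprints are 10 km axis-aligned rectangles on a
  40 km lon/lat grid; forecast zones are bounding boxes of 2×2 ZIP blocks.
  With these spacings the 20 km buffer rule recovers exactly the
  zone-membership exposure truth, so linkage is exercised with a known
  answer; nothing attempts to mimic real U.S. geography.
* **Environment** — each variable is an annual sinusoid plus a ZIP-level
  intercept and daily Gaussian noise, with additive dust-day shifts
  defaulting to the observed contrasts: PM10 +47.8 µg/m³, PM2.5 +3.7,
  temperature +2.38 °F, dew point +2.34 °F, ozone −0.52 ppb,
  precipitation 0. One monitor sits at each ZIP centroid; PM2.5
  monitor-days are deleted at rate 2/3 by default, emulating 1-in-3
  sampling schedules. A single ZIP-level field plus monitor noise is used;
  no within-ZIP spatial correlation structure is modelled.
* **Counts** — for three disjoint components (respiratory,
  cardiovascular, other; baseline means 0.7, 1.6, 0.4 per ZIP-day) the
  mean is baseline × day-of-week factor × lognormal ZIP effect ×
  Π_k lag_rr[k]^dust(d−k), with default respiratory lag relative risks
  (1.092, 1, 1, 1, 1, 1.075) and null cardiovascular ones. Overdispersion
  (default 1.5) is a gamma mixture giving variance = φ × mean exactly.
  Day-of-week factors default weekday > weekend so the design's automatic
  weekday control is actually exercised. The reported `all` endpoint is
  the component sum, which preserves the nesting invariants; its lag
  structure is therefore a blend of the component risks rather than an
  independent dial.

What passing tests on this generator do **not** show: robustness to real
monitor network geometry, to spatially correlated exposure error, to
endpoint overlap (real admissions can carry both respiratory and
cardiovascular codes), or to secular reporting changes in the storm
database.

## Problem sizes used in the checks

The recovery check fits the full confounder design on a 48-ZIP, 16-year
world (~1,500 informative strata), matching the scale at which the
published lag effects were estimated to within an order of magnitude.
Interval-coverage uses 200 count redraws on a fixed 24-ZIP, 4-year world
with the dust-only design — the coverage of the Wald intervals is a
property of the estimator, not of the confounder set — and dispersion,
meteorology-contrast and null-calibration checks use similar mid-sized
worlds. The null check reads "no rejection" as the joint 6-df Wald test
per endpoint at the 5% level.

## Known limitations

* Footprint distances use a local equirectangular projection; exact
  geodesic polygon clearance is unnecessary at 20 km tolerance, but the
  approximation degrades for footprints spanning many degrees or at
  extreme latitudes.
* Unconstrained distributed lags only; no penalised lag structures and no
  bootstrap or small-sample inference.
* The sensitivity grid's nine confounder subsets are a configurable
  lattice, not a canonical list.
* Multi-day storm events expose their begin date only, consistent with
  storms lasting a few hours.
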