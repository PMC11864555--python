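# Methods

This note records the modeling choices behind `chumrun`, the defaults and
their rationale, what the synthetic generator does and does not emulate,
and the numerical conventions.

## Study geometry and dates

Six coastal regions partition into a northern (CR1–CR3) and a southern
(CR4–CR6) area at 37 °N, the latitude of the subpolar front during the
spawning season. Each region carries both a lat/lon box (used when
averaging gridded SST: all grid cells whose centers fall in the closed box)
and a representative site point at the river mouth. The site point, not
the box midpoint, decides the north/south assignment — CR4's box straddles
37 °N but its river mouth (36.97 °N) is southern.

All dates are integer day offsets from Oct 1 (day 0) of the migration
year; the Oct 1–Dec 31 window is always 92 days (it never contains Feb 29),
and no window crosses a year boundary.

## SST-regime typing

* **Crossing date**: first day with SST *strictly* below the 20 °C
  threshold ("decreases below" is read strictly; a value of exactly 20.0
  does not trigger). Interior gaps of ≤ 3 days are bridged linearly;
  longer gaps, or missing edges, are data-quality errors — reanalysis
  products are gap-free, and no data is invented.
* **"Average year"** is operationalized as the per-region mean crossing
  day over all years in the dataset (leave-self-in). This keeps every year
  labelable and makes all anomalies — and therefore all labels — invariant
  to adding a constant to every crossing day.
* **Classification**: the T2 test has priority. With per-region anomalies
  a_r = cross_day − baseline_r, a year is **T2** when
  mean(a_south) − mean(a_north) ≥ 7 days (the north cooled well before the
  south, whatever the overall sign); otherwise **T1** if the mean anomaly
  over all regions is negative, else **T3**. The north–south gap is
  computed on *anomalies*: southern regions cool later climatologically
  (~8 days in the defaults), and a raw-gap rule would label every year T2.
  The 7-day default separates regimes cleanly in the synthetic presets but
  is an implementation choice, exposed as a tunable and echoed in reports —
  the field literature gives no numeric criterion for a "significant"
  north–south difference.

## Phenology statistics

* **MDMT** is the first day whose cumulative catch strictly exceeds 50 %
  of the window total ("more than 50 %"): an even total split exactly at
  the half mark resolves to the next day.
* **Residence time** is riverine − coastal MDMT, signed. Negative values
  are retained but flagged, not dropped.
* **Temperature binning**: each day's catch joins the 1 °C left-closed bin
  [t, t+1) containing that day's SST; bins accumulate over the pooled
  years of one regime and are normalized to fractions per (region,
  regime). Normalization (rather than raw counts) puts the response on a
  0–1 scale, consistent with thermal-response mean-squared errors of order
  0.002.

## Mixed-effects model comparison

Three candidate structures for each response (coastal MDMT; residence
days): (1) regime-only fixed effects, (2) regime fixed + region random
intercept, (3) full regime × region fixed interaction (ordinary least
squares — the saturated interaction leaves nothing for a random term).

* **ML, not REML.** AIC comparisons span different fixed-effect
  structures; REML likelihoods are not comparable across those.
* **AIC = 2k − 2 logLik**, with k counting fixed effects *and* variance
  components (residual variance always; the random-intercept variance for
  structure 2). Log-likelihoods agree with R's `lm`/`lmer(REML=FALSE)` to
  1e-4 (cross-checked in the test suite). Ties break to smaller k, then
  lower structure number.
* **Contrasts** are Wald tests on linear combinations of fixed effects
  with a t reference at n − k_fixed degrees of freedom (Satterthwaite
  approximations are out of scope). Reference levels are T1 and the
  alphabetically first region. For structure 3 the package reports both
  regime differences within each region and region differences within each
  regime.
* **Significance markers** follow the study area's reporting convention —
  `*` p < 0.01, `**` p < 0.05, `***` p < 0.001 — which inverts the usual
  meaning of `*` and `**`; numeric p-values are always emitted alongside,
  and p < 0.1 is tiered "marginal".
* **Boundary behavior.** When the region variance is (near) zero the
  marginal likelihood optimum sits on the boundary and the mixed-model
  Hessian is singular; `fit_lme` then returns the exact boundary fit
  (OLS on the same fixed effects with σ²_region = 0 and unchanged k), and
  also prefers the boundary fit whenever its likelihood beats the
  optimizer's.
* **A caveat on structure selection.** Marginal-ML AIC is known to be
  biased against random effects (Greven & Kneib 2010): with only six
  regions, the marginal likelihood effectively pays the Gaussian density
  of the six realized region means, while the fixed interaction model pays
  just two AIC points per extra coefficient. Consequently, when the
  between-region spread is large relative to the residual noise, AIC often
  prefers structure 3 over structure 2 *even on data generated with a
  genuine random intercept* — selection between structures 2 and 3 should
  be read as "is the regional structure worth 14 extra parameters here",
  not as a test of whether region effects are random. The package reports
  the full comparison table so this is always visible.

## Thermal-response models

* Families: quadratic polynomial (b1 + b2·x + b3·x²), exponential
  a·e^(bx), logistic L / (1 + e^(−k(x − x0))) — the minimal standard 3-,
  2- and 3-parameter forms.
* Abscissae are bin centers (left edge + width/2). Bins with zero
  accumulated catch are excluded from the regression by default
  (configurable): a temperature range with no recorded catch is
  indistinguishable from one the run never visited, and anchoring the
  curve at zero there biases it toward unvisited temperatures.
* AIC uses the Gaussian log-likelihood with σ² estimated by ML and counted
  in k, so families with different parameter counts are comparable; MSE is
  reported and flagged above the 0.002 benchmark.
* Nonlinear fits run from five deterministic starts spanning the data
  range (both slope signs for the logistic) and keep the lowest-RSS
  converged solution; a family that converges from no start is dropped
  from the comparison with a flag.
* The peak temperature is the vertex −b2/(2·b3), defined only for b3 < 0.
  Pipeline reports flag vertices outside the observed bin range
  (`in_range = false`): there the fitted response was effectively monotone
  and the vertex is an extrapolation, which happens occasionally for
  southern regions where the warm flank of the arrival pulse is truncated
  by the window start.

## The synthetic generator

The generator reproduces the statistical structure the analysis assumes,
with exact ground truth for recovery testing.

* **SST**: a logistic-in-time cooling ramp from 24 °C to 12 °C over the
  92-day window (time scale 10 days — autumn coastal cooling is
  sigmoid-like, fast mid-season and flat at both ends), time-shifted so
  the *mean curve* crosses 20 °C half a day before the intended integer
  crossing day; the first noise-free sub-threshold day is then exactly
  that integer, making truth analytic. Daily i.i.d. N(0, 0.3 °C) noise is
  added. Climatological crossing days (CR1→CR6: 25, 28, 31, 33, 36, 40)
  put the north ~8 days ahead of the south. Regime shifts: T1 moves every
  region 10 days early, T3 10 days late, T2 moves the north 10 days early
  and delays the south by 8 days.
* **Coastal catch**: a Gaussian day-pulse (sd 4 days) of expected total
  1000 fish, sampled as independent Poisson counts. The pulse center sits
  a fixed lag after the *climatological* crossing day — not the year's
  realized crossing — advanced by 4 days in T2 years. This decoupling is
  deliberate: observed arrival timing in this system is insensitive to
  whether the whole area cooled early or late (T1 ≈ T3) but advances ~4
  days in split-cooling years, so the regime shifts move the *thermal*
  environment of a fixed-schedule arrival rather than the arrival itself.
  The per-area lags are chosen analytically so the mean ramp reads
  ~18.5 °C (north) / ~20.5 °C (south) at the pulse center, matching the
  observed thermal preference of coastal arrival in each area (southern
  fish arrive while the surface is still above the 20 °C cue).
* **Riverine catch** is the realized coastal count vector shifted by a
  per-region residence time (CR1→CR6: 25, 15, 12, 10, 8, 7 days — longest
  in the far north) and binomially thinned (return rate 0.8), so no fish
  is created in the river.
* **Interannual noise**: integer jitters on the arrival center (sd 3.5
  days) and the residence shift (sd 2 days). These magnitudes are
  back-derived from the published model-comparison table for this system
  (its log-likelihoods imply residual sds of ≈ 3.5 days for coastal MDMT
  and ≈ 2 days for the riverine response), so simulated records carry
  realistic year-to-year variance.
* **Reproducibility**: every region-year draws from its own RNG substream
  keyed by (seed, region index, year, stream), so a fixed seed fixes the
  dataset bit-for-bit and adding regions or years never perturbs existing
  series.
* **Presets**: `mixed-13yr` (the 3 T1 / 5 T2 / 5 T3 composition of a
  13-year study period, 2006–2018 order), single-regime `T1-like` /
  `T2-like` / `T3-like`, and `thermal-response` (shift-free, for
  peak-recovery experiments). `Scenario.without_noise()` disables every
  stochastic component for exact-identity tests.

**What the generator does not emulate** — and what passing tests therefore
do not show about real data: tidal and river-discharge cues, vertical
temperature structure and fish depth choice, spatially varying fishing
effort, autocorrelated SST noise or marine heatwaves, regime-dependent
residence times (only the T2 arrival advance is injected), straying, and
non-Gaussian run shapes (double pulses). Catch-count noise is Poisson by
assumption; nothing in the source system characterizes it.

## Experiment sizes

The recovery experiments (shared by `tests/test_acceptance.py` and
`scripts/acceptance.py`) use: 78 region-year records per simulated study
(6 regions × 13 years); 16 replicate studies (208 year-labels) for
classification robustness; 500 replicate studies (tests) or 200 (script)
for the T2-effect recovery; 100 (tests) or 60 (script) replicates per
generating structure for structure recovery; and 50 replicates × one
northern + one southern region (100 fits) for thermal-peak recovery.
These sizes give Monte-Carlo standard errors an order of magnitude below
the quantities' tolerances.

## Known limitations

* The regime classifier needs a mixed-regime dataset: with a single-regime
  history the leave-in baseline absorbs the common shift and anomalies
  collapse to zero (the T1/T3 distinction is then meaningless).
* Marginal-ML AIC's bias against random effects (above) makes structure-2
  vs structure-3 selection sensitive to the region-spread-to-residual
  ratio at only six regions.
* The quadratic vertex is a biased peak estimator when the pulse support
  is asymmetric in temperature (truncation at the warm end pulls southern
  peaks ~0.4 °C cold at the defaults); recovery is still well within
  0.5 °C.
* `validate_inputs` checks per-file schema, window coverage and signs; it
  does not cross-validate that catch and SST cover identical region-year
  sets (the pipeline raises at the alignment stage instead).
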