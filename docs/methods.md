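# Methods

## Scope and model

The package quantifies the effect of atmospheric vapor pressure deficit
(VPD) on vegetation growth in northern peatlands, and the mechanisms behind
it, through five linked analyses: closed-form ecophysiological quantities,
per-pixel detrended partial-correlation (PCOR) maps, warming-experiment
statistics, random-forest perturbation sensitivity, and serial two-mediator
mediation.  All analyses are exercised on synthetic data whose generating
parameters are known, so correctness claims are statements about recovery of
planted structure, not about any external dataset.

## Ecophysiological formulas

* **Saturation vapor pressure.** Magnus form
  `SVP(Ta) = 6.11·exp(17.27·Ta/(Ta+273.3))` hPa.  VPD is `SVP·(1−RH/100)`
  (tower route) or `SVP−AVP` (gridded route); the two are algebraically
  identical and tested to machine precision on a 10⁴-point grid.  Negative
  VPD from the AVP route (supersaturation, present in gridded products) is
  retained and logged, never zeroed, because silent clipping biases means.
* **Canopy conductance.** Gc inverts the Penman–Monteith equation from
  latent (LE) and sensible (H) heat fluxes.  The thermodynamic inputs the
  inversion needs but that have no single conventional source are fixed as:
  Δ = analytic derivative of the Magnus SVP curve (Pa K⁻¹);
  γ = Cp·P/(0.622·λv) with Cp = 1013 J kg⁻¹ K⁻¹ and λv = 2.44 MJ kg⁻¹
  (consistent with the LE→ET conversion); ρ from the dry-air ideal-gas law
  at (Ta, P).  All are overridable through `PhysConstants`.
* **Aerodynamic resistance.** `ra = ws·k²/ln(exp(k·ws/u*)−0.7)²` with the
  natural logarithm (the standard choice in Monin–Obukhov-derived
  resistances) and k = 0.4.  For typical tower inputs this formula yields
  resistances orders of magnitude below textbook aerodynamic resistances;
  it is the package's convention applied verbatim, and the round-trip tests
  use the exactly matching forward model, so the discrepancy does not affect
  any conclusion drawn here.  Inputs that drive the squared log term toward
  zero are treated as degenerate (error for scalars, masked for arrays).
* **LE→ET.** The conversion divides LE by the latent heat of vaporization.
  The conventional printed factor "2.44" is dimensionally a MJ kg⁻¹
  quantity; the default is therefore 2.44×10⁶ J kg⁻¹, with
  `coefficient=2.44` available for the literal J kg⁻¹ reading.
* **Non-physical inversions.** Gc with a non-positive bracketed term is
  masked to NaN and counted in the log.  Inversion of noisy fluxes produces
  such values routinely; masking (rather than clipping) keeps regional
  statistics unbiased.
* **Units.** VPD is hPa everywhere internally.  uWUE is the single
  kPa-facing quantity; its VPD argument must be converted explicitly
  (`hpa_to_kpa`), which keeps the leading unit-mixing failure mode loud.
* **Growing season.** Months whose (climatological) mean Ta exceeds 0 °C,
  strict inequality.

## Partial-correlation mapping

The temporal unit is the **annual growing-season mean** per pixel, so the
per-pixel sample size equals the year span (37 for the default 1982–2018
emulation); trend analyses are then per-year quantities and the t-test
degrees of freedom match year counts.  Monthly cubes can be aggregated with
`annual_growing_season_mean` or passed directly for a monthly-anomaly
variant.

Per pixel, every series (GPP, VPD, Ta, radiation, wind, precipitation) is
detrended by OLS on time; the PCOR of GPP with VPD given the four covariates
is the Pearson correlation of the residuals of the two covariate
regressions, with p from a two-sided t on df = n − 2 − g.  Choices that the
problem leaves open, fixed here:

* **No multiple-testing correction** across pixels: maps report raw
  p < 0.05 classes, the convention for this kind of spatial summary.
* **Pixel validity:** ≥ 80 % of time steps jointly valid across all cubes
  (configurable), else the pixel is masked.
* **Extent bins** at 10, 20, …, 70 % (left-closed) with a final closed
  bin [70, 100] and the ≥10 % union; empty bins yield zero-pixel
  placeholders.  Ties at r = 0 count as positive in the four-way
  percentage partition (measure-zero, deterministic).
* **Regional means** are unweighted by default; cos-latitude weighting is a
  flag (`cos_lat_weights`), since area weighting is a presentation choice.
* Latitude axes are normalized ascending on input.

## Warming-experiment analysis

Paired t tests on warming−control differences, with Shapiro–Wilk normality
diagnostics; when Shapiro–Wilk p ≤ 0.05 a Wilcoxon signed-rank p is attached
as the nonparametric fallback (the 0.05 trigger is itself a convention).
Zero-variance differences are reported as degenerate rather than producing
a meaningless t.

The Ta–VPD coupling VPD = a·exp(b·Ta) is fitted by OLS on ln VPD —
deterministic and closed-form; a nonlinear refinement would change the
weighting of large-VPD points but not the sign or approximate magnitude of
b, and is not the default.  Per-site ΔVPD is a·exp(b·Ta_warm) −
a·exp(b·Ta_control).  The synthesis table carries one (Ta, VPD) pair per
site per treatment, which identifies only a **pooled** fit across sites;
pooled is therefore the default, and per-site fits apply when per-site
series are supplied (`fit_table`).  The growth response is the log response
ratio ln(warming/control) by default (ratio and difference modes exist).
The headline statistic is the OLS slope of response on ΔVPD; a 95 % CI
covering zero is the neutral-effect outcome.

## Random-forest sensitivity

500 trees by default (scikit-learn defaults otherwise), seeded 60/40
train/validation split, predictors z-score normalized, response left raw.
Sensitivities are only reported when the held-out Pearson r exceeds 0.8
(override with `force=True`).  The sensitivity of the response to predictor
j perturbs the normalized column by +1 (one SD), re-predicts with the fixed
fitted forest, and divides the mean prediction change by the raw response
SD.  What varies across the 15 repeats is unspecified by convention; here
it is bootstrap resampling of the prediction rows with the model held
fixed (re-fitting per repeat is available behind a flag-free alternative:
fit with different seeds).  The perturbation is +1 SD only by default; a
symmetric ±1 SD average is available.  Rows with any missing value are
dropped listwise with a logged count.  The statistic is scale-free in the
response (verified by a rescaling test to an absolute tolerance of 0.02 —
rescaling perturbs floating-point split selection slightly, so exact
equality is not expected).

Tree ensembles attenuate sensitivities relative to the generative linear
slope (they cannot extrapolate beyond the training range), so recovery
tests assert sign fidelity and calibrated magnitude bands rather than exact
slopes.

## Serial mediation

X → M1 → M2 → Y with M1 = uWUE and M2 = the Et-vs-VPD coupling, as the
causal ordering drawn by the mechanism (soil/water conditions set the
water-use strategy, which sets the transpiration response); the ordering is
configurable.  All variables are z-standardized, three OLS regressions give
the paths, indirect effects are path products, and
c_total = c′ + a1·b1 + a2·b2 + a1·d21·b2 holds exactly on any sample (an
OLS identity, asserted to 1e−10).  Uncertainty: seeded percentile bootstrap
over rows, default 5,000 resamples (tests and the pipeline use 250–2,000 to
stay fast); an effect is significant when its CI excludes zero.  Pixel rows
are treated as exchangeable (no spatial blocking), matching the convention
for these grid-scale mediation analyses.

## Synthetic generators

Every generator requires a seed, is bit-reproducible, and emits a truth
sidecar; recovery tests read truth only from the sidecar.

* **Gridded cubes** (`gen_gridded`): Ta = pixel baseline + linear trend
  (default 0.028 °C yr⁻¹, the observed high-latitude warming rate) +
  Gaussian interannual noise (0.6 °C); VPD = a·exp(b·Ta) with a = 2 hPa,
  b = 0.06 °C⁻¹ and 8 % lognormal noise, resampled below saturation so the
  derived RH always lies in (0, 100); covariate anomalies share a 0.3
  cross-correlation.  The GPP anomaly is built from the *sample* residual
  of detrended VPD on the detrended covariates plus independent noise
  passed through the same detrend-and-residualize filter, so the planted
  conditional correlation ρ is the expectation of the recovered coefficient
  and the ρ = 0 case is exactly null-distributed (empirical rejection
  5.8 % at α = 0.05 over 2,500 pixels).  ρ can be constant, per-pixel, or
  a function of the peatland-extent field.
* **Flux tower** (`gen_flux_tower`): LE from the forward Penman–Monteith
  model at a known Gc; GPP = uWUE_true·ET/√VPD so uWUE recovery is exact;
  optional multiplicative lognormal flux noise (5 % noise keeps the median
  Gc inversion error near 3.5 %).
* **Warming sites** (`gen_warming_sites`): 67 sites by default, warming
  increments 2.7 ± 0.6 °C (the synthesis-scale warming), growth log-ratio =
  slope·ΔVPD + noise with a default noise SD of 0.55, which sizes the
  67-site regression standard error near 0.27 — the scale on which the
  neutral-effect claim operates.  slope = 0 is the neutral scenario.
* **Trait/mediation tables** (`gen_rf_table`, `gen_mediation_data`,
  `gen_trait_table`): additive or serial-path structure on the z scale with
  realistic raw units; the mediation generator scales residual variances so
  all variables have unit variance, making planted structural paths equal
  to the standardized paths the analysis estimates.

What the generators deliberately do **not** emulate: spatial
autocorrelation, seasonality within the growing season, heteroscedastic or
autocorrelated interannual noise, non-Gaussian tails, and observational
error structure of specific satellite products.  Passing tests therefore
demonstrate the statistical machinery is correct and calibrated under the
stated data-generating assumptions — not that any particular real-world
dataset satisfies those assumptions.

## Problem sizes and numerics

Default verification sizes: 2,500 pixels × 37 years for null calibration,
200 pixels for planted-ρ recovery, 1,000 draws for the conductance round
trip (relative error < 1e−12 noiseless), 50 seeded replicates at 1,500 rows
and 150 trees for the sensitivity sign check, 200 replicates at n = 200 and
500 bootstrap resamples for mediation CI coverage.  Collinear designs raise
rather than regularize; residuals that vanish to numerical precision
(relative 1e−10) leave a correlation undefined (NaN) rather than returning
noise.  NetCDF I/O uses the NetCDF3-classic (scipy) backend.

## Known limitations

* The aerodynamic-resistance convention above is applied verbatim; users
  comparing Gc magnitudes against other inversions should expect offsets.
* No energy-balance closure correction or flux gap-filling.
* No spatial-autocorrelation correction in map significance; percentages of
  significant pixels are descriptive, not family-wise inferential.
* The random-forest sensitivity inherits ensemble attenuation; comparisons
  across predictors (signs, ranking) are more robust than absolute values.
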