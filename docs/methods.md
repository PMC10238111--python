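# Methods

## Estimation chain

The package estimates rice aboveground biomass (AGB, g/m² dry weight)
from two UAV-derived plot-level time series: band reflectance at
550/670/720/800 nm (from a 12-band multispectral camera, empirical-line
calibrated) and canopy height (from DSM differencing). The chain is

1. DN → reflectance per band: `R = gain·DN + offset`, OLS-fitted on
   ground panels (standard ladder 0.03…0.80). The model is fitted in the
   applied direction; fitting DN on R and inverting would minimise a
   different residual and give a different line.
2. Canopy height `H = DSM − DSM_soil`, the soil surface acquired before
   transplanting. Negative differences (photogrammetric noise over
   water/soil) are clamped to 0 m and counted; downstream models require
   h ≥ 0.
3. Plot aggregation by cell-center-in-polygon zonal means. VIs are
   computed **from the ROI-mean reflectances** (plot level), not averaged
   per-pixel VIs; the two differ on heterogeneous plots, and plot-level
   spectra are what the calibration models consume.
4. Vegetation indices per the registry in `vegindex`. OSAVI is
   implemented with the 720 nm red-edge band —
   `(1+0.16)(R800−R720)/(R800+R720+0.16)` — not the canonical 670 nm red
   band. This is the formulation this chain was built and validated
   with; it is kept deliberately and documented here because silently
   "fixing" it would change every downstream calibration.
5. LAI model, PAM/SPAM accumulation, OLS calibration against destructive
   AGB, evaluation.

Time is measured in integer days after transplanting (DAT; transplanting
= day 0). Flight and destructive-sampling calendars are typically offset
by 0–2 days; tables are joined on nearest DAT within a configurable
tolerance (default ±2 days).

## The LAI model

Vertical leaf-area density is modelled as the quadratic
`LAD(z) = a1·z² + a2·z` through LAD(0) = 0 and LAD(H) = 0 with its peak
LADmax at z = H/2, giving `a1 = −4·LADmax/H²`, `a2 = 4·LADmax/H` and the
closed form `LAI = ⅔·LADmax·H`. The boundary condition LAD(H) = 0 is our
reading of the measured bell shape (dense mid-canopy, sparse at both
ends). Since a VI tracks vegetation cover and cover tracks LADmax, the
estimator is the OLS line `LAI = b1·(VI·H) + b0`. The intercept is
retained — the proportionality need not pass exactly through the origin
for destructive measurements — and predictions are floored at 0.

## PAM and SPAM

PAM accumulates `VI1·VI2·h` over flight dates with the right-endpoint
rectangle rule (the form the model is written in); a trapezoid option is
provided, with an implicit zero integrand at transplanting since
seedlings have essentially no canopy. The two rules converge to the same
limit under dense sampling (tested). The default is the same VI in both
slots (NAR proxy and LAI component): any of NDVI, EVI2, WDRVI, NDRE,
OSAVI, GNDVI used twice performs on par with mixed pairs.

SPAM replaces the full sum with triangle/trapezoid areas anchored at the
heading stage T1, and is restricted to the six indices above — the
simplification is only valid where h·VI² actually rises to a single peak
near heading. If no flight lands exactly on T1 the nearest flight within
a window (default ±5 days) supplies the heading observation; beyond the
window it is an error, not a silent extrapolation.

Calibration is simple OLS with intercept of measured W on the index
(via `scipy.stats.linregress`); predictions are floored at 0 g/m² with a
logged count, since raw linear models can go negative early in the
season. Calibration can be done per season or pooled across seasons
before transfer to a new year; both are just choices of which rows enter
`fit`, and the package exposes no special harmonisation for
between-season slope differences (none is defined).

## Evaluation statistics

R² defaults to the regression-sum-of-squares form Σ(ŷ−ȳ)²/Σ(y−ȳ)² with ȳ
the mean of the measured values (the only reading under which the
in-sample tables are self-consistent for OLS fits). For OLS-with-
intercept fitted values this equals the conventional 1 − SSE/SST
exactly (asserted to 1e−12 in tests); for out-of-sample transfer the
eq9 form can exceed 1 and mislead, so the conventional form is exposed
and recommended there. RMSE is √(Σ(y−ŷ)²/n); rRMSE = 100·RMSE/ȳ %.

## The synthetic benchmark

No field data ship with the package, so the simulator generates seasons
with the structure the models assume, and every end-to-end claim in the
test suite is a claim about these conditions:

* **Height**: logistic `h(t) = h_max·σ(k_h(t−t_mid))`, anchored by
  subtracting its t = 0 value and floored at 0. Defaults
  h_max ∈ [0.8, 1.2] m, k_h ∈ [0.12, 0.18]/day, t_mid ∈ [40, 50] DAT.
* **Cover**: logistic fraction f(t) with rate cover_rate ∈ [0.12, 0.18]
  and midpoint cover_mid ∈ [25, 35]. (A logistic needs a midpoint as
  well as a rate; `cover_mid` is a simulator parameter in its own
  right, set so canopies close around jointing.)
* **Panicles**: fraction p(t) = min(panicle_rate·(t−T1)₊, 0.5) after
  heading T1 ∈ [55, 70]; panicle_rate ∈ [0.015, 0.03]/day.
* **Reflectance**: three-endmember linear mixing,
  `(1−f)·soil + f·((1−p)·leaf + p·panicle)`. The panicle endmember is
  redder than leaf (0.20 vs 0.04 at 670 nm), which *mechanically*
  produces the post-heading VI decline instead of hand-drawing VI
  curves.
* **Truth**: `lai = ⅔·lad_peak·f·h` (lad_peak ∈ [3.5, 5.5] 1/m);
  `agb(t) = c_conv · Σ_τ≤t NDVI(τ)²·h(τ)·1 day` with conversion
  efficiency c_conv ∈ [3, 6] g/m² per VI²·m·day. NDVI drives the truth
  integrand; it is also the default index in both PAM slots, so on
  noiseless daily sampling the fitted slope recovers c_conv exactly — a
  deliberate closure property used as the parameter-recovery oracle.
  With this c_conv range end-of-season AGB is of order 10² g/m², a
  nominal scale; the R²-based comparisons are scale-free.
* **Observations**: the daily truth sampled on a 13-date flight calendar
  (DAT 17…86 over a 90-day season) with multiplicative mean-one
  lognormal noise, CV 0.05 for reflectance, height and the destructive
  LAI/AGB samples (destructive noise independent across plot-dates —
  distinct plants are cut each time). All randomness flows from an
  explicit seed; identical seeds give bit-identical seasons.

The default benchmark draws 48 cultivars (one plot each) uniformly from
the ranges above — 48 × 13 = 624 samples, the scale of a dense
single-season campaign.

**What the simulator does not emulate:** radiative transfer (no PROSAIL-
style leaf optics), weather/temperature forcing, nitrogen treatments,
lodging, between-plot spatial correlation, registration or
reconstruction artefacts in the rasters, and structural mismatch between
the truth process and the fitted model family (the AGB truth *is* an
accumulation process). Passing benchmarks therefore demonstrate internal
consistency and statistical behaviour of the chain under realistic noise
and phenology spread — not field-data performance.

## Benchmark results and problem sizes

The standard comparison (`ricepam.benchmark`) calibrates PAM, SPAM,
single-date-VI and height models on each of ten benchmark realizations
(seeds 1–10) and evaluates eq9 R² on fitted values. Median R² is ≈ 0.93
for PAM and ≈ 0.88 for SPAM with NDVI, and on every seed the ordering
PAM > height model > VI model holds, as does VI·H > VI-only for LAI.
Parameter recovery of c_conv is exact (< 1e−10 relative) noiseless and
biased < 5% in median at 5% noise. These sizes (48 plots, 10 seeds,
90-day seasons) run in seconds and are the package's reference
configuration.

## Numerical choices

* OLS lines via `scipy.stats.linregress`; degenerate designs (constant
  regressor, < 3 points) raise rather than return NaN.
* VI denominators exactly zero raise `DegenerateReflectanceError`
  (never ±inf). Band lookup is exact on nm keys — no nearest-band
  substitution. Reflectance > 1 warns (calibration overshoot is real);
  NaN or negative reflectance is an error.
* Calibrated reflectance is clipped to [0, 1.5] (not [0, 1]) with a
  logged count, keeping moderate overshoot visible.
* Rasters are row-major, origin top-left, square-cell north-up grids
  with explicit nodata; alignment checks require identical shape,
  origin, cellsize and CRS string. Zonal statistics use the
  deterministic cell-center rule; fractional-area weighting is out of
  scope.
* Logistics use `scipy.special.expit` to avoid overflow at extreme
  arguments (degenerate no-vegetation configurations exercise this).

## Known limitations

* SPAM inherits a per-plot heading date; with uncertain phenology the
  ±5-day window is the only guard against picking a mis-timed flight.
* MTCI's denominator (R720 − R670) can approach zero on early-season
  soil-dominated spectra; such samples raise rather than produce wild
  values, and MTCI is outside the SPAM whitelist.
* The eq9 R² is an in-sample statistic; all headline medians here are
  calibration (not cross-validated) accuracies, matching how the
  models are normally reported.
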