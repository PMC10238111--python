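# ricepam

Estimation of rice aboveground biomass (AGB, g/m²) over the whole growing
season from UAV observations: multispectral reflectance converted to
vegetation indices (VIs) and photogrammetric canopy height, combined
through **photosynthetic accumulation models**.

Single-date predictors fail over a full rice season — VIs saturate at
canopy closure and drop after panicle emergence, and height growth is
strongly nonlinear — so this package estimates biomass from the *time
accumulation* of the photosynthetic proxy instead.

## Who it is for

Crop phenotyping and precision-agriculture groups flying multispectral +
RGB drones over rice trials: per-plot reflectance and height time series
in, calibrated full-season biomass estimates out. Everything is plain
CSV / JSON / ESRI-ASCII / GeoJSON, usable as a Python library
(scikit-learn-style estimators) or a CLI.

## The models

**LAI from height and a VI.** The vertical leaf-area density of a rice
canopy is bell shaped; modelling it as the quadratic through LAD(0) = 0
and LAD(H) = 0 with peak LADmax at half height gives
LAI = ∫₀ᴴ LAD(z) dz = ⅔·LADmax·H. Since a VI tracks vegetation cover and
hence LADmax, LAI ∝ VI·H, fitted as an OLS line.

**PAM.** Dry matter accumulates as (assimilation rate per leaf area) ×
(leaf area) integrated over time. With a VI standing in for both factors'
observable parts:

    PAM(t) = Σᵢ VI1ᵢ · VI2ᵢ · hᵢ · (tᵢ − tᵢ₋₁),   t₀ = transplanting

summed over flight dates (right-rectangle rule; trapezoid optional), then
W = slope·PAM + intercept by OLS against destructive AGB samples. Using
one of NDVI, EVI2, WDRVI, NDRE, OSAVI or GNDVI in *both* slots works as
well as mixing two.

**SPAM.** Because h·VI² rises to a peak near the heading stage T1 and
declines slowly after, the full integral is well approximated from just
two flights — the target date and one near heading:

    t ≤ T1:  VI_t²·h_t·(t−t₀)/2                      (triangle)
    t > T1:  VI_T1²·h_T1·(T1−t₀)/2
             + (VI_t²·h_t + VI_T1²·h_T1)·(t−T1)/2    (+ trapezoid)

**Supporting stages.** Nine VI formulas (note: OSAVI here is the
red-edge/720 nm variant, as used throughout this chain); empirical-line
DN→reflectance calibration fitted on ground panels; canopy height as
DSM − DSM_soil; plot means by cell-center-in-polygon zonal statistics;
evaluation by R² (regression-SS form by default, conventional form for
out-of-sample transfer), RMSE and rRMSE.

No field campaign is bundled; `ricepam.synthetic` simulates
multi-cultivar seasons (logistic height growth, canopy-closure/panicle
spectral mixing driving the rise-then-fall VI shape, accumulation-derived
AGB truth, lognormal observation noise) so the whole chain is testable
end to end.

## Worked example

```sh
ricepam simulate --n-plots 4 --seed 3 --out-dir sim
ricepam pam  --obs sim/observations.csv --out pam.csv  --fit-out pamfit.json
ricepam spam --obs sim/observations.csv --vi NDVI \
             --heading-csv sim/params.csv --out spam.csv --fit-out spamfit.json
```

`pamfit.json` from that exact run:

```json
{
  "form": "eq9",
  "index_kind": "PAM",
  "intercept": -1.5830798993484123,
  "n": 52,
  "r2": 0.9508149764351602,
  "rmse": 6.362641303849339,
  "rrmse": 18.805024907752195,
  "slope": 3.8949463008872334
}
```

Reading: across the 52 plot-dates (4 plots × 13 flights) the PAM index
explains 95% of the variance in measured AGB; the slope ≈ 3.9 g/m² per
VI²·m·day is the calibrated conversion efficiency. The SPAM fit on the
same data gives r2 ≈ 0.855 — slightly below PAM, the price of needing
only two flights per estimate. The same workflow in Python:

```python
from ricepam import PAMConfig, fit_agb_model, generate_benchmark
from ricepam.pipeline import pam_table, join_measurements

bench = generate_benchmark(n_plots=48, seed=1)
table = join_measurements(pam_table(bench.observations, PAMConfig()), 
                          bench.observations, "agb")
model = fit_agb_model(table[["pam_index", "agb"]].to_numpy())
print(model.slope_, model.r2_, model.rmse_)
```

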