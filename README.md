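# somfuse

Wavelet fusion of multi-temporal satellite imagery, NDVI phenology
features, and machine-learning regression for digital soil mapping of
soil organic matter (SOM, g/kg).

## The problem

Predicting topsoil SOM over cropland from remote sensing is hard with a
single acquisition date: apparent reflectance is confounded by transient
soil moisture, residue and atmospheric state. Two remedies are combined
here:

1. **Multi-temporal image fusion.** Bare-soil images from several years
   are fused per spectral band with a local-energy-weighted discrete
   wavelet transform (LEW-DWT). Each normalized band is decomposed with a
   2-level orthonormal Haar DWT. The deepest approximation (LL) plane is
   merged as an energy-weighted mean,

   E_i = Σ x²,  W_i = E_i / Σ_j E_j,  C_fused = Σ_i W_i · C_i,

   while every detail plane (HL/LH/HH) is assembled per position by
   picking the coefficient of the source with the largest local energy in
   a 3×3 window (ties go to the baseline sampling-year image). This
   averages away date-specific disturbances in the low-frequency content
   while keeping the sharpest field boundaries and textures. Baselines:
   traditional mean-rule DWT fusion and simple band splicing. Fusion
   quality is scored by spectral angle (SAM), information entropy (IE)
   and average gradient (AG).

2. **Phenology features.** Per-pixel 16-day NDVI series (23 composites a
   year) are smoothed with a Savitzky–Golay filter and summarized into
   N_Min, N_Max, N_Std, growing-season length (threshold rule),
   and the annual harmonic's amplitude and phase
   (`A·cos(2πt/23 − φ) → (A, φ)`), plus the raw-series mean/SD.

SOM is regressed on environmental covariates (**Ev**), optionally
augmented with the time-series NDVI features (**Tn**) and the fused
multi-temporal bands (**Mm**), by a random forest (250 trees, depth 6)
and a shallow CNN on 7×7 patches (conv 3×3×32 → pool → conv 2×2×48/24/12
→ dense 80/15/1, Adam, MSE, dropout), both under seeded 10-fold
cross-validation with fold-wise standardization. Accuracy is reported as
MAE, RMSE and R² on pooled out-of-fold predictions, with the derived
statistics soil surveys quote (relative changes, RMSE/MAE ratio,
relative RMSE, CV).

A seeded synthetic-scene generator supplies ground truth for every
stage: an autocorrelated SOM field (mean 20.12, SD 2.42 g/kg),
reflectance negatively loaded on SOM (strongest in SWIR/NIR) with
per-date transients, a double-peak (wheat–maize) NDVI cycle, covariates
with exactly realized correlations, and point samples.

## Worked example

`examples/` holds one short script per capability. For instance
`python examples/03_som_benchmark.py` (a 64×64 scene, 150 samples,
measurement noise at 25% of the field SD) prints:

```
out-of-fold accuracy (5-fold CV pooled, g/kg):
  rf/Ev          MAE 0.809  RMSE 1.044  R2 0.838
  rf/Ev-Tn-Mm    MAE 0.720  RMSE 0.901  R2 0.880

Ev -> Ev-Tn-Mm derived statistics (%):
  r2_relative_change_pct       4.9
  mae_reduction_pct            10.9
  rmse_reduction_pct           13.7
  ...
```

The composite Ev-Tn-Mm feature set beats the environmental covariates
alone (R² 0.88 vs 0.84 here), and the derived statistics quantify the
gain the way survey reports do. `examples/01_fuse_and_score.py` scores
LEW-DWT against mean-rule DWT fusion (the local-energy rule preserves a
~4× higher average gradient on the default scene), and
`examples/02_ndvi_phenology.py` walks through the phenology features of
one pixel.

A thin CLI mirrors the library: `somfuse synth|fuse|quality|run|compare-fusions`
(see `somfuse --help`).

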