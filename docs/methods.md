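# Methods

## Rasters and grids

A `RasterGrid` is one 2-D band with affine geometry (pixel-is-area,
upper-left origin, north-up, row-major) plus a nodata mask; masked cells
are excluded from every statistic. Point→pixel mapping uses half-open
pixel intervals, and sample points are read at the pixel containing
them (center-of-pixel extraction). GeoTIFF I/O is carried by `tifffile`
with the four tags needed for georeferencing (ModelPixelScale,
ModelTiepoint, a GeoKeyDirectory holding one EPSG code, GDAL_NODATA);
reprojection between CRSs is out of scope — inputs must share a CRS.
All internal arithmetic is float64; files are written float32.

Resampling onto the analysis grid uses Cubic Convolution (the Keys
kernel, a = −0.5, edge-replicated) for continuous variables and nearest
neighbor for categorical ones, so categorical outputs never invent
labels. The Keys kernel reproduces node values and linear ramps exactly,
which the tests exploit as a closed-form oracle. Cubic *spline*
interpolation (what scipy/scikit-image offer) is a different
interpolant, which is why the convolution kernel is implemented here.

## LEW-DWT fusion

Inputs are co-registered single-band images of the same scene at N
acquisition dates. Steps:

1. **Normalize** each image to [0, 1] by min–max over unmasked cells
   (a constant image maps to zeros). Normalization is per image; this
   also absorbs most of any per-date illumination offset.
2. **Energy weights.** E_i = Σ x² over the normalized image,
   W_i = E_i / Σ_j E_j. Weights are computed once per source image (not
   per level). If every input is constant (all energies zero) the
   weights fall back to equal — there is no information to weight.
3. **Decompose** each image with a 2-level orthonormal Haar DWT
   (configurable wavelet and 1–4 levels). Images are symmetrically
   padded to a multiple of 2^levels; the original shape is recorded so
   reconstruction is exact (≤1e-8) and output shape equals input shape.
4. **Merge.** The deepest LL plane is the W-weighted mean of the
   sources. Every detail plane is assembled per position by taking the
   coefficient of the source with the largest local energy (sum of
   squared coefficients in a centered 3×3 window, reflective padding;
   on coefficient planes smaller than the window the window is clamped
   to the largest odd size that fits). Ties go to the baseline-date
   source, then the lowest date index. Both rules are configurable
   (`rule_low`, `rule_high` ∈ {energy_weighted, local_energy_max, mean}).
5. **Reconstruct** by the inverse DWT and crop the padding.

The fused band is left in normalized [0, 1] space: the regression models
standardize their inputs per training fold anyway, so rescaling to
physical reflectance would be a no-op downstream. The rationale for the
split rule: the approximation should keep the *most informative overall*
spectral background (a weighted mean suppresses date-specific
transients by ~1/N in variance), while detail planes should keep the
*locally strongest* edges and textures, which a mean would blur.

Baselines: `traditional_dwt` (plain mean of every coefficient plane)
and `simple_splicing` (no fusion; the normalized per-date bands are
stacked as separate features). Multi-band stacks are fused per spectral
band across dates, so 7 bands stay 7 bands regardless of the number of
dates.

### Quality metrics

The standard fusion-literature definitions: SAM = mean per-pixel angle
arccos(⟨f, r⟩/(‖f‖‖r‖)) in radians against the baseline-date image
(zero-norm spectra excluded); IE = Shannon entropy of the 256-level
min–max-quantized histogram (bits), which makes it invariant to affine
rescaling; AG = mean of √((Δx² + Δy²)/2) with forward differences over
the interior. IE and AG are reported per band and as the band mean; SAM
is inherently multi-band.

## NDVI phenology features

NDVI = (NIR − RED)/(NIR + RED), clipped to [−1, 1], masked where the
denominator is zero. Per-pixel series at 23 composites/year are smoothed
with a Savitzky–Golay filter — defaults window 7, order 3, a common
choice for 16-day composites; ends are handled by evaluating the edge
window's polynomial, so polynomials of degree ≤ order pass unchanged.
Multi-year series are smoothed as one concatenated series.

Features of the smoothed series: min, max, population SD;
growing-season length = per-year count of composites at or above a
threshold (default dynamic: min + 20% of amplitude, a standard
phenology rule; configurable to a fixed NDVI value; a zero-amplitude
series is defined to have a full-year season), averaged over whole
years and reported in composite periods (×16 for days); and the annual
harmonic, read from the DFT bin at the annual frequency of the
whole-years-trimmed series: amplitude 2|X_Y|/N and phase
atan2(−Im X_Y, Re X_Y), fixed by the contract that A·cos(2πt/23 − φ)
returns exactly (A, φ), with phase in (−π, π]. The raw (unsmoothed)
series contributes its long-term mean and SD as two further covariates.

## Feature engineering

Multi-date products always include the baseline (sampling-year) date:
with 7 dates there are C(6, m−1) subsets of size m, 64 in total,
enumerated in deterministic lexicographic order.

Recursive feature elimination uses a random-forest ranker (the RF's own
best hyperparameters; one feature eliminated per iteration, continuing
to a full ranking). It is repeated (default 10×) with distinct
sub-seeds; features are ranked by how often they survive into the kept
set, ties broken by mean elimination order. Selection is applied to the
environmental covariates, with the NDVI and fused-band features
appended afterwards (both orders are possible by applying
`rfe_select` to whichever table is assembled). Categorical covariates
are one-hot encoded. Standardization is z-scoring with statistics from
the training folds only; zero-variance features are left centered and
flagged.

CNN inputs are 7×7 windows centered on the sample's pixel, reflection-
padded at scene edges, channel-ordered like the feature table; the
window center equals the point-extracted value exactly.

## Models and evaluation

**Random forest:** scikit-learn, defaults n_estimators = 250,
max_depth = 6; an optional inner grid search scans
{100,150,200,250,300,350} × {3..8}. Variable importance is the
impurity-based importance normalized to percentages; category shares
are sums over member features, so both levels sum to 100 exactly.

**CNN:** a compact numpy implementation (im2col-free direct
convolutions, inverted dropout, Adam, MSE). Architecture:
conv 3×3×32 ReLU → maxpool 2×2 → conv 2×2×48 ReLU → dropout 0.2 →
conv 2×2×24 ReLU → conv 2×2×12 ReLU → dropout 0.2 → flatten →
dense 80 ReLU → dropout 0.1 → dense 15 ReLU → dense 1 linear.
Convolutions use valid padding; the max-pool uses stride 1, so the
spatial extent shrinks 7→5→4→3→2→1 through the conv stack — with a
stride-2 pool the third 2×2 convolution would underflow a 1×1 map, so
the overlapping pool is the design choice that realizes this layer
order on 7×7 inputs. Training defaults: Adam lr 1e-3, batch 16, up to
300 epochs with early stopping (patience 30) on a 10% split of the
training fold; the target is z-scored internally and predictions return
in g/kg. Weight init, shuffling and dropout all flow from one seed;
dropout is inactive at inference, so prediction is deterministic. The
backward pass is validated by a numerical gradient check in the tests.

**Evaluation:** seeded 10-fold CV; standardization refit per training
fold; pooled MAE/RMSE/R² on the concatenated out-of-fold predictions
plus per-fold metrics. R² uses SS_tot about the observed mean; negative
values are possible and not clamped; a zero-variance target yields a
missing R². Derived statistics: relative change 100(b−a)/a, percent
reduction 100(a−b)/a, RMSE/MAE ratio, relative RMSE 100·RMSE/mean(obs),
CV 100·SD/mean — rounded to one decimal (two for ratios) for reporting.

**Maps:** per-pixel prediction = mean over the 10 CV-fold models;
uncertainty = SD across those fold models, a definition consistent with
the CV design (per-tree SD or MC-dropout could be substituted but are
not the default). Pixels masked in any input are masked in both maps.

## Synthetic scenes

The generator mirrors the emulated study's data shapes: 7 dates ×
7 bands, 10 years × 23 NDVI composites, SOM field rescaled to mean
20.12 / SD 2.42 g/kg, 198 samples by default. The SOM field is a
Gaussian random field (spectrally filtered white noise, kernel scale =
correlation length, default 8 px) rescaled exactly to the target
moments. Reflectance is affine in SOM per band (negative loadings,
strongest SWIR1 ≥ SWIR2 ≥ NIR), plus three per-date disturbances: a
constant illumination offset (SD 0.015), a spatially smooth transient
field (SD 0.020, kernel 6 px) standing in for atmosphere/moisture
state, and white pixel noise (SD 0.003). The transient dominates the
per-band SOM signal (SD ≈ 0.010 for SWIR1), which is the realistic
regime for decade-spanning bare-soil composites and the disturbance
regime multi-temporal fusion exists to suppress. NDVI follows two
Gaussian pulses per year (wheat ≈ composite 8, maize ≈ 16.5, width 2)
scaled by a SOM-linked productivity factor, plus noise (SD 0.05).
Covariate rasters realize their configured correlation with SOM
*exactly* in-sample (the independent component is orthogonalized
against the SOM field before mixing); defaults span seven categories
with soil-moisture covariates strongest (r = 0.85/0.75/0.70). Samples
are drawn uniformly without replacement (optional SOM-quantile
stratification) and read the field at pixel centers, with optional
Gaussian measurement noise.

### The standard benchmark, and what it shows

`benchmark_config(seed)`: 200×200 scene, 500 samples, measurement noise
SD = 25% of the SOM field SD (0.605 g/kg), 10-fold CV, CNN capped at
150 epochs (patience 25) so a full run stays within a few minutes on
one CPU. Under these conditions both models recover the signal well
(out-of-fold R² ≈ 0.83 on Ev, ≈ 0.88–0.92 on Ev-Tn-Mm), the composite
feature set matches or beats the environmental set, and the LEW-DWT
features are at least as good as simple splicing. Because the 0.605
g/kg measurement noise bounds the attainable RMSE below by ≈ 0.6, the
three fusion strategies differ by only ~1% RMSE here — the benchmark
establishes ordering and recovery, not the effect sizes a real
landscape would show.

What the generator does *not* emulate: nonlinear soil–spectra
relationships, spatially structured sampling bias, co-registration
error, clouds/gaps in the NDVI record, and category-confounded
covariates. Passing the synthetic suite therefore demonstrates that the
algorithms are implemented correctly and recover known structure, not
that any particular accuracy will transfer to field data.

## Numerical choices and limitations

* Haar with `periodization` mode after explicit symmetric padding keeps
  every level's halving exact and reconstruction lossless.
* Local-energy windows use scipy's reflective boundary (symmetric
  padding), matching the brute-force oracle in the tests.
* Fold assignment, RF seeds, CNN seeds and sub-seeds all derive from
  the config seed; rerunning a config reproduces reports byte-for-byte.
* The RFE ranker refits one forest per elimination step; with many
  features and the full 250-tree ranker this is the slowest stage and
  can be scaled down via its `n_estimators` argument.
* Masked cells propagate as the union of input masks through fusion and
  feature maps; samples on masked cells are dropped with a logged count.
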