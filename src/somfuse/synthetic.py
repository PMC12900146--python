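"""Self-contained synthetic study areas with known ground truth.

The generator emulates the inputs of a cropland SOM mapping study:

* a spatially autocorrelated SOM field (Gaussian random field rescaled to
  a target mean/SD; defaults 20.12 and 2.42 g/kg, the sampled-field
  statistics of the emulated study area);
* multi-date multi-band surface reflectance in which every band is an
  affine function of SOM (negative loadings, strongest in SWIR/NIR) plus
  three date-specific disturbances the fusion is meant to suppress: a
  constant illumination offset, a spatially smooth transient field
  (atmosphere / surface moisture), and white pixel noise;
* a per-pixel NDVI time series with a double-peak annual cycle (winter
  wheat + summer maize) whose pulse height scales with a SOM-linked
  productivity factor;
* environmental covariate rasters with exactly realized in-sample
  correlation to the SOM field (the independent component is
  orthogonalized against SOM before mixing);
* a point-sample table drawn uniformly (or stratified by SOM quantile)
  from the unmasked pixels, with optional measurement noise.

Every draw flows from the recipe's seed, so scenes are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dfield

import numpy as np
import pandas as pd
from scipy import ndimage

from .raster import GridGeometry, RasterGrid, SceneStack

__all__ = ["BAND_NAMES", "DEFAULT_BAND_PARAMS", "DEFAULT_COVARIATES",
           "SceneRecipe", "SyntheticScene", "make_som_field", "make_scene",
           "draw_samples"]

BAND_NAMES = ["Coastal", "Blue", "Green", "Red", "NIR", "SWIR1", "SWIR2"]

# band -> (intercept reflectance, loading per g/kg of SOM)
DEFAULT_BAND_PARAMS = {
    "Coastal": (0.10, -0.0008),
    "Blue": (0.11, -0.0010),
    "Green": (0.13, -0.0014),
    "Red": (0.16, -0.0018),
    "NIR": (0.24, -0.0030),
    "SWIR1": (0.28, -0.0040),
    "SWIR2": (0.26, -0.0034),
}

# name -> (category, target correlation with SOM)
DEFAULT_COVARIATES = {
    "msm": ("soil", 0.85),
    "msms6": ("soil", 0.75),
    "msms3": ("soil", 0.70),
    "gwtd": ("soil", -0.35),
    "map": ("climate", 0.55),
    "maat": ("climate", -0.45),
    "psd": ("climate", 0.40),
    "mdlst": ("land-surface-thermal", -0.30),
    "dem": ("topographic", -0.20),
    "twi": ("topographic", 0.25),
    "regolith": ("parent material", 0.15),
    "pop_density": ("anthropogenic", -0.10),
}


@dataclass(frozen=True)
class SceneRecipe:
    rows: int = 200
    cols: int = 200
    correlation_length: float = 8.0          # pixels; Gaussian kernel scale
    som_mean: float = 20.12                  # g/kg
    som_sd: float = 2.42                     # g/kg
    n_dates: int = 7
    baseline_date_index: int = 4             # mirrors 2020 among 2014..2023
    band_params: dict = dfield(default_factory=lambda: dict(DEFAULT_BAND_PARAMS))
    illumination_sd: float = 0.015           # per-date constant offset
    transient_sd: float = 0.020              # per-date smooth disturbance field
    transient_length: float = 6.0
    pixel_noise_sd: float = 0.003
    n_years: int = 10
    samples_per_year: int = 23
    ndvi_base: float = 0.25
    pulse_amplitudes: tuple = (0.45, 0.40)   # wheat, maize
    pulse_centers: tuple = (8.0, 16.5)       # composite index within the year
    pulse_width: float = 2.0
    productivity_slope: float = 0.15         # per SD of SOM
    ndvi_noise_sd: float = 0.05
    covariates: dict = dfield(default_factory=lambda: dict(DEFAULT_COVARIATES))
    n_samples: int = 198
    measurement_noise_sd: float = 0.0        # g/kg, added to sampled SOM
    pixel_size: float = 30.0
    crs: int = 32650
    seed: int = 0

    def geometry(self) -> GridGeometry:
        return GridGeometry(x0=500000.0, y0=4100000.0, dx=self.pixel_size,
                            dy=-self.pixel_size, rows=self.rows, cols=self.cols)


@dataclass
class SyntheticScene:
    recipe: SceneRecipe
    som: RasterGrid
    stack: SceneStack
    ndvi: np.ndarray                  # (T, rows, cols)
    covariates: dict[str, RasterGrid]
    covariate_kinds: dict[str, str]


def _smooth_field(rng: np.random.Generator, shape, length: float) -> np.ndarray:
    """Standardized Gaussian random field (zero mean, unit SD over pixels)."""
    white = rng.standard_normal(shape)
    if length > 0:
        fieldv = ndimage.gaussian_filter(white, sigma=length, mode="wrap")
    else:
        fieldv = white
    fieldv -= fieldv.mean()
    sd = fieldv.std()
    return fieldv / sd if sd > 0 else fieldv


def make_som_field(recipe: SceneRecipe) -> RasterGrid:
    """Spatially autocorrelated SOM field with exactly the target mean/SD."""
    rng = np.random.default_rng(recipe.seed)
    z = _smooth_field(rng, (recipe.rows, recipe.cols), recipe.correlation_length)
    values = recipe.som_mean + recipe.som_sd * z
    return RasterGrid(values=values, geometry=recipe.geometry(), crs=recipe.crs)


def make_scene(recipe: SceneRecipe, som: RasterGrid | None = None) -> SyntheticScene:
    """Generate the reflectance stack, NDVI time series and covariates."""
    if som is None:
        som = make_som_field(recipe)
    if som.shape != (recipe.rows, recipe.cols):
        raise ValueError("SOM field does not match the recipe grid")
    rng = np.random.default_rng(recipe.seed + 1)
    geom, crs = som.geometry, som.crs
    z = (som.values - som.values.mean()) / som.values.std()

    # --- multi-date multi-band reflectance -------------------------------
    bands: dict[tuple, RasterGrid] = {}
    for d in range(recipe.n_dates):
        illum = rng.normal(0.0, recipe.illumination_sd)
        transient = recipe.transient_sd * _smooth_field(
            rng, som.shape, recipe.transient_length)
        for name in BAND_NAMES:
            intercept, loading = recipe.band_params[name]
            noise = rng.normal(0.0, recipe.pixel_noise_sd, size=som.shape)
            refl = intercept + loading * som.values + illum + transient + noise
            bands[(d, name)] = RasterGrid(values=refl, geometry=geom, crs=crs)
    stack = SceneStack(bands, BAND_NAMES)

    # --- NDVI time series -------------------------------------------------
    spy = recipe.samples_per_year
    t = np.arange(spy, dtype=float)
    pulses = np.zeros(spy)
    for amp, center in zip(recipe.pulse_amplitudes, recipe.pulse_centers):
        pulses += amp * np.exp(-0.5 * ((t - center) / recipe.pulse_width) ** 2)
    productivity = 1.0 + recipe.productivity_slope * z    # (rows, cols)
    annual = recipe.ndvi_base + productivity[None, :, :] * pulses[:, None, None]
    cube = np.tile(annual, (recipe.n_years, 1, 1))
    if recipe.ndvi_noise_sd > 0:
        cube = cube + rng.normal(0.0, recipe.ndvi_noise_sd, size=cube.shape)
    cube = np.clip(cube, -1.0, 1.0)

    # --- covariates: exact in-sample correlation --------------------------
    zf = z.ravel()
    zf = zf / np.sqrt(zf @ zf)
    covariates: dict[str, RasterGrid] = {}
    kinds: dict[str, str] = {}
    for name, (kind, r) in recipe.covariates.items():
        w = _smooth_field(rng, som.shape, recipe.correlation_length).ravel()
        w = w - (w @ zf) * zf                 # orthogonal to SOM in-sample
        w = w / w.std()
        mixed = r * z.ravel() / z.ravel().std() + np.sqrt(max(0.0, 1.0 - r * r)) * w
        covariates[name] = RasterGrid(values=mixed.reshape(som.shape),
                                      geometry=geom, crs=crs)
        kinds[name] = kind
    return SyntheticScene(recipe=recipe, som=som, stack=stack, ndvi=cube,
                          covariates=covariates, covariate_kinds=kinds)


def draw_samples(recipe: SceneRecipe, som: RasterGrid, stratified: bool = False,
                 n_bins: int = 5) -> pd.DataFrame:
    """Point samples (id, x, y, som_g_per_kg) drawn from the SOM field.

    Uniform without replacement over unmasked pixels by default; the
    stratified mode bins the field into `n_bins` quantile strata and draws
    n/n_bins (+-1) per stratum. Measurement noise (recipe) is added to the
    field value read at the pixel center.
    """
    rng = np.random.default_rng(recipe.seed + 2)
    valid = np.flatnonzero(~som.mask.ravel())
    n = recipe.n_samples
    if n > len(valid):
        raise ValueError("more samples requested than available pixels")
    if stratified:
        vals = som.values.ravel()[valid]
        edges = np.quantile(vals, np.linspace(0, 1, n_bins + 1))
        edges[-1] += 1e-9
        chosen = []
        base, extra = divmod(n, n_bins)
        for b in range(n_bins):
            pool = valid[(vals >= edges[b]) & (vals < edges[b + 1])]
            k = base + (1 if b < extra else 0)
            chosen.append(rng.choice(pool, size=min(k, len(pool)), replace=False))
        idx = np.concatenate(chosen)
    else:
        idx = rng.choice(valid, size=n, replace=False)
    row, col = np.unravel_index(idx, som.shape)
    x, y = som.geometry.pixel_center(row, col)
    values = som.values[row, col]
    if recipe.measurement_noise_sd > 0:
        values = values + rng.normal(0.0, recipe.measurement_noise_sd, size=len(values))
    return pd.DataFrame({
        "sample_id": np.arange(len(idx)),
        "x": x, "y": y,
        "som_g_per_kg": values,
    })
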