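"""NDVI time-series smoothing and phenology feature extraction.

Per-pixel NDVI series (16-day composites, 23 samples per year) are smoothed
with a Savitzky-Golay filter and summarized into six phenology features:

* ``n_min`` / ``n_max`` / ``n_std`` — minimum, maximum and population
  standard deviation of the smoothed series;
* ``n_gsl`` — growing-season length: per-year count of composites at or
  above a threshold (by default min + 20% of the amplitude), averaged over
  whole years; in units of composite periods (multiply by 16 for days);
* ``n_amplitude`` / ``n_phase`` — amplitude and phase of the annual
  (first) harmonic of the smoothed series, with the convention that a
  series A*cos(2*pi*t/23 - phi) yields exactly (A, phi).

Raw-series mean and SD (``mndvi`` / ``sdndvi``) are kept alongside, as the
conventional long-term vegetation covariates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter

from .raster import RasterGrid

SAMPLES_PER_YEAR = 23

FEATURE_NAMES = ["n_min", "n_max", "n_std", "n_gsl", "n_amplitude", "n_phase",
                 "mndvi", "sdndvi"]

__all__ = ["SAMPLES_PER_YEAR", "FEATURE_NAMES", "PhenologyFeatures", "ndvi",
           "sg_filter", "stat_features", "growing_season_length",
           "first_harmonic", "series_features", "per_pixel_features"]


@dataclass(frozen=True)
class PhenologyFeatures:
    n_min: float
    n_max: float
    n_std: float
    n_gsl: float
    n_amplitude: float
    n_phase: float
    mndvi: float
    sdndvi: float

    def as_dict(self) -> dict[str, float]:
        return {k: getattr(self, k) for k in FEATURE_NAMES}


def ndvi(nir, red):
    """(NIR - RED) / (NIR + RED), clipped to [-1, 1]; NaN where NIR+RED == 0."""
    nir = np.asarray(nir, dtype=float)
    red = np.asarray(red, dtype=float)
    denom = nir + red
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(denom != 0, (nir - red) / denom, np.nan)
    out = np.clip(out, -1.0, 1.0)
    if out.ndim == 0:
        return float(out) if denom != 0 else float("nan")
    return out


def sg_filter(values: np.ndarray, window: int = 7, order: int = 3) -> np.ndarray:
    """Savitzky-Golay smoothing along the last axis.

    Ends are handled by fitting the edge window's polynomial and evaluating
    it at the boundary samples (scipy's 'interp' mode), so a series that is
    exactly a polynomial of degree <= order passes through unchanged.
    """
    values = np.asarray(values, dtype=float)
    if window % 2 == 0 or window < 3:
        raise ValueError("window must be odd and >= 3")
    if order >= window:
        raise ValueError("order must be < window")
    if values.shape[-1] < window:
        raise ValueError("series shorter than the filter window")
    return savgol_filter(values, window_length=window, polyorder=order,
                         axis=-1, mode="interp")


def stat_features(values: np.ndarray, mask: np.ndarray | None = None):
    """(min, max, population SD) over unmasked samples."""
    v = np.asarray(values, dtype=float)
    if mask is not None:
        v = v[~np.asarray(mask, dtype=bool)]
    if v.size < 2:
        raise ValueError("need at least two unmasked samples")
    return float(v.min()), float(v.max()), float(v.std())


def growing_season_length(smoothed: np.ndarray, threshold: float | None = None,
                          samples_per_year: int = SAMPLES_PER_YEAR) -> float:
    """Mean per-year count of composites with NDVI >= threshold.

    The default threshold is dynamic: min + 0.2 * (max - min) of the whole
    smoothed series. A zero-amplitude series is defined to have a
    full-year growing season.
    """
    v = np.asarray(smoothed, dtype=float)
    n_years = v.shape[-1] // samples_per_year
    if n_years < 1:
        raise ValueError("need at least one full year of composites")
    v = v[..., : n_years * samples_per_year]
    if threshold is None:
        lo, hi = v.min(), v.max()
        if hi == lo:
            return float(samples_per_year)
        threshold = lo + 0.2 * (hi - lo)
    per_year = (v.reshape(-1, n_years, samples_per_year) >= threshold).sum(axis=-1)
    return float(per_year.mean())


def first_harmonic(smoothed: np.ndarray,
                   samples_per_year: int = SAMPLES_PER_YEAR):
    """Amplitude and phase of the annual harmonic.

    The series is trimmed to whole years (length N = Y * samples_per_year)
    and the DFT bin at the annual frequency (index Y) is read out:
    amplitude = 2|X_Y|/N, phase = atan2(-Im X_Y, Re X_Y), so that
    A*cos(2*pi*t/samples_per_year - phi) returns exactly (A, phi).
    """
    v = np.asarray(smoothed, dtype=float)
    n_years = v.shape[-1] // samples_per_year
    if n_years < 1:
        raise ValueError("need at least one full year of composites")
    v = v[..., : n_years * samples_per_year]
    n = v.shape[-1]
    t = np.arange(n)
    w = 2.0 * np.pi * n_years * t / n
    re = (v * np.cos(w)).sum(axis=-1)
    im = -(v * np.sin(w)).sum(axis=-1)   # X_Y = sum v * exp(-i w)
    amplitude = 2.0 * np.hypot(re, im) / n
    phase = np.arctan2(-im, re)
    if v.ndim == 1:
        return float(amplitude), float(phase)
    return amplitude, phase


def series_features(raw: np.ndarray, window: int = 7, order: int = 3,
                    gsl_threshold: float | None = None,
                    samples_per_year: int = SAMPLES_PER_YEAR) -> PhenologyFeatures:
    """All phenology features of one raw NDVI series."""
    raw = np.asarray(raw, dtype=float)
    smoothed = sg_filter(raw, window=window, order=order)
    n_min, n_max, n_std = stat_features(smoothed)
    n_gsl = growing_season_length(smoothed, threshold=gsl_threshold,
                                  samples_per_year=samples_per_year)
    n_amp, n_phase = first_harmonic(smoothed, samples_per_year=samples_per_year)
    return PhenologyFeatures(n_min=n_min, n_max=n_max, n_std=n_std, n_gsl=n_gsl,
                             n_amplitude=n_amp, n_phase=n_phase,
                             mndvi=float(raw.mean()), sdndvi=float(raw.std()))


def per_pixel_features(stack: np.ndarray | list[RasterGrid], window: int = 7,
                       order: int = 3, gsl_threshold: float | None = None,
                       samples_per_year: int = SAMPLES_PER_YEAR):
    """Phenology feature maps from an NDVI composite stack.

    `stack` is a (T, rows, cols) array or a co-registered list of grids
    (one per composite date). Returns a dict feature name -> RasterGrid
    (or plain 2-D array when the input is an array). A pixel masked in any
    composite is masked in every feature map.
    """
    template = None
    if isinstance(stack, (list, tuple)):
        from .raster import assert_coregistered
        assert_coregistered(list(stack))
        template = stack[0]
        mask = np.logical_or.reduce([g.mask for g in stack])
        cube = np.stack([g.values for g in stack])
    else:
        cube = np.asarray(stack, dtype=float)
        mask = np.zeros(cube.shape[1:], dtype=bool)

    t, rows, cols = cube.shape
    series = cube.reshape(t, -1).T  # (pixels, T)
    smoothed = sg_filter(series, window=window, order=order)

    n_years = t // samples_per_year
    if n_years < 1:
        raise ValueError("need at least one full year of composites")
    trimmed = smoothed[:, : n_years * samples_per_year]

    n_min = trimmed.min(axis=1)
    n_max = trimmed.max(axis=1)
    n_std = trimmed.std(axis=1)
    if gsl_threshold is None:
        amp = n_max - n_min
        thr = n_min + 0.2 * amp
        above = trimmed >= thr[:, None]
        counts = above.reshape(-1, n_years, samples_per_year).sum(axis=-1)
        n_gsl = np.where(amp > 0, counts.mean(axis=1), float(samples_per_year))
    else:
        above = trimmed >= gsl_threshold
        n_gsl = above.reshape(-1, n_years, samples_per_year).sum(axis=-1).mean(axis=1)
    n_amp, n_phase = first_harmonic(trimmed, samples_per_year=samples_per_year)

    maps = {
        "n_min": n_min, "n_max": n_max, "n_std": n_std, "n_gsl": n_gsl,
        "n_amplitude": n_amp, "n_phase": n_phase,
        "mndvi": series.mean(axis=1), "sdndvi": series.std(axis=1),
    }
    out = {}
    for name, flat in maps.items():
        plane = flat.reshape(rows, cols)
        if template is not None:
            out[name] = template.with_values(np.where(mask, 0.0, plane), mask=mask.copy())
        else:
            out[name] = np.where(mask, np.nan, plane)
    return out
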