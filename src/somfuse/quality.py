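"""Fusion quality metrics: spectral angle, information entropy, average gradient.

Standard definitions from the image-fusion literature are used:

* SAM — mean over unmasked pixels of the angle arccos(<f, r> / (|f| |r|))
  between the per-pixel spectra of a fused and a reference multi-band image
  (radians; 0 means no spectral distortion).
* IE — Shannon entropy (bits) of the min-max-quantized value histogram
  (256 levels by default); higher means richer spatial information.
* AG — average gradient: mean over the interior of
  sqrt((dx^2 + dy^2) / 2) with forward differences; higher means sharper
  textures and edges.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .raster import RasterGrid, SceneStack

__all__ = ["QualityReport", "spectral_angle", "information_entropy",
           "average_gradient", "quality_report"]


def _values_mask(img):
    if isinstance(img, RasterGrid):
        return img.values, img.mask
    arr = np.asarray(img, dtype=float)
    return arr, np.zeros(arr.shape, dtype=bool)


def spectral_angle(fused, reference) -> float:
    """Mean per-pixel spectral angle (radians) between two multi-band images.

    Accepts two :class:`SceneStack` of one date each, or two (bands, h, w)
    arrays / lists of grids. Pixels with a zero-norm spectrum in either
    image, or masked in any band, are excluded.
    """
    def to_cube(obj):
        if isinstance(obj, SceneStack):
            if len(obj.dates) != 1:
                raise ValueError("spectral_angle expects single-date stacks")
            grids = obj.grids_for_date(obj.dates[0])
        elif isinstance(obj, (list, tuple)):
            grids = list(obj)
        else:
            cube = np.asarray(obj, dtype=float)
            return cube, np.zeros(cube.shape[1:], dtype=bool)
        vals = np.stack([g.values for g in grids])
        mask = np.logical_or.reduce([g.mask for g in grids])
        return vals, mask

    f, fmask = to_cube(fused)
    r, rmask = to_cube(reference)
    if f.shape != r.shape:
        raise ValueError(f"band/shape mismatch: {f.shape} vs {r.shape}")
    if f.shape[0] < 2:
        raise ValueError("spectra need at least 2 bands")
    mask = fmask | rmask
    nf = np.sqrt((f * f).sum(axis=0))
    nr = np.sqrt((r * r).sum(axis=0))
    valid = (~mask) & (nf > 0) & (nr > 0)
    if not valid.any():
        raise ValueError("no valid pixels for spectral angle")
    cos = (f * r).sum(axis=0)[valid] / (nf[valid] * nr[valid])
    return float(np.mean(np.arccos(np.clip(cos, -1.0, 1.0))))


def information_entropy(img, bins: int = 256) -> float:
    """Shannon entropy (bits) of the min-max quantized image histogram."""
    values, mask = _values_mask(img)
    v = values[~mask]
    if v.size == 0:
        raise ValueError("no unmasked cells")
    lo, hi = v.min(), v.max()
    if hi == lo:
        return 0.0
    levels = np.minimum((v - lo) / (hi - lo) * bins, bins - 1).astype(int)
    counts = np.bincount(levels, minlength=bins)
    p = counts[counts > 0] / v.size
    return float(-(p * np.log2(p)).sum())


def average_gradient(img) -> float:
    """Mean forward-difference gradient magnitude sqrt((dx^2 + dy^2)/2)."""
    values, mask = _values_mask(img)
    if values.shape[0] < 2 or values.shape[1] < 2:
        raise ValueError("image must be at least 2x2")
    dx = values[:-1, 1:] - values[:-1, :-1]
    dy = values[1:, :-1] - values[:-1, :-1]
    g = np.sqrt((dx * dx + dy * dy) / 2.0)
    valid = ~(mask[:-1, :-1] | mask[:-1, 1:] | mask[1:, :-1])
    if not valid.any():
        raise ValueError("no valid interior cells")
    return float(g[valid].mean())


@dataclass
class QualityReport:
    """SAM against the reference plus per-band IE / AG of the fused bands."""

    sam_radians: float
    entropy_bits: dict[str, float]
    avg_gradient: dict[str, float]

    @property
    def mean_entropy(self) -> float:
        return float(np.mean(list(self.entropy_bits.values())))

    @property
    def mean_avg_gradient(self) -> float:
        return float(np.mean(list(self.avg_gradient.values())))

    def to_dict(self) -> dict:
        return {
            "sam_radians": self.sam_radians,
            "entropy_bits": dict(self.entropy_bits),
            "entropy_bits_mean": self.mean_entropy,
            "avg_gradient": dict(self.avg_gradient),
            "avg_gradient_mean": self.mean_avg_gradient,
        }


def quality_report(fused: dict[str, RasterGrid], reference: dict[str, RasterGrid],
                   bins: int = 256) -> QualityReport:
    """Evaluate fused bands (name -> grid) against reference bands."""
    names = list(fused)
    if set(names) != set(reference):
        raise ValueError("fused and reference band names differ")
    sam = spectral_angle([fused[n] for n in names], [reference[n] for n in names])
    ie = {n: information_entropy(fused[n], bins=bins) for n in names}
    ag = {n: average_gradient(fused[n]) for n in names}
    return QualityReport(sam_radians=sam, entropy_bits=ie, avg_gradient=ag)
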