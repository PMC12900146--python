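"""Local-energy-weighted DWT fusion of multi-temporal single-band images.

The fusion normalizes each input image to [0, 1], decomposes it with an
orthonormal 2-D wavelet (Haar by default, two cascade levels), and merges
the coefficient pyramids of all acquisition dates into one:

* the deepest approximation (LL) plane is an energy-weighted mean of the
  sources, with weights ``W_i = E_i / sum_j E_j`` where ``E_i`` is the sum
  of squared normalized pixel values of source *i*;
* every detail plane (HL/LH/HH at every level) is assembled per position
  by picking the coefficient of the source with the largest local energy
  in a centered sliding window (3x3 by default). Ties go to the baseline
  date, then to the lowest date index.

An inverse transform and padding crop return a fused band with the input
shape. Two baselines are provided: traditional DWT fusion (plain mean of
all coefficient planes) and simple splicing (no fusion; bands are stacked
as separate features).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pywt
from scipy import ndimage

from .raster import RasterGrid, SceneStack, assert_coregistered

__all__ = [
    "FusionConfig",
    "WaveletPyramid",
    "normalize_band",
    "image_energy",
    "energy_weights",
    "dwt_decompose",
    "dwt_reconstruct",
    "local_energy",
    "fuse_coefficients",
    "lew_dwt_fuse",
    "fuse_baseline",
    "fuse_stack",
]


@dataclass(frozen=True)
class FusionConfig:
    levels: int = 2
    wavelet: str = "haar"
    window: int = 3
    rule_low: str = "energy_weighted"      # or "local_energy_max"
    rule_high: str = "local_energy_max"    # or "energy_weighted" | "mean"
    baseline_index: int = 0                # index of the reference date

    def __post_init__(self) -> None:
        if not (1 <= self.levels <= 4):
            raise ValueError("levels must be in [1, 4]")
        if self.window < 3 or self.window % 2 == 0:
            raise ValueError("window must be odd and >= 3")
        if self.rule_low not in ("energy_weighted", "local_energy_max"):
            raise ValueError(f"unknown rule_low {self.rule_low!r}")
        if self.rule_high not in ("local_energy_max", "energy_weighted", "mean"):
            raise ValueError(f"unknown rule_high {self.rule_high!r}")


@dataclass
class WaveletPyramid:
    """Multi-level 2-D DWT coefficients of one image.

    ``approx`` is the deepest LL plane; ``details[k]`` holds the
    (HL, LH, HH) planes of level k+1 (level 1 = finest). ``orig_shape``
    records the pre-padding image shape so reconstruction can crop.
    """

    approx: np.ndarray
    details: list[tuple[np.ndarray, np.ndarray, np.ndarray]]
    wavelet: str
    orig_shape: tuple[int, int]

    @property
    def levels(self) -> int:
        return len(self.details)

    def same_structure(self, other: "WaveletPyramid") -> bool:
        if (self.wavelet != other.wavelet or self.levels != other.levels
                or self.approx.shape != other.approx.shape
                or self.orig_shape != other.orig_shape):
            return False
        return all(a[0].shape == b[0].shape for a, b in zip(self.details, other.details))


def normalize_band(img: RasterGrid | np.ndarray) -> np.ndarray:
    """Min-max scale unmasked cells to [0, 1]; a constant image maps to zeros.

    Masked cells are excluded from the min/max and set to 0 in the output.
    """
    if isinstance(img, RasterGrid):
        values, mask = img.values, img.mask
    else:
        values, mask = np.asarray(img, dtype=float), np.zeros(np.shape(img), dtype=bool)
    if mask.all():
        raise ValueError("cannot normalize a fully masked image")
    valid = values[~mask]
    lo, hi = valid.min(), valid.max()
    if hi == lo:
        out = np.zeros_like(values)
    else:
        out = (values - lo) / (hi - lo)
    out[mask] = 0.0
    return out


def image_energy(x: np.ndarray, mask: np.ndarray | None = None) -> float:
    """Sum of squared elements over unmasked cells (E = sum x_i^2)."""
    x = np.asarray(x, dtype=float)
    if mask is not None:
        x = x[~np.asarray(mask, dtype=bool)]
    return float(np.sum(x * x))


def energy_weights(energies: Sequence[float]) -> np.ndarray:
    """Normalize energies to weights W_i = E_i / sum_j E_j."""
    e = np.asarray(energies, dtype=float)
    if e.size == 0:
        raise ValueError("no energies given")
    if np.any(e < 0):
        raise ValueError("energies must be nonnegative")
    total = e.sum()
    if total == 0:
        raise ValueError("all energies are zero")
    return e / total


def _pad_to_multiple(img: np.ndarray, factor: int) -> np.ndarray:
    pr = (-img.shape[0]) % factor
    pc = (-img.shape[1]) % factor
    if pr or pc:
        img = np.pad(img, ((0, pr), (0, pc)), mode="symmetric")
    return img


def dwt_decompose(img: np.ndarray, cfg: FusionConfig = FusionConfig()) -> WaveletPyramid:
    """Cascaded orthonormal 2-D DWT of the LL chain.

    The image is symmetrically padded to a multiple of 2**levels (recorded
    in ``orig_shape``) so every level halves exactly and reconstruction is
    perfect.
    """
    img = np.asarray(img, dtype=np.float64)
    if img.ndim != 2:
        raise ValueError("expected a 2-D image")
    factor = 2 ** cfg.levels
    if min(img.shape) < factor:
        raise ValueError(
            f"image {img.shape} too small for {cfg.levels}-level decomposition")
    orig_shape = img.shape
    padded = _pad_to_multiple(img, factor)
    coeffs = pywt.wavedec2(padded, cfg.wavelet, mode="periodization", level=cfg.levels)
    approx = coeffs[0]
    # wavedec2 orders detail tuples deepest-first; store finest-first
    details = [tuple(np.asarray(p) for p in triple) for triple in coeffs[1:]][::-1]
    return WaveletPyramid(approx=approx, details=details, wavelet=cfg.wavelet,
                          orig_shape=orig_shape)


def dwt_reconstruct(pyr: WaveletPyramid) -> np.ndarray:
    """Inverse transform; crops the recorded padding."""
    coeffs = [pyr.approx] + [tuple(t) for t in pyr.details[::-1]]
    rec = pywt.waverec2(coeffs, pyr.wavelet, mode="periodization")
    r, c = pyr.orig_shape
    return rec[:r, :c]


def local_energy(coeff: np.ndarray, window: int = 3) -> np.ndarray:
    """Per-position sum of squared coefficients over a centered window.

    Edges are reflection-padded (symmetric, edge value included).
    """
    if window % 2 == 0:
        raise ValueError("window must be odd")
    coeff = np.asarray(coeff, dtype=np.float64)
    if window > min(coeff.shape):
        raise ValueError("window exceeds the smallest coefficient-plane dimension")
    sq = coeff * coeff
    return ndimage.uniform_filter(sq, size=window, mode="reflect") * (window ** 2)


def _select_by_local_energy(planes: np.ndarray, window: int, order: np.ndarray) -> np.ndarray:
    """Per-position pick from `planes` (N, h, w) of the plane with the largest
    local energy; `order` is the tie-preference ordering of plane indices.

    On coefficient planes smaller than the window (deep decomposition
    levels) the window is clamped to the largest odd size that fits.
    """
    w = min(window, min(planes.shape[1:]))
    if w % 2 == 0:
        w -= 1
    w = max(w, 1)
    ordered = planes[order]
    le = np.stack([local_energy(p, w) for p in ordered])
    pick = np.argmax(le, axis=0)  # first max wins -> earlier in `order` wins ties
    return np.take_along_axis(ordered, pick[None], axis=0)[0]


def fuse_coefficients(pyramids: Sequence[WaveletPyramid], cfg: FusionConfig,
                      weights: Sequence[float] | None = None) -> WaveletPyramid:
    """Merge coefficient pyramids into one.

    `weights` are the per-source global energy weights (computed from the
    normalized images); if omitted they are computed from the approximation
    planes' energies.
    """
    if len(pyramids) == 0:
        raise ValueError("no pyramids given")
    ref = pyramids[0]
    for p in pyramids[1:]:
        if not ref.same_structure(p):
            raise ValueError("pyramids are structurally incompatible")
    n = len(pyramids)
    if weights is None:
        weights = energy_weights([image_energy(p.approx) for p in pyramids])
    else:
        weights = np.asarray(weights, dtype=float)
        if weights.shape != (n,):
            raise ValueError("one weight per pyramid required")

    base = cfg.baseline_index
    if not (0 <= base < n):
        raise ValueError("baseline_index out of range")
    order = np.array([base] + [i for i in range(n) if i != base])

    def merge(planes: list[np.ndarray], rule: str) -> np.ndarray:
        stack = np.stack(planes)
        if rule == "energy_weighted":
            return np.tensordot(weights, stack, axes=1)
        if rule == "mean":
            return stack.mean(axis=0)
        return _select_by_local_energy(stack, cfg.window, order)

    approx = merge([p.approx for p in pyramids], cfg.rule_low)
    details = []
    for lev in range(ref.levels):
        triple = tuple(
            merge([p.details[lev][k] for p in pyramids], cfg.rule_high)
            for k in range(3)
        )
        details.append(triple)
    return WaveletPyramid(approx=approx, details=details, wavelet=ref.wavelet,
                          orig_shape=ref.orig_shape)


def _prepare(images: Sequence[RasterGrid | np.ndarray]):
    if len(images) == 0:
        raise ValueError("no images given")
    grids = [img for img in images if isinstance(img, RasterGrid)]
    if grids:
        if len(grids) != len(images):
            raise ValueError("mix of RasterGrid and arrays not supported")
        assert_coregistered(grids)
        for g in grids:
            if g.mask.all():
                raise ValueError("fully masked image cannot be fused")
        mask = np.logical_or.reduce([g.mask for g in grids])
        template = grids[0]
    else:
        mask = np.zeros(np.shape(images[0]), dtype=bool)
        template = None
    normalized = [normalize_band(img) for img in images]
    return normalized, mask, template


def _wrap(values: np.ndarray, mask: np.ndarray, template: RasterGrid | None):
    if template is None:
        return values
    return template.with_values(np.where(mask, 0.0, values), mask=mask)


def lew_dwt_fuse(images: Sequence[RasterGrid | np.ndarray],
                 cfg: FusionConfig = FusionConfig()):
    """Fuse co-registered single-band images with the local-energy rule.

    Returns the fused band in normalized [0, 1] space, with the union of
    input nodata masks when inputs are :class:`RasterGrid`.
    """
    normalized, mask, template = _prepare(images)
    if len(normalized) == 1:
        return _wrap(normalized[0], mask, template)
    energies = [image_energy(x) for x in normalized]
    if sum(energies) == 0:  # all inputs constant: no information to weight
        weights = np.full(len(normalized), 1.0 / len(normalized))
    else:
        weights = energy_weights(energies)
    pyramids = [dwt_decompose(x, cfg) for x in normalized]
    fused = dwt_reconstruct(fuse_coefficients(pyramids, cfg, weights=weights))
    return _wrap(fused, mask, template)


def fuse_baseline(images: Sequence[RasterGrid | np.ndarray], method: str,
                  cfg: FusionConfig = FusionConfig()):
    """Baseline strategies: 'traditional_dwt' (mean rule on every plane)
    or 'simple_splicing' (no fusion; returns the normalized band list)."""
    if method == "traditional_dwt":
        mean_cfg = FusionConfig(levels=cfg.levels, wavelet=cfg.wavelet, window=cfg.window,
                                rule_low="energy_weighted", rule_high="mean",
                                baseline_index=cfg.baseline_index)
        normalized, mask, template = _prepare(images)
        if len(normalized) == 1:
            return _wrap(normalized[0], mask, template)
        n = len(normalized)
        pyramids = [dwt_decompose(x, mean_cfg) for x in normalized]
        fused = dwt_reconstruct(
            fuse_coefficients(pyramids, mean_cfg, weights=np.full(n, 1.0 / n)))
        return _wrap(fused, mask, template)
    if method == "simple_splicing":
        normalized, mask, template = _prepare(images)
        return [_wrap(x, mask, template) for x in normalized]
    raise ValueError(f"unknown baseline method {method!r}")


def fuse_stack(stack: SceneStack, method: str = "lew_dwt",
               cfg: FusionConfig = FusionConfig()) -> dict[str, RasterGrid | list]:
    """Fuse a multi-date stack per spectral band across dates.

    Returns a map band_name -> fused grid ('lew_dwt' / 'traditional_dwt')
    or band_name -> list of normalized per-date grids ('simple_splicing').
    """
    out = {}
    for name in stack.band_names:
        imgs = stack.grids_for_band(name)
        if method == "lew_dwt":
            out[name] = lew_dwt_fuse(imgs, cfg)
        else:
            out[name] = fuse_baseline(imgs, method, cfg)
    return out
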