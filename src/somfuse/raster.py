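"""Georeferenced raster grids: I/O, co-registration checks, resampling.

A :class:`RasterGrid` is one 2-D band with grid geometry (pixel-is-area,
origin at the upper-left corner, row-major) and a nodata mask. Grids are
read from and written to GeoTIFF via :mod:`tifffile`, carrying the
ModelPixelScale / ModelTiepoint / GeoKeyDirectory / GDAL_NODATA tags.

Point <-> pixel mapping uses half-open pixel intervals: the point (x, y)
falls in pixel (row, col) iff x0 + col*dx <= x < x0 + (col+1)*dx and
y0 + row*dy >= y > y0 + (row+1)*dy (dy < 0 for north-up grids).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from typing import Iterator, Sequence

import numpy as np
import tifffile

__all__ = [
    "GridGeometry",
    "RasterGrid",
    "SceneStack",
    "read_raster",
    "write_raster",
    "resample_to_grid",
    "assert_coregistered",
]

# GeoTIFF / GDAL private tags
_TAG_MODEL_PIXEL_SCALE = 33550
_TAG_MODEL_TIEPOINT = 33922
_TAG_GEO_KEY_DIRECTORY = 34735
_TAG_GDAL_NODATA = 42113

# GeoKey ids
_KEY_MODEL_TYPE = 1024
_KEY_GEOGRAPHIC_TYPE = 2048
_KEY_PROJECTED_CS_TYPE = 3072


@dataclass(frozen=True)
class GridGeometry:
    """Affine grid geometry for an axis-aligned, north-up raster.

    ``x0, y0`` are the map coordinates of the *outer* corner of the
    upper-left pixel; ``dx > 0`` and ``dy < 0`` are the pixel sizes.
    """

    x0: float
    y0: float
    dx: float
    dy: float
    rows: int
    cols: int

    def __post_init__(self) -> None:
        if self.dx <= 0 or self.dy >= 0:
            raise ValueError(f"pixel size must have dx > 0 and dy < 0, got ({self.dx}, {self.dy})")
        if self.rows < 1 or self.cols < 1:
            raise ValueError("grid must have at least one row and one column")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.rows, self.cols)

    def pixel_center(self, row, col):
        """Map coordinates of pixel centers (vectorized)."""
        x = self.x0 + (np.asarray(col) + 0.5) * self.dx
        y = self.y0 + (np.asarray(row) + 0.5) * self.dy
        return x, y

    def locate(self, x, y):
        """Pixel (row, col) whose half-open extent contains the point."""
        col = np.floor((np.asarray(x, dtype=float) - self.x0) / self.dx).astype(int)
        row = np.floor((np.asarray(y, dtype=float) - self.y0) / self.dy).astype(int)
        return row, col

    def approx_equal(self, other: "GridGeometry", tol: float = 1e-9) -> bool:
        return (
            self.shape == other.shape
            and abs(self.x0 - other.x0) <= tol
            and abs(self.y0 - other.y0) <= tol
            and abs(self.dx - other.dx) <= tol
            and abs(self.dy - other.dy) <= tol
        )


@dataclass
class RasterGrid:
    """One 2-D band with geometry, CRS identifier and a nodata mask."""

    values: np.ndarray
    geometry: GridGeometry
    crs: int  # EPSG code
    mask: np.ndarray = field(default=None)  # True where nodata

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("RasterGrid values must be 2-D")
        if self.mask is None:
            self.mask = np.zeros(self.values.shape, dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.values.shape:
            raise ValueError("values and mask must have identical shape")
        if self.values.shape != self.geometry.shape:
            raise ValueError(
                f"values shape {self.values.shape} != geometry shape {self.geometry.shape}"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def unmasked(self) -> np.ndarray:
        """1-D array of valid values."""
        return self.values[~self.mask]

    def with_values(self, values: np.ndarray, mask: np.ndarray | None = None) -> "RasterGrid":
        return RasterGrid(values=values, geometry=self.geometry, crs=self.crs,
                          mask=self.mask.copy() if mask is None else mask)


class SceneStack:
    """Co-registered multi-band rasters indexed by (date, band_name)."""

    def __init__(self, bands: dict[tuple, RasterGrid], band_names: Sequence[str]):
        if not bands:
            raise ValueError("empty SceneStack")
        self.band_names = list(band_names)
        self.bands = dict(bands)
        self.dates = sorted({d for d, _ in self.bands})
        for d in self.dates:
            for name in self.band_names:
                if (d, name) not in self.bands:
                    raise ValueError(f"date {d!r} is missing band {name!r}")
        assert_coregistered(list(self.bands.values()))

    def __getitem__(self, key: tuple) -> RasterGrid:
        return self.bands[key]

    def grids_for_band(self, name: str) -> list[RasterGrid]:
        return [self.bands[(d, name)] for d in self.dates]

    def grids_for_date(self, date) -> list[RasterGrid]:
        return [self.bands[(date, name)] for name in self.band_names]

    def iter_items(self) -> Iterator[tuple[tuple, RasterGrid]]:
        return iter(self.bands.items())

    @property
    def geometry(self) -> GridGeometry:
        return next(iter(self.bands.values())).geometry


# ---------------------------------------------------------------------------
# GeoTIFF I/O

def _geo_tags(grid: RasterGrid, nodata: float) -> list:
    geom = grid.geometry
    scale = [geom.dx, -geom.dy, 0.0]
    tiepoint = [0.0, 0.0, 0.0, geom.x0, geom.y0, 0.0]
    # EPSG < 32768 are projected or geographic; classify by common ranges:
    # geographic CRS codes (4xxx) use GeographicTypeGeoKey, else projected.
    geographic = 4000 <= grid.crs < 5000
    model_type = 2 if geographic else 1
    cs_key = _KEY_GEOGRAPHIC_TYPE if geographic else _KEY_PROJECTED_CS_TYPE
    keys = [
        1, 1, 0, 2,            # version, revision, minor, number of keys
        _KEY_MODEL_TYPE, 0, 1, model_type,
        cs_key, 0, 1, int(grid.crs),
    ]
    return [
        (_TAG_MODEL_PIXEL_SCALE, "d", 3, scale),
        (_TAG_MODEL_TIEPOINT, "d", 6, tiepoint),
        (_TAG_GEO_KEY_DIRECTORY, "H", len(keys), keys),
        (_TAG_GDAL_NODATA, "s", 0, str(nodata)),
    ]


def write_raster(path: str, grid: RasterGrid | Sequence[RasterGrid],
                 nodata: float = -9999.0) -> None:
    """Write one grid (or a list of co-registered grids, as bands) as GeoTIFF."""
    grids = [grid] if isinstance(grid, RasterGrid) else list(grid)
    assert_coregistered(grids)
    planes = []
    for g in grids:
        vals = g.values.astype(np.float32)
        vals = np.where(g.mask, np.float32(nodata), vals)
        planes.append(vals)
    data = planes[0] if len(planes) == 1 else np.stack(planes)
    tifffile.imwrite(path, data, photometric="minisblack",
                     extratags=_geo_tags(grids[0], nodata))


def _parse_geokeys(keys) -> int | None:
    keys = list(keys)
    n = keys[3]
    for i in range(n):
        key_id, _loc, _cnt, value = keys[4 + 4 * i: 8 + 4 * i]
        if key_id in (_KEY_PROJECTED_CS_TYPE, _KEY_GEOGRAPHIC_TYPE):
            return int(value)
    return None


def read_raster(path: str) -> RasterGrid | list[RasterGrid]:
    """Read a single- or multi-band GeoTIFF.

    Returns one :class:`RasterGrid` for a single band, a list for several.
    The GDAL nodata value is translated into the mask; NaNs are always masked.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    with tifffile.TiffFile(path) as tf:
        page = tf.pages[0]
        data = tf.asarray().astype(np.float64)
        tags = {t.code: t.value for t in page.tags}
        samples_per_pixel = page.samplesperpixel
    if _TAG_MODEL_PIXEL_SCALE not in tags or _TAG_MODEL_TIEPOINT not in tags:
        raise ValueError(f"{path}: no grid geometry (ModelPixelScale/Tiepoint tags absent)")
    if _TAG_GEO_KEY_DIRECTORY not in tags:
        raise ValueError(f"{path}: no CRS (GeoKeyDirectory tag absent)")
    crs = _parse_geokeys(tags[_TAG_GEO_KEY_DIRECTORY])
    if crs is None:
        raise ValueError(f"{path}: GeoKeyDirectory carries no EPSG code")
    sx, sy, _ = tags[_TAG_MODEL_PIXEL_SCALE]
    tie = tags[_TAG_MODEL_TIEPOINT]
    x0 = tie[3] - tie[0] * sx
    y0 = tie[4] + tie[1] * sy

    if data.ndim == 2:
        planes = data[None]
    elif samples_per_pixel > 1:  # (h, w, c) interleaved layout
        planes = np.moveaxis(data, -1, 0)
    else:  # one band per page -> (bands, h, w)
        planes = data

    nodata = None
    if _TAG_GDAL_NODATA in tags:
        try:
            nodata = float(str(tags[_TAG_GDAL_NODATA]).strip("\x00 "))
        except ValueError:
            nodata = None

    rows, cols = planes.shape[1:]
    geom = GridGeometry(x0=x0, y0=y0, dx=sx, dy=-sy, rows=rows, cols=cols)
    grids = []
    for plane in planes:
        mask = ~np.isfinite(plane)
        if nodata is not None:
            mask |= plane == nodata
        grids.append(RasterGrid(values=np.where(mask, 0.0, plane), geometry=geom,
                                crs=crs, mask=mask))
    return grids[0] if len(grids) == 1 else grids


# ---------------------------------------------------------------------------
# Resampling

def _keys_weights(t: np.ndarray) -> np.ndarray:
    """Keys cubic-convolution weights (a = -0.5) for the 4 taps at offsets
    -1-t, -t, 1-t, 2-t given fractional position t in [0, 1)."""
    a = -0.5
    s = np.stack([1.0 + t, t, 1.0 - t, 2.0 - t])  # |distance| of each tap
    w = np.empty_like(s)
    inner = np.abs(s) <= 1
    w[inner] = ((a + 2) * np.abs(s[inner]) - (a + 3)) * s[inner] ** 2 + 1
    w[~inner] = a * (np.abs(s[~inner]) ** 3 - 5 * s[~inner] ** 2 + 8 * np.abs(s[~inner]) - 4)
    return w


def _cubic_convolution(values: np.ndarray, r: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Sample `values` at fractional positions (r, c) with Keys bicubic
    convolution; edge-replicated beyond the border."""
    padded = np.pad(values, 2, mode="edge")
    r0 = np.floor(r).astype(int)
    c0 = np.floor(c).astype(int)
    tr = r - r0
    tc = c - c0
    wr = _keys_weights(tr)  # (4, ...)
    wc = _keys_weights(tc)
    out = np.zeros(r.shape, dtype=np.float64)
    for i in range(4):
        row_idx = np.clip(r0 + i - 1 + 2, 0, padded.shape[0] - 1)
        acc = np.zeros(r.shape, dtype=np.float64)
        for j in range(4):
            col_idx = np.clip(c0 + j - 1 + 2, 0, padded.shape[1] - 1)
            acc += wc[j] * padded[row_idx, col_idx]
        out += wr[i] * acc
    return out


def resample_to_grid(src: RasterGrid, target: GridGeometry, kind: str,
                     crs: int | None = None) -> RasterGrid:
    """Resample `src` onto `target` geometry.

    ``kind='continuous'`` uses Cubic Convolution interpolation (Keys kernel,
    a=-0.5); ``kind='categorical'`` uses Nearest Neighbor, so output values
    are a subset of the input values.
    """
    if kind not in ("continuous", "categorical"):
        raise ValueError(f"unknown resampling kind {kind!r}")
    if crs is not None and crs != src.crs:
        raise ValueError("resampling does not reproject; CRSs must match")

    sg, tg = src.geometry, target
    # target pixel centers in source fractional index space
    rr, cc = np.meshgrid(np.arange(tg.rows), np.arange(tg.cols), indexing="ij")
    tx, ty = tg.pixel_center(rr, cc)
    fc = (tx - sg.x0) / sg.dx - 0.5
    fr = (ty - sg.y0) / sg.dy - 0.5
    if fr.max() < -0.5 or fr.min() > sg.rows - 0.5 or fc.max() < -0.5 or fc.min() > sg.cols - 0.5:
        raise ValueError("target grid does not overlap the source extent")

    if kind == "categorical":
        ri = np.clip(np.rint(fr).astype(int), 0, sg.rows - 1)
        ci = np.clip(np.rint(fc).astype(int), 0, sg.cols - 1)
        values = src.values[ri, ci]
        mask = src.mask[ri, ci]
    else:
        values = _cubic_convolution(src.values, fr, fc)
        # a target cell is nodata if its nearest source cell is
        ri = np.clip(np.rint(fr).astype(int), 0, sg.rows - 1)
        ci = np.clip(np.rint(fc).astype(int), 0, sg.cols - 1)
        mask = src.mask[ri, ci]
    return RasterGrid(values=np.where(mask, 0.0, values), geometry=tg, crs=src.crs, mask=mask)


def assert_coregistered(grids: Sequence[RasterGrid]) -> None:
    """Raise unless all grids share shape, geometry and CRS."""
    if len(grids) == 0:
        raise ValueError("no grids given")
    ref = grids[0]
    for i, g in enumerate(grids[1:], start=1):
        if g.shape != ref.shape:
            raise ValueError(f"grids 0 and {i} differ in shape: {ref.shape} vs {g.shape}")
        if not ref.geometry.approx_equal(g.geometry):
            raise ValueError(f"grids 0 and {i} differ in geometry: {ref.geometry} vs {g.geometry}")
        if g.crs != ref.crs:
            raise ValueError(f"grids 0 and {i} differ in CRS: {ref.crs} vs {g.crs}")
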