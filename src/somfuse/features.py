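"""Covariate assembly, image-combination enumeration, RFE selection, patches.

The model inputs are a :class:`FeatureTable` (samples x named covariates plus
the SOM target, in g/kg) for the random forest, and a :class:`PatchTensor`
of 7x7 neighborhoods per sample for the CNN. Multi-temporal image subsets
always contain the baseline acquisition date; with 7 dates this yields
C(6, m-1) subsets of size m and 64 subsets overall.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor

from .raster import RasterGrid, assert_coregistered

__all__ = [
    "FeatureTable", "PatchTensor", "Standardizer",
    "count_combinations", "enumerate_mmi", "rfe_select",
    "extract_patches", "extract_point_values", "one_hot_encode",
]


@dataclass
class FeatureTable:
    """Samples x named covariates plus the SOM target."""

    frame: pd.DataFrame                       # columns: sample_id, x, y, som, features...
    feature_names: list[str]
    feature_kinds: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        required = {"sample_id", "x", "y", "som"}
        missing = required - set(self.frame.columns)
        if missing:
            raise ValueError(f"FeatureTable frame lacks columns {sorted(missing)}")
        if len(set(self.feature_names)) != len(self.feature_names):
            raise ValueError("feature names must be unique")
        for name in self.feature_names:
            if name not in self.frame.columns:
                raise ValueError(f"feature column {name!r} absent from frame")
        if self.frame[self.feature_names + ["som"]].isna().any().any():
            raise ValueError("FeatureTable must have no missing values after assembly")

    @property
    def n_samples(self) -> int:
        return len(self.frame)

    @property
    def X(self) -> np.ndarray:
        return self.frame[self.feature_names].to_numpy(dtype=float)

    @property
    def y(self) -> np.ndarray:
        return self.frame["som"].to_numpy(dtype=float)

    def subset_features(self, names: Sequence[str]) -> "FeatureTable":
        names = list(names)
        cols = ["sample_id", "x", "y", "som"] + names
        kinds = {n: self.feature_kinds[n] for n in names if n in self.feature_kinds}
        return FeatureTable(self.frame[cols].copy(), names, kinds)

    def to_csv(self, path: str, kinds_path: str | None = None) -> None:
        self.frame.to_csv(path, index=False)
        if kinds_path:
            with open(kinds_path, "w") as fh:
                json.dump(self.feature_kinds, fh, indent=1)

    @classmethod
    def from_csv(cls, path: str, kinds_path: str | None = None) -> "FeatureTable":
        frame = pd.read_csv(path)
        features = [c for c in frame.columns if c not in ("sample_id", "x", "y", "som")]
        kinds = {}
        if kinds_path:
            with open(kinds_path) as fh:
                kinds = json.load(fh)
        return cls(frame, features, kinds)


@dataclass
class PatchTensor:
    """Per-sample 7x7xC windows, channel-aligned with a feature list."""

    patches: np.ndarray           # (n, window, window, C)
    channel_names: list[str]
    som: np.ndarray               # (n,)

    def __post_init__(self) -> None:
        if self.patches.ndim != 4:
            raise ValueError("patches must be (n, window, window, channels)")
        if self.patches.shape[3] != len(self.channel_names):
            raise ValueError("channel_names must align with the channel axis")
        if self.patches.shape[0] != len(self.som):
            raise ValueError("one target per patch required")

    @property
    def n_samples(self) -> int:
        return self.patches.shape[0]

    @property
    def center(self) -> np.ndarray:
        """(n, C) values at the patch centers."""
        m = self.patches.shape[1] // 2
        return self.patches[:, m, m, :]


def count_combinations(n: int, k: int) -> int:
    """Binomial coefficient C(n, k)."""
    if k < 0 or k > n:
        raise ValueError(f"require 0 <= k <= n, got n={n}, k={k}")
    return math.comb(n, k)


def enumerate_mmi(dates: Sequence, baseline, m: int) -> list[tuple]:
    """All m-date subsets that contain the baseline date.

    With |dates| = d there are C(d-1, m-1) subsets, returned in
    deterministic lexicographic order of the non-baseline dates.
    """
    dates = list(dates)
    if baseline not in dates:
        raise ValueError("baseline date not among dates")
    if not (1 <= m <= len(dates)):
        raise ValueError(f"m must be in [1, {len(dates)}]")
    others = sorted(d for d in dates if d != baseline)
    out = []
    for extra in combinations(others, m - 1):
        subset = tuple(sorted((baseline,) + extra))
        out.append(subset)
    return out


def rfe_select(table: FeatureTable, n_keep: int = 24, repeats: int = 10,
               seed: int = 0, n_estimators: int = 250, max_depth: int = 6
               ) -> pd.DataFrame:
    """Repeated recursive feature elimination with an RF ranker.

    Each repeat eliminates the least-important feature one at a time until
    ``n_keep`` remain. Features are ranked by their selection frequency
    across repeats, ties broken by mean elimination order (later elimination
    = more important). Returns a frame (feature, frequency, mean_rank, rank)
    sorted by rank; the top ``n_keep`` rows are the selected set.
    """
    names = list(table.feature_names)
    p = len(names)
    if n_keep > p:
        raise ValueError("n_keep exceeds the number of features")
    if table.n_samples < 20:
        raise ValueError("too few samples for RFE")
    X, y = table.X, table.y
    if n_keep == p:
        return pd.DataFrame({"feature": names, "frequency": 1.0,
                             "mean_rank": 0.0, "rank": np.arange(1, p + 1)})

    selected_counts = np.zeros(p)
    elim_order = np.zeros(p)  # higher = survived longer
    rng = np.random.default_rng(seed)
    for _ in range(repeats):
        rep_seed = int(rng.integers(0, 2**31 - 1))
        remaining = list(range(p))
        step = 0
        order = np.zeros(p)
        # eliminate all the way down to a full ranking; the survivors at the
        # n_keep threshold count toward the selection frequency
        while len(remaining) > 1:
            if len(remaining) == n_keep:
                selected_counts[remaining] += 1
            rf = RandomForestRegressor(n_estimators=n_estimators, max_depth=max_depth,
                                       random_state=rep_seed, n_jobs=1)
            rf.fit(X[:, remaining], y)
            worst = remaining[int(np.argmin(rf.feature_importances_))]
            order[worst] = step
            remaining.remove(worst)
            step += 1
        order[remaining[0]] = step
        if n_keep == 1:
            selected_counts[remaining] += 1
        elim_order += order

    freq = selected_counts / repeats
    mean_order = elim_order / repeats
    df = pd.DataFrame({"feature": names, "frequency": freq, "mean_rank": mean_order})
    df = df.sort_values(["frequency", "mean_rank", "feature"],
                        ascending=[False, False, True], kind="mergesort")
    df["rank"] = np.arange(1, p + 1)
    return df.reset_index(drop=True)


def extract_point_values(grids: dict[str, RasterGrid], x: np.ndarray, y: np.ndarray
                         ) -> tuple[pd.DataFrame, np.ndarray]:
    """Values of each named raster at the pixels containing the points.

    Returns (frame of feature columns, boolean keep-mask of samples whose
    pixel is valid in every raster). Points outside the extent raise.
    """
    names = list(grids)
    assert_coregistered([grids[n] for n in names])
    geom = grids[names[0]].geometry
    row, col = geom.locate(np.asarray(x, float), np.asarray(y, float))
    if (row < 0).any() or (row >= geom.rows).any() or (col < 0).any() or (col >= geom.cols).any():
        raise ValueError("sample point outside the raster extent")
    data = {}
    keep = np.ones(len(row), dtype=bool)
    for n in names:
        g = grids[n]
        data[n] = g.values[row, col]
        keep &= ~g.mask[row, col]
    return pd.DataFrame(data), keep


def extract_patches(grids: dict[str, RasterGrid], x: np.ndarray, y: np.ndarray,
                    som: np.ndarray, window: int = 7) -> PatchTensor:
    """7x7 windows centered on each sample's pixel, reflection-padded at edges.

    Channel order follows the dict insertion order of `grids`.
    """
    if window % 2 == 0:
        raise ValueError("window must be odd")
    names = list(grids)
    assert_coregistered([grids[n] for n in names])
    geom = grids[names[0]].geometry
    row, col = geom.locate(np.asarray(x, float), np.asarray(y, float))
    if (row < 0).any() or (row >= geom.rows).any() or (col < 0).any() or (col >= geom.cols).any():
        raise ValueError("sample point outside the raster extent")
    half = window // 2
    cube = np.stack([np.pad(grids[n].values, half, mode="symmetric") for n in names],
                    axis=-1)  # (rows+2h, cols+2h, C)
    patches = np.empty((len(row), window, window, len(names)))
    for i, (r, c) in enumerate(zip(row, col)):
        patches[i] = cube[r: r + window, c: c + window, :]
    return PatchTensor(patches=patches, channel_names=names,
                       som=np.asarray(som, dtype=float))


def one_hot_encode(frame: pd.DataFrame, column: str, kind: str | None = None,
                   kinds: dict[str, str] | None = None) -> tuple[pd.DataFrame, list[str]]:
    """Replace a categorical column with 0/1 indicator columns."""
    dummies = pd.get_dummies(frame[column], prefix=column).astype(float)
    out = pd.concat([frame.drop(columns=[column]), dummies], axis=1)
    new_names = list(dummies.columns)
    if kinds is not None and kind is not None:
        for n in new_names:
            kinds[n] = kind
    return out, new_names


class Standardizer:
    """Per-feature (or per-channel) z-scoring fit on training data only.

    Zero-variance features are left centered (scale 1) and recorded in
    ``degenerate``.
    """

    def __init__(self) -> None:
        self.mean_: np.ndarray | None = None
        self.scale_: np.ndarray | None = None
        self.degenerate: list[int] = []

    @staticmethod
    def _flat(data: np.ndarray) -> np.ndarray:
        # table (n, F) -> as-is; tensor (n, h, w, C) -> (n*h*w, C)
        if data.ndim == 2:
            return data
        return data.reshape(-1, data.shape[-1])

    def fit(self, data: np.ndarray) -> "Standardizer":
        flat = self._flat(np.asarray(data, dtype=float))
        self.mean_ = flat.mean(axis=0)
        sd = flat.std(axis=0)
        self.degenerate = list(np.flatnonzero(sd == 0))
        self.scale_ = np.where(sd == 0, 1.0, sd)
        return self

    def transform(self, data: np.ndarray) -> np.ndarray:
        if self.mean_ is None:
            raise RuntimeError("Standardizer not fitted")
        return (np.asarray(data, dtype=float) - self.mean_) / self.scale_

    def inverse_transform(self, data: np.ndarray) -> np.ndarray:
        if self.mean_ is None:
            raise RuntimeError("Standardizer not fitted")
        return np.asarray(data, dtype=float) * self.scale_ + self.mean_
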