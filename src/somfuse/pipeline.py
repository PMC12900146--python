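"""End-to-end experiment orchestration: fuse -> features -> select -> train
-> evaluate -> map -> report, from a single declarative config.

The pipeline operates on a synthetic scene (or on rasters loaded from
disk through :mod:`somfuse.raster`) and produces a machine-readable report
bundle: per model x variable-set accuracy, fusion-quality metrics, variable
importance, derived comparison statistics, and optional prediction /
uncertainty maps. All randomness flows from the config seed.

Variable sets follow the study design:

* ``Ev`` — environmental covariates only;
* ``Ev-Tn-Mm`` — environmental covariates + time-series NDVI phenology
  features + multi-temporal multispectral bands fused across dates.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .features import (FeatureTable, Standardizer, extract_patches,
                       extract_point_values, rfe_select)
from .fusion import FusionConfig, fuse_stack
from .models import (CnnSpec, EvalReport, RfSpec, cross_validate, derived_stats,
                     metrics, percent_lower, predict_map, train_rf,
                     variable_importance)
from .quality import QualityReport, quality_report
from .raster import RasterGrid
from .synthetic import SceneRecipe, SyntheticScene, draw_samples, make_scene
from .timeseries import per_pixel_features

logger = logging.getLogger("somfuse")

VARIABLE_SETS = ("Ev", "Ev-Tn-Mm")
FUSION_METHODS = ("lew_dwt", "traditional_dwt", "simple_splicing")

__all__ = ["VARIABLE_SETS", "FUSION_METHODS", "RunConfig", "FeatureBundle",
           "build_features", "assemble_tables", "run", "compare_fusions",
           "benchmark_config"]


@dataclass(frozen=True)
class RunConfig:
    recipe: SceneRecipe = field(default_factory=SceneRecipe)
    fusion: FusionConfig = field(default_factory=FusionConfig)
    fusion_method: str = "lew_dwt"
    variable_sets: tuple = VARIABLE_SETS
    models: tuple = ("rf", "cnn")
    folds: int = 10
    seed: int = 0
    sg_window: int = 7
    sg_order: int = 3
    rfe_n_keep: int | None = None      # None disables selection
    rfe_repeats: int = 10
    rf: RfSpec = field(default_factory=RfSpec)
    cnn: CnnSpec = field(default_factory=CnnSpec)
    patch_window: int = 7
    make_maps: bool = False

    def __post_init__(self) -> None:
        for vs in self.variable_sets:
            if vs not in VARIABLE_SETS:
                raise ValueError(f"unknown variable set {vs!r}; expected {VARIABLE_SETS}")
        for m in self.models:
            if m not in ("rf", "cnn"):
                raise ValueError(f"unknown model {m!r}")
        if self.fusion_method not in FUSION_METHODS:
            raise ValueError(f"unknown fusion method {self.fusion_method!r}")


@dataclass
class FeatureBundle:
    """Named feature rasters plus their categories, per variable set."""

    grids: dict[str, RasterGrid]
    kinds: dict[str, str]


def _fused_feature_grids(scene: SyntheticScene, method: str,
                         cfg: FusionConfig) -> tuple[dict, dict]:
    cfg = dataclasses.replace(cfg, baseline_index=scene.recipe.baseline_date_index)
    fused = fuse_stack(scene.stack, method=method, cfg=cfg)
    grids: dict[str, RasterGrid] = {}
    kinds: dict[str, str] = {}
    n = scene.recipe.n_dates
    for band, result in fused.items():
        if isinstance(result, list):  # simple splicing: one plane per date
            for d, g in enumerate(result):
                name = f"mmi_{band.lower()}_d{d}"
                grids[name] = g
                kinds[name] = "multitemporal multispectral"
        else:
            name = f"mmi{n}_{band.lower()}"
            grids[name] = result
            kinds[name] = "multitemporal multispectral"
    return grids, kinds


def build_features(scene: SyntheticScene, config: RunConfig,
                   fusion_method: str | None = None) -> dict[str, FeatureBundle]:
    """Assemble the feature rasters of each requested variable set."""
    method = fusion_method or config.fusion_method
    ev = FeatureBundle(grids=dict(scene.covariates),
                       kinds=dict(scene.covariate_kinds))
    bundles = {"Ev": ev}
    if "Ev-Tn-Mm" in config.variable_sets:
        tn_maps = per_pixel_features(
            scene.ndvi, window=config.sg_window, order=config.sg_order,
            samples_per_year=scene.recipe.samples_per_year)
        geom, crs = scene.som.geometry, scene.som.crs
        grids = dict(ev.grids)
        kinds = dict(ev.kinds)
        for name, plane in tn_maps.items():
            grids[name] = RasterGrid(values=plane, geometry=geom, crs=crs)
            kinds[name] = "time-series NDVI"
        mm_grids, mm_kinds = _fused_feature_grids(scene, method, config.fusion)
        grids.update(mm_grids)
        kinds.update(mm_kinds)
        bundles["Ev-Tn-Mm"] = FeatureBundle(grids=grids, kinds=kinds)
    return bundles


def assemble_tables(bundle: FeatureBundle, samples: pd.DataFrame,
                    patch_window: int = 7):
    """Point-extracted FeatureTable and patch tensor for one variable set.

    Samples falling on masked cells are dropped (with a logged count).
    """
    x = samples["x"].to_numpy(float)
    y = samples["y"].to_numpy(float)
    som = samples["som_g_per_kg"].to_numpy(float)
    values, keep = extract_point_values(bundle.grids, x, y)
    dropped = int((~keep).sum())
    if dropped:
        logger.info("dropped %d samples on masked cells", dropped)
    frame = pd.DataFrame({
        "sample_id": samples["sample_id"].to_numpy()[keep],
        "x": x[keep], "y": y[keep], "som": som[keep],
    })
    for name in bundle.grids:
        frame[name] = values[name].to_numpy()[keep]
    table = FeatureTable(frame.reset_index(drop=True), list(bundle.grids),
                         dict(bundle.kinds))
    patches = extract_patches(bundle.grids, x[keep], y[keep], som[keep],
                              window=patch_window)
    return table, patches


def benchmark_config(seed: int = 0) -> RunConfig:
    """The standard synthetic benchmark: a 200x200 scene, 500 samples with
    measurement noise at 25% of the SOM field's SD, 10-fold CV, and CNN
    training capped at 150 epochs (patience 25) to keep runs short."""
    recipe = SceneRecipe(rows=200, cols=200, n_samples=500,
                         measurement_noise_sd=0.25 * 2.42, seed=seed)
    return RunConfig(recipe=recipe, seed=seed,
                     cnn=CnnSpec(epochs=150, patience=25))


def run(config: RunConfig) -> dict:
    """Execute the full experiment; returns the report bundle as a dict."""
    scene = make_scene(config.recipe)
    samples = draw_samples(config.recipe, scene.som)
    logger.info("scene %dx%d, %d samples", config.recipe.rows, config.recipe.cols,
                len(samples))
    bundles = build_features(scene, config)

    report: dict = {
        "config": {"seed": config.seed, "folds": config.folds,
                   "fusion_method": config.fusion_method,
                   "variable_sets": list(config.variable_sets),
                   "models": list(config.models),
                   "n_samples": int(len(samples))},
        "evaluations": {},
    }

    # fusion quality against the baseline-date bands
    if "Ev-Tn-Mm" in config.variable_sets:
        base = scene.recipe.baseline_date_index
        reference = {name: scene.stack[(base, name)] for name in scene.stack.band_names}
        quality = {}
        for method in ("lew_dwt", "traditional_dwt"):
            fused = fuse_stack(scene.stack, method=method,
                               cfg=dataclasses.replace(config.fusion,
                                                       baseline_index=base))
            quality[method] = quality_report(fused, reference).to_dict()
        report["fusion_quality"] = quality

    tables = {}
    for vs in config.variable_sets:
        table, patches = assemble_tables(bundles[vs], samples,
                                         patch_window=config.patch_window)
        if config.rfe_n_keep is not None and vs == "Ev":
            ranking = rfe_select(table, n_keep=config.rfe_n_keep,
                                 repeats=config.rfe_repeats, seed=config.seed)
            selected = list(ranking["feature"][: config.rfe_n_keep])
            table = table.subset_features(selected)
            report["rfe"] = ranking.to_dict(orient="list")
        tables[vs] = (table, patches)
        for model in config.models:
            data = table if model == "rf" else patches
            spec = config.rf if model == "rf" else config.cnn
            ev_report = cross_validate(data, model=model, spec=spec,
                                       folds=config.folds, seed=config.seed)
            report["evaluations"][f"{model}/{vs}"] = ev_report.to_dict()
            logger.info("%s / %s: MAE %.3f RMSE %.3f R2 %.3f", model, vs,
                        ev_report.mae, ev_report.rmse, ev_report.r2)
            if config.make_maps:
                pred, unc = predict_map(ev_report.fold_models,
                                        bundles[vs].grids, model=model,
                                        window=config.patch_window)
                report.setdefault("maps", {})[f"{model}/{vs}"] = {
                    "prediction": pred, "uncertainty": unc}

    # derived comparison stats Ev -> Ev-Tn-Mm per model
    if set(config.variable_sets) >= {"Ev", "Ev-Tn-Mm"}:
        obs_mean = float(samples["som_g_per_kg"].mean())
        for model in config.models:
            a = report["evaluations"].get(f"{model}/Ev")
            b = report["evaluations"].get(f"{model}/Ev-Tn-Mm")
            if a and b:
                report.setdefault("derived", {})[model] = derived_stats(
                    a, b, observed_mean=obs_mean)

    # variable importance from an RF fit on the richest table
    if "rf" in config.models:
        vs = "Ev-Tn-Mm" if "Ev-Tn-Mm" in tables else "Ev"
        table = tables[vs][0]
        std = Standardizer().fit(table.X)
        frame = table.frame.copy()
        frame[table.feature_names] = std.transform(table.X)
        rf = train_rf(FeatureTable(frame, table.feature_names, table.feature_kinds),
                      config.rf, seed=config.seed)
        report["importance"] = variable_importance(
            rf, table.feature_names, table.feature_kinds).to_dict()
    return report


def compare_fusions(config: RunConfig, methods: tuple = FUSION_METHODS,
                    model: str = "rf") -> dict:
    """Train the same model on identical folds for each fusion strategy.

    Emits per-method pooled metrics plus the pairwise percent RMSE
    reduction table (rows = method kept, columns = method compared against).
    """
    if len(methods) < 2:
        raise ValueError("need at least two fusion methods to compare")
    scene = make_scene(config.recipe)
    samples = draw_samples(config.recipe, scene.som)
    results = {}
    for method in methods:
        bundle = build_features(scene, config, fusion_method=method)["Ev-Tn-Mm"]
        table, patches = assemble_tables(bundle, samples,
                                         patch_window=config.patch_window)
        data = table if model == "rf" else patches
        spec = config.rf if model == "rf" else config.cnn
        rep = cross_validate(data, model=model, spec=spec,
                             folds=config.folds, seed=config.seed)
        results[method] = {"mae": rep.mae, "rmse": rep.rmse, "r2": rep.r2}
        logger.info("fusion %s: RMSE %.3f R2 %.3f", method, rep.rmse, rep.r2)
    reduction = {
        m1: {m2: round(percent_lower(results[m2]["rmse"], results[m1]["rmse"]), 1)
             for m2 in methods}
        for m1 in methods
    }
    return {"model": model, "metrics": results, "rmse_reduction_pct": reduction}
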