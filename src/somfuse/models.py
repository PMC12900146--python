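"""RF / CNN SOM regressors, 10-fold cross-validation, derived statistics.

Accuracy metrics are MAE = mean|P - Q|, RMSE = sqrt(mean (P - Q)^2) and
R^2 = 1 - SS_res / SS_tot with SS_tot about the observed mean (negative
values possible and not clamped). Cross-validation uses seeded fold
assignment; standardization is fitted on the training folds only, and the
pooled metrics are computed on the concatenated out-of-fold predictions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.ensemble import RandomForestRegressor
from sklearn.model_selection import GridSearchCV, KFold

from .cnn import CnnRegressor
from .features import FeatureTable, PatchTensor, Standardizer
from .raster import RasterGrid, assert_coregistered

__all__ = [
    "RF_N_ESTIMATORS_GRID", "RF_MAX_DEPTH_GRID", "RF_DEFAULTS", "RfSpec", "CnnSpec",
    "EvalReport", "ImportanceReport", "metrics", "relative_change", "percent_lower",
    "rmse_mae_ratio", "relative_rmse", "cv_percent", "derived_stats",
    "train_rf", "train_cnn", "cross_validate", "variable_importance", "predict_map",
]

RF_N_ESTIMATORS_GRID = (100, 150, 200, 250, 300, 350)
RF_MAX_DEPTH_GRID = (3, 4, 5, 6, 7, 8)
RF_DEFAULTS = {"n_estimators": 250, "max_depth": 6}


@dataclass(frozen=True)
class RfSpec:
    n_estimators: int = RF_DEFAULTS["n_estimators"]
    max_depth: int = RF_DEFAULTS["max_depth"]
    grid_search: bool = False


@dataclass(frozen=True)
class CnnSpec:
    lr: float = 1e-3
    batch_size: int = 16
    epochs: int = 300
    patience: int = 30


# ---------------------------------------------------------------------------
# Metrics and derived reporting statistics

def metrics(observed: Sequence[float], predicted: Sequence[float]):
    """(MAE, RMSE, R^2) of predictions against observations (g/kg)."""
    q = np.asarray(observed, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if q.shape != p.shape or q.ndim != 1 or len(q) < 2:
        raise ValueError("observed/predicted must be equal-length vectors of length >= 2")
    err = p - q
    mae = float(np.mean(np.abs(err)))
    rmse = float(np.sqrt(np.mean(err * err)))
    ss_tot = float(np.sum((q - q.mean()) ** 2))
    r2 = float("nan") if ss_tot == 0 else float(1.0 - np.sum(err * err) / ss_tot)
    return mae, rmse, r2


def relative_change(a: float, b: float) -> float:
    """100 * (b - a) / a : percent change from a to b."""
    if a == 0:
        raise ZeroDivisionError("relative change from a zero base")
    return 100.0 * (b - a) / a


def percent_lower(a: float, b: float) -> float:
    """100 * (a - b) / a : how much lower b is than a, in percent."""
    if a == 0:
        raise ZeroDivisionError("percent reduction from a zero base")
    return 100.0 * (a - b) / a


def rmse_mae_ratio(rmse: float, mae: float) -> float:
    if mae == 0:
        raise ZeroDivisionError("RMSE/MAE ratio with zero MAE")
    return rmse / mae


def relative_rmse(rmse: float, mean_observed: float) -> float:
    """100 * RMSE / mean(observed), percent."""
    if mean_observed == 0:
        raise ZeroDivisionError("relative RMSE with zero mean")
    return 100.0 * rmse / mean_observed


def cv_percent(sd: float, mean: float) -> float:
    """Coefficient of variation, percent."""
    if mean == 0:
        raise ZeroDivisionError("CV with zero mean")
    return 100.0 * sd / mean


def derived_stats(base: dict, improved: dict, observed_mean: float | None = None) -> dict:
    """Derived reporting table comparing two metric dicts {mae, rmse, r2}."""
    out = {
        "r2_relative_change_pct": round(relative_change(base["r2"], improved["r2"]), 1),
        "mae_reduction_pct": round(percent_lower(base["mae"], improved["mae"]), 1),
        "rmse_reduction_pct": round(percent_lower(base["rmse"], improved["rmse"]), 1),
        "rmse_mae_ratio_base": round(rmse_mae_ratio(base["rmse"], base["mae"]), 2),
        "rmse_mae_ratio_improved": round(rmse_mae_ratio(improved["rmse"], improved["mae"]), 2),
    }
    if observed_mean is not None:
        out["relative_rmse_pct"] = round(relative_rmse(improved["rmse"], observed_mean), 1)
    return out


# ---------------------------------------------------------------------------
# Reports

@dataclass
class EvalReport:
    """Pooled and per-fold accuracy of one model on one feature set."""

    mae: float
    rmse: float
    r2: float
    fold_metrics: list[dict] = field(default_factory=list)
    oof_predictions: np.ndarray | None = None
    fold_assignment: np.ndarray | None = None
    seed: int | None = None

    def to_dict(self) -> dict:
        return {
            "mae": self.mae, "rmse": self.rmse, "r2": self.r2,
            "folds": self.fold_metrics, "seed": self.seed,
        }


@dataclass
class ImportanceReport:
    """Relative feature importances (%) and category aggregates (%)."""

    per_feature: dict[str, float]
    per_category: dict[str, float]

    def to_dict(self) -> dict:
        return {"per_feature": dict(self.per_feature),
                "per_category": dict(self.per_category)}


# ---------------------------------------------------------------------------
# Training

def train_rf(table: FeatureTable, spec: RfSpec = RfSpec(), seed: int = 0
             ) -> RandomForestRegressor:
    """Fit a seeded random forest; with grid_search, an inner CV picks
    (n_estimators, max_depth) from the standard grids."""
    X, y = table.X, table.y
    if spec.grid_search:
        search = GridSearchCV(
            RandomForestRegressor(random_state=seed, n_jobs=1),
            {"n_estimators": list(RF_N_ESTIMATORS_GRID),
             "max_depth": list(RF_MAX_DEPTH_GRID)},
            cv=5, scoring="neg_mean_squared_error", n_jobs=1)
        search.fit(X, y)
        return search.best_estimator_
    rf = RandomForestRegressor(n_estimators=spec.n_estimators, max_depth=spec.max_depth,
                               random_state=seed, n_jobs=1)
    rf.fit(X, y)
    return rf


def train_cnn(patches: PatchTensor | np.ndarray, y: np.ndarray | None = None,
              spec: CnnSpec = CnnSpec(), seed: int = 0) -> CnnRegressor:
    """Fit the shallow CNN on (pre-standardized) 7x7xC patches."""
    if isinstance(patches, PatchTensor):
        x, y = patches.patches, patches.som
    else:
        x = np.asarray(patches, dtype=float)
        if y is None:
            raise ValueError("y required when passing a raw patch array")
    model = CnnRegressor(n_channels=x.shape[3], seed=seed, lr=spec.lr,
                         batch_size=spec.batch_size, epochs=spec.epochs,
                         patience=spec.patience, input_size=x.shape[1])
    model.fit(x, y)
    return model


# ---------------------------------------------------------------------------
# Cross-validation

def _fit_predict(model_kind, spec, X_train, y_train, X_test, seed):
    std = Standardizer().fit(X_train)
    Xtr = std.transform(X_train)
    Xte = std.transform(X_test)
    if model_kind == "rf":
        flat_tr = Xtr if Xtr.ndim == 2 else Xtr.reshape(len(Xtr), -1)
        flat_te = Xte if Xte.ndim == 2 else Xte.reshape(len(Xte), -1)
        rf = RandomForestRegressor(n_estimators=spec.n_estimators,
                                   max_depth=spec.max_depth, random_state=seed, n_jobs=1)
        rf.fit(flat_tr, y_train)
        return rf.predict(flat_te), (rf, std)
    model = CnnRegressor(n_channels=Xtr.shape[3], seed=seed, lr=spec.lr,
                         batch_size=spec.batch_size, epochs=spec.epochs,
                         patience=spec.patience, input_size=Xtr.shape[1])
    model.fit(Xtr, y_train)
    return model.predict(Xte), (model, std)


def cross_validate(data: FeatureTable | PatchTensor, model: str = "rf",
                   spec: RfSpec | CnnSpec | None = None, folds: int = 10,
                   seed: int = 0) -> EvalReport:
    """K-fold cross-validation with seeded folds and per-fold standardization.

    ``model`` is ``'rf'`` (tabular) or ``'cnn'`` (patches; a tabular input
    is rejected). Returns pooled metrics on the concatenated out-of-fold
    predictions, fold-level metrics, and the fitted fold models (stored on
    the report's ``fold_models`` attribute for prediction/uncertainty maps).
    """
    if model not in ("rf", "cnn"):
        raise ValueError(f"unknown model {model!r}")
    if spec is None:
        spec = RfSpec() if model == "rf" else CnnSpec()
    if isinstance(data, FeatureTable):
        X, y = data.X, data.y
    elif isinstance(data, PatchTensor):
        X, y = data.patches, data.som
    else:
        raise TypeError("data must be a FeatureTable or PatchTensor")
    if model == "cnn" and X.ndim != 4:
        raise ValueError("the CNN requires patch input")
    n = len(y)
    if folds > n:
        raise ValueError("more folds than samples")

    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    oof = np.empty(n)
    assignment = np.empty(n, dtype=int)
    fold_metrics = []
    fold_models = []
    for k, (tr, te) in enumerate(kf.split(X)):
        pred, fitted = _fit_predict(model, spec, X[tr], y[tr], X[te], seed + k)
        oof[te] = pred
        assignment[te] = k
        mae, rmse, r2 = metrics(y[te], pred)
        fold_metrics.append({"fold": k, "mae": mae, "rmse": rmse, "r2": r2})
        fold_models.append(fitted)
    mae, rmse, r2 = metrics(y, oof)
    report = EvalReport(mae=mae, rmse=rmse, r2=r2, fold_metrics=fold_metrics,
                        oof_predictions=oof, fold_assignment=assignment, seed=seed)
    report.fold_models = fold_models
    return report


# ---------------------------------------------------------------------------
# Importance and mapping

def variable_importance(rf: RandomForestRegressor, feature_names: Sequence[str],
                        feature_kinds: dict[str, str] | None = None) -> ImportanceReport:
    """Impurity-based importances as percentages, plus category shares."""
    if not hasattr(rf, "feature_importances_"):
        raise ValueError("model is not a fitted random forest")
    imp = np.asarray(rf.feature_importances_, dtype=float)
    if len(imp) != len(feature_names):
        raise ValueError("feature name count does not match the fitted model")
    total = imp.sum()
    if total == 0:
        raise ValueError("all importances are zero")
    pct = 100.0 * imp / total
    per_feature = {n: float(v) for n, v in zip(feature_names, pct)}
    per_category: dict[str, float] = {}
    kinds = feature_kinds or {}
    for name, v in per_feature.items():
        cat = kinds.get(name, "other")
        per_category[cat] = per_category.get(cat, 0.0) + v
    return ImportanceReport(per_feature=per_feature, per_category=per_category)


def predict_map(fold_models: list, grids: dict[str, RasterGrid], model: str = "rf",
                window: int = 7, batch: int = 4096):
    """Per-pixel prediction and uncertainty maps from the CV-fold models.

    Prediction = mean across fold models; uncertainty = standard deviation
    across fold models. Channel order follows `grids` insertion order and
    must match the training feature order. Pixels masked in any input are
    masked in the output.
    """
    names = list(grids)
    glist = [grids[n] for n in names]
    assert_coregistered(glist)
    template = glist[0]
    rows, cols = template.shape
    mask = np.logical_or.reduce([g.mask for g in glist])

    if model == "rf":
        X = np.stack([g.values.ravel() for g in glist], axis=1)
        preds = []
        for rf, std in fold_models:
            preds.append(rf.predict(std.transform(X)))
        stack = np.stack(preds)
    elif model == "cnn":
        half = window // 2
        cube = np.stack([np.pad(g.values, half, mode="symmetric") for g in glist], axis=-1)
        view = np.lib.stride_tricks.sliding_window_view(cube, (window, window), axis=(0, 1))
        patches = view.transpose(0, 1, 3, 4, 2).reshape(-1, window, window, len(names))
        stack = np.empty((len(fold_models), rows * cols))
        for i, (net, std) in enumerate(fold_models):
            out = np.empty(rows * cols)
            for start in range(0, rows * cols, batch):
                out[start:start + batch] = net.predict(std.transform(patches[start:start + batch]))
            stack[i] = out
    else:
        raise ValueError(f"unknown model {model!r}")

    pred = stack.mean(axis=0).reshape(rows, cols)
    unc = stack.std(axis=0).reshape(rows, cols)
    pred_grid = template.with_values(np.where(mask, 0.0, pred), mask=mask.copy())
    unc_grid = template.with_values(np.where(mask, 0.0, unc), mask=mask.copy())
    return pred_grid, unc_grid
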