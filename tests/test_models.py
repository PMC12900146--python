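"""Accuracy metrics, derived statistics, cross-validation, RF, importance."""

import numpy as np
import pandas as pd
import pytest

from somfuse.features import FeatureTable
from somfuse.models import (EvalReport, RfSpec, cross_validate, cv_percent,
                            derived_stats, metrics, percent_lower, predict_map,
                            relative_change, relative_rmse, rmse_mae_ratio,
                            train_rf, variable_importance)


def _table(X, y, kinds=None, names=None):
    names = names or [f"f{i}" for i in range(X.shape[1])]
    frame = pd.DataFrame(X, columns=names)
    frame.insert(0, "som", y)
    frame.insert(0, "y", 0.0)
    frame.insert(0, "x", 0.0)
    frame.insert(0, "sample_id", np.arange(len(y)))
    return FeatureTable(frame, names, kinds or {})


class TestMetrics:
    def test_perfect_prediction(self):
        assert metrics([1, 2, 3], [1, 2, 3]) == (0.0, 0.0, 1.0)

    def test_mean_predictor_gives_zero_r2(self):
        q = np.array([1.0, 2.0, 3.0, 6.0])
        _, _, r2 = metrics(q, np.full(4, q.mean()))
        assert r2 == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_example(self):
        mae, rmse, r2 = metrics([0.0, 0.0, 4.0], [1.0, 1.0, 1.0])
        assert mae == pytest.approx(5 / 3, abs=1e-4)
        assert rmse == pytest.approx(1.9149, abs=1e-4)
        assert r2 == pytest.approx(-0.03125, abs=1e-5)

    def test_rmse_at_least_mae(self, rng):
        for _ in range(20):
            q = rng.normal(size=10)
            p = rng.normal(size=10)
            mae, rmse, _ = metrics(q, p)
            assert rmse >= mae - 1e-12

    def test_zero_variance_observed_gives_nan_r2(self):
        _, _, r2 = metrics([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])
        assert np.isnan(r2)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            metrics([1, 2], [1, 2, 3])


class TestDerivedStats:
    def test_printed_relative_enhancement(self):
        assert round(relative_change(0.47, 0.53), 1) == 12.8

    def test_printed_ratio(self):
        assert round(rmse_mae_ratio(1.29, 0.91), 2) == 1.42

    def test_no_change_is_zero(self):
        assert relative_change(0.62, 0.62) == 0.0
        assert percent_lower(1.5, 1.5) == 0.0

    def test_relative_rmse_and_cv(self):
        assert relative_rmse(1.29, 20.12) == pytest.approx(6.41, abs=0.01)
        assert round(cv_percent(2.42, 20.12)) == 12

    def test_zero_base_rejected(self):
        for fn in (relative_change, percent_lower):
            with pytest.raises(ZeroDivisionError):
                fn(0.0, 1.0)

    def test_table_assembly(self):
        out = derived_stats({"mae": 1.28, "rmse": 1.59, "r2": 0.47},
                            {"mae": 1.18, "rmse": 1.52, "r2": 0.53},
                            observed_mean=20.12)
        assert out["r2_relative_change_pct"] == 12.8
        assert out["mae_reduction_pct"] == 7.8
        assert out["rmse_reduction_pct"] == 4.4
        assert out["relative_rmse_pct"] == 7.6


class TestCrossValidation:
    def test_same_seed_identical_reports(self, rng):
        X = rng.standard_normal((60, 3))
        y = X[:, 0] + rng.normal(0, 0.1, 60)
        t = _table(X, y)
        spec = RfSpec(n_estimators=20, max_depth=4)
        a = cross_validate(t, "rf", spec, folds=5, seed=3)
        b = cross_validate(t, "rf", spec, folds=5, seed=3)
        np.testing.assert_array_equal(a.fold_assignment, b.fold_assignment)
        np.testing.assert_allclose(a.oof_predictions, b.oof_predictions)
        assert a.rmse == b.rmse

    def test_strong_signal_recovered(self, rng):
        n = 300
        X = rng.standard_normal((n, 2))
        y = 5.0 + 2.0 * X[:, 0]
        rep = cross_validate(_table(X, y), "rf", RfSpec(n_estimators=50),
                             folds=5, seed=0)
        assert rep.r2 > 0.9

    def test_pure_noise_gives_low_r2(self, rng):
        n = 200
        X = rng.standard_normal((n, 3))
        y = rng.standard_normal(n)
        rep = cross_validate(_table(X, y), "rf", RfSpec(n_estimators=50),
                             folds=5, seed=0)
        assert rep.r2 <= 0.1

    def test_fold_count_and_report_shape(self, rng):
        X = rng.standard_normal((40, 2))
        t = _table(X, X[:, 0])
        rep = cross_validate(t, "rf", RfSpec(n_estimators=10), folds=4, seed=0)
        assert len(rep.fold_metrics) == 4
        assert sorted(np.unique(rep.fold_assignment)) == [0, 1, 2, 3]
        assert rep.rmse >= rep.mae

    def test_too_many_folds_rejected(self, rng):
        t = _table(rng.standard_normal((5, 2)), np.arange(5.0))
        with pytest.raises(ValueError):
            cross_validate(t, "rf", folds=10)

    def test_unknown_model_rejected(self, rng):
        t = _table(rng.standard_normal((20, 2)), np.arange(20.0))
        with pytest.raises(ValueError):
            cross_validate(t, "svm")


class TestTrainRf:
    def test_deterministic_predictions(self, rng):
        X = rng.standard_normal((80, 3))
        y = X[:, 1] * 2
        t = _table(X, y)
        a = train_rf(t, RfSpec(n_estimators=30), seed=5).predict(X)
        b = train_rf(t, RfSpec(n_estimators=30), seed=5).predict(X)
        np.testing.assert_array_equal(a, b)

    def test_grid_search_picks_from_grids(self, rng):
        from somfuse.models import RF_MAX_DEPTH_GRID, RF_N_ESTIMATORS_GRID
        X = rng.standard_normal((60, 2))
        y = X[:, 0] + rng.normal(0, 0.2, 60)
        rf = train_rf(_table(X, y), RfSpec(grid_search=True), seed=0)
        assert rf.n_estimators in RF_N_ESTIMATORS_GRID
        assert rf.max_depth in RF_MAX_DEPTH_GRID


class TestImportance:
    def test_single_feature_gets_everything(self, rng):
        X = rng.standard_normal((60, 1))
        t = _table(X, 3 * X[:, 0], names=["only"])
        rf = train_rf(t, RfSpec(n_estimators=20), seed=0)
        rep = variable_importance(rf, ["only"], {"only": "soil"})
        assert rep.per_feature["only"] == pytest.approx(100.0)
        assert rep.per_category["soil"] == pytest.approx(100.0)

    def test_both_levels_sum_to_100(self, rng):
        X = rng.standard_normal((100, 5))
        y = X[:, 0] + 0.5 * X[:, 3] + rng.normal(0, 0.1, 100)
        kinds = {"f0": "soil", "f1": "climate", "f2": "climate",
                 "f3": "vegetation", "f4": "soil"}
        t = _table(X, y, kinds=kinds)
        rf = train_rf(t, RfSpec(n_estimators=30), seed=0)
        rep = variable_importance(rf, t.feature_names, kinds)
        assert sum(rep.per_feature.values()) == pytest.approx(100.0, abs=1e-9)
        assert sum(rep.per_category.values()) == pytest.approx(100.0, abs=1e-9)

    def test_driver_ranked_first(self, rng):
        n = 200
        X = rng.standard_normal((n, 4))
        y = 4.0 * X[:, 2] + rng.normal(0, 0.1, n)
        t = _table(X, y)
        rf = train_rf(t, RfSpec(n_estimators=50), seed=0)
        rep = variable_importance(rf, t.feature_names)
        assert max(rep.per_feature, key=rep.per_feature.get) == "f2"

    def test_unfitted_model_rejected(self):
        from sklearn.ensemble import RandomForestRegressor
        with pytest.raises(ValueError):
            variable_importance(RandomForestRegressor(), ["a"])


class TestPredictMap:
    def _fold_models(self, rng, grids, y_fn, n_folds=3):
        from somfuse.features import Standardizer
        from sklearn.ensemble import RandomForestRegressor
        names = list(grids)
        X = np.stack([grids[n].values.ravel() for n in names], axis=1)
        y = y_fn(X)
        models = []
        for k in range(n_folds):
            std = Standardizer().fit(X)
            rf = RandomForestRegressor(n_estimators=10, random_state=k)
            rf.fit(std.transform(X), y)
            models.append((rf, std))
        return models

    def test_identical_fold_models_zero_uncertainty(self, rng, grid_factory):
        grids = {"a": grid_factory(rng.random((6, 6)))}
        from somfuse.features import Standardizer
        from sklearn.ensemble import RandomForestRegressor
        X = grids["a"].values.reshape(-1, 1)
        std = Standardizer().fit(X)
        rf = RandomForestRegressor(n_estimators=5, random_state=0)
        rf.fit(std.transform(X), X[:, 0] * 2)
        pred, unc = predict_map([(rf, std)] * 4, grids, model="rf")
        np.testing.assert_allclose(unc.values, 0.0, atol=1e-12)

    def test_constant_inputs_give_constant_map(self, rng, grid_factory):
        grids = {"a": grid_factory(np.full((5, 5), 2.0)),
                 "b": grid_factory(np.full((5, 5), -1.0))}
        models = self._fold_models(rng, grids, lambda X: np.full(len(X), 20.0))
        pred, _ = predict_map(models, grids, model="rf")
        assert np.ptp(pred.values) == pytest.approx(0.0, abs=1e-9)

    def test_masked_input_masks_output(self, rng, grid_factory):
        mask = np.zeros((5, 5), dtype=bool)
        mask[0, 0] = True
        grids = {"a": grid_factory(rng.random((5, 5)), mask=mask)}
        models = self._fold_models(rng, grids, lambda X: X[:, 0])
        pred, unc = predict_map(models, grids, model="rf")
        assert pred.mask[0, 0] and unc.mask[0, 0]
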