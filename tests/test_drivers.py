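"""VIF screening, boosted regression, SHAP attribution, PDP, and thresholds."""

import numpy as np
import pandas as pd
import pytest

from ecovuln.drivers import (
    SMALL_GRID,
    detect_threshold,
    partial_dependence,
    per_ecosystem_analysis,
    run_driver_analysis,
    shap_attribution,
    train_model,
    vif_screen,
)
from ecovuln.synthetic import DriverSpec, default_driver_spec, generate_driver_table

TINY_GRID = {"n_estimators": [150], "max_depth": [3], "learning_rate": [0.1]}


@pytest.fixture(scope="module")
def fitted():
    """One fitted model on the default planted table, shared across tests."""
    X, y, truth = generate_driver_table(default_driver_spec(), 2000, seed=11)
    retained, report = vif_screen(X)
    model, metrics = train_model(X[retained], y, grid=TINY_GRID, seed=11)
    return X, y, truth, retained, model, metrics


class TestVifScreen:
    def test_orthogonal_features_all_retained(self, rng):
        X = pd.DataFrame(rng.standard_normal((500, 5)), columns=list("abcde"))
        retained, report = vif_screen(X)
        assert retained == list("abcde")
        assert all(v < 1.2 for v in report[0]["vifs"].values())

    def test_duplicated_feature_drops_exactly_one(self, rng):
        x = rng.standard_normal(400)
        X = pd.DataFrame({"a": x, "b": x.copy(), "c": rng.standard_normal(400)})
        retained, _ = vif_screen(X)
        assert sorted(retained) in (["a", "c"], ["b", "c"])

    def test_planted_pair_dropped_and_remainder_clean(self):
        import statsmodels.api as sm

        spec = DriverSpec(collinear_pairs=(("TEM", "TMX", 0.999),))
        X, _, _ = generate_driver_table(spec, 1000, seed=2)
        retained, _ = vif_screen(X)
        assert len({"TEM", "TMX"} & set(retained)) == 1
        # Independent statsmodels-based VIF recomputation on the retained set.
        Xr = X[retained].to_numpy()
        for j in range(Xr.shape[1]):
            others = sm.add_constant(np.delete(Xr, j, axis=1))
            r2 = sm.OLS(Xr[:, j], others).fit().rsquared
            assert 1.0 / (1.0 - r2) < 10.0

    def test_idempotent(self):
        X, _, _ = generate_driver_table(default_driver_spec(), 800, seed=3)
        retained, _ = vif_screen(X)
        retained2, _ = vif_screen(X[retained])
        assert retained2 == retained

    def test_needs_enough_samples(self):
        X = pd.DataFrame(np.eye(3), columns=list("abc"))
        with pytest.raises(ValueError):
            vif_screen(X)


class TestTrainModel:
    def test_learnable_signal(self, rng):
        X = pd.DataFrame({"x": rng.uniform(0, 10, 2000),
                          "z": rng.uniform(0, 1, 2000)})
        y = np.sin(X["x"].to_numpy())
        model, metrics = train_model(X, y, grid=TINY_GRID, seed=0)
        assert metrics["r2"] >= 0.99

    def test_pure_noise_has_no_skill(self, rng):
        X = pd.DataFrame(rng.standard_normal((1500, 3)), columns=list("abc"))
        y = rng.standard_normal(1500)
        _, metrics = train_model(X, y, grid=TINY_GRID, seed=0)
        assert metrics["r2"] <= 0.1

    def test_planted_effects_fit_well(self, fitted):
        _, _, _, _, _, metrics = fitted
        assert metrics["r2"] >= 0.8
        assert metrics["rmse"] == pytest.approx(np.sqrt(metrics["mse"]), abs=1e-10)
        assert metrics["n_train"] == 1600 and metrics["n_test"] == 400

    def test_degenerate_target_rejected(self, rng):
        X = pd.DataFrame(rng.standard_normal((600, 2)), columns=list("ab"))
        with pytest.raises(ValueError, match="degenerate"):
            train_model(X, np.ones(600), grid=TINY_GRID)


class TestShap:
    def test_additivity(self, fitted):
        X, _, _, retained, model, _ = fitted
        shap, base, _ = shap_attribution(model, X[retained])
        pred = model.predict(X[retained])
        assert np.max(np.abs(base + shap.sum(axis=1) - pred)) < 1e-4

    def test_importance_sums_to_100_and_flat_feature_near_zero(self, fitted):
        X, _, truth, retained, model, _ = fitted
        _, _, imp = shap_attribution(model, X[retained])
        assert imp.sum() == pytest.approx(100.0, abs=1e-6)
        flat = [f for f in retained if truth["effects"][f][0] == "flat"]
        assert imp[flat].max() < 5.0

    def test_importance_ratio_tracks_planted_effect_sizes(self):
        # Two orthogonal linear effects with slope ratio 3:1.
        ratios = []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            X = pd.DataFrame({"big": rng.uniform(-1, 1, 2000),
                              "small": rng.uniform(-1, 1, 2000)})
            y = 3.0 * X["big"].to_numpy() + 1.0 * X["small"].to_numpy()
            y = y + rng.normal(0, 0.1, 2000)
            model, _ = train_model(X, y, grid=TINY_GRID, seed=seed)
            _, _, imp = shap_attribution(model, X)
            ratios.append(imp["big"] / imp["small"])
        assert all(2.0 <= r <= 4.5 for r in ratios)

    def test_permuting_columns_permutes_importances(self, fitted):
        X, y, _, retained, _, _ = fitted
        perm = list(reversed(retained))
        m1, _ = train_model(X[retained], y, grid=TINY_GRID, seed=0)
        m2, _ = train_model(X[perm], y, grid=TINY_GRID, seed=0)
        _, _, imp1 = shap_attribution(m1, X[retained])
        _, _, imp2 = shap_attribution(m2, X[perm])
        assert np.allclose(imp1.sort_index().values, imp2.sort_index().values, atol=1.0)

    def test_feature_mismatch_rejected(self, fitted):
        X, _, _, retained, model, _ = fitted
        with pytest.raises(ValueError, match="feature names"):
            shap_attribution(model, X[list(reversed(retained))])


class TestPartialDependence:
    def test_single_split_model_gives_step_curve(self, rng):
        import xgboost as xgb

        X = pd.DataFrame({"x": rng.uniform(0, 10, 3000)})
        y = (X["x"] > 5).astype(float)
        model = xgb.XGBRegressor(n_estimators=1, max_depth=1, learning_rate=1.0,
                                 base_score=0.5, n_jobs=1)
        model.fit(X, y)
        gx, gy = partial_dependence(model, X, "x", grid_size=50)
        jumps = np.abs(np.diff(gy))
        assert np.count_nonzero(jumps > 0.1) == 1
        assert abs(gx[np.argmax(jumps)] - 5.0) < 0.5

    def test_additive_identity_response(self, rng):
        X = pd.DataFrame({"x": rng.uniform(0, 10, 3000),
                          "z": rng.uniform(0, 10, 3000)})
        y = X["x"].to_numpy().copy()
        model, _ = train_model(X, y, grid=TINY_GRID, seed=1)
        gx, gy = partial_dependence(model, X, "x")
        slope = np.polyfit(gx[5:-5], gy[5:-5], 1)[0]
        assert slope == pytest.approx(1.0, abs=0.1)

    def test_at_means_agrees_with_averaged_for_additive_model(self, rng):
        X = pd.DataFrame({"x": rng.uniform(0, 10, 3000),
                          "z": rng.uniform(0, 10, 3000)})
        y = X["x"].to_numpy() + 0.5 * X["z"].to_numpy()
        model, _ = train_model(X, y, grid=TINY_GRID, seed=1)
        gx, y1 = partial_dependence(model, X, "x", mode="at_means")
        _, y2 = partial_dependence(model, X, "x", mode="averaged")
        # Curves agree up to a constant offset for an additive fit.
        assert np.std((y1 - y1.mean()) - (y2 - y2.mean())) < 0.05 * y.std()

    def test_constant_feature_rejected(self, fitted, rng):
        X = pd.DataFrame({"x": rng.uniform(0, 1, 600), "c": np.ones(600)})
        model, _ = train_model(X, X["x"].to_numpy(), grid=TINY_GRID, seed=0)
        with pytest.raises(ValueError, match="constant"):
            partial_dependence(model, X, "c")


class TestDetectThreshold:
    def test_clean_step_at_79(self):
        gx = np.linspace(50, 110, 60)
        gy = np.where(gx < 79, 1.0, 0.0)
        th = detect_threshold(gx, gy)
        assert th and abs(th[0] - 79.0) <= (gx[1] - gx[0]) + 1e-9

    def test_linear_curve_yields_nothing(self):
        gx = np.linspace(0, 1, 40)
        assert detect_threshold(gx, 2.0 * gx + 1.0) == []

    def test_flat_curve_yields_nothing(self):
        gx = np.linspace(0, 1, 40)
        assert detect_threshold(gx, np.zeros(40)) == []

    def test_too_short_curve_rejected(self):
        with pytest.raises(ValueError):
            detect_threshold(np.arange(5.0), np.arange(5.0))

    def test_end_to_end_sm_plateau_recovery(self):
        # Full generate -> screen -> train -> pdp -> detect chain; the soil
        # moisture step planted at 79 mm must be recovered within 5%.
        hits = 0
        for seed in range(3):
            X, y, truth = generate_driver_table(default_driver_spec(), 3000, seed=seed)
            analysis = run_driver_analysis(X, y, grid=TINY_GRID, seed=seed)
            assert "SM" in analysis.thresholds
            th = analysis.thresholds["SM"]
            hits += any(abs(t - 79.0) <= 0.05 * 79.0 for t in th)
        assert hits >= 2


class TestPerEcosystem:
    def test_identical_tables_identical_outputs(self):
        X, y, _ = generate_driver_table(default_driver_spec(), 800, seed=6)
        res = per_ecosystem_analysis(
            {"grassland": (X, y), "forest": (X.copy(), y.copy())},
            grid=TINY_GRID, seed=6, pdp_features=1,
        )
        g, f = res["grassland"], res["forest"]
        assert g.retained_features == f.retained_features
        assert np.allclose(g.importance_percent.values, f.importance_percent.values)

    def test_small_class_skipped_with_flag(self):
        X, y, _ = generate_driver_table(default_driver_spec(), 800, seed=6)
        with pytest.warns(UserWarning, match="skipped"):
            res = per_ecosystem_analysis({"wetland": (X.head(100), y[:100])})
        assert res["wetland"].skipped is True
        assert res["wetland"].n_samples == 100
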