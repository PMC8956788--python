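"""Feature building, splitting, the two classifiers and their diagnostics."""

import numpy as np
import pandas as pd
import pytest

from cpirank import AnalysisError
from cpirank.ml import (
    build_features,
    evaluate,
    fit_gradient_boosting,
    fit_random_forest,
    model_report,
    partial_dependence,
    split_data,
)


def _results_frame(n=120, n_countries=4, seed=0, label_by_area=True):
    """Synthetic classified-results table; label determined by area alone."""
    rng = np.random.default_rng(seed)
    area = rng.lognormal(3.0, 1.0, n)
    frame = pd.DataFrame(
        {
            "lake": [f"L{i}" for i in range(n)],
            "country": rng.choice([f"C{j}" for j in range(n_countries)], n),
            "richness": rng.integers(1, 40, n),
            "cwt": rng.integers(1, 200, n).astype(float),
            "rrw": rng.uniform(0, 10, n),
            "area_km2": area,
        }
    )
    if label_by_area:
        frame["priority_class"] = np.where(area < np.median(area), "high", "low")
    else:
        frame["priority_class"] = rng.choice(["high", "low"], n)
    return frame


class TestFeatures:
    def test_column_layout(self):
        frame = _results_frame(n=3, n_countries=2, seed=1)
        X, y = build_features(frame)
        numeric = ["area_km2", "cwt", "rrw"]
        assert list(X.columns[:3]) == numeric
        assert all(c.startswith("country_") for c in X.columns[3:])
        assert (X[X.columns[3:]].sum(axis=1) == 1.0).all()
        assert len(y) == 3

    def test_single_country_gives_constant_indicator(self):
        frame = _results_frame(n=5, n_countries=1, seed=2)
        X, _ = build_features(frame)
        assert X.shape[1] == 4
        assert (X.iloc[:, 3] == 1.0).all()

    def test_row_shuffle_permutes_rows_only(self):
        frame = _results_frame(n=30, seed=3)
        X1, y1 = build_features(frame)
        shuffled = frame.sample(frac=1.0, random_state=9).reset_index(drop=True)
        X2, y2 = build_features(shuffled)
        assert list(X1.columns) == list(X2.columns)
        merged1 = X1.assign(label=y1.to_numpy()).sort_values(list(X1.columns)).reset_index(drop=True)
        merged2 = X2.assign(label=y2.to_numpy()).sort_values(list(X2.columns)).reset_index(drop=True)
        pd.testing.assert_frame_equal(merged1, merged2)


class TestSplit:
    def test_sizes_and_stratification(self):
        frame = _results_frame(n=100, seed=4, label_by_area=False)
        frame["priority_class"] = ["high"] * 20 + ["low"] * 80
        X, y = build_features(frame)
        X_tr, X_te, y_tr, y_te = split_data(X, y, train_fraction=0.7, seed=0)
        assert len(X_tr) == 70 and len(X_te) == 30
        assert abs((y_tr == "high").sum() - 14) <= 1
        assert abs((y_te == "high").sum() - 6) <= 1

    def test_same_seed_reproduces_split(self):
        X, y = build_features(_results_frame(n=60, seed=5))
        a = split_data(X, y, seed=11)
        b = split_data(X, y, seed=11)
        assert list(a[0].index) == list(b[0].index)

    def test_different_seeds_differ(self):
        X, y = build_features(_results_frame(n=60, seed=5))
        base = set(split_data(X, y, seed=0)[0].index)
        assert any(
            set(split_data(X, y, seed=s)[0].index) != base for s in range(1, 11)
        )

    def test_singleton_class_rejected_with_hint(self):
        frame = _results_frame(n=10, seed=6)
        frame["priority_class"] = ["high"] + ["low"] * 9
        X, y = build_features(frame)
        with pytest.raises(AnalysisError, match="data"):
            split_data(X, y)


class TestModels:
    @pytest.mark.parametrize("fit", [fit_random_forest, fit_gradient_boosting])
    def test_area_determined_label_ranks_area_first(self, fit):
        frame = _results_frame(n=200, seed=7)
        X, y = build_features(frame)
        kwargs = {"n_estimators": 100} if fit is fit_random_forest else {}
        model = fit(X, y, seed=1, **kwargs)
        col = "mean_decrease_accuracy" if model.name == "rf" else "gain"
        top = model.importances.sort_values(col, ascending=False)["feature"].iloc[0]
        assert top == "area_km2"

    def test_gbt_gain_importances_sum_to_one(self):
        X, y = build_features(_results_frame(n=150, seed=8))
        model = fit_gradient_boosting(X, y, seed=2)
        assert model.importances["gain"].sum() == pytest.approx(1.0)
        assert (model.importances["gain"] >= 0).all()

    def test_informative_binary_feature_is_learnable(self):
        rng = np.random.default_rng(9)
        n = 500
        flag = rng.integers(0, 2, n)
        frame = pd.DataFrame(
            {
                "lake": [f"L{i}" for i in range(n)],
                "country": "C0",
                "cwt": flag.astype(float),  # the single informative feature
                "rrw": rng.uniform(0, 1, n),
                "area_km2": rng.uniform(1, 2, n),
                "priority_class": np.where(flag == 1, "high", "low"),
            }
        )
        X, y = build_features(frame)
        X_tr, X_te, y_tr, y_te = split_data(X, y, seed=3)
        for model in (
            fit_random_forest(X_tr, y_tr, n_estimators=100, seed=3),
            fit_gradient_boosting(X_tr, y_tr, seed=3),
        ):
            metrics = evaluate(model, X_te, y_te)
            assert metrics["accuracy"] > 0.95

    def test_pure_noise_oob_accuracy_near_majority_rate(self):
        hits = []
        for seed in range(5):
            frame = _results_frame(n=200, seed=seed, label_by_area=False)
            frame["priority_class"] = ["high"] * 60 + ["low"] * 140
            X, y = build_features(frame)
            model = fit_random_forest(X, y, n_estimators=100, seed=seed, tune=False)
            hits.append(model.params["oob_accuracy"])
        assert abs(np.mean(hits) - 0.7) < 0.1

    def test_seeded_fit_is_reproducible(self):
        X, y = build_features(_results_frame(n=120, seed=10))
        a = fit_random_forest(X, y, n_estimators=80, seed=4)
        b = fit_random_forest(X, y, n_estimators=80, seed=4)
        pd.testing.assert_frame_equal(a.importances, b.importances)
        g1 = fit_gradient_boosting(X, y, seed=4)
        g2 = fit_gradient_boosting(X, y, seed=4)
        pd.testing.assert_frame_equal(g1.importances, g2.importances)


class TestEvaluate:
    def test_hand_confusion_matrix(self):
        # TP=9, FN=1, TN=7, FP=1 realized through a constant-prediction stub
        class Stub:
            feature_names = ["x"]
            classes = ["high", "low"]
            name = "stub"

            def predict(self, X):
                return np.array(
                    ["high"] * 9 + ["low"] * 1 + ["low"] * 7 + ["high"] * 1
                )

        y = pd.Series(["high"] * 10 + ["low"] * 8)
        X = pd.DataFrame({"x": np.zeros(18)})
        metrics = evaluate(Stub(), X, y)
        assert metrics["precision"] == pytest.approx(0.9)
        assert metrics["recall"] == pytest.approx(0.9)
        assert metrics["specificity"] == pytest.approx(0.875)
        assert metrics["f1"] == pytest.approx(0.9)
        assert metrics["accuracy"] == pytest.approx(16 / 18)

    def test_perfect_predictions_score_one(self):
        X, y = build_features(_results_frame(n=100, seed=11))
        model = fit_random_forest(X, y, n_estimators=60, seed=5, tune=False)
        metrics = evaluate(model, X, y)  # in-sample: forest memorizes
        assert metrics["accuracy"] == 1.0
        assert metrics["f1"] == 1.0

    def test_all_majority_predictions_metrics(self):
        class Majority:
            feature_names = ["x"]

            def predict(self, X):
                return np.array(["low"] * len(X))

        y = pd.Series(["low"] * 16 + ["high"] * 4)
        X = pd.DataFrame({"x": np.zeros(20)})
        metrics = evaluate(Majority(), X, y)
        assert metrics["accuracy"] == pytest.approx(0.8)
        assert metrics["recall"] == 0.0
        assert np.isnan(metrics["precision"])

    def test_f1_identity_holds(self):
        X, y = build_features(_results_frame(n=150, seed=12))
        X_tr, X_te, y_tr, y_te = split_data(X, y, seed=6)
        model = fit_gradient_boosting(X_tr, y_tr, seed=6)
        m = evaluate(model, X_te, y_te)
        for v in m.values():
            assert np.isnan(v) or 0.0 <= v <= 1.0
        assert m["f1"] == pytest.approx(
            2 * m["precision"] * m["recall"] / (m["precision"] + m["recall"])
        )


class TestPartialDependence:
    def test_ignored_feature_gives_flat_curve(self):
        class Constant:
            feature_names = ["area_km2", "cwt"]
            classes = ["high", "low"]

            def predict_proba_high(self, X):
                return np.full(len(X), 0.25)

        X = pd.DataFrame({"area_km2": [1.0, 2.0, 3.0], "cwt": [1.0, 1.0, 1.0]})
        curve = partial_dependence(Constant(), X, "area_km2", grid=[0.5, 1.5, 9.0])
        assert (curve["p_high"] == 0.25).all()

    def test_area_threshold_label_yields_decreasing_curve(self):
        frame = _results_frame(n=300, seed=13)
        X, y = build_features(frame)
        model = fit_random_forest(X, y, n_estimators=100, seed=7, tune=False)
        grid = np.quantile(X["area_km2"], np.linspace(0.02, 0.98, 12))
        curve = partial_dependence(model, X, "area_km2", grid=grid)
        assert curve["p_high"].iloc[0] > curve["p_high"].iloc[-1]
        # decreasing overall, not just at the ends
        assert np.corrcoef(curve[curve.columns[0]], curve["p_high"])[0, 1] < -0.5

    def test_unknown_feature_rejected(self):
        X, y = build_features(_results_frame(n=50, seed=14))
        model = fit_gradient_boosting(X, y, seed=8)
        with pytest.raises(AnalysisError):
            partial_dependence(model, X, "depth_m")

    def test_model_report_bundles_everything(self):
        X, y = build_features(_results_frame(n=120, seed=15))
        X_tr, X_te, y_tr, y_te = split_data(X, y, seed=9)
        model = fit_gradient_boosting(X_tr, y_tr, seed=9)
        rep = model_report(model, X_te, y_te)
        assert rep.model_name == "gbt"
        assert set(rep.pd_curves) == {"area_km2", "cwt", "rrw"}
        assert set(rep.metrics) == {"accuracy", "recall", "specificity", "precision", "f1"}
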