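"""Shapley attributions: axioms, oracle agreement, reports."""

import numpy as np
import pandas as pd
import pytest
import xgboost as xgb

from pulsebp.estimation import TrainedEstimator, _parse_booster
from pulsebp.interpretation import (
    REMAINDER_LABEL,
    ShapMatrix,
    beeswarm_export,
    brute_force_shapley,
    dependence_export,
    global_importance,
    shap_attributions,
    subsample_background,
    subset_reports,
)


def _make_estimator(X, y, names=None, **params):
    model = xgb.XGBRegressor(random_state=0, n_jobs=1, **params)
    model.fit(X, y)
    trees, base = _parse_booster(model.get_booster())
    return TrainedEstimator(
        model=model,
        feature_names=list(names or [f"x{i}" for i in range(X.shape[1])]),
        trees=trees,
        base_score=base,
    )


@pytest.fixture(scope="module")
def small_model():
    rng = np.random.default_rng(8)
    X = rng.normal(size=(400, 5))
    y = 3.0 * X[:, 0] - 2.0 * X[:, 1] + 0.5 * X[:, 2] ** 2 + rng.normal(0, 0.1, 400)
    est = _make_estimator(X, y)
    return est, X


class TestShapAttributions:
    def test_local_accuracy_for_every_sample(self, small_model):
        est, X = small_model
        bg = X[:64]
        shap = shap_attributions(est, X[100:200], bg)
        np.testing.assert_allclose(
            shap.predictions, est.predict(X[100:200]), atol=1e-9
        )

    def test_unused_feature_gets_exactly_zero(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(300, 4))
        X[:, 3] = 1.23  # constant column can never be split on
        y = X[:, 0] + rng.normal(0, 0.05, 300)
        est = _make_estimator(X, y)
        shap = shap_attributions(est, X[:50], X[50:150])
        assert np.all(shap.values[:, 3] == 0.0)

    def test_single_stump_attributes_only_its_feature(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(300, 3))
        y = (X[:, 1] > 0).astype(float)
        est = _make_estimator(X, y, n_estimators=1, max_depth=1)
        bg = X[:100]
        shap = shap_attributions(est, X[:40], bg)
        assert np.all(shap.values[:, 0] == 0.0)
        assert np.all(shap.values[:, 2] == 0.0)
        np.testing.assert_allclose(
            shap.values[:, 1], est.predict(X[:40]) - est.predict(bg).mean(), atol=1e-9
        )

    def test_feature_mismatch_reports_columns(self, small_model):
        est, X = small_model
        frame = pd.DataFrame(X[:5], columns=[f"x{i}" for i in range(5)]).drop(columns="x2")
        with pytest.raises(ValueError, match="x2"):
            shap_attributions(est, frame, X[:10])

    def test_matches_brute_force_enumeration(self, small_model):
        """Tree-exact attributions equal the 2^M coalition enumeration with
        the same interventional background."""
        est, X = small_model
        bg = X[:40]
        shap = shap_attributions(est, X[200:215], bg)
        for i, x in enumerate(X[200:215]):
            phi = brute_force_shapley(est.predict, x, bg)
            np.testing.assert_allclose(shap.values[i], phi, atol=1e-6)

    def test_importance_invariant_under_sample_permutation(self, small_model):
        est, X = small_model
        bg = X[:64]
        shap = shap_attributions(est, X[100:180], bg)
        perm = np.random.default_rng(0).permutation(80)
        shuffled = ShapMatrix(
            values=shap.values[perm],
            base_value=shap.base_value,
            feature_values=shap.feature_values[perm],
            feature_names=shap.feature_names,
        )
        pd.testing.assert_series_equal(
            global_importance(shap).importances, global_importance(shuffled).importances
        )


class TestBruteForce:
    def test_additive_model_closed_form(self):
        """For f(x) = sum w_j x_j the interventional Shapley value is
        w_j (x_j - background mean of x_j)."""
        w = np.array([2.0, -1.0, 0.5])
        rng = np.random.default_rng(3)
        bg = rng.normal(size=(50, 3))
        x = rng.normal(size=3)
        phi = brute_force_shapley(lambda M: M @ w, x, bg)
        np.testing.assert_allclose(phi, w * (x - bg.mean(axis=0)), atol=1e-10)

    def test_symmetric_features_equal_attributions(self):
        bg = np.tile([[1.0, 1.0]], (10, 1))
        x = np.array([4.0, 4.0])
        phi = brute_force_shapley(lambda M: M[:, 0] * M[:, 1], x, bg)
        assert phi[0] == pytest.approx(phi[1], abs=1e-12)

    def test_efficiency_axiom(self):
        rng = np.random.default_rng(4)
        bg = rng.normal(size=(30, 4))
        x = rng.normal(size=4)

        def f(M):
            return np.sin(M[:, 0]) + M[:, 1] * M[:, 2] - M[:, 3] ** 2

        phi = brute_force_shapley(f, x, bg)
        assert phi.sum() == pytest.approx(f(x[None, :])[0] - f(bg).mean(), abs=1e-10)

    def test_feature_count_limit(self):
        with pytest.raises(ValueError, match="tree-exact"):
            brute_force_shapley(lambda M: M.sum(axis=1), np.zeros(13), np.zeros((5, 13)))


class TestGlobalImportance:
    def _matrix(self, values, names=("a", "b", "c")):
        return ShapMatrix(
            values=np.asarray(values, dtype=float),
            base_value=0.0,
            feature_values=np.zeros_like(np.asarray(values, dtype=float)),
            feature_names=list(names),
        )

    def test_all_zero_attributions(self):
        rep = global_importance(self._matrix(np.zeros((4, 3))))
        assert all(v == 0.0 for v in rep.as_dict().values())

    def test_single_sample_equals_absolute_row(self):
        rep = global_importance(self._matrix([[1.0, -2.0, 0.5]]))
        assert rep.as_dict() == {"b": 2.0, "a": 1.0, "c": 0.5}
        assert rep.top(1) == ["b"]
        assert rep.rank("c") == 3

    def test_dominant_feature_ranks_first(self, small_results):
        """BP generated from skew (dominant) and b/a: skew tops the list."""
        shap = small_results.explain(background_size=100, seed=0)
        assert global_importance(shap).top(1) == ["skew"]


@pytest.fixture(scope="module")
def shap(small_results):
    return small_results.explain(background_size=100, seed=0)


class TestBeeswarmExport:

    def test_full_topk_leaves_zero_remainder(self, shap):
        table = beeswarm_export(shap, top_k=len(shap.feature_names))
        rest = table[table["feature"] == REMAINDER_LABEL]
        np.testing.assert_allclose(rest["shap_value"], 0.0, atol=1e-12)

    def test_per_sample_conservation(self, shap):
        table = beeswarm_export(shap, top_k=9)
        sums = table.groupby("sample")["shap_value"].sum()
        expected = pd.Series(shap.values.sum(axis=1), index=shap.sample_ids)
        np.testing.assert_allclose(sums.sort_index(), expected.sort_index(), atol=1e-9)

    def test_nine_plus_aggregate_series(self, shap):
        table = beeswarm_export(shap, top_k=9)
        features = set(table["feature"])
        assert len(features) == 10
        assert REMAINDER_LABEL in features

    def test_topk_beyond_feature_count_rejected(self, shap):
        with pytest.raises(ValueError):
            beeswarm_export(shap, top_k=16)


class TestDependenceExport:

    def test_no_trim_keeps_all_rows(self, shap):
        table, _ = dependence_export(shap, "skew", trim=(0.0, 100.0))
        assert len(table) == shap.values.shape[0]

    def test_one_percent_trim_row_count(self):
        rng = np.random.default_rng(0)
        n = 1000
        vals = rng.uniform(size=(n, 2))
        shap = ShapMatrix(values=vals.copy(), base_value=0.0,
                          feature_values=vals, feature_names=["u", "v"])
        table, _ = dependence_export(shap, "u", trim=(1.0, 99.0))
        assert 975 <= len(table) <= 985

    def test_monotone_relation_gives_unit_rank_correlation(self):
        x = np.linspace(0, 1, 200)
        vals = np.column_stack([np.exp(x), np.zeros(200)])
        shap = ShapMatrix(values=vals, base_value=0.0,
                          feature_values=np.column_stack([x, x]),
                          feature_names=["u", "v"])
        _, rho = dependence_export(shap, "u", trim=(0.0, 100.0))
        assert rho == pytest.approx(1.0)

    def test_unknown_feature_rejected(self, shap):
        with pytest.raises(ValueError, match="unknown"):
            dependence_export(shap, "nope")


class TestSubsetReports:

    def test_perfect_predictions_leave_high_error_stratum_empty(self):
        vals = np.ones((20, 2))
        shap = ShapMatrix(values=vals, base_value=0.0, feature_values=vals,
                          feature_names=["a", "b"])
        pred = np.full(20, 120.0)
        reports = subset_reports(shap, pred, pred.copy(), mae=1.0, top_k=2)
        assert reports["high_error"].empty
        assert reports["high_error"].n == 0

    def test_prediction_strata_partition(self, shap, small_results):
        pred = shap.predictions
        reports = subset_reports(
            shap, pred, small_results.test.y, mae=small_results.metrics["overall"].mae
        )
        n = pred.size
        low = reports["low_prediction"].n
        high = reports["high_prediction"].n
        mid = int(np.sum((pred >= 0.8 * pred.mean()) & (pred <= 1.2 * pred.mean())))
        assert low + high + mid == n

    def test_dominant_feature_leads_every_populated_stratum(self):
        """With BP driven by skew alone, skew ranks first in every
        populated stratum."""
        from pulsebp.estimation import BloodPressureModel
        from pulsebp.synthetic import BPCoupling, SyntheticConfig, synthesize_dataset

        cfg = SyntheticConfig(
            n_subjects=15, beats_per_subject=30, seed=42,
            bp_coupling=BPCoupling(name="linear_skew", noise_sd=0.5),
        )
        results = BloodPressureModel(synthesize_dataset(cfg), seed=42).fit()
        shap = results.explain(background_size=100, seed=0)
        reports = subset_reports(
            shap,
            shap.predictions,
            results.test.y,
            mae=results.metrics["overall"].mae,
            sources=results.test.sources,
        )
        assert any(not rep.empty for rep in reports.values())
        for rep in reports.values():
            if not rep.empty and rep.n >= 10:
                assert rep.importance.top(1) == ["skew"]

    def test_misaligned_arrays_rejected(self, shap):
        with pytest.raises(ValueError):
            subset_reports(shap, np.zeros(3), np.zeros(4), mae=1.0)


class TestBackground:
    def test_subsample_is_seeded_and_bounded(self):
        X = np.arange(5000, dtype=float).reshape(1000, 5)
        a = subsample_background(X, 200, seed=3)
        b = subsample_background(X, 200, seed=3)
        np.testing.assert_array_equal(a, b)
        assert a.shape == (200, 5)
        small = subsample_background(X[:50], 200, seed=3)
        assert small.shape == (50, 5)
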