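"""Splitting, weighting, regression, median filtering and metrics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pulsebp.estimation import (
    BeatDataset,
    BloodPressureModel,
    SplitSpec,
    TrainedEstimator,
    compute_metrics,
    median_postfilter,
    sample_weights,
    split_subjects,
    train_regressor,
)
from pulsebp.features import FEATURE_NAMES


def _dataset(n_subjects=10, beats=20, sources=("synthetic",), seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for src in sources:
        for s in range(n_subjects):
            for t in range(beats):
                row = {
                    "subject": f"{src}-S{s:02d}",
                    "source": src,
                    "record": f"{src}-S{s:02d}",
                    "time_index": t,
                    "response_bp": float(rng.normal(120, 10)),
                }
                row.update({f: float(rng.normal()) for f in FEATURE_NAMES})
                rows.append(row)
    return BeatDataset(pd.DataFrame(rows))


class TestSplit:
    def test_strict_eighty_twenty_disjoint(self):
        ds = _dataset(n_subjects=10)
        train, test = split_subjects(ds, SplitSpec(mode="strict", seed=1))
        assert len(set(train.subjects)) == 8
        assert len(set(test.subjects)) == 2
        assert not set(train.subjects) & set(test.subjects)

    def test_co_assignment_never_straddles(self):
        ds = _dataset(n_subjects=6)
        group = frozenset({"synthetic-S00", "synthetic-S01"})
        for seed in range(25):
            spec = SplitSpec(mode="strict", seed=seed, co_assignment_groups=(group,))
            train, test = split_subjects(ds, spec)
            sides = {s: ("train" if s in set(train.subjects) else "test") for s in group}
            assert len(set(sides.values())) == 1

    def test_pooled_deterministic_row_count(self):
        ds = _dataset(n_subjects=10, beats=10)  # 100 rows... need 1000
        ds = _dataset(n_subjects=50, beats=20)
        train, test = split_subjects(ds, SplitSpec(mode="pooled", seed=3))
        assert len(train) == 800
        assert len(test) == 200

    def test_no_leakage_across_seeds(self):
        ds = _dataset(n_subjects=7)
        for seed in range(100):
            train, test = split_subjects(ds, SplitSpec(mode="strict", seed=seed))
            assert not set(train.subjects) & set(test.subjects)
            assert len(test.subjects) > 0

    def test_single_subject_source_rejected(self):
        ds = _dataset(n_subjects=1)
        with pytest.raises(ValueError, match="strict"):
            split_subjects(ds, SplitSpec(mode="strict"))


class TestSampleWeights:
    def _ds_with_bp(self, values):
        rng = np.random.default_rng(0)
        rows = []
        for i, bp in enumerate(values):
            row = {"subject": f"S{i}", "source": "x", "record": f"S{i}",
                   "time_index": 0, "response_bp": float(bp)}
            row.update({f: float(rng.normal()) for f in FEATURE_NAMES})
            rows.append(row)
        return BeatDataset(pd.DataFrame(rows))

    def test_above_half_max_downweighted(self):
        w = sample_weights(self._ds_with_bp([120.0, 90.0, 200.0]))
        assert w.tolist() == [0.375, 1.0, 0.375]

    def test_equal_responses_all_downweighted(self):
        # every positive value exceeds half of itself
        w = sample_weights(self._ds_with_bp([130.0, 130.0, 130.0]))
        assert (w == 0.375).all()

    def test_empty_training_set_rejected(self):
        ds = self._ds_with_bp([120.0])
        with pytest.raises(ValueError):
            sample_weights(ds.subset(np.zeros(1, dtype=bool)))


class TestTrainRegressor:
    def test_deterministic_given_seed(self):
        ds = _dataset(n_subjects=10, beats=15, seed=4)
        probe = np.random.default_rng(1).normal(size=(20, 15))
        p1 = train_regressor(ds, seed=7).predict(probe)
        p2 = train_regressor(ds, seed=7).predict(probe)
        np.testing.assert_array_equal(p1, p2)

    def test_constant_response_predicts_constant(self):
        ds = _dataset(n_subjects=10, beats=15, seed=4)
        ds.frame["response_bp"] = 117.0
        est = train_regressor(ds)
        pred = est.predict(np.random.default_rng(0).normal(size=(10, 15)))
        np.testing.assert_allclose(pred, 117.0, atol=1e-6)

    def test_too_few_rows_rejected(self):
        ds = _dataset(n_subjects=2, beats=10)
        with pytest.raises(ValueError, match="100"):
            train_regressor(ds)

    def test_float64_evaluator_matches_xgboost(self):
        """The parsed-tree evaluator reproduces xgboost's own predictions
        up to its float32 accumulation error."""
        ds = _dataset(n_subjects=10, beats=15, seed=4)
        est = train_regressor(ds, seed=0)
        probe = np.random.default_rng(5).normal(size=(200, 15))
        np.testing.assert_allclose(est.predict(probe), est.predict_native(probe),
                                   atol=1e-3)

    def test_save_load_roundtrip(self, tmp_path):
        ds = _dataset(n_subjects=10, beats=15, seed=4)
        est = train_regressor(ds, seed=0)
        est.save(tmp_path / "m.json", tmp_path / "m_manifest.json")
        loaded = TrainedEstimator.load(tmp_path / "m.json", tmp_path / "m_manifest.json")
        probe = np.random.default_rng(5).normal(size=(50, 15))
        np.testing.assert_allclose(loaded.predict(probe), est.predict(probe), atol=1e-10)

    def test_manifest_records_hyperparams(self):
        ds = _dataset(n_subjects=10, beats=15, seed=4)
        est = train_regressor(ds, seed=0)
        assert est.manifest["feature_names"] == FEATURE_NAMES
        assert "hyperparams" in est.manifest


class TestMedianPostfilter:
    def test_constant_unchanged(self):
        x = np.full(50, 5.0)
        np.testing.assert_array_equal(median_postfilter(x), x)

    def test_single_spike_removed_entirely(self):
        x = np.full(50, 100.0)
        x[25] = 400.0
        np.testing.assert_array_equal(median_postfilter(x, 11), np.full(50, 100.0))

    def test_short_series_returned_unchanged(self):
        x = np.array([1.0, 9.0, 2.0, 8.0, 3.0])
        np.testing.assert_array_equal(median_postfilter(x, 11), x)

    def test_even_kernel_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            median_postfilter(np.ones(20), kernel=10)


class TestComputeMetrics:
    def test_hand_worked_example(self):
        m = compute_metrics([120.0, 130.0, 140.0], [125.0, 125.0, 145.0])
        assert m.mae == pytest.approx(5.0)
        assert m.me == pytest.approx(-5.0 / 3.0)
        assert m.sde == pytest.approx(4.714, abs=1e-3)
        assert m.r == pytest.approx(0.866, abs=1e-3)

    def test_identical_series(self):
        m = compute_metrics([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert m.mae == m.me == m.sde == 0.0
        assert m.r == pytest.approx(1.0)

    def test_matches_independent_formulas(self, rng):
        """100 random pairs agree with scipy/numpy reference formulas."""
        for _ in range(100):
            n = rng.integers(5, 300)
            x = rng.normal(120, 15, size=n)
            xh = x + rng.normal(0, 8, size=n)
            m = compute_metrics(x, xh)
            err = x - xh
            assert m.mae == pytest.approx(np.abs(err).mean(), abs=1e-10)
            assert m.me == pytest.approx(err.mean(), abs=1e-10)
            assert m.sde == pytest.approx(err.std(ddof=0), abs=1e-10)
            assert m.r == pytest.approx(stats.pearsonr(x, xh).statistic, abs=1e-10)
            assert m.mae >= abs(m.me)

    def test_translation_shifts_me_not_sde(self, rng):
        x = rng.normal(size=50)
        xh = x + rng.normal(0, 1, size=50)
        m0 = compute_metrics(x, xh)
        m1 = compute_metrics(x, xh + 7.0)
        assert m1.me == pytest.approx(m0.me - 7.0)
        assert m1.sde == pytest.approx(m0.sde)

    def test_zero_variance_r_undefined(self):
        m = compute_metrics([1.0, 1.0, 1.0], [2.0, 3.0, 4.0])
        assert m.r is None

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            compute_metrics([1.0, 2.0], [1.0])


class TestModelResults:
    def test_strict_recovery_on_noiseless_two_feature_response(self):
        """When BP is a noiseless function of two features, the held-out
        correlation is essentially perfect."""
        from pulsebp.synthetic import BPCoupling, SyntheticConfig, synthesize_dataset

        cfg = SyntheticConfig(
            n_subjects=30, beats_per_subject=50, seed=13,
            bp_coupling=BPCoupling(noise_sd=0.0),
        )
        res = BloodPressureModel(synthesize_dataset(cfg), seed=13).fit()
        assert res.metrics["overall"].r > 0.95

    def test_summary_mentions_metrics(self, small_results):
        text = small_results.summary()
        assert "MAE" in text and "SDE" in text and "split: strict" in text

    def test_metrics_invariant_mae_bounds_me(self, small_results):
        for rep in small_results.metrics.values():
            assert rep.mae >= abs(rep.me) - 1e-12

    def test_unfiltered_sources_skip_median_filter(self):
        ds = _dataset(n_subjects=6, beats=30)
        res = BloodPressureModel(ds, unfiltered_sources=("synthetic",), seed=0).fit()
        np.testing.assert_array_equal(
            res.predictions["predicted_bp_filtered"],
            res.predictions["predicted_bp_raw"],
        )
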