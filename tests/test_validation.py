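"""Phase-2 external validation: metrics and subset ranking."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from modesus import (
    SearchConfig,
    AggregationParams,
    GAConfig,
    ValidationConfig,
    classification_metrics,
    partition_dataset,
    regression_metrics,
    run_search,
    validate_subsets,
)
from modesus.validation import SubsetReport, _evaluate_mask_once, save_reports, load_reports
from modesus.models import LearnerSpec, fit_predict


def _confusion_fixture(tp, tn, fp, fn):
    y_true = np.array(["RB"] * (tp + fn) + ["NRB"] * (tn + fp), dtype=object)
    y_pred = np.array(
        ["RB"] * tp + ["NRB"] * fn + ["NRB"] * tn + ["RB"] * fp, dtype=object
    )
    return y_true, y_pred


class TestClassificationMetrics:
    def test_hand_evaluated_confusion_matrix(self):
        y_true, y_pred = _confusion_fixture(tp=50, tn=40, fp=5, fn=5)
        pcc, mcc, _ = classification_metrics(y_true, y_pred, None, None)
        assert pcc == pytest.approx(90.0, abs=1e-12)
        assert mcc == pytest.approx(1975 / 2475, abs=1e-12)

    def test_inverting_predictions_flips_mcc_sign(self):
        y_true, y_pred = _confusion_fixture(tp=50, tn=40, fp=5, fn=5)
        inverted = np.where(y_pred == "RB", "NRB", "RB").astype(object)
        _, mcc, _ = classification_metrics(y_true, y_pred, None, None)
        _, mcc_inv, _ = classification_metrics(y_true, inverted, None, None)
        assert mcc_inv == pytest.approx(-mcc, abs=1e-12)

    def test_perfect_classifier(self):
        y = np.array(["RB", "NRB", "RB", "NRB"], dtype=object)
        scores = np.array([[0.0, 1.0], [1.0, 0.0], [0.1, 0.9], [0.8, 0.2]])
        pcc, mcc, roc = classification_metrics(y, y.copy(), scores, ["NRB", "RB"])
        assert (pcc, mcc, roc) == (100.0, 1.0, 1.0)

    def test_degenerate_single_class_prediction(self):
        y_true = np.array(["RB"] * 50 + ["NRB"] * 50, dtype=object)
        y_pred = np.array(["RB"] * 100, dtype=object)
        pcc, mcc, _ = classification_metrics(y_true, y_pred, None, None)
        assert pcc == 50.0
        assert mcc == 0.0

    @given(st.integers(0, 1 << 30))
    @settings(derandomize=True, max_examples=200)
    def test_bounds_on_random_predictions(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 60))
        labels = np.array(["A", "B"], dtype=object)
        y_true = labels[rng.integers(0, 2, n)]
        if len(set(y_true)) < 2:
            y_true[0], y_true[1] = "A", "B"
        y_pred = labels[rng.integers(0, 2, n)]
        s = rng.random((n, 2))
        s = s / s.sum(axis=1, keepdims=True)
        pcc, mcc, roc = classification_metrics(y_true, y_pred, s, ["A", "B"])
        assert 0.0 <= pcc <= 100.0
        assert -1.0 <= mcc <= 1.0
        assert 0.0 <= roc <= 1.0

    def test_multiclass_reduces_to_weighted_ovr(self):
        rng = np.random.default_rng(3)
        labels = np.array(["a", "b", "c"], dtype=object)
        y_true = labels[rng.integers(0, 3, 90)]
        y_pred = labels[rng.integers(0, 3, 90)]
        s = rng.random((90, 3))
        s /= s.sum(axis=1, keepdims=True)
        pcc, mcc, roc = classification_metrics(y_true, y_pred, s, list(labels))
        assert 0.0 <= pcc <= 100.0
        assert -1.0 <= mcc <= 1.0


class TestRegressionMetrics:
    def test_perfect_fit(self):
        y = np.array([1.0, 2.0, 3.0])
        assert regression_metrics(y, y) == (0.0, 0.0, 1.0)

    def test_mean_predictor_has_zero_r2(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        mse, rmse, r2 = regression_metrics(y, np.full(4, y.mean()))
        assert r2 == pytest.approx(0.0, abs=1e-15)

    def test_two_point_hand_computation(self):
        mse, rmse, r2 = regression_metrics(np.array([0.0, 2.0]),
                                           np.array([1.0, 1.0]))
        assert (mse, rmse, r2) == (1.0, 1.0, 0.0)

    def test_constant_truth_gives_nan_r2(self):
        mse, rmse, r2 = regression_metrics(np.array([2.0, 2.0]),
                                           np.array([1.0, 3.0]))
        assert np.isnan(r2)


@pytest.fixture(scope="module")
def searched_small(small_classification):
    ds, truth = small_classification
    from modesus import remove_constant_descriptors
    ds_clean, _ = remove_constant_descriptors(ds)
    part = partition_dataset(ds_clean, 0.75, 2)
    cfg = SearchConfig(
        mode="aggregation", trials=1, agg=AggregationParams(alpha=0.7, pm=5),
        wrapper_learner="knn",
        ga=GAConfig(population_size=25, max_generations=15, seed=2),
    )
    result = run_search(ds_clean.subset_rows(part.internal_indices), cfg)
    return ds_clean, part, result


class TestValidateSubsets:
    def test_clipping_when_front_is_small(self, searched_small):
        ds, part, result = searched_small
        cfg = ValidationConfig(
            n_subsets_to_evaluate=50, learner="random_forest",
            learner_params={"n_estimators": 15}, n_runs=2, seed=1,
        )
        reports = validate_subsets(result, ds, part, cfg)
        assert len(reports) == min(50, len(result.front))

    def test_metrics_are_run_averages(self, searched_small):
        ds, part, result = searched_small
        cfg = ValidationConfig(
            n_subsets_to_evaluate=2, learner="random_forest",
            learner_params={"n_estimators": 15}, n_runs=5, seed=4,
        )
        reports = validate_subsets(result, ds, part, cfg)
        for r in reports:
            assert len(r.per_run) == 5
            for key, value in r.metrics.items():
                assert value == pytest.approx(
                    np.mean([run[key] for run in r.per_run]), abs=1e-12
                )

    def test_per_run_metrics_recomputable_from_internal_training(
        self, searched_small
    ):
        """A report's per-run metrics equal metrics of a model trained on
        internal rows only — external targets never reach training."""
        from modesus import classification_metrics

        ds, part, result = searched_small
        cfg = ValidationConfig(
            n_subsets_to_evaluate=1, learner="random_forest",
            learner_params={"n_estimators": 15}, n_runs=1, seed=9,
        )
        report = validate_subsets(result, ds, part, cfg)[0]
        cols = [ds.descriptor_names.index(n) for n in report.descriptor_names]
        spec = LearnerSpec("random_forest", {"n_estimators": 15}, seed=9)
        pred = fit_predict(
            spec,
            ds.X[np.ix_(part.internal_indices, cols)], ds.y[part.internal_indices],
            ds.X[np.ix_(part.external_indices, cols)], ds.task,
        )
        pcc, mcc, roc = classification_metrics(
            ds.y[part.external_indices], pred.predictions, pred.scores, pred.classes
        )
        assert report.per_run[0]["pcc"] == pytest.approx(pcc, abs=1e-12)
        assert report.per_run[0]["mcc"] == pytest.approx(mcc, abs=1e-12)
        assert report.per_run[0]["avg_roc"] == pytest.approx(roc, abs=1e-12)

    def test_poisoned_external_targets_leave_predictions_unchanged(
        self, searched_small
    ):
        from modesus import Dataset

        ds, part, result = searched_small
        y_poison = ds.y.copy()
        rng = np.random.default_rng(0)
        ext = part.external_indices
        y_poison[ext] = y_poison[rng.permutation(ext)]
        ds_poison = Dataset(ds.X, list(ds.descriptor_names), y_poison, ds.task)

        mask = np.zeros(ds.n_descriptors, dtype=bool)
        mask[:4] = True
        spec = LearnerSpec("random_forest", {"n_estimators": 10}, seed=3)
        cols = np.flatnonzero(mask)
        probe = ds.X[np.ix_(ext, cols)]
        for data in (ds, ds_poison):
            pred = fit_predict(
                spec,
                data.X[np.ix_(part.internal_indices, cols)],
                data.y[part.internal_indices],
                probe, ds.task,
            )
            # training depends only on internal rows, which are identical
            if data is ds:
                reference = pred.predictions
            else:
                np.testing.assert_array_equal(pred.predictions, reference)

    def test_ranking_is_deterministic_best_first(self, searched_small):
        ds, part, result = searched_small
        cfg = ValidationConfig(
            n_subsets_to_evaluate=5, learner="random_forest",
            learner_params={"n_estimators": 15}, n_runs=2, seed=1,
        )
        reports = validate_subsets(result, ds, part, cfg)
        keys = [(-r.metrics["pcc"], -r.metrics["mcc"], r.cardinality)
                for r in reports]
        assert keys == sorted(keys)

    def test_perfectly_separable_fixture_scores_perfect(self, noiseless_12d):
        ds, truth = noiseless_12d
        part = partition_dataset(ds, 0.75, 1)
        cfg = SearchConfig(
            mode="aggregation", agg=AggregationParams(alpha=0.7, pm=3),
            wrapper_learner="knn",
            ga=GAConfig(population_size=25, max_generations=15, seed=1),
        )
        result = run_search(ds.subset_rows(part.internal_indices), cfg)
        vcfg = ValidationConfig(
            n_subsets_to_evaluate=3, learner="random_forest",
            learner_params={"n_estimators": 30}, n_runs=2, seed=0,
        )
        top = validate_subsets(result, ds, part, vcfg)[0]
        assert top.metrics["pcc"] == 100.0
        assert top.metrics["mcc"] == 1.0
        assert top.metrics["avg_roc"] == 1.0

    def test_report_serialization_round_trip(self, searched_small, tmp_path):
        ds, part, result = searched_small
        cfg = ValidationConfig(
            n_subsets_to_evaluate=3, learner="random_forest",
            learner_params={"n_estimators": 10}, n_runs=1, seed=0,
        )
        reports = validate_subsets(result, ds, part, cfg)
        jp, cp = tmp_path / "r.json", tmp_path / "r.csv"
        save_reports(reports, json_path=jp, csv_path=cp)
        back = load_reports(jp)
        assert [r.to_dict() for r in back] == [r.to_dict() for r in reports]
        assert cp.read_text().splitlines()[0].startswith("rank,")

    def test_invalid_learner_rejected(self):
        with pytest.raises(ValueError, match="phase-2 learner"):
            ValidationConfig(learner="knn")

    def test_mcc_sign_flip_property_on_random_vectors(self):
        rng = np.random.default_rng(5)
        labels = np.array(["NRB", "RB"], dtype=object)
        for _ in range(200):
            n = int(rng.integers(6, 40))
            y_true = labels[rng.integers(0, 2, n)]
            if len(set(y_true)) < 2:
                continue
            y_pred = labels[rng.integers(0, 2, n)]
            inv = np.where(y_pred == "RB", "NRB", "RB").astype(object)
            _, mcc, _ = classification_metrics(y_true, y_pred, None, None)
            _, mcc_i, _ = classification_metrics(y_true, inv, None, None)
            assert mcc_i == pytest.approx(-mcc, abs=1e-12)
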