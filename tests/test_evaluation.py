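"""Confusion matrices, classification metrics and run statistics.

The worked examples reproduce the published patch-classification results
of the four-class habitat study from its printed per-class correct counts,
and are cross-checked against scikit-learn as an independent oracle.
"""

import numpy as np
import pytest

from baoscnn.evaluation import (
    classification_metrics,
    confusion_matrix,
    export_convergence,
    run_statistics,
)

CLASSES = ("Amphibolis", "Background", "Halophila", "Posidonia")
# per-class correctly classified patches, of 9,360 test patches per class
CORRECT = (8681, 9271, 9354, 9189)


def _published_counts():
    """Counts with each class's misses assigned to one off-diagonal cell
    (recall/accuracy depend only on the diagonal and row totals)."""
    counts = np.zeros((4, 4), dtype=int)
    for i, correct in enumerate(CORRECT):
        counts[i, i] = correct
        counts[i, (i + 1) % 4] = 9360 - correct
    return counts


def _labels_from_counts(counts):
    y_true, y_pred = [], []
    for i in range(counts.shape[0]):
        for j in range(counts.shape[1]):
            y_true += [i] * counts[i, j]
            y_pred += [j] * counts[i, j]
    return np.array(y_true), np.array(y_pred)


class TestConfusionMatrix:
    def test_perfect_prediction_is_diagonal(self):
        y = np.array([0, 1, 2, 3, 2, 1])
        cm = confusion_matrix(y, y, 4)
        assert np.array_equal(cm.counts, np.diag(np.bincount(y, minlength=4)))

    def test_total_count_conserved(self, rng):
        y_true = rng.integers(0, 3, 100)
        y_pred = rng.integers(0, 3, 100)
        assert confusion_matrix(y_true, y_pred, 3).total == 100

    def test_small_enumeration(self):
        cm = confusion_matrix([0, 0, 1], [0, 1, 1], 2)
        assert cm.counts.tolist() == [[1, 1], [0, 1]]

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            confusion_matrix([0, 1], [0], 2)
        with pytest.raises(ValueError):
            confusion_matrix([0, 5], [0, 1], 2)


class TestPublishedWorkedExamples:
    def test_overall_accuracy_matches_published_9748(self):
        report = classification_metrics(
            confusion_matrix(*_labels_from_counts(_published_counts()), 4, CLASSES)
        )
        assert round(report.accuracy, 4) == 0.9748

    def test_halophila_recall_matches_published_9994(self):
        report = classification_metrics(
            confusion_matrix(*_labels_from_counts(_published_counts()), 4, CLASSES)
        )
        assert round(report.recall[2], 4) == 0.9994

    def test_amphibolis_recall_from_printed_counts(self):
        report = classification_metrics(
            confusion_matrix(*_labels_from_counts(_published_counts()), 4, CLASSES)
        )
        assert report.recall[0] == pytest.approx(8681 / 9360, abs=1e-12)
        assert round(report.recall[0], 4) == 0.9275

    def test_against_sklearn_oracle(self):
        from sklearn.metrics import accuracy_score, precision_recall_fscore_support

        y_true, y_pred = _labels_from_counts(_published_counts())
        report = classification_metrics(confusion_matrix(y_true, y_pred, 4, CLASSES))
        p, r, f, _ = precision_recall_fscore_support(y_true, y_pred, zero_division=0)
        assert report.accuracy == pytest.approx(accuracy_score(y_true, y_pred))
        assert np.allclose(report.precision, p)
        assert np.allclose(report.recall, r)
        assert np.allclose(report.f1, f)


class TestMetricsIdentities:
    def test_f1_equals_precision_when_precision_equals_recall(self):
        cm = confusion_matrix([0, 0, 1, 1], [0, 1, 1, 0], 2)
        report = classification_metrics(cm)
        for c in range(2):
            assert report.precision[c] == report.recall[c]
            assert report.f1[c] == report.precision[c]

    def test_macro_recall_is_mean_of_per_class_recalls(self, rng):
        y_true = rng.integers(0, 4, 400)
        y_pred = rng.integers(0, 4, 400)
        cm = confusion_matrix(y_true, y_pred, 4)
        report = classification_metrics(cm)
        direct = np.mean(
            [np.diag(cm.counts)[c] / cm.counts[c].sum() for c in range(4)]
        )
        assert np.mean(report.recall) == pytest.approx(direct)

    def test_binary_one_vs_rest_accuracy_identity(self):
        cm = confusion_matrix([0, 0, 1, 1, 1, 0], [0, 1, 1, 1, 0, 0], 2)
        tp, fn = cm.counts[1, 1], cm.counts[1, 0]
        fp, tn = cm.counts[0, 1], cm.counts[0, 0]
        report = classification_metrics(cm)
        assert report.accuracy == pytest.approx((tp + tn) / (tp + tn + fp + fn))

    def test_zero_division_policy(self):
        # class 1 never predicted and never actual -> P = R = F1 = 0
        cm = confusion_matrix([0, 0], [0, 0], 2)
        report = classification_metrics(cm)
        assert report.precision[1] == report.recall[1] == report.f1[1] == 0.0

    def test_empty_matrix_rejected(self):
        cm = confusion_matrix([], [], 2)
        with pytest.raises(ValueError):
            classification_metrics(cm)


class TestRunStatistics:
    def test_constant_sequence(self):
        summary = run_statistics([0.95, 0.95, 0.95])
        assert summary.sd == pytest.approx(0.0, abs=1e-12)
        assert summary.best == summary.worst == 0.95
        assert summary.mean == pytest.approx(0.95)

    def test_two_point_mean(self):
        assert run_statistics([0.9, 1.0]).mean == pytest.approx(0.95)

    def test_sample_sd_matches_two_pass_computation(self, rng):
        values = rng.random(10)
        summary = run_statistics(values)
        mean = sum(values) / len(values)
        two_pass = (sum((v - mean) ** 2 for v in values) / (len(values) - 1)) ** 0.5
        assert summary.sd == pytest.approx(two_pass, abs=1e-12)
        assert summary.worst <= summary.mean <= summary.best

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            run_statistics([])


class TestConvergenceExport:
    def _result(self):
        from baoscnn.benchmarks import benchmark, benchmark_space
        from baoscnn.optimizers import OptimizerParams, optimize

        space = benchmark_space("sphere", 3)
        params = OptimizerParams(m=5, max_iterations=19, n_runs=1, seed=0)
        return optimize(lambda x: benchmark("sphere", x), space, params)

    def test_rows_and_monotonicity(self, tmp_path):
        import pandas as pd

        result = self._result()
        path = export_convergence({"baos": result}, tmp_path / "conv.csv")
        frame = pd.read_csv(path)
        assert len(frame) == 20
        assert frame["best_accuracy"].is_monotonic_increasing

    def test_round_trip_reproduces_trace(self, tmp_path):
        import pandas as pd

        result = self._result()
        path = export_convergence(
            {"baos": result}, tmp_path / "conv.csv", as_accuracy=False
        )
        frame = pd.read_csv(path)
        assert np.allclose(frame["best_energy"].to_numpy(), result.trace)

    def test_empty_results_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            export_convergence({}, tmp_path / "conv.csv")
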