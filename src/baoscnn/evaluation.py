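"""Classification metrics, multi-run statistics and convergence export.

Per-class precision, recall and F1 are computed one-vs-rest from an N x N
confusion matrix (rows = actual, columns = predicted); overall accuracy is
trace over total.  Zero-denominator cases are defined as 0 so the metrics
are total on degenerate folds.  Multi-run summaries report best / worst /
mean accuracy and the sample (n-1) standard deviation, the reporting
convention for small run counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from baoscnn.optimizers import OptimizationResult

__all__ = [
    "ConfusionMatrix",
    "MetricsReport",
    "RunSummary",
    "confusion_matrix",
    "classification_metrics",
    "run_statistics",
    "export_convergence",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    counts: np.ndarray  # (N, N), rows = actual, cols = predicted
    class_names: tuple[str, ...]

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.class_names, columns=self.class_names)


@dataclass(frozen=True)
class MetricsReport:
    precision: tuple[float, ...]
    recall: tuple[float, ...]
    f1: tuple[float, ...]
    accuracy: float
    class_names: tuple[str, ...]

    def to_dict(self) -> dict:
        per_class = {
            name: {
                "precision": round(self.precision[i], 4),
                "recall": round(self.recall[i], 4),
                "f1": round(self.f1[i], 4),
            }
            for i, name in enumerate(self.class_names)
        }
        return {"accuracy": round(self.accuracy, 4), "per_class": per_class}


@dataclass(frozen=True)
class RunSummary:
    best: float
    worst: float
    mean: float
    sd: float


def confusion_matrix(
    y_true: Sequence[int],
    y_pred: Sequence[int],
    n_classes: int,
    class_names: tuple[str, ...] | None = None,
) -> ConfusionMatrix:
    """counts[i, j] = number of samples with actual class i predicted j."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    if y_true.size and (
        y_true.min() < 0 or y_pred.min() < 0 or max(y_true.max(), y_pred.max()) >= n_classes
    ):
        raise ValueError("label outside [0, n_classes)")
    counts = np.zeros((n_classes, n_classes), dtype=int)
    np.add.at(counts, (y_true, y_pred), 1)
    if class_names is None:
        class_names = tuple(f"class_{i}" for i in range(n_classes))
    return ConfusionMatrix(counts=counts, class_names=tuple(class_names))


def classification_metrics(cm: ConfusionMatrix) -> MetricsReport:
    """One-vs-rest precision/recall/F1 per class plus overall accuracy."""
    counts = cm.counts
    if counts.sum() == 0:
        raise ValueError("empty confusion matrix")
    tp = np.diag(counts).astype(float)
    fp = counts.sum(axis=0) - tp  # predicted as c but not c
    fn = counts.sum(axis=1) - tp  # actual c missed
    with np.errstate(invalid="ignore", divide="ignore"):
        precision = np.where(tp + fp > 0, tp / (tp + fp), 0.0)
        recall = np.where(tp + fn > 0, tp / (tp + fn), 0.0)
        f1 = np.where(
            precision + recall > 0, 2 * precision * recall / (precision + recall), 0.0
        )
    return MetricsReport(
        precision=tuple(precision),
        recall=tuple(recall),
        f1=tuple(f1),
        accuracy=float(tp.sum() / counts.sum()),
        class_names=cm.class_names,
    )


def run_statistics(accuracies: Sequence[float]) -> RunSummary:
    """Best/worst/mean and sample standard deviation over runs."""
    acc = np.asarray(accuracies, dtype=float)
    if acc.size == 0:
        raise ValueError("need at least one accuracy value")
    sd = float(acc.std(ddof=1)) if acc.size > 1 else 0.0
    return RunSummary(
        best=float(acc.max()), worst=float(acc.min()), mean=float(acc.mean()), sd=sd
    )


def export_convergence(
    results: Mapping[str, OptimizationResult],
    path: str | Path,
    as_accuracy: bool = True,
) -> Path:
    """Write best-so-far traces as tidy CSV (algorithm, iteration, value).

    With ``as_accuracy`` the minimised energies ``E`` are exported as
    ``1 - E`` (a non-decreasing accuracy-maximisation trace); otherwise raw
    energies are written.
    """
    if not results:
        raise ValueError("no results to export")
    rows = []
    column = "best_accuracy" if as_accuracy else "best_energy"
    for name, result in results.items():
        for t, energy in enumerate(result.trace):
            value = 1.0 - energy if as_accuracy else energy
            rows.append({"algorithm": name, "iteration": t, column: value})
    path = Path(path)
    pd.DataFrame(rows).to_csv(path, index=False)
    return path
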