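"""Decoding hyperparameter assignments into CNN blueprints and scoring them
by stratified k-fold cross-validated accuracy.

The fitness of an assignment is the mean held-out-fold accuracy of a small
convolutional classifier trained from scratch on each of the k training
splits, with early stopping on validation loss.  This is the (maximised)
objective the optimizers see, negated into an "energy" by the runner.
Infeasible geometry never fails: kernel sizes are clipped to the current
spatial extent and pooling is skipped whenever it would shrink a spatial
dimension below one pixel, so every point of the search space decodes to a
trainable network.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any, Mapping, Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold

from baoscnn.nn_backend import ConvNet

__all__ = [
    "CNNBlueprint",
    "FitnessConfig",
    "Dataset",
    "FitnessRecord",
    "build_blueprint",
    "stratified_folds",
    "evaluate_fitness",
    "FitnessEvaluator",
]


@dataclass(frozen=True)
class Dataset:
    """Equal-shaped labelled images: ``images`` is (N, H, W, C) float in
    [0, 1], ``labels`` integer class indices."""

    images: np.ndarray
    labels: np.ndarray
    class_names: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.images.ndim != 4:
            raise ValueError("images must be (N, H, W, C)")
        if len(self.images) != len(self.labels):
            raise ValueError("one label per image required")
        if self.labels.size and int(self.labels.max()) >= self.n_classes:
            raise ValueError("label index out of range")

    @property
    def n_classes(self) -> int:
        return len(self.class_names)

    def subset(self, idx: np.ndarray) -> "Dataset":
        return Dataset(self.images[idx], self.labels[idx], self.class_names)

    def fingerprint(self) -> int:
        return hash(
            (self.images.shape, self.class_names, self.images.tobytes(), self.labels.tobytes())
        )


@dataclass(frozen=True)
class FitnessConfig:
    """Cross-validation protocol: five stratified folds, early-stopping
    patience of 20 epochs, and a per-fold epoch cap for desk-scale runs."""

    k_folds: int = 5
    patience: int = 20
    epoch_cap: int = 15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_folds < 2:
            raise ValueError("k_folds must be >= 2")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")


@dataclass(frozen=True)
class CNNBlueprint:
    """Backend-agnostic architecture description decoded from an assignment.

    ``blocks`` holds the feasible per-block (kernel, filters, pool) after
    geometric clipping; ``pool = 1`` marks a block whose pooling was skipped.
    """

    n_conv: int
    filters: int
    kernel: int
    pool: int
    dropout: float
    learning_rate: float
    momentum: float
    epochs: int
    batch_size: int
    input_shape: tuple[int, int, int]
    n_classes: int
    blocks: tuple[tuple[int, int, int], ...]

    def instantiate(self, seed: int) -> ConvNet:
        return ConvNet(
            input_shape=self.input_shape,
            n_classes=self.n_classes,
            blocks=list(self.blocks),
            dropout=self.dropout,
            lr=self.learning_rate,
            momentum=self.momentum,
            seed=seed,
        )


def build_blueprint(
    assignment: Mapping[str, Any], input_shape: tuple[int, int, int], n_classes: int
) -> CNNBlueprint:
    """Decode an assignment into a feasible blueprint.

    Builds ``n_conv`` blocks of conv -> ReLU -> max-pool, clipping each
    kernel to the current spatial extent and replacing pooling by identity
    (pool 1) once it would reduce a spatial dimension below one pixel.
    """
    h, w, _ = input_shape
    n_conv = int(assignment["n_conv"])
    kernel = int(assignment["kernel_size"])
    filters = int(assignment["n_filters"])
    pool = int(assignment["pool_size"])
    blocks = []
    for _ in range(n_conv):
        k = max(1, min(kernel, h, w))
        p = min(pool, h, w)
        if p < 2 or h // p < 1 or w // p < 1:
            p = 1
        blocks.append((k, filters, p))
        if p > 1:
            h, w = h // p, w // p
    return CNNBlueprint(
        n_conv=n_conv,
        filters=filters,
        kernel=kernel,
        pool=pool,
        dropout=float(assignment["dropout"]),
        learning_rate=float(assignment["learning_rate"]),
        momentum=float(assignment["momentum"]),
        epochs=int(assignment["n_epochs"]),
        batch_size=int(assignment["batch_size"]),
        input_shape=tuple(input_shape),
        n_classes=n_classes,
        blocks=tuple(blocks),
    )


def stratified_folds(
    labels: np.ndarray, k: int, rng: np.random.Generator
) -> list[np.ndarray]:
    """k disjoint, class-stratified fold index arrays covering all samples.

    Per fold and class the count is within one of the equal share.  Every
    class must have at least k members.
    """
    labels = np.asarray(labels)
    _, counts = np.unique(labels, return_counts=True)
    if counts.min() < k:
        raise ValueError(f"every class needs >= {k} members for {k}-fold stratification")
    seed = int(rng.integers(2**31))
    splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return [test for _, test in splitter.split(np.zeros(len(labels)), labels)]


@dataclass(frozen=True)
class FitnessRecord:
    fold_accuracies: tuple[float, ...]
    fitness: float
    best_fold: int
    history: tuple[tuple[float, ...], ...]  # per-fold validation losses
    diverged: bool = False


def _train_fold(
    blueprint: CNNBlueprint,
    train: Dataset,
    val: Dataset,
    config: FitnessConfig,
    seed: int,
) -> tuple[float, list[float], bool]:
    """Train one fold with early stopping; returns (accuracy at the
    best-validation-loss epoch, loss history, diverged flag)."""
    model = blueprint.instantiate(seed)
    n_epochs = min(blueprint.epochs, config.epoch_cap)
    best_loss = math.inf
    best_acc = 0.0
    since_best = 0
    losses: list[float] = []
    for _ in range(n_epochs):
        train_loss = model.train_epoch(train.images, train.labels, blueprint.batch_size)
        val_loss = model.loss(val.images, val.labels)
        if not (math.isfinite(train_loss) and math.isfinite(val_loss)):
            return 0.0, losses, True
        losses.append(val_loss)
        if val_loss < best_loss:
            best_loss = val_loss
            best_acc = float(np.mean(model.predict(val.images) == val.labels))
            since_best = 0
        else:
            since_best += 1
            if since_best >= config.patience:
                break
    return best_acc, losses, False


def _evaluate(
    assignment: Mapping[str, Any], dataset: Dataset, config: FitnessConfig
) -> FitnessRecord:
    blueprint = build_blueprint(
        assignment, dataset.images.shape[1:], dataset.n_classes
    )
    folds = stratified_folds(
        dataset.labels, config.k_folds, np.random.default_rng(config.seed)
    )
    all_idx = np.arange(len(dataset.labels))
    accuracies: list[float] = []
    histories: list[tuple[float, ...]] = []
    diverged = False
    for f, val_idx in enumerate(folds):
        train_idx = np.setdiff1d(all_idx, val_idx)
        acc, losses, bad = _train_fold(
            blueprint,
            dataset.subset(train_idx),
            dataset.subset(val_idx),
            config,
            seed=config.seed + 1000 * (f + 1),
        )
        accuracies.append(acc)
        histories.append(tuple(losses))
        diverged = diverged or bad
    fitness = 0.0 if diverged else float(np.mean(accuracies))
    return FitnessRecord(
        fold_accuracies=tuple(accuracies),
        fitness=fitness,
        best_fold=int(np.argmax(accuracies)),
        history=tuple(histories),
        diverged=diverged,
    )


def evaluate_fitness(
    assignment: Mapping[str, Any], dataset: Dataset, config: FitnessConfig
) -> FitnessRecord:
    """Cross-validated fitness of one assignment (uncached convenience)."""
    return _evaluate(assignment, dataset, config)


class FitnessEvaluator:
    """Caching fitness oracle over a fixed dataset and protocol.

    Identical assignments under the same seed return the stored record
    without retraining; ``trainings`` counts actual cross-validation runs.
    """

    def __init__(self, dataset: Dataset, config: FitnessConfig):
        self.dataset = dataset
        self.config = config
        self._cache: dict[tuple, FitnessRecord] = {}
        self.trainings = 0
        self.calls = 0

    @staticmethod
    def _key(assignment: Mapping[str, Any]) -> tuple:
        return tuple(sorted(assignment.items()))

    def evaluate(self, assignment: Mapping[str, Any]) -> FitnessRecord:
        self.calls += 1
        key = self._key(assignment)
        record = self._cache.get(key)
        if record is None:
            record = _evaluate(assignment, self.dataset, self.config)
            self._cache[key] = record
            self.trainings += 1
        return record

    def objective(self, space) -> "callable":
        """Energy view for the minimising optimizers: 1 - fitness of the
        decoded position."""

        def energy(position: np.ndarray) -> float:
            return 1.0 - self.evaluate(space.decode(position)).fitness

        return energy
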