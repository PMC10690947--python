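"""SGD/MSE training with early stopping, stratified CV, and metrics.

Training follows the published protocol: mini-batch stochastic gradient
descent on the mean-squared error between logistic class scores and
one-hot targets, learning rate 0.01, up to 100 epochs with batch size 30,
early stopping with patience 10 on the validation loss (best weights
restored).  Evaluation reports accuracy, sensitivity and specificity with
"responsive" as the positive class, plus the ROC curve and its AUC.
Cross-validation is stratified 5-fold; an optional hold-out test split is
carved out before the folds.

Segments are split individually (segment-wise), not grouped by subject.
With real clinical data this inflates performance estimates whenever one
subject contributes many windows; the synthetic generator draws windows
independently, so the caveat does not bite there.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.metrics import roc_curve
from sklearn.model_selection import StratifiedKFold, train_test_split

from .graph import GraphSample
from .model import (
    ArchConfig, CLASS_ORDER, Gradients, ModelParams, POSITIVE_CLASS,
    forward_batch, gradients, init_params, mse_loss, one_hot, sgd_step,
)


@dataclass(frozen=True)
class TrainConfig:
    """Published protocol defaults: lr 0.01, 100 epochs, batch 30,
    patience 10, 5 folds."""

    lr: float = 0.01
    epochs: int = 100
    batch_size: int = 30
    patience: int = 10
    k_folds: int = 5
    holdout_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.lr, self.epochs, self.batch_size,
               self.patience, self.k_folds) <= 0:
            raise ValueError("lr, epochs, batch_size, patience, k_folds "
                             "must all be positive")
        if not 0 <= self.holdout_fraction <= 0.5:
            raise ValueError("holdout_fraction must lie in [0, 0.5]")


@dataclass
class TrainHistory:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_accuracy: list[float] = field(default_factory=list)
    stopped_epoch: int = 0
    best_epoch: int = 0


@dataclass
class EvalMetrics:
    accuracy: float
    sensitivity: float
    specificity: float
    auc: float
    roc_points: list[tuple[float, float]]
    tp: int
    tn: int
    fp: int
    fn: int

    def as_dict(self) -> dict:
        return {
            "accuracy": self.accuracy, "sensitivity": self.sensitivity,
            "specificity": self.specificity, "auc": self.auc,
            "tp": self.tp, "tn": self.tn, "fp": self.fp, "fn": self.fn,
        }


# ---------------------------------------------------------------------------
# dataset stacking


@dataclass
class StackedDataset:
    """Graph samples stacked into contiguous arrays for fast batching."""

    X: np.ndarray        # (N, n_nodes, d)
    A: np.ndarray        # (N, n_nodes, n_nodes)
    y: np.ndarray        # (N,) class indices per CLASS_ORDER
    AX: np.ndarray | None = None  # cached A @ X

    def __len__(self) -> int:
        return self.X.shape[0]

    @property
    def targets(self) -> np.ndarray:
        return one_hot(self.y)

    def subset(self, idx) -> "StackedDataset":
        return StackedDataset(
            X=self.X[idx], A=self.A[idx], y=self.y[idx],
            AX=self.AX[idx] if self.AX is not None else None,
        )

    def with_cached_products(self) -> "StackedDataset":
        if self.AX is None:
            self.AX = self.A @ self.X
        return self


def stack_samples(samples: Sequence[GraphSample]) -> StackedDataset:
    labels = [s.label for s in samples]
    if any(l is None for l in labels):
        raise ValueError("all graph samples must carry a label")
    return StackedDataset(
        X=np.stack([s.X for s in samples]),
        A=np.stack([s.adjacency.A_hat for s in samples]),
        y=np.array([CLASS_ORDER.index(l) for l in labels]),
    )


def _scores(ds: StackedDataset, params: ModelParams) -> np.ndarray:
    return forward_batch(ds.X, ds.A, params, AX=ds.AX).scores


# ---------------------------------------------------------------------------
# training


def train(train_set: StackedDataset | Sequence[GraphSample],
          val_set: StackedDataset | Sequence[GraphSample],
          params: ModelParams, cfg: TrainConfig | None = None,
          ) -> tuple[ModelParams, TrainHistory]:
    """Mini-batch SGD with early stopping on validation loss.

    Shuffling, and hence the whole run, is deterministic in ``cfg.seed``.
    Early stopping: training halts once the validation loss has not
    improved for ``patience`` consecutive epochs; the parameters from the
    best epoch are returned.
    """
    cfg = cfg or TrainConfig()
    if not isinstance(train_set, StackedDataset):
        train_set = stack_samples(train_set)
    if not isinstance(val_set, StackedDataset):
        val_set = stack_samples(val_set)
    if len(train_set) == 0 or len(val_set) == 0:
        raise ValueError("train and validation sets must be non-empty")
    if np.unique(train_set.y).size < 2:
        warnings.warn("training set contains a single class; "
                      "the fit will be degenerate", stacklevel=2)
    train_set.with_cached_products()
    val_set.with_cached_products()

    rng = np.random.default_rng(cfg.seed)
    params = params.copy()
    best = params.copy()
    best_loss = np.inf
    history = TrainHistory()
    stall = 0
    n = len(train_set)
    train_targets = train_set.targets
    val_targets = val_set.targets

    for epoch in range(1, cfg.epochs + 1):
        order = rng.permutation(n)
        epoch_losses = []
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            grads, loss = gradients(
                (train_set.X[idx], train_set.A[idx]), train_targets[idx],
                params, AX=train_set.AX[idx],
            )
            sgd_step(params, grads, cfg.lr)
            epoch_losses.append(loss)
        val_scores = _scores(val_set, params)
        v_loss = mse_loss(val_scores, val_targets)
        v_acc = float(np.mean(
            np.argmax(val_scores, axis=1) == val_set.y
        ))
        history.train_loss.append(float(np.mean(epoch_losses)))
        history.val_loss.append(v_loss)
        history.val_accuracy.append(v_acc)
        history.stopped_epoch = epoch
        if v_loss < best_loss:
            best_loss = v_loss
            best = params.copy()
            history.best_epoch = epoch
            stall = 0
        else:
            stall += 1
            if stall >= cfg.patience:
                break
    return best, history


# ---------------------------------------------------------------------------
# metrics


def roc_auc(scores: np.ndarray, labels: np.ndarray
            ) -> tuple[list[tuple[float, float]], float]:
    """ROC points by threshold sweep and trapezoid AUC.

    ``labels`` are 1 for the positive class.  The trapezoid area equals
    the Mann-Whitney pairwise statistic with ties counted 1/2.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if np.unique(labels).size < 2:
        raise ValueError("ROC requires both classes present")
    fpr, tpr, _ = roc_curve(labels, scores)
    auc = float(np.trapezoid(tpr, fpr))
    return list(zip(fpr.tolist(), tpr.tolist())), auc


def metrics_from_scores(pos_score: np.ndarray, actual_pos: np.ndarray,
                        threshold: float = 0.5) -> EvalMetrics:
    """Confusion metrics from positive-class scores and boolean truth."""
    pos_score = np.asarray(pos_score, dtype=float)
    actual_pos = np.asarray(actual_pos, dtype=bool)
    if pos_score.size == 0:
        raise ValueError("empty test set")
    predicted_pos = pos_score >= threshold
    tp = int(np.sum(predicted_pos & actual_pos))
    tn = int(np.sum(~predicted_pos & ~actual_pos))
    fp = int(np.sum(predicted_pos & ~actual_pos))
    fn = int(np.sum(~predicted_pos & actual_pos))
    total = tp + tn + fp + fn
    accuracy = (tp + tn) / total
    sensitivity = tp / (tp + fn) if tp + fn else float("nan")
    specificity = tn / (tn + fp) if tn + fp else float("nan")
    if np.unique(actual_pos).size == 2:
        roc_points, auc = roc_auc(pos_score, actual_pos.astype(int))
    else:
        roc_points, auc = [], float("nan")
    return EvalMetrics(accuracy=accuracy, sensitivity=sensitivity,
                       specificity=specificity, auc=auc,
                       roc_points=roc_points, tp=tp, tn=tn, fp=fp, fn=fn)


def evaluate(params: ModelParams,
             test_set: StackedDataset | Sequence[GraphSample],
             threshold: float = 0.5) -> EvalMetrics:
    """Confusion-matrix metrics with "responsive" as the positive class.

    A sample is predicted positive when its responsive-class score is
    >= threshold; the ROC sweeps the same score.
    """
    if not isinstance(test_set, StackedDataset):
        test_set = stack_samples(test_set)
    if len(test_set) == 0:
        raise ValueError("empty test set")
    scores = _scores(test_set, params)
    pos_idx = CLASS_ORDER.index(POSITIVE_CLASS)
    return metrics_from_scores(scores[:, pos_idx], test_set.y == pos_idx,
                               threshold)


def aggregate_metrics(fold_metrics: Sequence[EvalMetrics]
                      ) -> tuple[dict[str, float], dict[str, float]]:
    """Mean and sample standard deviation of the headline metrics."""
    keys = ("accuracy", "sensitivity", "specificity", "auc")
    mean = {k: float(np.mean([getattr(m, k) for m in fold_metrics]))
            for k in keys}
    std = {k: float(np.std([getattr(m, k) for m in fold_metrics], ddof=1))
           for k in keys}
    return mean, std


# ---------------------------------------------------------------------------
# cross-validation


@dataclass
class CVResult:
    fold_metrics: list[EvalMetrics]
    fold_histories: list[TrainHistory]
    mean: dict[str, float]
    std: dict[str, float]


def kfold_cv(dataset: StackedDataset | Sequence[GraphSample],
             cfg: TrainConfig | None = None,
             arch: ArchConfig | None = None) -> CVResult:
    """Stratified k-fold cross-validation, one fresh model per fold.

    Fold f trains from ``init_params(arch, cfg.seed + f)`` on the other
    folds, using the held-out fold both for early stopping and for the
    fold's metrics.  Every sample lands in exactly one validation fold.
    """
    cfg = cfg or TrainConfig()
    if not isinstance(dataset, StackedDataset):
        dataset = stack_samples(dataset)
    class_counts = np.bincount(dataset.y, minlength=2)
    if class_counts.min() < cfg.k_folds:
        raise ValueError(
            f"need >= k={cfg.k_folds} samples per class, got {class_counts.tolist()}"
        )
    if arch is None:
        arch = ArchConfig(n_nodes=dataset.X.shape[1],
                          feature_dim=dataset.X.shape[2])
    dataset.with_cached_products()
    skf = StratifiedKFold(n_splits=cfg.k_folds, shuffle=True,
                          random_state=cfg.seed)
    fold_metrics, fold_histories = [], []
    for fold, (tr, va) in enumerate(skf.split(dataset.X[:, 0, 0], dataset.y)):
        params = init_params(arch, cfg.seed + fold)
        best, history = train(dataset.subset(tr), dataset.subset(va),
                              params, cfg)
        fold_metrics.append(evaluate(best, dataset.subset(va)))
        fold_histories.append(history)
    mean, std = aggregate_metrics(fold_metrics)
    return CVResult(fold_metrics=fold_metrics, fold_histories=fold_histories,
                    mean=mean, std=std)


def holdout_split(dataset: StackedDataset | Sequence[GraphSample],
                  cfg: TrainConfig | None = None
                  ) -> tuple[StackedDataset, StackedDataset]:
    """Stratified (train+CV, hold-out test) split, seeded by cfg.seed."""
    cfg = cfg or TrainConfig()
    if not isinstance(dataset, StackedDataset):
        dataset = stack_samples(dataset)
    if cfg.holdout_fraction == 0:
        return dataset, dataset.subset(np.array([], dtype=int))
    idx = np.arange(len(dataset))
    rest, hold = train_test_split(
        idx, test_size=cfg.holdout_fraction, stratify=dataset.y,
        random_state=cfg.seed,
    )
    return dataset.subset(rest), dataset.subset(hold)
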