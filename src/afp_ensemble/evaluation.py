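"""Confusion-matrix metrics and stratified K-fold cross-validation.

Sensitivity Sn = TP/(TP+FN), specificity Sp = TN/(TN+FP), accuracy
Acc = (TP+TN)/(TP+FP+TN+FN) and balanced accuracy BAcc = (Sn+Sp)/2.
BAcc is the headline metric under class imbalance: the all-majority
classifier scores BAcc = 0.5 at any imbalance ratio, while its Acc can be
arbitrarily high.  Cross-validation pools per-fold predictions into a
single confusion matrix (micro average) before applying the formulas —
per-fold rates are unstable with few positives per fold — and also
retains the per-fold reports.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from sklearn.model_selection import StratifiedKFold

from . import ensemble as ens
from .feature_assembly import FeatureMatrix


@dataclass(frozen=True)
class MetricsReport:
    """Confusion counts and the four derived rates.

    When a class is absent from ``y_true`` the corresponding rate (and
    BAcc) is NaN and the matching ``*_defined`` flag is False — never a
    silent zero.
    """

    TP: int
    FP: int
    TN: int
    FN: int
    Sn: float
    Sp: float
    Acc: float
    BAcc: float
    sn_defined: bool = True
    sp_defined: bool = True

    @property
    def n_positive(self) -> int:
        return self.TP + self.FN

    @property
    def n_negative(self) -> int:
        return self.TN + self.FP


def balanced_accuracy(sn: float, sp: float) -> float:
    """BAcc = (Sn + Sp)/2 from a (sensitivity, specificity) pair."""
    return 0.5 * (sn + sp)


def metrics_from_counts(tp: int, fp: int, tn: int, fn: int) -> MetricsReport:
    """Exact evaluation of the four rate formulas from confusion counts."""
    if min(tp, fp, tn, fn) < 0:
        raise ValueError("confusion counts must be non-negative")
    total = tp + fp + tn + fn
    if total == 0:
        raise ValueError("empty confusion matrix")
    sn_defined = (tp + fn) > 0
    sp_defined = (tn + fp) > 0
    sn = tp / (tp + fn) if sn_defined else math.nan
    sp = tn / (tn + fp) if sp_defined else math.nan
    bacc = (
        balanced_accuracy(sn, sp)
        if sn_defined and sp_defined else math.nan
    )
    return MetricsReport(
        TP=tp, FP=fp, TN=tn, FN=fn,
        Sn=sn, Sp=sp, Acc=(tp + tn) / total, BAcc=bacc,
        sn_defined=sn_defined, sp_defined=sp_defined,
    )


def compute_metrics(y_true, y_pred) -> MetricsReport:
    """Confusion-matrix metrics for binary label vectors (positive = 1)."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape or y_true.ndim != 1:
        raise ValueError("y_true and y_pred must be equal-length vectors")
    if not (np.isin(y_true, (0, 1)).all() and np.isin(y_pred, (0, 1)).all()):
        raise ValueError("labels must be binary")
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    return metrics_from_counts(tp, fp, tn, fn)


def stratified_kfold(
    X: FeatureMatrix, K: int = 10, seed: int = 0
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Per-class partition into K near-equal folds (sizes differ by <= 1).

    Fold k's test set is subset k of each class; returns ``(train_index,
    test_index)`` pairs that are disjoint and exhaustive.
    """
    if X.labels is None:
        raise ValueError("stratified_kfold requires labels")
    counts = np.bincount(X.labels, minlength=2)
    if counts.min() < K:
        raise ValueError(
            f"smallest class has {counts.min()} samples, fewer than "
            f"K={K} folds"
        )
    splitter = StratifiedKFold(n_splits=K, shuffle=True, random_state=seed)
    return [
        (train_idx, test_idx)
        for train_idx, test_idx in splitter.split(X.values, X.labels)
    ]


@dataclass(frozen=True)
class CVResult:
    """Pooled cross-validation metrics plus the per-fold reports."""

    pooled: MetricsReport
    per_fold: tuple[MetricsReport, ...]


def cross_validate(
    X: FeatureMatrix,
    config: ens.EnsembleConfig | None = None,
    K: int = 10,
    seed: int = 0,
) -> CVResult:
    """Stratified K-fold CV of the full undersampling-ensemble pipeline.

    Negative sampling is re-drawn independently inside each training fold
    (sampling seed derived from ``seed`` and the fold index), so every
    fold sees its own undersampled ensemble.
    """
    config = config or ens.EnsembleConfig()
    folds = stratified_kfold(X, K=K, seed=seed)
    y_true_all: list[np.ndarray] = []
    y_pred_all: list[np.ndarray] = []
    per_fold: list[MetricsReport] = []
    for fold_idx, (train_idx, test_idx) in enumerate(folds):
        fold_seed = (seed * 100003 + fold_idx) % (2**31 - 1)
        fold_config = ens.EnsembleConfig(
            G=config.G,
            n_trees=config.n_trees,
            max_features=config.max_features,
            seed=fold_seed,
            base_learner=config.base_learner,
            allow_any_G=config.allow_any_G,
        )
        model = ens.train(X.select_rows(train_idx), fold_config)
        test = X.select_rows(test_idx)
        y_pred, _ = ens.predict(model, test)
        y_true_all.append(test.labels)
        y_pred_all.append(y_pred)
        per_fold.append(compute_metrics(test.labels, y_pred))
    pooled = compute_metrics(
        np.concatenate(y_true_all), np.concatenate(y_pred_all)
    )
    return CVResult(pooled=pooled, per_fold=tuple(per_fold))
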