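"""k-fold cross-validation, confusion-count metrics and ROC/AUC.

Segments are split at random into k near-equal folds; each fold serves once
as the test set while the network (including its feature normalisation) is
fitted on the remaining folds only.  A true positive is an autistic segment
classified autistic.

Two flavours of the rate metrics are reported.  ``sensitivity_paper`` and
``specificity_paper`` follow the formulas exactly as printed in the source
method description — sensitivity = TN/(FP+TN), specificity = TP/(TP+FN) —
which swap the conventional definitions; ``sensitivity_std`` and
``specificity_std`` are the conventional TP/(TP+FN) and TN/(FP+TN).
Accuracy is (TP+TN)/total in both conventions.  All are percentages.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .classifier import ANNConfig, ANNModel, predict, train
from .features import FeatureVector


@dataclass
class ConfusionCounts:
    """TP/TN/FP/FN with autistic as the positive class."""

    tp: int = 0
    tn: int = 0
    fp: int = 0
    fn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.tp + other.tp, self.tn + other.tn,
                               self.fp + other.fp, self.fn + other.fn)


def kfold_split(n: int, k: int, seed: int) -> list[np.ndarray]:
    """k disjoint, exhaustive test-index sets with sizes differing by <= 1."""
    if k < 2:
        raise ValueError("k must be >= 2")
    if n < k:
        raise ValueError(f"cannot split {n} samples into {k} folds")
    perm = np.random.default_rng(seed).permutation(n)
    return [np.sort(f) for f in np.array_split(perm, k)]


def stratified_kfold_split(labels: Sequence[str], k: int, seed: int) -> list[np.ndarray]:
    """Random folds with near-equal class proportions in every fold.

    Keeps each test fold's class mix representative of the whole dataset, so
    a degenerate majority-class model scores ~50% instead of tracking the
    train/test imbalance (which plain random folds push in opposite
    directions).
    """
    from sklearn.model_selection import StratifiedKFold

    y = np.asarray(labels)
    if len(y) < k:
        raise ValueError(f"cannot split {len(y)} samples into {k} folds")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return [np.sort(test) for _, test in skf.split(np.zeros(len(y)), y)]


def confusion_metrics(c: ConfusionCounts) -> dict[str, float]:
    """Percentage metrics from confusion counts.

    Zero-denominator metrics are reported as NaN (not available) rather than
    raising.
    """
    def rate(num: int, den: int) -> float:
        return 100.0 * num / den if den > 0 else math.nan

    return {
        "sensitivity_paper": rate(c.tn, c.fp + c.tn),
        "specificity_paper": rate(c.tp, c.tp + c.fn),
        "sensitivity_std": rate(c.tp, c.tp + c.fn),
        "specificity_std": rate(c.tn, c.fp + c.tn),
        "accuracy": rate(c.tp + c.tn, c.total),
    }


def roc_auc(scores: Sequence[tuple[str, float]]) -> tuple[list[tuple[float, float]], float]:
    """ROC points and trapezoidal AUC from (true-label, p_autistic) pairs.

    The AUC equals the probability that a random positive outscores a random
    negative, with ties counted one half.  Requires both classes present.
    """
    from sklearn.metrics import roc_curve

    y = np.array([1 if lab == "autistic" else 0 for lab, _ in scores])
    s = np.array([p for _, p in scores], dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("ROC requires both classes present")
    fpr, tpr, _ = roc_curve(y, s, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    return list(zip(fpr.tolist(), tpr.tolist())), auc


@dataclass
class EvaluationReport:
    """Per-fold confusion counts and metrics plus pooled ROC/AUC."""

    fold_counts: list[ConfusionCounts]
    fold_metrics: list[dict[str, float]]
    mean_accuracy: float            # mean of per-fold accuracies, %
    pooled_counts: ConfusionCounts
    pooled_metrics: dict[str, float]
    roc_points: list[tuple[float, float]]
    auc: float
    n: int
    k: int
    seed: int
    models: list | None = None  # per-fold ANNModel when requested

    def to_dict(self) -> dict:
        return {
            "n": self.n, "k": self.k, "seed": self.seed,
            "mean_accuracy": self.mean_accuracy,
            "auc": self.auc,
            "pooled_counts": vars(self.pooled_counts),
            "pooled_metrics": self.pooled_metrics,
            "fold_counts": [vars(c) for c in self.fold_counts],
            "fold_metrics": self.fold_metrics,
            "roc_points": self.roc_points,
        }


def run_cross_validation(
    features: Sequence[FeatureVector],
    k: int = 10,
    seed: int = 0,
    ann_config: ANNConfig | None = None,
    stratified: bool = True,
    return_models: bool = False,
) -> EvaluationReport:
    """k-fold cross-validation of the network on labelled feature vectors.

    Each fold's model (weights *and* normalisation statistics) sees only that
    fold's training indices.  The report aggregates confusion counts over
    folds, averages per-fold accuracies, and computes ROC/AUC on the pooled
    test scores.  Folds are stratified by class label by default (see
    :func:`stratified_kfold_split`); pass ``stratified=False`` for plain
    random folds.  Deterministic given ``seed`` and ``ann_config.seed``.
    """
    n = len(features)
    labels = {fv.label for fv in features}
    if not {"autistic", "normal"} <= labels:
        raise ValueError(f"cross-validation needs both classes, got {sorted(labels)}")
    if stratified:
        folds = stratified_kfold_split([fv.label for fv in features], k, seed)
    else:
        folds = kfold_split(n, k, seed)
    ann_config = ann_config or ANNConfig()

    fold_counts: list[ConfusionCounts] = []
    fold_metrics: list[dict[str, float]] = []
    pooled_scores: list[tuple[str, float]] = []
    models = []
    for fold_id, test_idx in enumerate(folds):
        test_set = set(test_idx.tolist())
        train_fv = [fv for i, fv in enumerate(features) if i not in test_set]
        test_fv = [features[i] for i in test_idx]
        try:
            model = train(train_fv, ann_config)
        except ValueError as exc:
            raise ValueError(f"fold {fold_id}: {exc}") from exc
        preds = predict(model, test_fv)
        c = ConfusionCounts()
        for fv, (pred_label, probs) in zip(test_fv, preds):
            if fv.label == "autistic":
                if pred_label == "autistic":
                    c.tp += 1
                else:
                    c.fn += 1
            else:
                if pred_label == "autistic":
                    c.fp += 1
                else:
                    c.tn += 1
            pooled_scores.append((fv.label, probs[0]))
        fold_counts.append(c)
        fold_metrics.append(confusion_metrics(c))
        if return_models:
            models.append(model)

    pooled = sum(fold_counts, ConfusionCounts())
    roc_points, auc = roc_auc(pooled_scores)
    accs = [m["accuracy"] for m in fold_metrics if not math.isnan(m["accuracy"])]
    return EvaluationReport(
        fold_counts=fold_counts,
        fold_metrics=fold_metrics,
        mean_accuracy=float(np.mean(accs)),
        pooled_counts=pooled,
        pooled_metrics=confusion_metrics(pooled),
        roc_points=roc_points,
        auc=auc,
        n=n, k=k, seed=seed,
        models=models if return_models else None,
    )
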