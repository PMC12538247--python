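"""Classification metrics, ROC curves, and the k-fold cross-validation protocol.

Binary metrics are computed from the confusion-matrix counts:

    accuracy  = (TP + TN) / (TP + TN + FP + FN)
    precision = TP / (TP + FP)
    recall    = TP / (TP + FN)
    F1        = 2 * precision * recall / (precision + recall)

and the ROC curve sweeps a decision threshold over the positive-class
score, plotting TPR = TP/(TP+FN) against FPR = FP/(FP+TN).

Zero-denominator cases (no predicted positives, no true positives, or
precision + recall = 0) return 0 with a logged warning rather than raising:
grid-search tables must stay total even when a degenerate fold predicts a
single class.

Cross-validation forms k folds at the trial level by default (all segments
of a trial stay in one fold, preventing overlap leakage) and reports
per-fold metrics with mean and sample standard deviation (the (k-1)
denominator).
"""

from __future__ import annotations

import logging
import warnings
from collections.abc import Mapping, Sequence
from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd

from .errors import ValidationError

logger = logging.getLogger(__name__)

METRIC_NAMES = ("accuracy", "precision", "recall", "f1")


@dataclass(frozen=True)
class ConfusionMatrix:
    """TP/FP/TN/FN counts for one binary task."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValidationError("confusion counts must be non-negative")
        if self.total < 1:
            raise ValidationError("confusion matrix must cover at least one sample")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def as_table(self) -> pd.DataFrame:
        """2x2 table: rows = actual class, columns = predicted class."""
        return pd.DataFrame(
            [[self.tn, self.fp], [self.fn, self.tp]],
            index=pd.Index(["negative", "positive"], name="actual"),
            columns=pd.Index(["negative", "positive"], name="predicted"),
        )


def confusion(y_true: Sequence[int], y_pred: Sequence[int]) -> ConfusionMatrix:
    """Count TP/FP/TN/FN from aligned binary label vectors (1 = positive)."""
    yt = np.asarray(y_true)
    yp = np.asarray(y_pred)
    if yt.shape != yp.shape or yt.ndim != 1:
        raise ValidationError(
            f"y_true and y_pred must be equal-length 1-D vectors, "
            f"got {yt.shape} vs {yp.shape}"
        )
    if yt.size < 1:
        raise ValidationError("need at least one sample")
    if not (np.isin(yt, (0, 1)).all() and np.isin(yp, (0, 1)).all()):
        raise ValidationError("labels must be binary (0 = negative, 1 = positive)")
    return ConfusionMatrix(
        tp=int(np.sum((yt == 1) & (yp == 1))),
        fp=int(np.sum((yt == 0) & (yp == 1))),
        tn=int(np.sum((yt == 0) & (yp == 0))),
        fn=int(np.sum((yt == 1) & (yp == 0))),
    )


def _safe_ratio(num: int, den: int, what: str) -> float:
    if den == 0:
        logger.warning("%s undefined (zero denominator); returning 0", what)
        return 0.0
    return num / den


def accuracy(cm: ConfusionMatrix) -> float:
    return (cm.tp + cm.tn) / cm.total


def precision(cm: ConfusionMatrix) -> float:
    return _safe_ratio(cm.tp, cm.tp + cm.fp, "precision")


def recall(cm: ConfusionMatrix) -> float:
    return _safe_ratio(cm.tp, cm.tp + cm.fn, "recall")


def f1(cm: ConfusionMatrix) -> float:
    p, r = precision(cm), recall(cm)
    if p + r == 0.0:
        logger.warning("F1 undefined (precision + recall = 0); returning 0")
        return 0.0
    return 2.0 * p * r / (p + r)


def metrics_record(cm: ConfusionMatrix) -> dict[str, float]:
    """All four scalar metrics of one confusion matrix."""
    return {"accuracy": accuracy(cm), "precision": precision(cm),
            "recall": recall(cm), "f1": f1(cm)}


def macro_metrics(y_true: Sequence[int], y_pred: Sequence[int],
                  classes: Sequence[int]) -> dict[str, float]:
    """Macro-averaged one-vs-rest metrics for a multiclass task (SEED mode).

    Accuracy is the plain hit rate; precision/recall/F1 are averaged over
    per-class one-vs-rest confusion matrices.
    """
    yt = np.asarray(y_true)
    yp = np.asarray(y_pred)
    if yt.shape != yp.shape:
        raise ValidationError("length mismatch")
    per_class = [metrics_record(confusion((yt == c).astype(int), (yp == c).astype(int)))
                 for c in classes]
    out = {k: float(np.mean([m[k] for m in per_class]))
           for k in ("precision", "recall", "f1")}
    out["accuracy"] = float(np.mean(yt == yp))
    return out


# ---------------------------------------------------------------------------
# ROC
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RocPoint:
    """One operating point: classify positive when score >= threshold."""

    threshold: float
    fpr: float
    tpr: float


def roc_curve(y_true: Sequence[int], scores: Sequence[float]) -> list[RocPoint]:
    """Threshold sweep over the distinct scores, ties grouped into one step.

    The curve starts at (0, 0) (threshold +inf: nothing positive) and ends
    at (1, 1) (threshold -inf: everything positive); FPR and TPR are
    non-decreasing along the sweep.
    """
    yt = np.asarray(y_true)
    s = np.asarray(scores, dtype=float)
    if yt.shape != s.shape or yt.ndim != 1:
        raise ValidationError("y_true and scores must be equal-length 1-D vectors")
    n_pos = int(np.sum(yt == 1))
    n_neg = int(np.sum(yt == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValidationError("ROC needs at least one positive and one negative sample")
    order = np.argsort(-s, kind="stable")
    s_sorted = s[order]
    y_sorted = yt[order]
    points = [RocPoint(threshold=np.inf, fpr=0.0, tpr=0.0)]
    tp = fp = 0
    i = 0
    n = len(s_sorted)
    while i < n:
        thr = s_sorted[i]
        while i < n and s_sorted[i] == thr:  # group tied scores into one step
            if y_sorted[i] == 1:
                tp += 1
            else:
                fp += 1
            i += 1
        points.append(RocPoint(threshold=float(thr), fpr=fp / n_neg, tpr=tp / n_pos))
    return points


def roc_points_frame(points: Sequence[RocPoint]) -> pd.DataFrame:
    return pd.DataFrame([{"threshold": p.threshold, "fpr": p.fpr, "tpr": p.tpr}
                         for p in points])


def auc(points: Sequence[RocPoint]) -> float:
    """Trapezoidal area under the ROC curve."""
    f = np.array([p.fpr for p in points])
    t = np.array([p.tpr for p in points])
    return float(np.trapezoid(t, f))


# ---------------------------------------------------------------------------
# k-fold cross-validation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CVReport:
    """Per-fold metric records plus mean +/- sample std per metric per label."""

    per_fold: tuple[Mapping[str, Mapping[str, float]], ...]  # fold -> label -> metric

    def __post_init__(self) -> None:
        if len(self.per_fold) < 2:
            raise ValidationError("a CV report needs k >= 2 folds")

    @property
    def k(self) -> int:
        return len(self.per_fold)

    def summary(self) -> pd.DataFrame:
        """Long-format table: label, metric, mean, std (ddof=1), per-fold values."""
        rows = []
        labels = list(self.per_fold[0])
        for label in labels:
            for metric in self.per_fold[0][label]:
                vals = np.array([fold[label][metric] for fold in self.per_fold])
                rows.append({
                    "label": label,
                    "metric": metric,
                    "mean": float(vals.mean()),
                    "std": float(vals.std(ddof=1)),
                })
        return pd.DataFrame(rows)

    def formatted(self) -> pd.DataFrame:
        """Wide "mean +/- std" strings, metric rows x label columns."""
        s = self.summary()
        s["cell"] = [f"{m:.3f} ± {sd:.3f}" for m, sd in zip(s["mean"], s["std"])]
        return s.pivot(index="metric", columns="label", values="cell")


def kfold_indices(n: int, k: int, seed: int = 0) -> list[np.ndarray]:
    """Shuffled k-fold partition of range(n): disjoint, exhaustive, sizes within 1."""
    if k < 2:
        raise ValidationError("k must be >= 2")
    if k > n:
        raise ValidationError(f"k={k} exceeds the number of units n={n}")
    order = np.random.default_rng(seed).permutation(n)
    return [np.sort(chunk) for chunk in np.array_split(order, k)]


def cross_validate(
    units: Sequence,
    k: int,
    evaluate_fold: Callable[[list, list], Mapping[str, Mapping[str, float]]],
    seed: int = 0,
) -> CVReport:
    """k-fold CV over ``units`` (trials by default, matching the split unit).

    Each unit lands in exactly one test fold; ``evaluate_fold(train, test)``
    trains on the k-1 remaining folds and returns {label: {metric: value}}.
    """
    units = list(units)
    folds = kfold_indices(len(units), k, seed=seed)
    records = []
    for test_idx in folds:
        test_set = set(test_idx.tolist())
        train = [u for i, u in enumerate(units) if i not in test_set]
        test = [units[i] for i in test_idx]
        records.append(evaluate_fold(train, test))
    return CVReport(per_fold=tuple(records))


def plot_roc(points: Sequence[RocPoint], path, label: str = "") -> None:
    """Write a ROC curve plot to ``path`` (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 4))
    ax.plot([p.fpr for p in points], [p.tpr for p in points], marker=".",
            label=f"{label} (AUC={auc(points):.3f})" if label else None)
    ax.plot([0, 1], [0, 1], "k--", lw=0.8)
    ax.set_xlabel("False positive rate")
    ax.set_ylabel("True positive rate")
    if label:
        ax.legend(loc="lower right")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
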