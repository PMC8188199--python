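"""Performance metrics for trained classifiers.

Produces the full report a practitioner expects after training: confusion
matrix (rows = true class, columns = predicted), per-class precision /
recall / F1 / support, overall accuracy, one-vs-rest ROC and
precision-recall curves with trapezoidal AUCs, and the raw per-sample
probabilities.  Curve points are taken at every distinct predicted
probability (prediction positive when p >= threshold).

Also includes the probability-threshold purity analysis used for binary
sorting decisions: among events with p(positive) strictly above an upper
threshold, which fraction truly belongs to the positive class, and below a
lower threshold, which fraction belongs to the negative class; events
between the thresholds stay unassigned.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.metrics import (
    confusion_matrix,
    precision_recall_curve,
    precision_recall_fscore_support,
    roc_curve,
)

__all__ = [
    "EvaluationReport",
    "evaluate",
    "evaluate_probabilities",
    "confusion_cell_examples",
    "ThresholdPurity",
    "threshold_purity",
    "mean_sd",
]


@dataclass
class EvaluationReport:
    class_names: list
    confusion: np.ndarray          # (K, K) int, rows true / cols predicted
    precision: np.ndarray          # per class, one-vs-rest
    recall: np.ndarray
    f1: np.ndarray
    support: np.ndarray
    accuracy: float
    roc_points: list               # per class: (fpr, tpr) arrays
    pr_points: list                # per class: (recall, precision) arrays
    roc_auc: np.ndarray
    pr_auc: np.ndarray
    probabilities: np.ndarray      # (N, K)
    zero_division_classes: list = field(default_factory=list)

    @property
    def n_classes(self):
        return len(self.class_names)

    def per_class_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "class": self.class_names,
                "precision": self.precision,
                "recall": self.recall,
                "f1": self.f1,
                "support": self.support,
                "roc_auc": self.roc_auc,
                "pr_auc": self.pr_auc,
            }
        )

    def to_csv(self, path):
        self.per_class_table().to_csv(path, index=False)
        return path

    def confusion_to_csv(self, path):
        pd.DataFrame(
            self.confusion, index=self.class_names, columns=self.class_names
        ).to_csv(path)
        return path

    def to_json(self, path):
        payload = {
            "class_names": self.class_names,
            "accuracy": self.accuracy,
            "confusion": self.confusion.tolist(),
            "precision": self.precision.tolist(),
            "recall": self.recall.tolist(),
            "f1": self.f1.tolist(),
            "support": self.support.tolist(),
            "roc_auc": self.roc_auc.tolist(),
            "pr_auc": self.pr_auc.tolist(),
            "roc_points": [
                {"fpr": f.tolist(), "tpr": t.tolist()} for f, t in self.roc_points
            ],
            "pr_points": [
                {"recall": r.tolist(), "precision": p.tolist()}
                for r, p in self.pr_points
            ],
            "zero_division_classes": self.zero_division_classes,
        }
        Path(path).write_text(json.dumps(payload, indent=1))
        return path


def _trapezoid(y, x):
    return float(np.trapezoid(y, x))


def evaluate_probabilities(probabilities, labels, class_names=None
                           ) -> EvaluationReport:
    """Build a report from predicted class probabilities and true labels."""
    probs = np.asarray(probabilities, dtype=np.float64)
    labels = np.asarray(labels)
    if probs.ndim != 2:
        raise ValueError("probabilities must be (N, K)")
    n, k = probs.shape
    if class_names is None:
        class_names = [str(i) for i in range(k)]
    if len(class_names) != k:
        raise ValueError(
            f"{len(class_names)} class names for {k} probability columns"
        )
    if labels.max() >= k or labels.min() < 0:
        raise ValueError("labels out of range for probability columns")
    row_sums = probs.sum(axis=1)
    if np.any(np.abs(row_sums - 1.0) > 1e-5):
        raise ValueError("probability rows must sum to 1 (tolerance 1e-5)")

    pred = probs.argmax(axis=1)
    conf = confusion_matrix(labels, pred, labels=np.arange(k))
    precision, recall, f1, support = precision_recall_fscore_support(
        labels, pred, labels=np.arange(k), zero_division=0
    )
    zero_div = [
        class_names[c]
        for c in range(k)
        if (pred == c).sum() == 0 or (labels == c).sum() == 0
    ]
    accuracy = float(np.trace(conf) / n)

    roc_points, pr_points, roc_auc, pr_auc = [], [], [], []
    for c in range(k):
        truth = (labels == c).astype(int)
        score = probs[:, c]
        if truth.sum() in (0, n):
            # degenerate one-vs-rest split: curves undefined
            roc_points.append((np.array([0.0, 1.0]), np.array([0.0, 1.0])))
            pr_points.append((np.array([0.0, 1.0]), np.array([1.0, 1.0])))
            roc_auc.append(np.nan)
            pr_auc.append(np.nan)
            continue
        fpr, tpr, _ = roc_curve(truth, score, drop_intermediate=False)
        roc_points.append((fpr, tpr))
        roc_auc.append(_trapezoid(tpr, fpr))
        prec, rec, _ = precision_recall_curve(truth, score)
        # precision_recall_curve returns recall descending from 1 to 0
        pr_points.append((rec, prec))
        pr_auc.append(-_trapezoid(prec, rec))

    return EvaluationReport(
        class_names=list(class_names),
        confusion=conf,
        precision=precision,
        recall=recall,
        f1=f1,
        support=support,
        accuracy=accuracy,
        roc_points=roc_points,
        pr_points=pr_points,
        roc_auc=np.array(roc_auc),
        pr_auc=np.array(pr_auc),
        probabilities=probs,
        zero_division_classes=zero_div,
    )


def evaluate(predictor, data) -> EvaluationReport:
    """Run ``predictor`` on an :class:`~imgtrain.imageset.ImageSet`.

    ``predictor`` must expose ``predict_proba(images)`` over uint8 image
    arrays (e.g. a fitted :class:`~imgtrain.estimators.ImageClassifier`).
    """
    probs = predictor.predict_proba(data.images)
    if probs.shape[1] != data.n_classes:
        raise ValueError(
            f"predictor emits {probs.shape[1]} classes, dataset has "
            f"{data.n_classes}"
        )
    return evaluate_probabilities(probs, data.labels, data.class_names)


def confusion_cell_examples(true_labels, pred_labels, source_ids, cell):
    """Source ids of samples with true class ``cell[0]`` predicted ``cell[1]``.

    This is the drill-down behind an interactive confusion matrix: the
    returned list's length equals the corresponding confusion-matrix entry.
    """
    true_labels = np.asarray(true_labels)
    pred_labels = np.asarray(pred_labels)
    i, j = cell
    k = int(max(true_labels.max(), pred_labels.max())) + 1
    if not (0 <= i < k and 0 <= j < k):
        raise IndexError(f"cell {cell} out of range for {k} classes")
    mask = (true_labels == i) & (pred_labels == j)
    return [source_ids[n] for n in np.flatnonzero(mask)]


@dataclass
class ThresholdPurity:
    """Purity of the strata above/below two probability thresholds.

    ``above_fraction`` is the fraction of events with p(positive) strictly
    above ``upper`` that truly are positive; ``below_fraction`` the fraction
    strictly below ``lower`` that truly are negative.  ``None`` marks an
    empty (undefined) stratum.  Events in [lower, upper] are unassigned.
    """

    above_fraction: float | None
    below_fraction: float | None
    n_above: int
    n_below: int
    n_unassigned: int


def threshold_purity(probabilities, labels, upper=0.9, lower=0.1,
                     positive_label=1) -> ThresholdPurity:
    probs = np.asarray(probabilities, dtype=np.float64)
    labels = np.asarray(labels)
    if probs.ndim != 1 or probs.shape != labels.shape:
        raise ValueError("need matching 1-D probability and label vectors")
    if not (0 <= lower < upper <= 1):
        raise ValueError(
            f"thresholds must satisfy 0 <= lower < upper <= 1, got "
            f"lower={lower}, upper={upper}"
        )
    above = probs > upper
    below = probs < lower
    n_above, n_below = int(above.sum()), int(below.sum())
    above_fraction = (
        float((labels[above] == positive_label).mean()) if n_above else None
    )
    below_fraction = (
        float((labels[below] != positive_label).mean()) if n_below else None
    )
    return ThresholdPurity(
        above_fraction=above_fraction,
        below_fraction=below_fraction,
        n_above=n_above,
        n_below=n_below,
        n_unassigned=len(probs) - n_above - n_below,
    )


def mean_sd(values):
    """Mean and sample standard deviation (n-1 denominator).

    With a single value the SD is unavailable and reported as ``None``.
    """
    values = np.asarray(values, dtype=np.float64)
    if values.size == 0:
        raise ValueError("mean_sd needs at least one value")
    mean = float(values.mean())
    if values.size < 2:
        return mean, None
    return mean, float(values.std(ddof=1))
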