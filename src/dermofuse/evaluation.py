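"""Confusion-matrix metrics with support-weighted aggregation and
one-vs-rest ROC AUC.

Per-class metrics are one-vs-rest: each class in turn is "positive" and
all others "negative", giving TP/FP/FN/TN counts from the K x K
confusion matrix.  Two per-class headline numbers are reported side by
side because they are easily conflated in the dermoscopy literature:
one-vs-rest *accuracy* ``(TP+TN)/total`` and *recall* ``TP/(TP+FN)``;
the overall (micro) accuracy is the trace of the confusion matrix over
the sample count.  Ratios with zero denominators are reported as 0 and
flagged.  AUC uses the midrank (Mann-Whitney) formulation, equivalent
to trapezoidal integration of the ROC curve with tie handling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.metrics import confusion_matrix as _sk_confusion_matrix

__all__ = ["ConfusionCounts", "MetricsReport", "confusion_matrix",
           "per_class_metrics", "weighted_average", "roc_auc",
           "evaluate_predictions"]


@dataclass
class ConfusionCounts:
    """One-vs-rest counts per class, plus the full K x K matrix."""

    classes: tuple[str, ...]
    matrix: np.ndarray  # rows: true, cols: predicted
    tp: np.ndarray
    fp: np.ndarray
    fn: np.ndarray
    tn: np.ndarray

    @property
    def support(self) -> np.ndarray:
        return self.tp + self.fn

    @property
    def total(self) -> int:
        return int(self.matrix.sum())


def confusion_matrix(y_true, y_pred,
                     classes: tuple[str, ...]) -> ConfusionCounts:
    """K x K confusion matrix and derived one-vs-rest counts."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    bad = (set(np.unique(y_true)) | set(np.unique(y_pred))) - set(classes)
    if bad:
        raise ValueError(f"labels outside the class set: {sorted(map(str, bad))}")
    m = _sk_confusion_matrix(y_true, y_pred, labels=list(classes))
    tp = np.diag(m).astype(np.int64)
    fp = m.sum(axis=0) - tp
    fn = m.sum(axis=1) - tp
    tn = m.sum() - tp - fp - fn
    return ConfusionCounts(tuple(classes), m, tp, fp, fn, tn)


def _safe_div(num, den, flags, name):
    num = np.asarray(num, dtype=float)
    den = np.asarray(den, dtype=float)
    out = np.zeros_like(num)
    ok = den > 0
    out[ok] = num[ok] / den[ok]
    for i in np.nonzero(~ok)[0]:
        flags.append(f"{name} undefined (0/0) for class index {i}; reported 0")
    return out


@dataclass
class MetricsReport:
    """Per-class and support-weighted values of the evaluation suite."""

    classes: tuple[str, ...]
    confusion: ConfusionCounts
    per_class: pd.DataFrame           # rows: classes; cols: metric names
    weighted: dict[str, float]
    overall_accuracy: float
    flags: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "classes": list(self.classes),
            "confusion_matrix": self.confusion.matrix.tolist(),
            "per_class": {c: {k: (None if pd.isna(v) else float(v))
                              for k, v in row.items()}
                          for c, row in self.per_class.iterrows()},
            "weighted": {k: (None if pd.isna(v) else float(v))
                         for k, v in self.weighted.items()},
            "overall_accuracy": float(self.overall_accuracy),
            "flags": list(self.flags),
        }


def per_class_metrics(cc: ConfusionCounts) -> MetricsReport:
    """Accuracy, recall, specificity, precision and F1 per class (one-vs-rest),
    with support-weighted averages."""
    flags: list[str] = []
    total = cc.total
    acc = (cc.tp + cc.tn) / total if total else np.zeros(len(cc.classes))
    recall = _safe_div(cc.tp, cc.tp + cc.fn, flags, "recall")
    specificity = _safe_div(cc.tn, cc.tn + cc.fp, flags, "specificity")
    precision = _safe_div(cc.tp, cc.tp + cc.fp, flags, "precision")
    f1 = _safe_div(2 * precision * recall, precision + recall, flags, "F1")
    frame = pd.DataFrame(
        {"accuracy": acc, "recall": recall, "specificity": specificity,
         "precision": precision, "f1": f1},
        index=pd.Index(cc.classes, name="class"))
    support = cc.support
    weighted = {k: weighted_average(frame[k].to_numpy(), support)
                for k in frame.columns}
    overall = float(np.trace(cc.matrix) / total) if total else 0.0
    return MetricsReport(cc.classes, cc, frame, weighted, overall, flags)


def weighted_average(values, supports) -> float:
    """Support-weighted mean: sum(P_i * support_i) / sum(support_i)."""
    values = np.asarray(values, dtype=float)
    supports = np.asarray(supports, dtype=float)
    mask = ~np.isnan(values)
    tot = supports[mask].sum()
    if tot == 0:
        return float("nan")
    return float((values[mask] * supports[mask]).sum() / tot)


def roc_auc(y_true, scores: np.ndarray,
            classes: tuple[str, ...]) -> tuple[dict[str, float], float]:
    """One-vs-rest AUC per class (midrank / Mann-Whitney) + weighted AUC.

    ``scores`` is (n_samples, n_classes) of class scores (columns in the
    order of ``classes``).  A class absent from ``y_true`` has undefined
    AUC (NaN) and is excluded from the weighted average.
    """
    y_true = np.asarray(y_true)
    scores = np.asarray(scores, dtype=float)
    if scores.shape != (len(y_true), len(classes)):
        raise ValueError(f"scores must be (n_samples, {len(classes)})")
    aucs: dict[str, float] = {}
    supports = []
    for j, cls in enumerate(classes):
        pos = y_true == cls
        n_pos, n_neg = int(pos.sum()), int((~pos).sum())
        supports.append(n_pos)
        if n_pos == 0 or n_neg == 0:
            aucs[cls] = float("nan")
            continue
        ranks = rankdata(scores[:, j])  # midranks handle ties
        u = ranks[pos].sum() - n_pos * (n_pos + 1) / 2
        aucs[cls] = float(u / (n_pos * n_neg))
    weighted = weighted_average(list(aucs.values()), supports)
    return aucs, weighted


def evaluate_predictions(y_true, y_pred, scores: np.ndarray | None,
                         classes: tuple[str, ...]) -> MetricsReport:
    """Full metric suite from labels, predictions and optional scores."""
    cc = confusion_matrix(y_true, y_pred, classes)
    report = per_class_metrics(cc)
    if scores is not None:
        aucs, wauc = roc_auc(y_true, scores, classes)
        report.per_class["auc"] = [aucs[c] for c in classes]
        report.weighted["auc"] = wauc
    return report
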