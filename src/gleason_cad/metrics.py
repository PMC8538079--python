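"""Multi-class evaluation metrics.

All metrics derive from a single confusion matrix (rows = true class,
columns = predicted class).  Per-class metrics are one-vs-rest:
precision TP/(TP+FP), recall TP/(TP+FN), F1 = 2PR/(P+R), accuracy
(TP+TN)/total and NPV TN/(TN+FN).  Aggregates are reported three ways:
micro (pooled counts — for single-label classification micro-precision,
micro-recall, micro-F1 and overall accuracy are all the same number),
macro (unweighted class mean) and weighted (support-weighted mean).
Undefined 0/0 ratios are reported as 0 with a warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class ConfusionMatrix:
    counts: np.ndarray  # K x K, rows true, cols predicted
    classes: tuple

    @property
    def supports(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.classes),
                            columns=list(self.classes))


def confusion(
    true_labels: Sequence, pred_labels: Sequence, classes: Sequence
) -> ConfusionMatrix:
    """Tally the K x K confusion matrix over a fixed class list."""
    if len(true_labels) != len(pred_labels):
        raise ValueError("label sequences differ in length")
    classes = tuple(classes)
    index = {c: i for i, c in enumerate(classes)}
    counts = np.zeros((len(classes), len(classes)), dtype=np.int64)
    for t, p in zip(true_labels, pred_labels):
        if t not in index or p not in index:
            raise ValueError(f"unknown label in pair ({t!r}, {p!r})")
        counts[index[t], index[p]] += 1
    return ConfusionMatrix(counts=counts, classes=classes)


def _safe_div(num: np.ndarray, den: np.ndarray, what: str) -> np.ndarray:
    num = np.asarray(num, dtype=float)
    den = np.asarray(den, dtype=float)
    undefined = den == 0
    if np.any(undefined & (num == 0)):
        warnings.warn(f"{what}: 0/0 reported as 0", RuntimeWarning, stacklevel=3)
    out = np.zeros_like(num, dtype=float)
    np.divide(num, den, out=out, where=~undefined)
    return out


def per_class_metrics(cm: ConfusionMatrix) -> pd.DataFrame:
    """One-vs-rest precision/recall/F1/accuracy/NPV per class."""
    counts = cm.counts
    total = cm.total
    tp = np.diag(counts).astype(float)
    fp = counts.sum(axis=0) - tp
    fn = counts.sum(axis=1) - tp
    tn = total - tp - fp - fn
    precision = _safe_div(tp, tp + fp, "precision")
    recall = _safe_div(tp, tp + fn, "recall")
    f1 = _safe_div(2 * precision * recall, precision + recall, "F1")
    accuracy = _safe_div(tp + tn, np.full_like(tp, total), "accuracy")
    npv = _safe_div(tn, tn + fn, "NPV")
    return pd.DataFrame(
        {
            "precision": precision,
            "recall": recall,
            "f1": f1,
            "accuracy": accuracy,
            "npv": npv,
            "support": cm.supports,
        },
        index=list(cm.classes),
    )


def averaged_metrics(cm: ConfusionMatrix) -> dict[str, float]:
    """Overall accuracy plus micro/macro/weighted P, R and F1.

    Micro-averaging pools TP/FP/FN across classes; for single-label
    data every false positive is another class's false negative, so
    micro-P = micro-R = micro-F1 = accuracy.
    """
    per_class = per_class_metrics(cm)
    total = cm.total
    tp = float(np.diag(cm.counts).sum())
    fp = float(cm.counts.sum() - np.diag(cm.counts).sum())
    micro_p = tp / (tp + fp) if total else 0.0  # pooled FP == pooled FN
    supports = cm.supports.astype(float)
    weights = _safe_div(supports, np.full_like(supports, supports.sum()), "weights")
    out: dict[str, float] = {
        "accuracy": tp / total if total else 0.0,
        "micro_precision": micro_p,
        "micro_recall": micro_p,
        "micro_f1": micro_p,
    }
    for name in ("precision", "recall", "f1"):
        col = per_class[name].to_numpy()
        out[f"macro_{name}"] = float(col.mean())
        out[f"weighted_{name}"] = float((col * weights).sum())
    return out


@dataclass(frozen=True)
class MetricsReport:
    """Full evaluation report: per-class table plus aggregates."""

    confusion: ConfusionMatrix
    per_class: pd.DataFrame
    aggregate: dict[str, float]

    def to_json(self) -> str:
        import json

        return json.dumps(
            {
                "classes": [str(c) for c in self.confusion.classes],
                "confusion": self.confusion.counts.tolist(),
                "per_class": self.per_class.to_dict(orient="index"),
                "aggregate": self.aggregate,
            },
            default=float,
        )


def evaluate_predictions(
    true_labels: Sequence, pred_labels: Sequence, classes: Sequence
) -> MetricsReport:
    """Convenience wrapper: confusion matrix + all metrics in one call."""
    cm = confusion(true_labels, pred_labels, classes)
    return MetricsReport(cm, per_class_metrics(cm), averaged_metrics(cm))
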