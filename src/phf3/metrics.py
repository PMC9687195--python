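"""Evaluation metrics: multiclass confusion matrix, one-vs-rest per-class
rates (ACC/SEN/SPE/PPV/NPV/F1), total accuracy and per-class ROC AUC.

Per-class rates follow the one-vs-rest convention: the K×K confusion matrix
(rows = truth, columns = prediction) is collapsed against each class c in turn
to TP/FN/FP/TN, then

    ACC = (TP+TN)/N          SEN = TP/(TP+FN)       SPE = TN/(TN+FP)
    PPV = TP/(TP+FP)         NPV = TN/(TN+FN)       F1  = 2·SEN·PPV/(SEN+PPV)

Total accuracy is trace/N. Metrics with a zero denominator are reported as
NaN and flagged ``undefined`` rather than silently coerced to 0.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.metrics import roc_auc_score

__all__ = ["confusion_matrix", "per_class_metrics", "roc_auc", "MetricsReport"]

_RATE_NAMES = ("ACC", "SEN", "SPE", "PPV", "NPV", "F1")


def confusion_matrix(y_true, y_pred, num_classes: int) -> np.ndarray:
    """K×K counts, rows = true class, columns = predicted class (0-based)."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError(
            f"label vectors differ in length: {y_true.shape} vs {y_pred.shape}"
        )
    return _sk_confusion(y_true, y_pred, labels=np.arange(num_classes))


def per_class_metrics(confusion: np.ndarray) -> dict:
    """One-vs-rest rates per class from a confusion matrix.

    Returns a dict with arrays of length K for each rate (NaN where the
    denominator is zero), the set of (class, metric) pairs that were
    undefined, and ``total_accuracy``.
    """
    cm = np.asarray(confusion, dtype=float)
    k = cm.shape[0]
    if cm.shape != (k, k):
        raise ValueError(f"confusion matrix must be square, got {cm.shape}")
    n = cm.sum()
    tp = np.diag(cm)
    fn = cm.sum(axis=1) - tp
    fp = cm.sum(axis=0) - tp
    tn = n - tp - fn - fp

    def _safe(num, den):
        out = np.full(k, np.nan)
        ok = den > 0
        out[ok] = num[ok] / den[ok]
        return out

    rates = {
        "ACC": _safe(tp + tn, np.full(k, n)),
        "SEN": _safe(tp, tp + fn),
        "SPE": _safe(tn, tn + fp),
        "PPV": _safe(tp, tp + fp),
        "NPV": _safe(tn, tn + fn),
    }
    sen, ppv = rates["SEN"], rates["PPV"]
    with np.errstate(invalid="ignore"):
        f1 = 2.0 * sen * ppv / (sen + ppv)
    rates["F1"] = f1
    undefined = {
        (c, name)
        for name, vals in rates.items()
        for c in range(k)
        if np.isnan(vals[c])
    }
    total = float(tp.sum() / n) if n > 0 else float("nan")
    return {**rates, "total_accuracy": total, "undefined": undefined}


def roc_auc(scores: np.ndarray, y_true, num_classes: int | None = None) -> np.ndarray:
    """One-vs-rest trapezoidal AUC per class from an [N, K] score matrix.

    Classes absent from (or filling) the truth vector get NaN — an AUC is
    undefined without both positives and negatives.
    """
    scores = np.asarray(scores, dtype=float)
    y_true = np.asarray(y_true)
    k = scores.shape[1] if num_classes is None else num_classes
    out = np.full(k, np.nan)
    for c in range(k):
        pos = y_true == c
        if pos.any() and (~pos).any():
            out[c] = roc_auc_score(pos.astype(int), scores[:, c])
    return out


@dataclass
class MetricsReport:
    """Full evaluation summary for one model on one split."""

    confusion: np.ndarray
    per_class: dict = field(repr=False)
    total_accuracy: float
    auc: np.ndarray

    @classmethod
    def from_predictions(cls, y_true, y_pred, scores=None, num_classes: int = 4):
        cm = confusion_matrix(y_true, y_pred, num_classes)
        pc = per_class_metrics(cm)
        auc = (
            roc_auc(scores, y_true, num_classes)
            if scores is not None
            else np.full(num_classes, np.nan)
        )
        return cls(confusion=cm, per_class=pc,
                   total_accuracy=pc["total_accuracy"], auc=auc)

    def macro(self, name: str) -> float:
        return float(np.nanmean(self.per_class[name]))

    def to_frame(self) -> pd.DataFrame:
        """Per-class table, rows = metric, columns = class (plus AUC row)."""
        k = self.confusion.shape[0]
        data = {f"class_{c}": [self.per_class[m][c] for m in _RATE_NAMES] + [self.auc[c]]
                for c in range(k)}
        return pd.DataFrame(data, index=list(_RATE_NAMES) + ["AUC"])

    def to_json(self) -> str:
        k = self.confusion.shape[0]
        payload = {
            "confusion": self.confusion.tolist(),
            "total_accuracy": self.total_accuracy,
            "per_class": {
                m: [None if np.isnan(v) else float(v) for v in self.per_class[m]]
                for m in _RATE_NAMES
            },
            "auc": [None if np.isnan(v) else float(v) for v in self.auc],
            "undefined": sorted([c, m] for c, m in self.per_class["undefined"]),
            "num_classes": k,
        }
        return json.dumps(payload, indent=2)

    def save(self, json_path=None, csv_path=None):
        if json_path is not None:
            with open(json_path, "w") as fh:
                fh.write(self.to_json())
        if csv_path is not None:
            self.to_frame().to_csv(csv_path)
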