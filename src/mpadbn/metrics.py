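"""Multiclass evaluation: confusion matrix and one-vs-rest metrics.

Each class is scored against the rest: accuracy (TP+TN)/n, precision
TP/(TP+FP), recall TP/(TP+FN), F1, and ROC-AUC from the class's softmax
score column.  Macro values are unweighted means over classes; a class
absent from the truth has no defined AUC and is excluded from the AUC
macro with a warning.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.metrics import roc_auc_score as _sk_auc

logger = logging.getLogger(__name__)

METRIC_NAMES = ("accuracy", "precision", "recall", "f1", "auc")


@dataclass
class MetricsReport:
    labels: tuple
    confusion: np.ndarray             # rows true, columns predicted
    per_class: dict                   # metric name -> K-vector (fractions; AUC may be NaN)
    macro: dict                       # metric name -> scalar
    micro_accuracy: float
    n_test: int

    def percent(self) -> dict:
        """Per-class and macro metrics on the 0-100 scale, for reports."""
        out = {"labels": list(self.labels), "n_test": self.n_test,
               "micro_accuracy": self.micro_accuracy * 100.0,
               "per_class": {}, "macro": {}}
        for m in METRIC_NAMES:
            out["per_class"][m] = [None if np.isnan(v) else v * 100.0
                                   for v in self.per_class[m]]
            out["macro"][m] = self.macro[m] * 100.0
        return out


def evaluate(y_true: Sequence, y_pred: Sequence,
             y_scores: Optional[np.ndarray] = None,
             labels: Optional[Sequence] = None) -> MetricsReport:
    """Score predictions with per-class one-vs-rest metrics.

    ``y_scores`` is an n x K matrix of class probabilities (rows sum to 1)
    used only for AUC; without it AUC is reported as NaN.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred lengths differ")
    if labels is None:
        labels = np.unique(np.concatenate([y_true, y_pred]))
    labels = tuple(labels)
    K = len(labels)
    n = y_true.size
    if y_scores is not None:
        y_scores = np.asarray(y_scores, dtype=float)
        if y_scores.shape != (n, K):
            raise ValueError(f"y_scores must be {n}x{K}")

    conf = _sk_confusion(y_true, y_pred, labels=list(labels)).astype(int)
    tp = np.diag(conf).astype(float)
    fn = conf.sum(axis=1) - tp
    fp = conf.sum(axis=0) - tp
    tn = n - tp - fn - fp

    def safe_div(a, b):
        return np.where(b > 0, a / np.where(b > 0, b, 1.0), 0.0)

    acc = (tp + tn) / n
    prec = safe_div(tp, tp + fp)
    rec = safe_div(tp, tp + fn)
    f1 = safe_div(2.0 * prec * rec, prec + rec)

    auc = np.full(K, np.nan)
    if y_scores is not None:
        for k, lab in enumerate(labels):
            pos = (y_true == lab)
            if pos.all() or not pos.any():
                logger.warning("class %r absent from one side of y_true; "
                               "AUC undefined, excluded from macro", lab)
                continue
            auc[k] = _sk_auc(pos.astype(int), y_scores[:, k])

    per_class = {"accuracy": acc, "precision": prec, "recall": rec,
                 "f1": f1, "auc": auc}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        macro = {m: float(np.nanmean(v)) if not np.all(np.isnan(v)) else float("nan")
                 for m, v in per_class.items()}
    return MetricsReport(labels=labels, confusion=conf, per_class=per_class,
                         macro=macro, micro_accuracy=float(tp.sum() / n),
                         n_test=n)
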