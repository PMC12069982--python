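"""One-vs-rest confusion-matrix metrics and probability MSE.

Per class: sensitivity TP/(TP+FN), specificity TN/(TN+FP), precision
TP/(TP+FP), accuracy (TP+TN)/n and F1 = 2PR/(P+R). "Overall" values are
unweighted macro averages. MSE compares predicted probability vectors with
one-hot truth, averaged over samples and classes. Zero-denominator metrics
return 0 with a warning rather than raising.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ConfusionCounts",
    "confusion",
    "sensitivity",
    "specificity",
    "precision",
    "accuracy",
    "f1",
    "mse",
    "macro_report",
    "MetricsReport",
]

METRIC_NAMES = ("sensitivity", "specificity", "precision", "accuracy", "f1")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def confusion(y_true, y_pred, positive) -> ConfusionCounts:
    """One-vs-rest counts for one class treated as positive."""
    t = np.asarray(y_true)
    p = np.asarray(y_pred)
    if t.shape != p.shape:
        raise ValueError("y_true and y_pred must have equal length")
    tpos = t == positive
    ppos = p == positive
    return ConfusionCounts(
        tp=int(np.sum(tpos & ppos)),
        fp=int(np.sum(~tpos & ppos)),
        tn=int(np.sum(~tpos & ~ppos)),
        fn=int(np.sum(tpos & ~ppos)),
    )


def _ratio(num: float, den: float, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name}: zero denominator, reporting 0", RuntimeWarning, stacklevel=3)
        return 0.0
    return num / den


def sensitivity(c: ConfusionCounts) -> float:
    return _ratio(c.tp, c.tp + c.fn, "sensitivity")


def specificity(c: ConfusionCounts) -> float:
    return _ratio(c.tn, c.tn + c.fp, "specificity")


def precision(c: ConfusionCounts) -> float:
    return _ratio(c.tp, c.tp + c.fp, "precision")


def accuracy(c: ConfusionCounts) -> float:
    return _ratio(c.tp + c.tn, c.n, "accuracy")


def f1(c: ConfusionCounts) -> float:
    p = precision(c)
    r = sensitivity(c)
    if p + r == 0:
        return 0.0
    return 2 * p * r / (p + r)


def mse(y_true, proba, class_labels) -> float:
    """Mean squared error of probability vectors against one-hot truth.

    Averages over both samples and classes: (1/(nC)) sum_j ||Y_j - Yhat_j||^2.
    """
    t = np.asarray(y_true)
    P = np.asarray(proba, float)
    labels = list(class_labels)
    if P.shape != (t.shape[0], len(labels)):
        raise ValueError(f"probability matrix shape {P.shape} does not match "
                         f"{t.shape[0]} samples x {len(labels)} classes")
    onehot = (t[:, None] == np.asarray(labels)[None, :]).astype(float)
    return float(((onehot - P) ** 2).mean())


@dataclass
class MetricsReport:
    per_class: pd.DataFrame       # index = class, columns = METRIC_NAMES
    macro: dict[str, float]       # macro means plus mse

    def to_dict(self) -> dict:
        return {
            "per_class": {str(k): {m: float(v) for m, v in row.items()}
                          for k, row in self.per_class.iterrows()},
            "macro": {k: float(v) for k, v in self.macro.items()},
        }

    def to_frame(self) -> pd.DataFrame:
        """Flat class x metric table including a macro row."""
        out = self.per_class.copy()
        out.loc["macro"] = [self.macro[m] for m in out.columns]
        return out


def macro_report(y_true, y_pred, proba=None, class_labels=None) -> MetricsReport:
    """Per-class one-vs-rest metrics plus unweighted macro averages.

    class_labels fixes the class universe and order (defaults to the sorted
    union of observed labels); proba, when given, adds the probability MSE.
    """
    t = np.asarray(y_true)
    p = np.asarray(y_pred)
    if class_labels is None:
        class_labels = np.unique(np.concatenate([t, p]))
    labels = list(class_labels)
    rows = {}
    for lab in labels:
        c = confusion(t, p, lab)
        rows[lab] = {
            "sensitivity": sensitivity(c), "specificity": specificity(c),
            "precision": precision(c), "accuracy": accuracy(c), "f1": f1(c),
        }
    per_class = pd.DataFrame.from_dict(rows, orient="index")[list(METRIC_NAMES)]
    macro = {m: float(per_class[m].mean()) for m in METRIC_NAMES}
    if proba is not None:
        macro["mse"] = mse(t, proba, labels)
    return MetricsReport(per_class, macro)
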