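"""Classification metrics computed from the confusion table.

Accuracy, one-vs-rest precision/recall/F1 (in percent) and Matthews
correlation are derived directly from the C x C confusion matrix. The
primary MCC is the macro average of the per-class binary coefficients;
the standard multiclass generalization is reported alongside. Cells with
a zero denominator yield 0 and set ``zero_division_flag``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = ["MetricsReport", "confusion_matrix", "compute_metrics", "multiclass_mcc"]


@dataclass
class MetricsReport:
    labels: list
    confusion: np.ndarray
    accuracy: float                 # percent
    precision: dict                 # class -> percent
    recall: dict
    f1: dict
    macro_precision: float
    macro_recall: float
    macro_f1: float
    mcc_per_class: dict             # class -> [-1, 1]
    mcc_macro: float
    mcc_multiclass: float
    zero_division_flag: bool = False

    def to_dict(self) -> dict:
        return {
            "labels": list(self.labels),
            "confusion": self.confusion.tolist(),
            "accuracy": self.accuracy,
            "precision": self.precision, "recall": self.recall, "f1": self.f1,
            "macro_precision": self.macro_precision,
            "macro_recall": self.macro_recall, "macro_f1": self.macro_f1,
            "mcc_per_class": self.mcc_per_class,
            "mcc_macro": self.mcc_macro, "mcc_multiclass": self.mcc_multiclass,
            "zero_division_flag": self.zero_division_flag,
        }


def confusion_matrix(y_true: Sequence, y_pred: Sequence,
                     labels: Optional[Sequence] = None) -> tuple[np.ndarray, list]:
    y_true, y_pred = list(y_true), list(y_pred)
    if len(y_true) != len(y_pred):
        raise ValueError("label vectors must have equal length")
    if not y_true:
        raise ValueError("empty input")
    if labels is None:
        labels = sorted(set(y_true) | set(y_pred))
    index = {lab: i for i, lab in enumerate(labels)}
    table = np.zeros((len(labels), len(labels)), dtype=np.int64)
    for t, p in zip(y_true, y_pred):
        table[index[t], index[p]] += 1
    return table, list(labels)


def _safe_div(num: float, den: float) -> tuple[float, bool]:
    if den == 0:
        return 0.0, True
    return num / den, False


def _binary_mcc(tp: float, tn: float, fp: float, fn: float) -> tuple[float, bool]:
    den = np.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    if den == 0:
        return 0.0, True
    return float((tp * tn - fp * fn) / den), False


def multiclass_mcc(table: np.ndarray) -> float:
    """Covariance-form multiclass Matthews correlation."""
    table = np.asarray(table, dtype=np.float64)
    s = table.sum()
    c = np.trace(table)
    p = table.sum(axis=0)  # predicted counts
    t = table.sum(axis=1)  # true counts
    num = c * s - float(p @ t)
    den = np.sqrt((s ** 2 - float(p @ p)) * (s ** 2 - float(t @ t)))
    return float(num / den) if den > 0 else 0.0


def compute_metrics(y_true: Sequence, y_pred: Sequence,
                    labels: Optional[Sequence] = None) -> MetricsReport:
    table, labels = confusion_matrix(y_true, y_pred, labels)
    n = table.sum()
    accuracy = 100.0 * np.trace(table) / n
    precision, recall, f1, mcc_pc = {}, {}, {}, {}
    flag = False
    for i, lab in enumerate(labels):
        tp = float(table[i, i])
        fp = float(table[:, i].sum() - tp)
        fn = float(table[i, :].sum() - tp)
        tn = float(n - tp - fp - fn)
        prec, fl1 = _safe_div(tp, tp + fp)
        rec, fl2 = _safe_div(tp, tp + fn)
        f1v, fl3 = _safe_div(2 * prec * rec, prec + rec)
        mccv, fl4 = _binary_mcc(tp, tn, fp, fn)
        precision[lab], recall[lab], f1[lab] = 100 * prec, 100 * rec, 100 * f1v
        mcc_pc[lab] = mccv
        flag = flag or fl1 or fl2 or fl3 or fl4
    return MetricsReport(
        labels=labels, confusion=table, accuracy=float(accuracy),
        precision=precision, recall=recall, f1=f1,
        macro_precision=float(np.mean(list(precision.values()))),
        macro_recall=float(np.mean(list(recall.values()))),
        macro_f1=float(np.mean(list(f1.values()))),
        mcc_per_class=mcc_pc,
        mcc_macro=float(np.mean(list(mcc_pc.values()))),
        mcc_multiclass=multiclass_mcc(table),
        zero_division_flag=flag,
    )
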