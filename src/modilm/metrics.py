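"""Classification metrics with the binary/multi-class reporting convention.

Binary tasks report ACC, F1 of the positive class, and AUC from the
positive-class probability; multi-class tasks report ACC, support-weighted
F1 and macro F1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import accuracy_score, f1_score, roc_auc_score

__all__ = ["MetricsRecord", "evaluate_metrics"]


@dataclass
class MetricsRecord:
    acc: float
    f1: float | None = None
    auc: float | None = None
    f1_weighted: float | None = None
    f1_macro: float | None = None
    support: dict[int, int] | None = None

    def to_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items() if v is not None}


def evaluate_metrics(y_true: np.ndarray, y_pred: np.ndarray,
                     proba: np.ndarray | None = None) -> MetricsRecord:
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("prediction and truth lengths differ")
    classes = np.unique(np.concatenate([y_true, y_pred]))
    binary = len(classes) <= 2
    uniq, counts = np.unique(y_true, return_counts=True)
    support = {int(c): int(n) for c, n in zip(uniq, counts)}
    acc = float(accuracy_score(y_true, y_pred))
    if binary:
        pos = classes.max()
        f1 = float(f1_score(y_true, y_pred, pos_label=pos, zero_division=0))
        auc = None
        if proba is not None and len(np.unique(y_true)) == 2:
            auc = float(roc_auc_score(y_true == pos, np.asarray(proba)[:, -1]))
        return MetricsRecord(acc=acc, f1=f1, auc=auc, support=support)
    return MetricsRecord(
        acc=acc,
        f1_weighted=float(f1_score(y_true, y_pred, average="weighted", zero_division=0)),
        f1_macro=float(f1_score(y_true, y_pred, average="macro", zero_division=0)),
        support=support,
    )
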