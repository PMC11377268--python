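"""Confusion matrices and classification scores.

Per-class scores use the one-vs-rest convention: precision TP/(TP+FP),
recall TP/(TP+FN), F1 the harmonic mean, accuracy (TP+TN)/total; macro
scores are unweighted class means. Degenerate 0/0 ratios are defined as 0
(a class never predicted and never true contributes zeros, not NaNs).
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence

import numpy as np

__all__ = ["ConfusionMatrix", "confusion", "scores"]


@dataclass
class ConfusionMatrix:
    counts: np.ndarray  # K x K, rows = true, columns = predicted
    classes: List

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def per_class_tp_tn_fp_fn(self) -> Dict[object, Dict[str, int]]:
        out = {}
        total = self.counts.sum()
        for i, c in enumerate(self.classes):
            tp = self.counts[i, i]
            fp = self.counts[:, i].sum() - tp
            fn = self.counts[i, :].sum() - tp
            tn = total - tp - fp - fn
            out[c] = {"TP": int(tp), "TN": int(tn), "FP": int(fp), "FN": int(fn)}
        return out


def confusion(y_true: Sequence, y_pred: Sequence, classes: Sequence) -> ConfusionMatrix:
    """counts[i][j] = number of samples with true class i predicted as j."""
    if len(y_true) != len(y_pred):
        raise ValueError("y_true and y_pred must have equal length")
    classes = list(classes)
    lookup = {c: i for i, c in enumerate(classes)}
    counts = np.zeros((len(classes), len(classes)), dtype=int)
    for t, p in zip(y_true, y_pred):
        if t not in lookup or p not in lookup:
            raise ValueError(f"label {t if t not in lookup else p!r} not in vocabulary")
        counts[lookup[t], lookup[p]] += 1
    return ConfusionMatrix(counts, classes)


def _safe(num: float, den: float) -> float:
    return num / den if den > 0 else 0.0


def scores(cm: ConfusionMatrix, average: str = "macro") -> Dict:
    """Accuracy plus per-class and averaged precision/recall/F1.

    ``average='macro'`` (default) takes the unweighted class mean;
    ``'weighted'`` weights by true-class support.
    """
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    per = {}
    tptnfpfn = cm.per_class_tp_tn_fp_fn()
    supports = cm.counts.sum(axis=1)
    for c, d in tptnfpfn.items():
        p = _safe(d["TP"], d["TP"] + d["FP"])
        r = _safe(d["TP"], d["TP"] + d["FN"])
        f1 = _safe(2 * p * r, p + r)
        acc = (d["TP"] + d["TN"]) / cm.total
        per[c] = {"precision": p, "recall": r, "f1": f1, "accuracy": acc}
    if average == "macro":
        w = np.ones(len(cm.classes)) / len(cm.classes)
    elif average == "weighted":
        w = supports / supports.sum()
    else:
        raise ValueError(f"unknown average {average!r}")
    agg = {
        key: float(sum(w[i] * per[c][key] for i, c in enumerate(cm.classes)))
        for key in ("precision", "recall", "f1")
    }
    agg["accuracy"] = float(np.trace(cm.counts) / cm.total)
    return {"per_class": per, average: agg, "accuracy": agg["accuracy"]}
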