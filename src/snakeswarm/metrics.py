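"""Multiclass evaluation: one-vs-rest confusion tallies, the standard metric
suite (precision, recall, accuracy, F1, specificity, error rate) with
support-weighted aggregation, rank-statistic one-vs-rest ROC/AUC, and the
one-way ANOVA comparison of classifier accuracies with and without
optimization.

Zero-denominator metrics are defined as 0 and flagged rather than NaN, so
weighted averages stay defined on sparse classes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.metrics import multilabel_confusion_matrix, roc_curve

__all__ = [
    "ConfusionTally",
    "MetricsReport",
    "confusion_tally",
    "metrics_from_tally",
    "roc_auc_ovr",
    "compare_with_anova",
]

METRIC_NAMES = ("precision", "recall", "accuracy", "f1", "specificity", "error_rate")


@dataclass
class ConfusionTally:
    classes: list
    tp: np.ndarray
    fp: np.ndarray
    fn: np.ndarray
    tn: np.ndarray

    @property
    def support(self) -> np.ndarray:
        return self.tp + self.fn

    @property
    def n_samples(self) -> int:
        return int(self.tp[0] + self.fp[0] + self.fn[0] + self.tn[0])


@dataclass
class MetricsReport:
    per_class: dict  # class -> metric -> value
    weighted: dict  # metric -> support-weighted value
    accuracy: float  # overall correct / n
    error_rate: float
    mode: str = "weighted"
    auc: dict | None = None
    flags: list = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(
            {
                "per_class": {str(k): v for k, v in self.per_class.items()},
                "weighted": self.weighted,
                "accuracy": self.accuracy,
                "error_rate": self.error_rate,
                "auc": None if self.auc is None else {str(k): v for k, v in self.auc.items()},
                "mode": self.mode,
                "flags": self.flags,
            }
        )

    def to_csv_row(self, **context) -> dict:
        row = dict(context)
        row["accuracy"] = self.accuracy
        row["error_rate"] = self.error_rate
        for m in ("precision", "recall", "f1", "specificity"):
            row[m] = self.weighted[m]
        return row


def confusion_tally(y_true, y_pred, classes=None) -> ConfusionTally:
    """One-vs-rest TP/FP/FN/TN tallies per class."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred lengths differ")
    if classes is None:
        classes = sorted(np.unique(y_true).tolist())
    unknown = set(np.unique(y_pred)) - set(classes)
    if unknown:
        raise ValueError(f"label-mismatch: predictions contain unknown labels {unknown}")
    mcm = multilabel_confusion_matrix(y_true, y_pred, labels=classes)
    return ConfusionTally(
        classes=list(classes),
        tn=mcm[:, 0, 0].astype(int),
        fp=mcm[:, 0, 1].astype(int),
        fn=mcm[:, 1, 0].astype(int),
        tp=mcm[:, 1, 1].astype(int),
    )


def _safe_div(num: float, den: float, flags: list, what: str) -> float:
    if den == 0:
        flags.append(f"zero-denominator:{what}")
        return 0.0
    return num / den


def metrics_from_tally(tally: ConfusionTally, mode: str = "weighted") -> MetricsReport:
    """Per-class and support-weighted metric suite from one-vs-rest tallies.

    Overall accuracy is total correct / n (equivalently sum of per-class TP
    over n for single-label problems); error rate is its complement.
    """
    if mode not in ("per_class", "weighted"):
        raise ValueError(f"unknown aggregation mode {mode!r}")
    flags: list = []
    per_class: dict = {}
    n = tally.n_samples
    for i, cls in enumerate(tally.classes):
        tp, fp, fn, tn = (int(tally.tp[i]), int(tally.fp[i]), int(tally.fn[i]), int(tally.tn[i]))
        p = _safe_div(tp, tp + fp, flags, f"precision/{cls}")
        r = _safe_div(tp, tp + fn, flags, f"recall/{cls}")
        acc = _safe_div(tp + tn, n, flags, f"accuracy/{cls}")
        f1 = _safe_div(2 * p * r, p + r, flags, f"f1/{cls}")
        spec = _safe_div(tn, tn + fp, flags, f"specificity/{cls}")
        per_class[cls] = {
            "precision": p, "recall": r, "accuracy": acc, "f1": f1,
            "specificity": spec, "error_rate": 1.0 - acc,
        }
    support = tally.support.astype(float)
    weights = support / support.sum() if support.sum() > 0 else np.full(len(support), 1 / len(support))
    weighted = {
        m: float(sum(w * per_class[c][m] for w, c in zip(weights, tally.classes)))
        for m in ("precision", "recall", "f1", "specificity")
    }
    accuracy = float(tally.tp.sum() / n) if n else 0.0
    weighted["accuracy"] = accuracy
    weighted["error_rate"] = 1.0 - accuracy
    return MetricsReport(
        per_class=per_class,
        weighted=weighted,
        accuracy=accuracy,
        error_rate=1.0 - accuracy,
        mode=mode,
        flags=flags,
    )


def roc_auc_ovr(y_true, scores, classes=None) -> dict:
    """One-vs-rest AUC per class by the rank (Mann-Whitney) statistic.

    Ties receive half credit.  Returns class -> {"auc": value or None,
    "curve": [(fpr, tpr), ...]}; classes absent from ``y_true`` get
    ``auc=None`` with a flag entry instead of a number.
    """
    y_true = np.asarray(y_true)
    scores = np.asarray(scores, dtype=float)
    if classes is None:
        classes = sorted(np.unique(y_true).tolist())
    if scores.ndim != 2 or scores.shape[1] != len(classes):
        raise ValueError("scores must be (n_samples, n_classes)")
    out: dict = {}
    for j, cls in enumerate(classes):
        pos = y_true == cls
        n_pos, n_neg = int(pos.sum()), int((~pos).sum())
        if n_pos == 0 or n_neg == 0:
            out[cls] = {"auc": None, "flag": "class-absent", "curve": []}
            continue
        ranks = stats.rankdata(scores[:, j])
        auc = (ranks[pos].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
        fpr, tpr, _ = roc_curve(pos.astype(int), scores[:, j])
        out[cls] = {"auc": float(auc), "curve": list(zip(fpr.tolist(), tpr.tolist()))}
    return out


def compare_with_anova(acc_without, acc_with) -> tuple[float, float, tuple[float, float]]:
    """One-way ANOVA across the two accuracy groups.

    Returns (F, p, (mean_without, mean_with)).  Zero within-group variance
    with unequal means yields an infinite F; p is reported as 0.
    """
    a = np.asarray(acc_without, dtype=float)
    b = np.asarray(acc_with, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 entries")
    means = (float(a.mean()), float(b.mean()))
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if means[0] == means[1]:
            return 0.0, 1.0, means
        return float("inf"), 0.0, means
    f_stat, p = stats.f_oneway(a, b)
    return float(f_stat), float(p), means
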