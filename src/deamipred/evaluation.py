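"""Confusion-matrix metrics, ROC/AUC and the NG-motif sequence baseline.

Degenerate-case conventions for unbalanced data: precision is undefined
(reported as "-") when no positives are predicted, and MCC is 0 when any
factor of its denominator vanishes, so an all-negative predictor scores
MCC 0 rather than NaN.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np

from .structure import AsnSite

__all__ = [
    "ConfusionMatrix",
    "MetricsReport",
    "confusion",
    "metrics",
    "roc_auc",
    "ng_motif_baseline",
    "round_display",
]


def round_display(value: float | None, ndigits: int = 2):
    """Half-up decimal rounding for table display; None stays None."""
    if value is None:
        return None
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        for name in ("tp", "fp", "tn", "fn"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValueError(f"{name} must be a non-negative integer")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class MetricsReport:
    accuracy: float
    recall: float
    fpr: float
    specificity: float
    precision: float | None  # None = undefined (no predicted positives)
    mcc: float
    auc: float | None = None

    def display(self) -> dict:
        """Two-decimal half-up rendering; undefined precision prints '-'."""
        out = {
            "accuracy": round_display(self.accuracy),
            "recall": round_display(self.recall),
            "fpr": round_display(self.fpr),
            "specificity": round_display(self.specificity),
            "precision": "-" if self.precision is None else round_display(self.precision),
            "mcc": round_display(self.mcc),
        }
        if self.auc is not None:
            out["auc"] = round_display(self.auc)
        return out


def confusion(true_labels, predicted_labels) -> ConfusionMatrix:
    """Counts with positive = deamidated (label 1)."""
    t = np.asarray(true_labels, dtype=int)
    p = np.asarray(predicted_labels, dtype=int)
    if t.shape != p.shape:
        raise ValueError("label lists have different lengths")
    return ConfusionMatrix(
        tp=int(np.sum((t == 1) & (p == 1))),
        fp=int(np.sum((t == 0) & (p == 1))),
        tn=int(np.sum((t == 0) & (p == 0))),
        fn=int(np.sum((t == 1) & (p == 0))),
    )


def metrics(cm: ConfusionMatrix, auc: float | None = None) -> MetricsReport:
    """Full-precision metric suite from a confusion matrix."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    tp, fp, tn, fn = cm.tp, cm.fp, cm.tn, cm.fn
    accuracy = (tp + tn) / cm.total
    recall = tp / (tp + fn) if tp + fn else 0.0
    fpr = fp / (fp + tn) if fp + tn else 0.0
    specificity = tn / (fp + tn) if fp + tn else 0.0
    precision = tp / (tp + fp) if tp + fp else None
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / np.sqrt(denom) if denom else 0.0
    return MetricsReport(accuracy, recall, fpr, specificity, precision,
                         float(mcc), auc)


def roc_auc(true_labels, scores):
    """ROC points by threshold sweep and trapezoid AUC.

    The AUC equals the Mann-Whitney statistic with ties counted one
    half.  Points include the (0,0) and (1,1) anchors and are returned
    as (threshold, fpr, tpr) triples.
    """
    t = np.asarray(true_labels, dtype=int)
    s = np.asarray(scores, dtype=float)
    if t.shape != s.shape:
        raise ValueError("labels and scores have different lengths")
    if not np.all(np.isfinite(s)):
        raise ValueError("scores must be finite")
    n_pos = int(np.sum(t == 1))
    n_neg = int(np.sum(t == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC undefined: both classes must be present")

    points = [(np.inf, 0.0, 0.0)]
    for thr in np.unique(s)[::-1]:
        pred = s >= thr
        tpr = float(np.sum(pred & (t == 1))) / n_pos
        fpr = float(np.sum(pred & (t == 0))) / n_neg
        points.append((float(thr), fpr, tpr))
    if points[-1][1:] != (1.0, 1.0):
        points.append((-np.inf, 1.0, 1.0))

    fprs = np.array([p[1] for p in points])
    tprs = np.array([p[2] for p in points])
    auc = float(np.trapezoid(tprs, fprs))
    return points, auc


def ng_motif_baseline(sites: list[AsnSite]) -> list[int]:
    """Sequence baseline: positive iff the Asn is followed by glycine."""
    return [int(site.yyy == "G") for site in sites]
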