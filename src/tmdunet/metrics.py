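"""Segmentation evaluation: DSC, mIoU, precision, recall, specificity, F1.

Two aggregation policies are computed side by side:

* ``per_image_mean`` — overlap scores (DSC, mIoU) averaged over images;
* ``global_pixels`` — confusion counts pooled over all pixels first, the
  rate metrics derived from the pooled counts.

The default report uses per-image means for DSC/mIoU and pooled counts for
precision/recall/specificity/F1.
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict

import numpy as np

__all__ = ["ConfusionCounts", "MetricsReport", "confusion", "overlap_metrics",
           "rate_metrics", "evaluate_set"]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __add__(self, other):
        return ConfusionCounts(self.tp + other.tp, self.fp + other.fp,
                               self.tn + other.tn, self.fn + other.fn)

    @property
    def total(self):
        return self.tp + self.fp + self.tn + self.fn


def _as_binary(mask, name):
    a = np.asarray(mask)
    if not np.isin(a, (0, 1)).all():
        raise ValueError(f"{name} must be binary (0/1)")
    return a.astype(bool)


def confusion(y_true_mask, y_pred_mask) -> ConfusionCounts:
    """Exact pixel tallies of TP/FP/TN/FN."""
    y = _as_binary(y_true_mask, "y_true_mask")
    p = _as_binary(y_pred_mask, "y_pred_mask")
    if y.shape != p.shape:
        raise ValueError("masks must have congruent shapes")
    tp = int(np.sum(y & p))
    fp = int(np.sum(~y & p))
    tn = int(np.sum(~y & ~p))
    fn = int(np.sum(y & ~p))
    return ConfusionCounts(tp, fp, tn, fn)


def overlap_metrics(y_true_mask, y_pred_mask):
    """dsc = 2|Y∩Ŷ|/(|Y|+|Ŷ|), miou = |Y∩Ŷ|/|Y∪Ŷ|; two empty masks
    score 1 (correct rejection of absent foreground)."""
    c = confusion(y_true_mask, y_pred_mask)
    if c.tp + c.fp + c.fn == 0:
        return 1.0, 1.0
    dsc = 2.0 * c.tp / (2.0 * c.tp + c.fp + c.fn)
    miou = c.tp / (c.tp + c.fp + c.fn)
    return dsc, miou


def _safe_div(num, den, name):
    if den == 0:
        warnings.warn(f"zero denominator for {name}; reporting 0", stacklevel=3)
        return 0.0
    return num / den


def rate_metrics(counts: ConfusionCounts):
    """pr = TP/(TP+FP), re = TP/(TP+FN), sp = TN/(TN+FP),
    f1 = 2*pr*re/(pr+re)."""
    pr = _safe_div(counts.tp, counts.tp + counts.fp, "precision")
    re = _safe_div(counts.tp, counts.tp + counts.fn, "recall")
    sp = _safe_div(counts.tn, counts.tn + counts.fp, "specificity")
    f1 = _safe_div(2.0 * pr * re, pr + re, "f1")
    return pr, re, sp, f1


@dataclass
class MetricsReport:
    dsc: float
    miou: float
    re: float
    pr: float
    sp: float
    f1: float
    aggregation: str

    def as_percent(self, decimals=2):
        return {k: round(100.0 * v, decimals)
                for k, v in asdict(self).items() if k != "aggregation"}


def evaluate_set(pred_probability_maps, truth_masks, threshold=0.5,
                 aggregation="mixed"):
    """Binarize predictions at ``threshold`` and score the collection.

    aggregation: ``per_image_mean``, ``global_pixels`` or ``mixed`` (the
    default: per-image DSC/mIoU, pooled rates).
    """
    preds = list(pred_probability_maps)
    truths = list(truth_masks)
    if len(preds) == 0 or len(preds) != len(truths):
        raise ValueError("need equal-length, nonempty prediction/truth sets")
    if not (0.0 < threshold < 1.0):
        raise ValueError("threshold must lie in (0, 1)")
    bins = [(np.asarray(p) >= threshold).astype(np.uint8) for p in preds]

    per_dsc, per_miou = [], []
    pooled = ConfusionCounts(0, 0, 0, 0)
    for b, t in zip(bins, truths):
        d, m = overlap_metrics(t, b)
        per_dsc.append(d)
        per_miou.append(m)
        pooled = pooled + confusion(t, b)

    g_dsc, g_miou = (1.0, 1.0) if pooled.tp + pooled.fp + pooled.fn == 0 else (
        2.0 * pooled.tp / (2.0 * pooled.tp + pooled.fp + pooled.fn),
        pooled.tp / (pooled.tp + pooled.fp + pooled.fn))
    pr, re, sp, f1 = rate_metrics(pooled)

    if aggregation == "per_image_mean":
        dsc, miou = float(np.mean(per_dsc)), float(np.mean(per_miou))
    elif aggregation == "global_pixels":
        dsc, miou = g_dsc, g_miou
    elif aggregation == "mixed":
        dsc, miou = float(np.mean(per_dsc)), float(np.mean(per_miou))
    else:
        raise ValueError(f"unknown aggregation {aggregation!r}")
    return MetricsReport(dsc, miou, re, pr, sp, f1, aggregation)


def write_report_json(reports, path):
    """JSON export keyed metric x aggregation, percentages to 2 decimals."""
    payload = {r.aggregation: r.as_percent() for r in reports}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
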