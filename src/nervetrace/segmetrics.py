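"""Segmentation evaluation metrics: confusion counts, precision/recall,
DICE and IoU, with per-image summaries and the IoU histogram.

Definitions over pixel counts (TP true positive, FP false positive, FN
false negative):

    precision = TP / (TP + FP)
    recall    = TP / (TP + FN)
    DICE      = 2 / (1/precision + 1/recall) = 2 TP / (2 TP + FP + FN)
    IoU       = TP / (TP + FP + FN)

DICE is the harmonic mean of precision and recall, and IoU = DICE/(2-DICE).
Degenerate denominators follow documented conventions: with no predicted
foreground, precision is 1 if there is also no true foreground else 0
(symmetrically for recall); DICE and IoU of two empty masks are 1.
Metrics are computed per image and then averaged, never pooled over pixels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError, GeometryError

__all__ = [
    "ConfusionCounts",
    "SegMetrics",
    "confusion",
    "metrics_from_counts",
    "evaluate_pair",
    "summarize_metrics",
    "iou_histogram",
]

METRIC_NAMES = ("precision", "recall", "dice", "iou")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ConfigurationError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class SegMetrics:
    precision: float
    recall: float
    dice: float
    iou: float

    def as_dict(self) -> dict:
        return {"precision": self.precision, "recall": self.recall,
                "dice": self.dice, "iou": self.iou}


def _binary(pix, name):
    arr = np.asarray(getattr(pix, "pixels", pix))
    vals = np.unique(arr)
    if not np.isin(vals, (0, 1)).all():
        raise ConfigurationError(f"{name} mask must be binary 0/1")
    return arr.astype(bool)


def confusion(pred, truth) -> ConfusionCounts:
    """Per-pixel confusion counts of a predicted vs. ground-truth mask."""
    p = _binary(pred, "pred")
    t = _binary(truth, "truth")
    if p.shape != t.shape:
        raise GeometryError(f"shape mismatch {p.shape} vs {t.shape}")
    tp = int(np.count_nonzero(p & t))
    fp = int(np.count_nonzero(p & ~t))
    fn = int(np.count_nonzero(~p & t))
    tn = p.size - tp - fp - fn
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


def metrics_from_counts(c: ConfusionCounts) -> SegMetrics:
    """Derive the four metrics, with documented degenerate conventions."""
    tp, fp, fn = c.tp, c.fp, c.fn
    if tp + fp == 0:
        precision = 1.0 if fn == 0 else 0.0
    else:
        precision = tp / (tp + fp)
    if tp + fn == 0:
        recall = 1.0 if fp == 0 else 0.0
    else:
        recall = tp / (tp + fn)
    if tp + fp + fn == 0:  # both masks empty: perfect agreement
        dice = iou = 1.0
    else:
        dice = 2 * tp / (2 * tp + fp + fn)
        iou = tp / (tp + fp + fn)
    return SegMetrics(precision=precision, recall=recall, dice=dice, iou=iou)


def evaluate_pair(pred, truth) -> tuple[ConfusionCounts, SegMetrics]:
    c = confusion(pred, truth)
    return c, metrics_from_counts(c)


def iou_histogram(ious, bin_width: float = 0.1) -> tuple[np.ndarray, np.ndarray, float]:
    """Histogram of IoU values over [0, 1].

    Returns ``(counts, bin_edges, mode)`` where ``mode`` is the left edge of
    the most populated bin (ties resolve to the lowest edge).  IoU exactly
    1.0 falls in the last bin.
    """
    ious = np.asarray(list(ious), dtype=float)
    if ious.size == 0:
        raise ConfigurationError("empty IoU list")
    nbins = int(round(1.0 / bin_width))
    edges = np.linspace(0.0, 1.0, nbins + 1)
    counts, _ = np.histogram(ious, bins=edges)
    mode = float(edges[int(np.argmax(counts))])
    return counts, edges, mode


def summarize_metrics(per_image: list[SegMetrics]) -> dict:
    """Mean +/- sample S.D. per metric, plus the IoU distribution summary.

    Returns a dict with a ``table`` DataFrame (rows = metrics, columns =
    mean, sd), the IoU histogram (0.1-wide bins), its modal bin left edge,
    and the minimum IoU.  S.D. uses the n-1 denominator and is 0 for a
    single image.
    """
    if not per_image:
        raise ConfigurationError("summarize_metrics needs a non-empty list")
    data = {m: np.array([getattr(s, m) for s in per_image]) for m in METRIC_NAMES}
    table = pd.DataFrame({
        "mean": {m: float(v.mean()) for m, v in data.items()},
        "sd": {m: float(v.std(ddof=1)) if v.size > 1 else 0.0
               for m, v in data.items()},
    }).loc[list(METRIC_NAMES)]
    counts, edges, mode = iou_histogram(data["iou"])
    return {
        "table": table,
        "iou_hist_counts": counts,
        "iou_hist_edges": edges,
        "iou_mode": mode,
        "iou_min": float(data["iou"].min()),
        "n": len(per_image),
    }
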