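"""Segmentation overlap and error metrics against a ground-truth mask.

Dice = 2TP/(2TP+FP+FN), Jaccard = TP/(TP+FP+FN), the Pearson correlation of
the flattened pixels (population moments), and RMSE on the normalized
[0, 1] scale.  Dice and Jaccard are tied by D = 2J/(1+J).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "confusion",
    "dice",
    "jaccard",
    "correlation",
    "rmse",
    "evaluate_masks",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FP: int
    FN: int
    TN: int


@dataclass(frozen=True)
class MetricsReport:
    dice: float
    jaccard: float
    correlation: float
    rmse: float
    counts: ConfusionCounts
    M: int
    N: int

    def to_dict(self) -> dict:
        return {
            "dice": self.dice,
            "jaccard": self.jaccard,
            "correlation": self.correlation,
            "rmse": self.rmse,
            "TP": self.counts.TP, "FP": self.counts.FP,
            "FN": self.counts.FN, "TN": self.counts.TN,
            "M": self.M, "N": self.N,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)


def _as_bool_pair(segmented, truth):
    s = np.asarray(segmented)
    t = np.asarray(truth)
    if s.shape != t.shape:
        raise ValueError(f"masks differ in shape: {s.shape} vs {t.shape}")
    return s.astype(bool), t.astype(bool)


def confusion(segmented, truth) -> ConfusionCounts:
    """Per-pixel confusion counts of a predicted mask against ground truth."""
    s, t = _as_bool_pair(segmented, truth)
    tp = int((s & t).sum())
    fp = int((s & ~t).sum())
    fn = int((~s & t).sum())
    tn = int(s.size - tp - fp - fn)
    return ConfusionCounts(TP=tp, FP=fp, FN=fn, TN=tn)


def dice(counts: ConfusionCounts) -> float:
    """Dice similarity coefficient; 1.0 when both masks are empty."""
    denom = 2 * counts.TP + counts.FP + counts.FN
    if denom == 0:
        logger.info("both masks empty: Dice defined as 1.0 (perfect agreement on emptiness)")
        return 1.0
    return 2 * counts.TP / denom


def jaccard(counts: ConfusionCounts) -> float:
    """Jaccard index; 1.0 when both masks are empty."""
    denom = counts.TP + counts.FP + counts.FN
    if denom == 0:
        logger.info("both masks empty: Jaccard defined as 1.0 (perfect agreement on emptiness)")
        return 1.0
    return counts.TP / denom


def correlation(Is, Ig) -> float:
    """Pearson correlation of two images (or masks) over all pixels.

    Uses population (divide-by-MN) means and standard deviations; raises for
    constant input, where the correlation is undefined.
    """
    a = np.asarray(Is, dtype=float)
    b = np.asarray(Ig, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"images differ in shape: {a.shape} vs {b.shape}")
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        raise ValueError("correlation is undefined for a constant image")
    return float((((a - a.mean()) / sa) * ((b - b.mean()) / sb)).mean())


def rmse(Is, Ig) -> float:
    """Root mean squared pixel difference on the normalized [0, 1] scale."""
    a = np.asarray(Is, dtype=float)
    b = np.asarray(Ig, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"images differ in shape: {a.shape} vs {b.shape}")
    return float(np.sqrt(((a - b) ** 2).mean()))


def evaluate_masks(segmented, truth) -> MetricsReport:
    """Full metric report of a predicted mask against ground truth.

    The correlation is reported as NaN (with a warning) when either mask is
    constant, e.g. empty.
    """
    s, t = _as_bool_pair(segmented, truth)
    counts = confusion(s, t)
    try:
        corr = correlation(s, t)
    except ValueError:
        logger.warning("constant mask: correlation undefined, reporting NaN")
        corr = float("nan")
    return MetricsReport(
        dice=dice(counts), jaccard=jaccard(counts), correlation=corr,
        rmse=rmse(s.astype(float), t.astype(float)),
        counts=counts, M=s.shape[0], N=s.shape[1],
    )
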