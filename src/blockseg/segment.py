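"""K-means (K = 2) intensity clustering of the detected lesion block.

The block's raw intensities are split into two clusters; the brighter one is
labeled tumor (lesions are hyperintense on FLAIR/T1c — configurable for
hypointense targets).  Initial centers are spread between the block's
minimum and maximum intensity, a deterministic seeding for 1-D data, so the
whole stage is reproducible without randomness.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .blocksearch import Block

__all__ = ["SegmentationResult", "kmeans_1d", "segment_roi"]

logger = logging.getLogger(__name__)

_MAX_ITER = 300


@dataclass
class SegmentationResult:
    tumor_mask: np.ndarray
    roi: Block
    cluster_centers: tuple[float, ...]
    iterations_used: int


def _kmeans_core(x: np.ndarray, k: int, max_iter: int):
    centers = np.linspace(x.min(), x.max(), k)
    labels = np.zeros(x.size, dtype=int)
    iterations = 0
    for iterations in range(1, max_iter + 1):
        new_labels = np.abs(x[:, None] - centers[None, :]).argmin(axis=1)
        for j in range(k):
            members = x[new_labels == j]
            if members.size:
                centers[j] = members.mean()
            else:
                # re-seed an empty cluster at the point farthest from its
                # nearest surviving center
                occupied = np.unique(new_labels)
                dist = np.abs(x[:, None] - centers[None, occupied]).min(axis=1)
                centers[j] = x[dist.argmax()]
        if iterations > 1 and np.array_equal(new_labels, labels):
            labels = new_labels
            break
        labels = new_labels
    order = np.argsort(centers)
    remap = np.empty(k, dtype=int)
    remap[order] = np.arange(k)
    return remap[labels], centers[order], iterations


def kmeans_1d(values, k: int = 2, seed: int = 0,
              max_iter: int = _MAX_ITER) -> tuple[np.ndarray, np.ndarray]:
    """Cluster scalars into ``k`` groups by nearest-center assignment.

    Iterates assignment/update until no assignment changes (or ``max_iter``).
    Centers are returned sorted ascending with labels relabeled to match.
    ``seed`` is accepted for API symmetry; the initialization (centers
    spread evenly over [min, max], i.e. exactly {min, max} for K = 2) is
    deterministic.

    Raises ``ValueError`` when fewer than ``k`` distinct values exist.
    """
    x = np.asarray(values, dtype=float).ravel()
    if k < 1:
        raise ValueError("k must be >= 1")
    if np.unique(x).size < k:
        raise ValueError(f"need at least {k} distinct values for {k} clusters")
    labels, centers, _ = _kmeans_core(x, k, max_iter)
    return labels, centers


def segment_roi(diseased: np.ndarray, roi: Block, seed: int = 0,
                tumor_polarity: str = "bright") -> SegmentationResult:
    """Two-cluster segmentation of the ROI into tumor vs non-tumor.

    The tumor mask lives in the full image frame and is zero outside the
    ROI.  A constant ROI yields an empty mask with a logged warning (a flat
    block carries no lesion evidence) rather than an error.
    """
    if tumor_polarity not in ("bright", "dark"):
        raise ValueError(f'tumor_polarity must be "bright" or "dark", got {tumor_polarity!r}')
    img = np.asarray(diseased, dtype=float)
    roi.validate(img.shape)
    block = roi.view(img)

    mask = np.zeros(img.shape, dtype=bool)
    if np.ptp(block) == 0:
        logger.warning("ROI is constant; returning an empty tumor mask")
        c = float(block.flat[0])
        return SegmentationResult(mask, roi, (c, c), 0)

    labels, centers, iterations = _kmeans_core(block.ravel(), 2, _MAX_ITER)
    tumor_label = 1 if tumor_polarity == "bright" else 0
    mask[roi.top:roi.top + roi.height, roi.left:roi.left + roi.width] = \
        (labels == tumor_label).reshape(block.shape)
    return SegmentationResult(mask, roi, tuple(float(c) for c in centers), iterations)
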