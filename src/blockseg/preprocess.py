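"""Skull-stripping by thresholding and binary morphology.

The head image is binarized (Otsu by default, or a fixed threshold), holes
are filled, the mask is eroded with a disk structuring element to peel off
the thin bright skull ring, optionally only the largest 8-connected
component is kept, and the original image is masked.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label
from skimage.morphology import disk

__all__ = ["PreprocessConfig", "skull_strip"]


@dataclass(frozen=True)
class PreprocessConfig:
    """Skull-stripping parameters.

    threshold : float or "otsu"
        Binarization threshold on the normalized [0, 1] scale, or the token
        ``"otsu"`` for a data-driven threshold.
    erosion_radius : int
        Radius in pixels of the disk structuring element; 0 disables erosion.
    keep_largest_component : bool
        Keep only the largest 8-connected foreground component, discarding
        disconnected bright artifacts.
    """

    threshold: float | str = "otsu"
    erosion_radius: int = 5
    keep_largest_component: bool = True

    def validate(self) -> None:
        if isinstance(self.threshold, str):
            if self.threshold != "otsu":
                raise ValueError(f'threshold must be a float or "otsu", got {self.threshold!r}')
        elif not 0.0 < float(self.threshold) < 1.0:
            raise ValueError(f"numeric threshold must lie in (0, 1), got {self.threshold}")
        if self.erosion_radius < 0:
            raise ValueError(f"erosion_radius must be >= 0, got {self.erosion_radius}")


def skull_strip(image: np.ndarray,
                config: PreprocessConfig | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Strip non-brain structure from a head image.

    Returns ``(stripped, brain_mask)`` where ``stripped = image * brain_mask``.
    Raises ``ValueError`` if no brain region survives (e.g. an all-background
    image, or erosion consuming the whole foreground).
    """
    config = config or PreprocessConfig()
    config.validate()
    img = np.asarray(image, dtype=float)
    if img.ndim != 2 or img.size == 0:
        raise ValueError(f"expected a non-empty 2-d image, got shape {img.shape}")

    if config.threshold == "otsu":
        if np.ptp(img) == 0:
            raise ValueError("no brain region found: image is constant")
        thr = threshold_otsu(img)
    else:
        thr = float(config.threshold)
    mask = img > thr
    if not mask.any():
        raise ValueError("no brain region found: empty foreground after thresholding")

    mask = ndimage.binary_fill_holes(mask)
    if config.erosion_radius > 0:
        mask = ndimage.binary_erosion(mask, structure=disk(config.erosion_radius))
    if not mask.any():
        raise ValueError("no brain region found: erosion removed the whole foreground")
    if config.keep_largest_component:
        labels = label(mask, connectivity=2)
        sizes = np.bincount(labels.ravel())
        sizes[0] = 0
        mask = labels == sizes.argmax()

    return img * mask, mask
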