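"""Image loading and saving.

Images are loaded as 2-D grayscale arrays min-max normalized to [0, 1];
PNG/TIFF go through imageio, single slices of NIfTI volumes through
nibabel.  Grayscale images are written as 16-bit PNG/TIFF, binary masks as
8-bit PNG with values {0, 255}.
"""

from __future__ import annotations

import logging
from pathlib import Path

import imageio.v3 as iio
import numpy as np

__all__ = ["load_image", "load_mask", "save_image", "save_mask"]

logger = logging.getLogger(__name__)

_NIFTI_SUFFIXES = (".nii", ".nii.gz")


def _is_nifti(path: Path) -> bool:
    name = path.name.lower()
    return name.endswith(".nii") or name.endswith(".nii.gz")


def load_image(path, slice_index: int | None = None) -> np.ndarray:
    """Load a single 2-D grayscale frame, normalized to [0, 1].

    ``slice_index`` selects an axial slice of a 3-D NIfTI volume and is
    required for volumetric input; RGB images are rejected.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if _is_nifti(path):
        import nibabel as nib

        data = np.asanyarray(nib.load(str(path)).dataobj).astype(float)
        if data.ndim == 3:
            if slice_index is None:
                raise ValueError(
                    f"{path.name} is a 3-d volume; pass a slice index to select one frame"
                )
            data = data[:, :, slice_index]
        elif data.ndim != 2:
            raise ValueError(f"cannot interpret {data.ndim}-d NIfTI data as a single slice")
        arr = data
    else:
        arr = np.asarray(iio.imread(path)).astype(float)
        if arr.ndim == 3:
            if arr.shape[-1] in (3, 4):
                raise ValueError(
                    f"{path.name} is an RGB(A) image; convert it to grayscale first"
                )
            if slice_index is None:
                raise ValueError(
                    f"{path.name} is multi-frame; pass a slice index to select one frame"
                )
            arr = arr[slice_index]
        elif arr.ndim != 2:
            raise ValueError(f"cannot interpret {arr.ndim}-d image data as a single frame")

    if not np.isfinite(arr).all():
        raise ValueError(f"{path.name} contains non-finite pixel values")
    lo, hi = arr.min(), arr.max()
    if hi == lo:
        logger.warning("%s is constant; normalizing to all zeros", path.name)
        return np.zeros_like(arr, dtype=float)
    return (arr - lo) / (hi - lo)


def load_mask(path) -> np.ndarray:
    """Load a binary mask (any nonzero pixel counts as foreground)."""
    return np.asarray(iio.imread(Path(path))) > 0


def save_image(path, image: np.ndarray) -> None:
    """Write a [0, 1] grayscale image as 16-bit PNG or TIFF."""
    img = np.asarray(image, dtype=float)
    if img.min() < 0 or img.max() > 1:
        raise ValueError("image intensities must lie in [0, 1]")
    iio.imwrite(Path(path), np.rint(img * 65535.0).astype(np.uint16))


def save_mask(path, mask: np.ndarray) -> None:
    """Write a binary mask as 8-bit PNG with values {0, 255}."""
    m = np.asarray(mask).astype(bool)
    iio.imwrite(Path(path), (m.astype(np.uint8) * 255))
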