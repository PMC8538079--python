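"""Reading and writing slide images and Gleason-pattern masks.

Slides are 8-bit RGB rasters (PNG or TIFF); masks are single-channel
rasters with values 0 (background) through 5 (GP5).
"""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np

MASK_LABELS = frozenset(range(6))


def validate_image(img: np.ndarray) -> np.ndarray:
    """Check that ``img`` is a non-empty H x W x 3 uint8 raster."""
    img = np.asarray(img)
    if img.size == 0:
        raise ValueError("empty input")
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError(f"expected H x W x 3 RGB image, got shape {img.shape}")
    if img.dtype != np.uint8:
        raise ValueError(f"expected uint8 image, got {img.dtype}")
    return img


def validate_mask(mask: np.ndarray, image: np.ndarray | None = None) -> np.ndarray:
    """Check that ``mask`` is an integer raster with values in 0..5."""
    mask = np.asarray(mask)
    if mask.size == 0:
        raise ValueError("empty input")
    if mask.ndim != 2:
        raise ValueError(f"expected 2-D mask, got shape {mask.shape}")
    if not np.issubdtype(mask.dtype, np.integer):
        raise ValueError(f"expected integer mask, got {mask.dtype}")
    if mask.min() < 0 or mask.max() > 5:
        raise ValueError("illegal label")
    if image is not None and mask.shape != image.shape[:2]:
        raise ValueError(
            f"mask shape {mask.shape} does not match image {image.shape[:2]}"
        )
    return mask


def read_image(path: str | Path) -> np.ndarray:
    img = iio.imread(path)
    if img.ndim == 2:
        img = np.stack([img] * 3, axis=-1)
    if img.ndim == 3 and img.shape[2] == 4:  # drop alpha
        img = img[:, :, :3]
    return validate_image(img.astype(np.uint8, copy=False))


def write_image(path: str | Path, img: np.ndarray) -> None:
    iio.imwrite(path, validate_image(img))


def read_mask(path: str | Path) -> np.ndarray:
    mask = iio.imread(path)
    if mask.ndim == 3:
        mask = mask[:, :, 0]
    return validate_mask(mask.astype(np.uint8, copy=False))


def write_mask(path: str | Path, mask: np.ndarray) -> None:
    iio.imwrite(path, validate_mask(mask).astype(np.uint8))
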