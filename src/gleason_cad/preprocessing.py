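"""Slide preprocessing: histogram equalization followed by edge sharpening.

Equalization remaps each channel through its cumulative histogram so the
occupied intensity range is stretched to [0, 255]; sharpening convolves
each channel with a unit-DC-gain Laplacian kernel so flat regions are
unchanged while edges gain contrast.  Masks are never preprocessed —
only image pixels.
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import convolve
from skimage.color import rgb2ycbcr, ycbcr2rgb

from gleason_cad.io import validate_image

#: 3x3 sharpen kernel; rows sum to 1 so constant regions pass unchanged.
SHARPEN_KERNEL = np.array(
    [[0, -1, 0], [-1, 5, -1], [0, -1, 0]], dtype=np.float64
)


def _equalize_channel(channel: np.ndarray) -> np.ndarray:
    """Equalize one uint8 channel via its cumulative histogram.

    Uses the cdf_min-anchored mapping
    ``T(v) = round(255 * (cdf(v) - cdf_min) / (n - cdf_min))``
    so the minimum occupied bin maps to 0, the maximum to 255, and a
    constant channel is returned unchanged.
    """
    hist = np.bincount(channel.ravel(), minlength=256)
    cdf = np.cumsum(hist)
    cdf_min = cdf[np.nonzero(hist)[0][0]]
    denom = cdf[-1] - cdf_min
    if denom == 0:  # constant channel: nothing to stretch
        return channel.copy()
    lut = np.round(255.0 * (cdf - cdf_min) / denom).astype(np.uint8)
    return lut[channel]


def equalize_histogram(img: np.ndarray, luminance_only: bool = False) -> np.ndarray:
    """Histogram-equalize a slide image.

    Parameters
    ----------
    img
        H x W x 3 uint8 RGB image.
    luminance_only
        If True, equalize the luma channel in YCbCr space and leave
        chroma untouched; by default each RGB channel is equalized
        independently.
    """
    img = validate_image(img)
    if luminance_only:
        ycbcr = rgb2ycbcr(img)
        # luma occupies [16, 235]; quantize, equalize, rescale back
        y = np.clip(np.round(ycbcr[:, :, 0]), 0, 255).astype(np.uint8)
        ycbcr[:, :, 0] = _equalize_channel(y) * (235.0 - 16.0) / 255.0 + 16.0
        rgb = ycbcr2rgb(ycbcr)
        return np.clip(np.round(rgb * 255.0), 0, 255).astype(np.uint8)
    out = np.empty_like(img)
    for c in range(3):
        out[:, :, c] = _equalize_channel(img[:, :, c])
    return out


def enhance_edges(img: np.ndarray, kernel: np.ndarray | None = None) -> np.ndarray:
    """Sharpen a slide image by convolving each channel with ``kernel``.

    Borders are handled by edge replication so output size equals input
    size; results are clipped to [0, 255].
    """
    img = validate_image(img)
    k = SHARPEN_KERNEL if kernel is None else np.asarray(kernel, dtype=np.float64)
    out = np.empty_like(img)
    for c in range(3):
        conv = convolve(img[:, :, c].astype(np.float64), k, mode="nearest")
        out[:, :, c] = np.clip(np.round(conv), 0, 255).astype(np.uint8)
    return out


def preprocess(
    img: np.ndarray,
    *,
    enhance: bool = True,
    luminance_only: bool = False,
    kernel: np.ndarray | None = None,
) -> np.ndarray:
    """Full preprocessing: equalize the histogram, then sharpen edges."""
    out = equalize_histogram(img, luminance_only=luminance_only)
    if enhance:
        out = enhance_edges(out, kernel=kernel)
    return out
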