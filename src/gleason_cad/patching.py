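"""Pyramidal extraction of overlapping square patches.

Slides are tiled at three scales (patch sides 100, 150 and 200 px) with
75% overlap between successive patches, i.e. stride ``floor(scale / 4)``
(25, 37 and 50 px).  The last window along each axis is snapped to the
image boundary so the grid covers every pixel; windows are half-open
``[r, r+N) x [c, c+N)`` with 0-based origins.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from gleason_cad.io import validate_image, validate_mask

#: Canonical pyramid scales: small (CNNS), medium (CNNM), large (CNNL).
SCALES = (100, 150, 200)


@dataclass
class PatchRecord:
    """One extracted window of a slide."""

    slide_id: str
    scale: int
    origin: tuple[int, int]  # (row, col), 0-based top-left
    pixels: np.ndarray  # N x N x 3 uint8
    label: int | None = None  # training label, 1..5
    mask: np.ndarray | None = None  # N x N ground-truth window, 0..5


@dataclass(frozen=True)
class PatchGrid:
    """Row-major grid of patch origins at one scale."""

    scale: int
    stride: int
    row_starts: tuple[int, ...]
    col_starts: tuple[int, ...]

    @property
    def origins(self) -> list[tuple[int, int]]:
        return [(r, c) for r in self.row_starts for c in self.col_starts]

    def __len__(self) -> int:
        return len(self.row_starts) * len(self.col_starts)

    @property
    def overlap_fraction(self) -> float:
        return 1.0 - self.stride / self.scale


def _axis_starts(length: int, scale: int, stride: int) -> tuple[int, ...]:
    starts = list(range(0, length - scale + 1, stride))
    if starts[-1] != length - scale:  # snap final window to the boundary
        starts.append(length - scale)
    return tuple(starts)


def plan_grid(height: int, width: int, scale: int) -> PatchGrid:
    """Plan the overlapping-patch grid for an ``height x width`` slide.

    Stride is ``floor(scale / 4)``, giving >= 75% overlap at every
    canonical scale.  Raises if the slide is smaller than one patch.
    """
    if scale < 1:
        raise ValueError(f"invalid patch scale {scale}")
    if height < scale or width < scale:
        raise ValueError("image smaller than patch")
    stride = scale // 4
    return PatchGrid(
        scale=scale,
        stride=stride,
        row_starts=_axis_starts(height, scale, stride),
        col_starts=_axis_starts(width, scale, stride),
    )


def extract_patches(
    img: np.ndarray,
    grid: PatchGrid,
    mask: np.ndarray | None = None,
    slide_id: str = "",
) -> list[PatchRecord]:
    """Extract one :class:`PatchRecord` per grid origin, in grid order.

    When a ground-truth mask is supplied each record carries its mask
    window for downstream training-patch selection.
    """
    img = validate_image(img)
    if mask is not None:
        mask = validate_mask(mask, img)
    h, w = img.shape[:2]
    if grid.row_starts[-1] + grid.scale > h or grid.col_starts[-1] + grid.scale > w:
        raise ValueError("grid was not planned for this image size")
    n = grid.scale
    patches = []
    for r, c in grid.origins:
        patches.append(
            PatchRecord(
                slide_id=slide_id,
                scale=n,
                origin=(r, c),
                pixels=img[r : r + n, c : c + n].copy(),
                mask=None if mask is None else mask[r : r + n, c : c + n].copy(),
            )
        )
    return patches


def coverage_counts(grid: PatchGrid, height: int, width: int) -> np.ndarray:
    """Number of grid windows covering each pixel (for audits and voting)."""
    counts = np.zeros((height, width), dtype=np.int32)
    n = grid.scale
    for r, c in grid.origins:
        counts[r : r + n, c : c + n] += 1
    return counts
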