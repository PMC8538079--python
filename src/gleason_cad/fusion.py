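"""Patch-wise classification, pixel-wise majority voting and cross-scale
fusion.

Every overlapping patch receives one hard Gleason-pattern label (argmax
of the CNN's softmax, ties toward the smallest label).  Each pixel is
then assigned the modal label over all patches covering it, producing a
label map the same size as the slide; the three per-scale maps are fused
by a second majority vote.  When all three scales disagree the large
network's label wins — the large scale is the most accurate of the
three.  Voting never emits background (0); a known background mask can
be re-imposed afterwards with :func:`apply_background`.
"""

from __future__ import annotations

import numpy as np

from gleason_cad.io import validate_image, validate_mask
from gleason_cad.patching import PatchGrid


def classify_patches(
    model, grid: PatchGrid, img: np.ndarray, batch_size: int = 32
) -> np.ndarray:
    """Hard GP label (1..5) for each grid origin, in grid order.

    ``model`` is anything with ``predict_proba(batch) -> (B, 5)``; ties
    in the argmax go to the smallest label.
    """
    img = validate_image(img)
    if hasattr(model, "spec") and model.spec.input_side != grid.scale:
        raise ValueError(
            f"model input side {model.spec.input_side} != grid scale {grid.scale}"
        )
    n = grid.scale
    origins = grid.origins
    labels = np.empty(len(origins), dtype=np.uint8)
    x = img.astype(np.float32) / 255.0
    for i in range(0, len(origins), batch_size):
        batch = np.stack(
            [x[r : r + n, c : c + n] for r, c in origins[i : i + batch_size]]
        )
        probs = model.predict_proba(batch)
        labels[i : i + len(batch)] = probs.argmax(axis=1).astype(np.uint8) + 1
    return labels


def accumulate_votes(
    grid: PatchGrid, patch_labels: np.ndarray, height: int, width: int
) -> np.ndarray:
    """Per-pixel vote counts over labels 1..5 (an H x W x 5 field).

    The vote total at a pixel equals the number of patches covering it.
    """
    patch_labels = np.asarray(patch_labels)
    origins = grid.origins
    if len(patch_labels) != len(origins):
        raise ValueError("one label per grid origin required")
    votes = np.zeros((height, width, 5), dtype=np.int32)
    n = grid.scale
    for (r, c), label in zip(origins, patch_labels):
        if not 1 <= label <= 5:
            raise ValueError(f"patch label {label} outside 1..5")
        votes[r : r + n, c : c + n, label - 1] += 1
    return votes


def pixel_vote(
    grid: PatchGrid, patch_labels: np.ndarray, height: int, width: int
) -> np.ndarray:
    """Majority-vote label map (H x W, values 1..5) from patch labels.

    Each pixel takes the modal label among all covering patches; ties go
    to the smallest label.  Every pixel must be covered by at least one
    patch (boundary-snapped grids guarantee this).
    """
    votes = accumulate_votes(grid, patch_labels, height, width)
    if (votes.sum(axis=2) == 0).any():
        raise ValueError("pixel covered by zero patches")
    # argmax picks the first (smallest) label on ties
    return (votes.argmax(axis=2) + 1).astype(np.uint8)


def fuse_scales(
    map_s: np.ndarray, map_m: np.ndarray, map_l: np.ndarray
) -> np.ndarray:
    """Fuse the three per-scale label maps by pixel-wise majority.

    With three voters the modal label is whichever label appears at
    least twice; when all three disagree the large-scale map wins.
    Reduces to: take the small/medium label where they agree, else the
    large-scale label.
    """
    map_s, map_m, map_l = (np.asarray(m) for m in (map_s, map_m, map_l))
    if not (map_s.shape == map_m.shape == map_l.shape):
        raise ValueError("label maps differ in shape")
    return np.where(map_s == map_m, map_s, map_l).astype(np.uint8)


def fuse_probability_sum(per_scale_probs: list[np.ndarray]) -> np.ndarray:
    """Alternative soft fusion: argmax of summed per-pixel class
    probabilities (off by default in the pipeline)."""
    total = np.sum(per_scale_probs, axis=0)
    return (total.argmax(axis=2) + 1).astype(np.uint8)


def apply_background(label_map: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Re-impose known background: zero out pixels where ``mask`` is 0."""
    mask = validate_mask(mask)
    if mask.shape != label_map.shape:
        raise ValueError("mask shape does not match label map")
    return np.where(mask == 0, 0, label_map).astype(np.uint8)


class MajorityOracleClassifier:
    """Ground-truth stub classifier used to validate the voting stages.

    Returns, for each patch window, a one-hot "probability" on the
    majority Gleason pattern of the ground-truth mask (ties toward the
    smallest label); windows with no tissue pixels fall back to GP1.
    The constructor takes the slide's mask; patch windows are located by
    :func:`oracle_labels`, which pairs it with a grid.
    """

    def __init__(self, mask: np.ndarray):
        self.mask = validate_mask(mask)

    def labels_for_grid(self, grid: PatchGrid) -> np.ndarray:
        n = grid.scale
        labels = np.empty(len(grid.origins), dtype=np.uint8)
        for i, (r, c) in enumerate(grid.origins):
            counts = np.bincount(
                self.mask[r : r + n, c : c + n].ravel(), minlength=6
            )[1:]
            labels[i] = counts.argmax() + 1 if counts.any() else 1
        return labels


def predict_label_map(
    models: dict[int, object], img: np.ndarray, batch_size: int = 32
) -> np.ndarray:
    """Full multi-scale inference: classify, vote per scale, fuse.

    ``models`` maps patch scale -> classifier; the scales are used in
    ascending order (small, medium, large).
    """
    from gleason_cad.patching import plan_grid

    img = validate_image(img)
    h, w = img.shape[:2]
    maps = []
    for scale in sorted(models):
        grid = plan_grid(h, w, scale)
        labels = classify_patches(models[scale], grid, img, batch_size=batch_size)
        maps.append(pixel_vote(grid, labels, h, w))
    if len(maps) != 3:
        raise ValueError("expected exactly three scales for fusion")
    return fuse_scales(*maps)
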