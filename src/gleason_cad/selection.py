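"""Training-patch selection.

A patch is kept for training only when the winning label (WL) — the
majority Gleason pattern over the patch's non-background ground-truth
pixels — agrees with the center value (CV, the mask value at the patch
center) and the background ratio (RB, fraction of background pixels)
does not exceed 0.3.  The training label of a selected patch is its WL.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from gleason_cad.patching import PatchRecord

#: Maximum tolerated fraction of background pixels in a training patch.
MAX_BACKGROUND_RATIO = 0.3


@dataclass(frozen=True)
class SelectionDecision:
    """Outcome of the selection rule for one patch.

    ``wl`` is 0 when the window contains no tissue pixels at all (no
    Gleason pattern can win); such patches are never selected.
    """

    wl: int  # winning label, 1..5 (0: window is all background)
    cv: int  # mask value at the patch center, 0..5
    rb: float  # background fraction in [0, 1]
    selected: bool


def decide(patch_mask: np.ndarray) -> SelectionDecision:
    """Apply the selection rule to one patch's ground-truth window.

    WL is the modal label over non-background pixels, ties broken toward
    the smallest label; CV is the value at ``(N//2, M//2)``; RB is the
    fraction of zeros.  Selected iff ``WL == CV`` and ``RB <= 0.3``.
    """
    w = np.asarray(patch_mask)
    if w.ndim != 2 or w.size == 0:
        raise ValueError(f"expected non-empty 2-D mask window, got shape {w.shape}")
    if not np.issubdtype(w.dtype, np.integer) or w.min() < 0 or w.max() > 5:
        raise ValueError("illegal label")
    counts = np.bincount(w.ravel(), minlength=6)
    rb = counts[0] / w.size
    # argmax returns the first maximum, i.e. the smallest label on ties
    wl = int(np.argmax(counts[1:])) + 1 if counts[1:].any() else 0
    cv = int(w[w.shape[0] // 2, w.shape[1] // 2])
    selected = wl != 0 and wl == cv and rb <= MAX_BACKGROUND_RATIO
    return SelectionDecision(wl=wl, cv=cv, rb=float(rb), selected=selected)


def select_training_patches(patches: list[PatchRecord]) -> list[PatchRecord]:
    """Filter patches by the selection rule; label the survivors with WL.

    Order is preserved.  Every patch must carry its mask window.
    """
    kept = []
    for p in patches:
        if p.mask is None:
            raise ValueError("patch has no ground-truth mask window")
        d = decide(p.mask)
        if d.selected:
            p.label = d.wl
            kept.append(p)
    return kept


def selection_report(patches: list[PatchRecord]) -> pd.DataFrame:
    """Per-patch WL/CV/RB/selected table (one row per input patch)."""
    rows = []
    for p in patches:
        if p.mask is None:
            raise ValueError("patch has no ground-truth mask window")
        d = decide(p.mask)
        rows.append(
            {
                "slide_id": p.slide_id,
                "scale": p.scale,
                "row": p.origin[0],
                "col": p.origin[1],
                "WL": d.wl,
                "CV": d.cv,
                "RB": d.rb,
                "selected": d.selected,
            }
        )
    return pd.DataFrame(rows)
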