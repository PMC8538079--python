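"""Gleason score and ISUP grade-group derivation from a label map.

The two most frequent epithelial cancer patterns (GP3–GP5) in the final
pixel-wise label map define the primary and secondary pattern; their sum
is the Gleason score (GS 6–10) and the ordered pair maps onto the five
ISUP grade groups:

=========  ===  ==
pattern    GS   GG
=========  ===  ==
3 + 3       6   GG1
3 + 4       7   GG2
4 + 3       7   GG3
4 + 4       8   GG4
3 + 5       8   GG4
5 + 3       8   GG4
4 + 5       9   GG5
5 + 4       9   GG5
5 + 5      10   GG5
=========  ===  ==

GP1 (stroma) and GP2 (benign epithelium) never contribute to the score;
a slide with no qualifying cancer pattern is reported Benign.  A
pattern qualifies only if it covers at least a fraction ``min_fraction``
(default 1%) of the tissue pixels, so isolated misclassified pixels
cannot set the secondary pattern.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

#: Ordered (primary, secondary) -> grade group.
GG_TABLE: dict[tuple[int, int], str] = {
    (3, 3): "GG1",
    (3, 4): "GG2",
    (4, 3): "GG3",
    (4, 4): "GG4",
    (3, 5): "GG4",
    (5, 3): "GG4",
    (4, 5): "GG5",
    (5, 4): "GG5",
    (5, 5): "GG5",
}

#: Epithelial cancer patterns that can enter the Gleason score.
CANCER_PATTERNS = (3, 4, 5)

DEFAULT_MIN_FRACTION = 0.01


@dataclass(frozen=True)
class GradingResult:
    """Slide-level grading outcome."""

    slide_id: str
    primary_gp: int | None
    secondary_gp: int | None
    gs: int | None
    gg: str  # "Benign" or "GG1".."GG5"
    histogram: dict[int, int]  # pixel counts for labels 1..5

    @property
    def benign(self) -> bool:
        return self.primary_gp is None

    def to_json(self) -> str:
        return json.dumps(
            {
                "slide_id": self.slide_id,
                "primary_gp": self.primary_gp,
                "secondary_gp": self.secondary_gp,
                "gs": self.gs,
                "gg": self.gg,
                "histogram": {str(k): v for k, v in self.histogram.items()},
            }
        )


def pattern_histogram(label_map: np.ndarray) -> dict[int, int]:
    """Pixel counts per Gleason pattern (labels 1..5; 0 is background)."""
    label_map = np.asarray(label_map)
    if label_map.min() < 0 or label_map.max() > 5:
        raise ValueError("illegal label")
    counts = np.bincount(label_map.ravel(), minlength=6)
    return {k: int(counts[k]) for k in range(1, 6)}


def derive_gs(
    hist: dict[int, int], min_fraction: float = DEFAULT_MIN_FRACTION
) -> tuple[int, int, int] | None:
    """(primary, secondary, GS) from a pattern histogram, or None.

    Only cancer patterns (GP3–5) covering at least ``min_fraction`` of
    all tissue pixels qualify.  The primary pattern is the most frequent
    qualifier, the secondary the next (equal to the primary when only
    one qualifies); frequency ties go to the smaller pattern.  Returns
    None (benign) when nothing qualifies.
    """
    tissue = sum(hist.get(k, 0) for k in range(1, 6))
    if tissue == 0:
        return None
    floor = min_fraction * tissue
    qualifying = [
        (hist.get(p, 0), p)
        for p in CANCER_PATTERNS
        if hist.get(p, 0) >= floor and hist.get(p, 0) > 0
    ]
    if not qualifying:
        return None
    # sort by count desc, then pattern asc (tie toward the smaller GP)
    qualifying.sort(key=lambda cp: (-cp[0], cp[1]))
    primary = qualifying[0][1]
    secondary = qualifying[1][1] if len(qualifying) > 1 else primary
    return primary, secondary, primary + secondary


def gs_to_gg(primary_gp: int, secondary_gp: int) -> str:
    """Grade group for an ordered (primary, secondary) pattern pair."""
    key = (primary_gp, secondary_gp)
    if key not in GG_TABLE:
        raise ValueError(f"patterns must be in {{3,4,5}}, got {key}")
    return GG_TABLE[key]


def grade_slide(
    label_map: np.ndarray,
    slide_id: str = "",
    min_fraction: float = DEFAULT_MIN_FRACTION,
) -> GradingResult:
    """Grade one slide from its final pixel-wise label map."""
    hist = pattern_histogram(label_map)
    derived = derive_gs(hist, min_fraction=min_fraction)
    if derived is None:
        return GradingResult(slide_id, None, None, None, "Benign", hist)
    primary, secondary, gs = derived
    return GradingResult(slide_id, primary, secondary, gs, gs_to_gg(primary, secondary), hist)
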