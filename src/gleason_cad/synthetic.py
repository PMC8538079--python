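"""Synthetic pseudo-histology slides with per-pixel Gleason-pattern truth.

Each slide is a background frame around a tissue area partitioned into
Voronoi regions; every region carries one class (GP1..GP5, weighted so
GP1 — stroma — covers about 60% of tissue, matching the imbalance seen
in real biopsy cohorts).  Each class renders with a distinct base color
and a characteristic density of darker elliptical blobs (a cartoon of
gland/nucleus density falling from GP3 to GP5), plus Gaussian pixel
noise.  The generator makes no attempt at histological realism; it
reproduces the statistical structure the pipeline needs — multi-class
regions, class imbalance, a background margin, and per-class visual
signatures a small CNN can learn.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from skimage.draw import disk

from gleason_cad.grading import grade_slide
from gleason_cad import io


@dataclass(frozen=True)
class ClassTexture:
    base_color: tuple[int, int, int]
    blob_color: tuple[int, int, int]
    blob_density: float  # blobs per pixel of class area
    blob_radius: float


#: Visual signature per mask label (0 = background).  Base colors are
#: hue-distinct (different channel orderings), not merely brightness
#: levels, so class identity survives the per-channel histogram
#: equalization applied by the preprocessing stage (a monotone remap of
#: each channel).  Blob density falls from GP3 to GP5 while blob size
#: grows, echoing the loss of gland density in higher patterns.
CLASS_TEXTURES: dict[int, ClassTexture] = {
    0: ClassTexture((243, 242, 245), (243, 242, 245), 0.0, 0.0),
    1: ClassTexture((235, 200, 215), (205, 150, 175), 3e-4, 3.0),
    2: ClassTexture((225, 215, 150), (180, 160, 90), 8e-4, 6.0),
    3: ClassTexture((170, 120, 200), (90, 40, 130), 3e-3, 3.0),
    4: ClassTexture((90, 160, 170), (30, 90, 100), 1.5e-3, 4.0),
    5: ClassTexture((140, 60, 70), (70, 20, 30), 6e-4, 5.0),
}


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic slide.

    ``class_weights`` is a 6-vector over (background, GP1..GP5) used to
    draw each Voronoi region's class; the default puts 60% of tissue on
    GP1 and 10% on each of GP2..GP5.  Same seed -> bit-identical output.
    """

    height: int = 320
    width: int = 320
    n_regions: int = 5  # few regions -> regions large vs. patch sizes
    margin: int = 20  # background frame width in px
    class_weights: tuple[float, ...] = (0.0, 0.6, 0.1, 0.1, 0.1, 0.1)
    noise_sd: float = 6.0
    seed: int = 0

    def validate(self) -> None:
        if self.height <= 2 * self.margin or self.width <= 2 * self.margin:
            raise ValueError("degenerate spec: no tissue area")
        w = np.asarray(self.class_weights, dtype=float)
        if len(w) != 6 or (w < 0).any() or not np.isclose(w.sum(), 1.0):
            raise ValueError("class_weights must be 6 non-negative values summing to 1")
        if self.n_regions < 1:
            raise ValueError("need at least one region")


def generate_slide(spec: SyntheticSpec) -> tuple[np.ndarray, np.ndarray]:
    """Render one (image, mask) pair from ``spec``."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    h, w, m = spec.height, spec.width, spec.margin

    # --- mask: Voronoi partition of the tissue rectangle ---
    points = np.column_stack(
        [rng.uniform(m, h - m, spec.n_regions), rng.uniform(m, w - m, spec.n_regions)]
    )
    region_class = rng.choice(6, size=spec.n_regions, p=spec.class_weights)
    rows, cols = np.mgrid[m : h - m, m : w - m]
    coords = np.column_stack([rows.ravel(), cols.ravel()])
    _, nearest = cKDTree(points).query(coords)
    mask = np.zeros((h, w), dtype=np.uint8)
    mask[m : h - m, m : w - m] = (
        region_class[nearest].reshape(rows.shape).astype(np.uint8)
    )

    # --- image: base color per class, blobs, noise ---
    img = np.empty((h, w, 3), dtype=np.float64)
    img[:] = CLASS_TEXTURES[0].base_color
    for label in range(1, 6):
        sel = mask == label
        if not sel.any():
            continue
        tex = CLASS_TEXTURES[label]
        img[sel] = tex.base_color
        n_blobs = int(tex.blob_density * sel.sum())
        if n_blobs == 0:
            continue
        pix_r, pix_c = np.nonzero(sel)
        centers = rng.choice(len(pix_r), size=n_blobs, replace=True)
        radii = tex.blob_radius * rng.uniform(0.6, 1.4, size=n_blobs)
        for idx, radius in zip(centers, radii):
            rr, cc = disk((pix_r[idx], pix_c[idx]), radius, shape=(h, w))
            inside = mask[rr, cc] == label  # blobs never cross region edges
            img[rr[inside], cc[inside]] = tex.blob_color
    img += rng.normal(0.0, spec.noise_sd, size=img.shape)
    return np.clip(np.round(img), 0, 255).astype(np.uint8), mask


def derive_slide_seeds(master_seed: int, n_slides: int) -> list[int]:
    """Per-slide seeds spawned from one master seed (collision-free by
    construction of :class:`numpy.random.SeedSequence`)."""
    children = np.random.SeedSequence(master_seed).spawn(n_slides)
    return [int(c.generate_state(1)[0]) for c in children]


def generate_dataset(
    n_slides: int,
    spec: SyntheticSpec | None = None,
    seed: int = 0,
    out_dir: str | Path | None = None,
) -> tuple[list[tuple[str, np.ndarray, np.ndarray]], pd.DataFrame]:
    """Generate ``n_slides`` slide/mask pairs plus a manifest.

    The manifest records per-slide class areas and the ground-truth
    grading (primary/secondary GP, GS, GG) computed from the true mask.
    When ``out_dir`` is given, slides, masks and the manifest CSV are
    written there.
    """
    if n_slides < 1:
        raise ValueError("n_slides must be >= 1")
    spec = spec or SyntheticSpec()
    slides = []
    rows = []
    for i, slide_seed in enumerate(derive_slide_seeds(seed, n_slides)):
        slide_id = f"slide_{i:03d}"
        img, mask = generate_slide(replace(spec, seed=slide_seed))
        slides.append((slide_id, img, mask))
        counts = np.bincount(mask.ravel(), minlength=6)
        result = grade_slide(mask, slide_id=slide_id)
        rows.append(
            {
                "slide_id": slide_id,
                "seed": slide_seed,
                **{f"area_{k}": int(counts[k]) for k in range(6)},
                "primary_gp": result.primary_gp,
                "secondary_gp": result.secondary_gp,
                "gs": result.gs,
                "gg": result.gg,
            }
        )
    manifest = pd.DataFrame(rows)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for slide_id, img, mask in slides:
            io.write_image(out / f"{slide_id}.png", img)
            io.write_mask(out / f"{slide_id}_mask.png", mask)
        manifest.to_csv(out / "manifest.csv", index=False)
    return slides, manifest
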