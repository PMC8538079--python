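import numpy as np
import pytest

from gleason_cad import patching, preprocessing, selection
from gleason_cad import synthetic as syn


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def default_dataset():
    """20 synthetic slides at generator defaults (the desk-scale study set)."""
    slides, manifest = syn.generate_dataset(20, seed=1)
    return slides, manifest


@pytest.fixture(scope="session")
def selected_patches_100(default_dataset):
    """Preprocessed, selection-filtered training patches at scale 100."""
    slides, _ = default_dataset
    patches = []
    for sid, img, mask in slides:
        pre = preprocessing.preprocess(img)
        grid = patching.plan_grid(*img.shape[:2], 100)
        patches += selection.select_training_patches(
            patching.extract_patches(pre, grid, mask=mask, slide_id=sid)
        )
    return patches


def random_rgb(rng, h=16, w=16):
    return rng.integers(0, 256, size=(h, w, 3), dtype=np.uint8)
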