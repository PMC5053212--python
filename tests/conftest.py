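import numpy as np
import pytest
from scipy import ndimage

import mammodense as md
from mammodense.features import DensePatch
from mammodense.image import MammogramImage


@pytest.fixture(scope="session")
def sim_default():
    """One default synthetic image with ground truth (seeded)."""
    return md.generate_breast_image(md.ImageSimParams(seed=11))


@pytest.fixture(scope="session")
def preprocessed_default(sim_default):
    img, truth = sim_default
    norm, mask, log = md.preprocess_image(img)
    return norm, mask, truth


def random_patch(seed: int, height: int = 28, width: int = 24,
                 dense_q: float = 0.5) -> DensePatch:
    """Random blobby dense patch: smooth-field mask, rough intensities."""
    rng = np.random.default_rng(seed)
    field = ndimage.gaussian_filter(rng.standard_normal((height, width)), 3)
    mask = field > np.quantile(field, dense_q)
    vals = np.where(mask, rng.uniform(0.2, 1.0, mask.shape), 0.0)
    img = MammogramImage(vals, bit_depth=12, id=f"patch-{seed}")
    return DensePatch.from_image(img, mask)


@pytest.fixture
def patch_factory():
    return random_patch
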