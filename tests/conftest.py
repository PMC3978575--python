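import numpy as np
import pytest

from mammodensity.image_io import GreyscaleImage
from mammodensity.phantom import PhantomSpec, generate_phantom


@pytest.fixture
def clean_spec():
    """A clean, artefact-free phantom at the default study conditions."""
    return PhantomSpec(dense_fraction=0.25, noise_sd=8.0, seed=7)


@pytest.fixture
def clean_phantom(clean_spec):
    return generate_phantom(clean_spec)


@pytest.fixture
def blob_image():
    """Small random image plus an irregular blob mask for filter oracles."""
    rng = np.random.default_rng(11)
    px = rng.integers(0, 256, size=(40, 40)).astype(np.uint8)
    yy, xx = np.mgrid[0:40, 0:40]
    mask = ((xx - 19) ** 2 / 15.0**2 + (yy - 20) ** 2 / 12.0**2) <= 1.0
    return GreyscaleImage(px, bit_depth=8, source_id="blob"), mask
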