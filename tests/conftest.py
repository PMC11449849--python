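import warnings

import numpy as np
import pytest

from octaquant.phantom import (
    make_enface_phantom,
    make_structural_phantom,
    make_temporal_phantom,
    random_enface_spec,
    random_two_layer_spec,
)

# skimage 0.26 deprecation chatter from morphology helpers is not under test
warnings.filterwarnings("ignore", category=FutureWarning, module="skimage")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def enface_phantom():
    """Noise-free 2D tube phantom with analytic ground truth."""
    spec = random_enface_spec(seed=7, extents=(256, 256), noise_free=True)
    image, gt = make_enface_phantom(spec)
    return image, gt


@pytest.fixture(scope="session")
def structural_phantom():
    """Small noisy two-layer 3D phantom."""
    spec = random_two_layer_spec(seed=11, extents=(128, 160, 160))
    vol, gt = make_structural_phantom(spec)
    return vol, gt


@pytest.fixture(scope="session")
def temporal_phantom():
    """Small 4-frame acquisition with static tissue and decorrelating vessels."""
    spec = random_two_layer_spec(seed=5, extents=(96, 128, 128))
    vol, gt = make_temporal_phantom(spec)
    return vol, gt
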