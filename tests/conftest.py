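import numpy as np
import pytest

from qsigmoid import GaussianSceneSpec, GrayImage, gaussian_scene, ground_truth_mask


@pytest.fixture(scope="session")
def phantom_spec():
    return GaussianSceneSpec()


@pytest.fixture(scope="session")
def phantom(phantom_spec):
    return gaussian_scene(phantom_spec)


@pytest.fixture(scope="session")
def truth(phantom_spec):
    return ground_truth_mask(phantom_spec)


@pytest.fixture(scope="session")
def ramp_image():
    """Smooth-gradient image: 65536 distinct, evenly spread intensities."""
    r, c = np.mgrid[0:256, 0:256]
    return GrayImage((r * 256 + c) / 65535.0, 1.0)
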