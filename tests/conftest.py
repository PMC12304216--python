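import numpy as np
import pytest

from angiorecon import phantoms as ph


@pytest.fixture(scope="session")
def straight_sample():
    """Noiseless straight tube: radius 3 mm, length 40 mm, 64^3 grid."""
    return ph.generate_phantom(ph.straight_tube_spec())


@pytest.fixture(scope="session")
def occluded_sample():
    """Straight ICA tube with a 6 mm occlusion in the middle."""
    return ph.generate_phantom(ph.occluded_tube_spec())


@pytest.fixture(scope="session")
def y_sample():
    """Carotid-like Y with distinct labels (CCA trunk, ICA/ECA daughters)."""
    return ph.generate_phantom(ph.y_bifurcation_spec())


@pytest.fixture(scope="session")
def noisy_sample():
    """Straight tube with Gaussian noise on all sequences."""
    return ph.generate_phantom(ph.straight_tube_spec(noise=5.0, seed=7))


def visible_mask(sample):
    """The mask a bright-blood-only segmentation would see (occlusions gone)."""
    from angiorecon.types import VesselMask
    data = sample.mask.data.copy()
    data[sample.occluded] = 0
    return VesselMask(data, sample.mask.spacing)
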