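import numpy as np
import pytest

from neuroqc.synthetic_phantoms import PhantomSpec, make_structural
from neuroqc.volume_io import Volume3D


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def noise_volume(rng):
    """32^3 white-noise volume, 1 mm voxels."""
    return Volume3D(rng.normal(100.0, 10.0, size=(32, 32, 32)), (1.0, 1.0, 1.0))


@pytest.fixture
def clean_phantom():
    """Noise-free default structural phantom with ground truth."""
    return make_structural(PhantomSpec(seed=0))


@pytest.fixture
def noisy_phantom():
    """Structural phantom with sigma=2 Gaussian noise and ground truth."""
    return make_structural(PhantomSpec(noise_sigma=2.0, seed=0))


#: compact anisotropic geometry used by motion-recovery tests (the default
#: near-cubic phantom is almost spherical, leaving rotations unidentifiable)
MOTION_GEOMETRY = dict(shape=(48, 40, 34), smooth_fwhm_mm=3.0,
                       head_fraction=0.62, brain_fraction=0.5,
                       gm_fraction=0.4, wm_fraction=0.25)
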