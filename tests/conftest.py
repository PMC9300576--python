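import numpy as np
import pytest
from hypothesis import settings
from scipy.spatial.transform import Rotation

from femnsa.synthetic import FemurSpec, generate_femur

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def clean_femur():
    """Noise-free, offset-free, anteversion-free femur with exact truth."""
    return generate_femur(FemurSpec(nsa_true=126.0, anteversion=0.0, noise_sigma=0.0))


@pytest.fixture(scope="session")
def default_femur():
    """Default-condition femur (noise at half the CT voxel pitch)."""
    return generate_femur(FemurSpec(seed=1))


@pytest.fixture
def random_rotation():
    def make(seed=0):
        rng = np.random.default_rng(seed)
        return Rotation.random(random_state=rng).as_matrix()

    return make
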