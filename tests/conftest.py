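import numpy as np
import pytest

from cardiorecon.io import LabelVolume
from cardiorecon.phantom import PhantomParams, generate_phantom


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def random_volume(rng):
    """Small random 8-class label volume with anisotropic spacing."""
    voxels = rng.integers(0, 8, size=(6, 12, 16)).astype(np.int16)
    return LabelVolume(voxels, spacing=(2.0, 1.0, 1.0))


@pytest.fixture(scope="session")
def desk_params():
    return PhantomParams.desk_scale()


@pytest.fixture(scope="session")
def desk_phantom(desk_params):
    return generate_phantom(desk_params, np.random.default_rng(7))


@pytest.fixture(scope="session")
def tiny_params():
    """Very small phantom configuration for fast training smoke tests."""
    return PhantomParams(
        grid=(16, 32, 32), spacing=(2.0, 1.0, 1.0),
        chamber_scales={
            "LV": ((2.5, 3.5), (5.0, 6.0), (5.0, 6.0)),
            "RV": ((2.0, 3.0), (4.0, 5.0), (4.0, 5.0)),
            "LA": ((1.5, 2.0), (3.0, 4.0), (3.0, 4.0)),
            "RA": ((1.5, 2.0), (3.0, 4.0), (3.0, 4.0)),
        },
        myo_thickness=(2, 2), vessel_radius=(1.5, 1.8),
        pose_jitter_deg=5.0, pose_jitter_vox=1.0)


@pytest.fixture(scope="session")
def tiny_phantoms(tiny_params):
    rng = np.random.default_rng(42)
    return [generate_phantom(tiny_params, rng) for _ in range(4)]
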