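import numpy as np
import pytest

from relsens import RigidTransform, Volume
from relsens.phantom import PhantomSpec, make_phantom


@pytest.fixture
def rng():
    return np.random.default_rng(20220321)


def grid_volume(shape=(16, 16, 16), voxel_mm=2.0, data=None):
    aff = np.diag([voxel_mm] * 3 + [1.0])
    aff[:3, 3] = -(np.asarray(shape) - 1) / 2.0 * voxel_mm
    if data is None:
        data = np.zeros(shape)
    return Volume(data, aff)


def polynomial_bias(shape, amplitude=0.1):
    """Smooth harmonic log-bias field on a normalized [-1, 1]^3 grid."""
    idx = np.indices(shape).astype(float)
    w = [(idx[a] - (shape[a] - 1) / 2) / ((shape[a] - 1) / 2) for a in range(3)]
    return amplitude * (0.8 * w[0] - 0.6 * w[2] + 0.5 * w[1] * w[2] + 0.4 * w[0] * w[1])


MOTION_7T = RigidTransform((5.0, -7.0, 6.0), (4.0, -3.0, 6.0))


@pytest.fixture(scope="session")
def moving_phantom():
    """64^3 two-position session with 7T-like differential fields, SNR 50."""
    return make_phantom(
        PhantomSpec(shape=(64, 64, 64), motion=MOTION_7T, snr=50.0, seed=11)
    )


@pytest.fixture(scope="session")
def still_phantom():
    """Same anatomy and noise level without motion or differential fields."""
    return make_phantom(
        PhantomSpec(
            shape=(64, 64, 64),
            motion=RigidTransform(),
            snr=50.0,
            seed=11,
            receive_rel_range=(1.0, 1.0),
            transmit_rel_range=(1.0, 1.0),
        )
    )
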