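import warnings

import numpy as np
import pytest

from spionquant.synthetic import make_particle_mask
from spionquant.types import ParticleShapeParams, ProbeGrid

SPHERE_VOLUME = 4.0 / 3.0 * np.pi * 10.0**3  # r = 10 nm
SPHERE_SURFACE = 4.0 * np.pi * 10.0**2


@pytest.fixture(scope="session")
def probe_grid():
    """Default probe grid (0.91 nm^2 per point, 0.95 nm spacing)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return ProbeGrid()


@pytest.fixture(scope="session")
def sphere_particle():
    """Voxelized sphere, r = 10 nm at 0.5 nm voxels."""
    particle, _ = make_particle_mask(ParticleShapeParams(semi_axes=(10.0, 10.0, 10.0)), 0.5)
    return particle


@pytest.fixture(scope="session")
def oblate_particle():
    """Axis-aligned oblate spheroid (semi-axes 10, 10, 5 nm), lying flat
    (short axis along the beam), 0.5 nm voxels."""
    params = ParticleShapeParams(semi_axes=(10.0, 10.0, 5.0), euler_angles=(0.0, 90.0, 0.0))
    particle, _ = make_particle_mask(params, 0.5)
    return particle


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
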