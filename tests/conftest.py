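import numpy as np
import pytest

from rasta import (
    BeamParams,
    build_orientation_quadrature,
    build_polar_grid,
    simulate_imageset,
)
from rasta.io_cli import make_toy_molecule


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def beam():
    return BeamParams(wavelength=2.5, i0_eff=4e-3, kmax=3.0)


@pytest.fixture(scope="session")
def quad():
    return build_orientation_quadrature(18)


@pytest.fixture(scope="session")
def grid(beam):
    return build_polar_grid(16, 16, beam)


@pytest.fixture(scope="session")
def sim_grid(beam):
    return build_polar_grid(48, 48, beam)


@pytest.fixture(scope="session")
def toy4():
    return make_toy_molecule("random-cluster", 4, spacing=3.0, seed=3)


@pytest.fixture(scope="session")
def toy8():
    return make_toy_molecule("random-cluster", 8, spacing=3.0, seed=11)


@pytest.fixture(scope="session")
def images20(toy4, beam, sim_grid):
    return simulate_imageset(toy4, beam, 20, seed=4, sim_grid=sim_grid)
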