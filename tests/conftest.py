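import numpy as np
import pytest

from cgabm.microenvironment import build_disc_mesh
from cgabm.params import MechanicsParams, PhenotypeParams, SimulationConfig
from cgabm.population import Population, Q
from cgabm.simulator import ScenarioSpec


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def mech():
    return MechanicsParams()


@pytest.fixture
def phen_params():
    return PhenotypeParams()


@pytest.fixture(scope="session")
def small_mesh():
    return build_disc_mesh(600.0, 300, seed=0)


@pytest.fixture(scope="session")
def fine_mesh():
    return build_disc_mesh(600.0, 1200, seed=0)


def make_population(x, radius=9.953, phenotype=Q, m=1, **kw):
    x = np.atleast_2d(np.asarray(x, dtype=float))
    n = x.shape[0]
    r = np.broadcast_to(np.asarray(radius, float), (n,))
    return Population(x=x, radius=r, phenotype=phenotype, clock=0.0,
                      target_area=np.pi * r**2, m=m, **kw)


@pytest.fixture
def small_scenario():
    """A down-scaled well used throughout the fast tests."""
    return ScenarioSpec(name="test-5M", glucose0=0.5, seeding_density=5.0e4,
                        init_live_confluence=0.4, init_dead_confluence=0.05,
                        well_radius=400.0, horizon=24.0, sample_interval=3.0)


@pytest.fixture
def small_config():
    return SimulationConfig(m=16, mesh_target_elements=120)
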