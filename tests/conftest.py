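import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from coevogame import LatticeWorld, Neighborhood, SimulationParams, build_lattice

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture
def small_params() -> SimulationParams:
    return SimulationParams(
        b0=1.2, theta_th=0.5, L=4, sweeps=10, record_every=1,
        stationary_window=5, seed=7, replicates=2,
    )


@pytest.fixture
def small_world(small_params) -> LatticeWorld:
    return build_lattice(small_params, np.random.default_rng(small_params.seed))


def make_world(strategy, perception, neighborhood=Neighborhood.MOORE8) -> LatticeWorld:
    """World from explicit grids (allows odd L, unlike build_lattice)."""
    strategy = np.asarray(strategy, dtype=np.int8)
    perception = np.asarray(perception, dtype=np.float64)
    return LatticeWorld(strategy.shape[0], neighborhood, strategy, perception)
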