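import numpy as np
import pytest

from leksim import DynamicsConfig, initialize_random, periodic_neighbor_graph, run_to_convergence


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20_240_101)


@pytest.fixture(scope="session")
def converged_two_class():
    """A converged weighted configuration (N=120, phi=0.8, rho=0.3)."""
    pop = initialize_random(120, 0.8, 0.3, seed=42)
    final, report = run_to_convergence(pop, DynamicsConfig(msd_threshold=1e-12, max_steps=50_000))
    assert report.converged
    return final, report


@pytest.fixture(scope="session")
def converged_graph(converged_two_class):
    final, _ = converged_two_class
    return periodic_neighbor_graph(final.positions)
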