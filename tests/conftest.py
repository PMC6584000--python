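import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from plume_ed.decay import DecayModelSpec
from plume_ed.synthetic import SimulationConfig, simulate_sites


@pytest.fixture(scope="session")
def sites17():
    """Default monitoring geometry: 17 sites, 0.19-34.8 km, log-spaced."""
    return simulate_sites(17, 0.19, 34.8)


@pytest.fixture(scope="session")
def distances17(sites17):
    return sites17["distance_km"].to_numpy()


@pytest.fixture()
def small_config():
    """A scaled-down campaign for fast end-to-end tests."""
    return SimulationConfig(
        n_sites=8,
        n_days=140,
        baseline_days=42,
        colonies_per_site=12,
        massive_min_per_site=5,
        seed=0,
    )


@pytest.fixture()
def quick_spec():
    """Very short sampler profile for structural (non-accuracy) checks."""
    return DecayModelSpec.test_profile(n_burnin=200, n_iter=400, seed=0)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
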