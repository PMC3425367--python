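import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from augermc import EnergyModel, bundled_atom, bundled_scheme, make_toy_atom

settings.register_profile(
    "deterministic",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")

#: (n_subshells, rate_seed) pairs used across the MC/oracle comparisons
TOY_FIXTURES = [(3, 7), (3, 2), (4, 7), (4, 5), (5, 3)]


@pytest.fixture(scope="session")
def tc():
    table, rates = bundled_atom("Tc")
    return table


@pytest.fixture(scope="session")
def ru():
    table, rates = bundled_atom("Ru")
    return table


@pytest.fixture(scope="session")
def cd():
    table, rates = bundled_atom("Cd")
    return table


@pytest.fixture(scope="session")
def indium():
    table, rates = bundled_atom("In")
    return table


@pytest.fixture(scope="session")
def tc99m():
    return bundled_scheme("tc99m")


@pytest.fixture(scope="session")
def in111():
    return bundled_scheme("in111")


@pytest.fixture(scope="session")
def toy5():
    """Five-subshell toy atom with a neutral energy model."""
    table, rates = make_toy_atom(5, rate_seed=3)
    return table, rates, EnergyModel("neutral", table)


@pytest.fixture(scope="session")
def toy3():
    table, rates = make_toy_atom(3, rate_seed=7)
    return table, rates, EnergyModel("neutral", table)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
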