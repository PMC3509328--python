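import numpy as np
import pytest

from cfcsim.engine import ChainConditioner
from cfcsim.kinetics import RateConstants
from cfcsim.params import derived_defaults, table1_defaults


@pytest.fixture(scope="session")
def params():
    """Self-consistent chain parameter set from the standard derivation chain."""
    return derived_defaults()


@pytest.fixture(scope="session")
def published():
    """(ChainParams, RateConstants) as printed, with relaxed consistency."""
    return table1_defaults()


@pytest.fixture(scope="session")
def rates():
    return RateConstants()


@pytest.fixture(scope="session")
def conditioner(params):
    """Shared 700-site chain-state evaluator (engine's hot path)."""
    return ChainConditioner(params, 700)


@pytest.fixture
def rng():
    """Fresh deterministic generator per test (order-independent draws)."""
    return np.random.default_rng(2024)
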