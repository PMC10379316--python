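import numpy as np
import pytest

from carpfrost import (
    Indicator,
    anchor_table,
    carp_253K_fixture,
    default_carp_config,
)


@pytest.fixture(scope="session")
def fixture_253():
    return carp_253K_fixture()


@pytest.fixture(scope="session")
def anchors():
    return anchor_table()


@pytest.fixture(scope="session")
def carp_config():
    return default_carp_config(seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def indicator_order():
    return (Indicator.TBARS, Indicator.FFA, Indicator.SSP,
            Indicator.CA_ATPASE, Indicator.SH)
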