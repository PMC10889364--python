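import numpy as np
import pytest

from sceptic import AgentParams, BasisConfig, make_contingency


@pytest.fixture(scope="session")
def cfg():
    """Default basis: 24 elements over 4 s, 0.1-s bins, 50% adjacent overlap."""
    return BasisConfig()


@pytest.fixture(scope="session")
def default_agent():
    return AgentParams(alpha=0.1, beta=5.0, gamma=0.3)


@pytest.fixture(scope="session")
def iev():
    return make_contingency("IEV")


@pytest.fixture(scope="session")
def dev():
    return make_contingency("DEV")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
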