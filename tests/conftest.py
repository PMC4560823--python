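import numpy as np
import pytest

from contextrl import (
    ABSOLUTE,
    RELATIVE,
    AgentParams,
    simulate_agent,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def relative_params():
    return AgentParams.group_means(RELATIVE, "ll")


@pytest.fixture(scope="session")
def absolute_params():
    return AgentParams.group_means(ABSOLUTE, "ll")


@pytest.fixture(scope="session")
def small_dataset():
    """One simulated subject's full 384-trial table (RELATIVE generator)."""
    rng = np.random.default_rng(11)
    sim = simulate_agent(RELATIVE, AgentParams.group_means(RELATIVE, "ll"), rng)
    return sim.frame


@pytest.fixture(scope="session")
def small_dataset_absolute():
    rng = np.random.default_rng(12)
    sim = simulate_agent(ABSOLUTE, AgentParams.group_means(ABSOLUTE, "ll"), rng)
    return sim.frame
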