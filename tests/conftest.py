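import numpy as np
import pytest

from valueframe import (
    GroundTruth,
    ProspectParams,
    generate_stimulus_set,
    simulate_choices,
)


@pytest.fixture(scope="session")
def agent_params():
    return ProspectParams(alpha=0.8, gamma=0.7, beta=3.0)


@pytest.fixture(scope="session")
def small_trials(agent_params):
    """100 trials per type with simulated choices; shared across tests."""
    trials = generate_stimulus_set(n_per_type=100, seed=11)
    return simulate_choices(trials, agent_params, seed=12)


@pytest.fixture(scope="session")
def full_trials(agent_params):
    """A full-size session (324 trials per type)."""
    trials = generate_stimulus_set(n_per_type=324, seed=21)
    return simulate_choices(trials, agent_params, seed=22)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def null_truth():
    return GroundTruth(g_value=0.0, g_choice=0.0, seed=7)
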