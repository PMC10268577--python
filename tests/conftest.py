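import numpy as np
import pytest

from enforcegame import (
    PopulationState,
    alternative_parameters,
    baseline_parameters,
    build_strategy_set,
)


@pytest.fixture
def baseline():
    return baseline_parameters()


@pytest.fixture
def alternative():
    return alternative_parameters()


@pytest.fixture
def exact_regime(baseline):
    """Baseline parameters in the analytical regime (no mistakes, exact best reply)."""
    return baseline.replace(mu=0.0, v=0.0, eta=0.0, epsilon=0.0)


@pytest.fixture
def ce2():
    return build_strategy_set("CE2")


@pytest.fixture
def rng():
    return np.random.default_rng(20230606)


def state_of(strategy_set, **counts) -> PopulationState:
    return PopulationState.from_counts(strategy_set, counts)
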