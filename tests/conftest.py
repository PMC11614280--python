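import numpy as np
import pytest

from rewardbases.neural_analysis import ConditionTable
from rewardbases.synthetic_spikes import GeneratorConfig, generate


@pytest.fixture(scope="session")
def condition_table():
    return ConditionTable.default()


@pytest.fixture(scope="session")
def planted_dataset(condition_table):
    """Population of 19 neurons, 7 with a nonzero value-identity interaction."""
    return generate(GeneratorConfig.planted(seed=11), condition_table)


@pytest.fixture(scope="session")
def null_dataset(condition_table):
    """Population with no value-identity interaction anywhere."""
    return generate(GeneratorConfig.null(seed=12), condition_table)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
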