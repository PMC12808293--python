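import numpy as np
import pytest

from recatmem import (
    assign_segments,
    make_powerlaw_sequence,
    make_rule_plus_exception,
    make_uniform_sequence,
)


@pytest.fixture(scope="session")
def structure():
    return make_rule_plus_exception()


@pytest.fixture(scope="session")
def uniform_seq(structure):
    return make_uniform_sequence(structure, 44, 1)


@pytest.fixture(scope="session")
def powerlaw_seq(structure):
    return make_powerlaw_sequence(structure, seed=2)


@pytest.fixture(scope="session")
def sequential_assignment(uniform_seq):
    return assign_segments(uniform_seq, "sequential", 11)


@pytest.fixture(scope="session")
def powerlaw_assignment(powerlaw_seq):
    return assign_segments(powerlaw_seq, "power_law", 11)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
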