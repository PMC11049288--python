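import numpy as np
import pytest

from microhet import Observation, PeriodicCell, generate_ideal_gas


@pytest.fixture
def rng():
    return np.random.default_rng(20240409)


@pytest.fixture
def cubic_cell():
    return PeriodicCell.cubic(5000.0)


@pytest.fixture
def ideal_gas_config(cubic_cell):
    return generate_ideal_gas(512, cubic_cell, seed=7)


@pytest.fixture
def obs_all():
    return Observation("all")
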