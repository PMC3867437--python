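import numpy as np
import pytest

from coopbreed import ModelParams, ParamRanges, PopulationState


@pytest.fixture
def midpoint() -> ModelParams:
    """Centre of every hypothesized range, assortment off."""
    return ParamRanges.table_defaults().fix(r_kin=0.0, a_assort=0.0).midpoint()


@pytest.fixture
def table_ranges() -> ParamRanges:
    return ParamRanges.table_defaults()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture
def mixed_state() -> PopulationState:
    return PopulationState(x_cm=0.3, y_om=0.3, z_im=0.4, q_coal=0.5)
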