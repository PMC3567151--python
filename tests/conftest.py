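import numpy as np
import pytest

from decoysim.conflict_model import ModelParams
from decoysim.population import SimConfig


@pytest.fixture
def params() -> ModelParams:
    return ModelParams()


@pytest.fixture
def tiny_config() -> SimConfig:
    """A configuration small enough for sub-second runs."""
    return SimConfig(N=200, generations=400, window=200, n_replicates=2, seed=9)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
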