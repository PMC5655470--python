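import numpy as np
import pytest

from fracpop import ModelParams, SelectionFunction


@pytest.fixture
def figure_params() -> ModelParams:
    """Survival-regime parameter set used by the four-alpha figure suite."""
    return ModelParams(a=0.02, b=0.01, p=0.9, v=SelectionFunction.constant(0.01))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260920)
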