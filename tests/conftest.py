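import numpy as np
import pytest

from dogpopsim import InitialConditions, ParameterSet, initialize_population


@pytest.fixture
def params():
    return ParameterSet()


@pytest.fixture
def default_population(params):
    return initialize_population(InitialConditions(), params,
                                 rng=np.random.default_rng(12345))
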