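import numpy as np
import pytest

from crnbridge import build_example


@pytest.fixture
def death_net():
    return build_example("death", c=0.5)


@pytest.fixture
def gtt_net():
    return build_example("gtt", kappa1=100.0, kappa2=10.0, dM=25.0, dP=1.0)


@pytest.fixture
def enzyme_net():
    return build_example("enzyme", kappa=(5.0, 5.0, 3.0))


@pytest.fixture
def rng():
    return np.random.default_rng(0)
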