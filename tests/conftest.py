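import numpy as np
import pytest

from forcejump import TetherGeometry


@pytest.fixture(scope="session")
def geom55():
    return TetherGeometry(bridge_nt=55)


@pytest.fixture(scope="session")
def geom70():
    return TetherGeometry(bridge_nt=70)


@pytest.fixture
def rng():
    return np.random.default_rng(20230901)
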