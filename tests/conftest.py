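import numpy as np
import pytest

from megfc.preprocessing import BandSpec


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def alpha_band():
    return BandSpec("alpha", 8.0, 14.0)


@pytest.fixture(scope="session")
def node_table():
    from megfc.io import load_node_table

    return load_node_table()
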