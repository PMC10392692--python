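import numpy as np
import pytest

from asynsalt.sequences import load_asyn, load_asyn_ctail


@pytest.fixture(scope="session")
def asyn():
    return load_asyn()


@pytest.fixture(scope="session")
def ctail():
    return load_asyn_ctail()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
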