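import numpy as np
import pytest

from lipoglo.presets import load_presets


@pytest.fixture(scope="session")
def presets():
    return load_presets()


@pytest.fixture(scope="session")
def wt(presets):
    return presets["WT"]


@pytest.fixture(scope="session")
def apoc2(presets):
    return presets["apoc2_mut"]


@pytest.fixture(scope="session")
def mtp(presets):
    return presets["mtp_mut"]


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
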