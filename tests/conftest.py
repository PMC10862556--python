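import numpy as np
import pytest

from dustbiome.io import campaign_element_panel, load_campaign_table
from dustbiome.simulate import gen_profiles


@pytest.fixture(scope="session")
def campaign_table():
    return load_campaign_table()


@pytest.fixture(scope="session")
def campaign_panel():
    return campaign_element_panel()


@pytest.fixture(scope="session")
def profiles7():
    return gen_profiles(7, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
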