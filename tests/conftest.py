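import numpy as np
import pytest

from adiponet import synthetic_data as sd


@pytest.fixture(scope="session")
def small_config() -> sd.SimConfig:
    return sd.SimConfig(seed=11, n_mrna=400, n_lnc=40)


@pytest.fixture(scope="session")
def small_truth(small_config):
    return sd.build_truth(small_config)


@pytest.fixture(scope="session")
def small_study(small_config):
    return sd.generate_study(small_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
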