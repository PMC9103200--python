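import numpy as np
import pytest

from tempsep import ModelConfig, build_connectivity


@pytest.fixture
def cfg():
    return ModelConfig()


@pytest.fixture
def single_r_cfg():
    return ModelConfig(expansion_factor=1 / 8)


@pytest.fixture
def dense_conn(single_r_cfg):
    return build_connectivity(single_r_cfg, "dense", np.random.default_rng(3))
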