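import numpy as np
import pytest

from bgspike.network import NetworkConfig, build_network
from bgspike.plasticity import PlasticityTraces


@pytest.fixture(scope="session")
def desk_config():
    return NetworkConfig.desk_scale()


@pytest.fixture(scope="session")
def desk_network(desk_config):
    """One shared desk-scale network (read-only structural checks)."""
    return build_network(desk_config, seed=123)


@pytest.fixture(scope="session")
def mini_config():
    return NetworkConfig.mini()


@pytest.fixture
def traces():
    return PlasticityTraces()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
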