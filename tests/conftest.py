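import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from sccnet import (
    RateConstants,
    find_scc,
    kinetic_couplings,
    merge_couplings,
    structural_couplings,
)
from sccnet.examples import chain_network, demo_network, demo_theta, diamond_network

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def chain_net():
    return chain_network()


@pytest.fixture
def chain_theta():
    return RateConstants({"R1": 2.0, "R2": 1.0, "R3": 4.0})


@pytest.fixture
def demo_net():
    return demo_network()


@pytest.fixture
def diamond_net():
    return diamond_network()


@pytest.fixture
def chain_cr(chain_net):
    return merge_couplings(structural_couplings(chain_net), kinetic_couplings(chain_net))


@pytest.fixture
def chain_certs(chain_net, chain_cr):
    return find_scc(chain_net, chain_cr)


@pytest.fixture
def demo_cr(demo_net):
    return merge_couplings(structural_couplings(demo_net), kinetic_couplings(demo_net))


@pytest.fixture
def demo_certs(demo_net, demo_cr):
    return find_scc(demo_net, demo_cr)


@pytest.fixture
def demo_th():
    return demo_theta()
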