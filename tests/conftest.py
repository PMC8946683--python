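import pytest

from g1snet.io import loads_bnet
from g1snet.model import build_nsclc_model


@pytest.fixture(scope="session")
def toggle():
    """Two-node toggle switch (mutual inhibition): bistable."""
    return loads_bnet("targets, factors\nA, !B\nB, !A\n", "toggle")


@pytest.fixture(scope="session")
def mutual_activation():
    """Two-node mutual activation: bistable between all-off and all-on."""
    return loads_bnet("targets, factors\nA, B\nB, A\n", "mutual_act")


@pytest.fixture(scope="session")
def negative_loop():
    """Two-node negative feedback loop: a single cyclic attractor."""
    return loads_bnet("targets, factors\nA, !B\nB, A\n", "negloop")


@pytest.fixture(scope="session")
def bundle():
    """The NSCLC G1/S checkpoint model bundle (shared across tests)."""
    return build_nsclc_model()
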