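import pytest

from mfptnet import MfptQuery, parse_network
from mfptnet import generators as G

SQUARE_BASIC = "\n".join(
    ["NODE 0 1 3", "NODE 1 0 2", "NODE 2 1 3", "NODE 3 2 0"]
) + "\n"

# 3-node path: 0 - 1 - 2, uniform exits, unit times
PATH3_BASIC = "NODE 0 1\nNODE 1 0 2\nNODE 2 1\n"


@pytest.fixture
def square_net():
    net, _ = parse_network(SQUARE_BASIC, "basic")
    return net


@pytest.fixture
def path3_net():
    net, _ = parse_network(PATH3_BASIC, "basic")
    return net


@pytest.fixture
def random_net_factory():
    """Factory for the small random stress-test networks."""

    def make(n, seed, **kw):
        return G.random_network(n, seed=seed, **kw)

    return make


def adjacent_query(net):
    return MfptQuery(0, {1})
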