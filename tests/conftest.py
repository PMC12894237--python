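import numpy as np
import pytest

import isingnet as ig


def make_net(W, tau, communities=None, ids=None):
    W = np.asarray(W, dtype=float)
    p = W.shape[0]
    ids = ids or [f"V{i + 1}" for i in range(p)]
    communities = communities or ["knowledge"] * (p - p // 2) + ["stigma"] * (p // 2)
    return ig.IsingNetwork(W, np.asarray(tau, dtype=float), ids, communities)


def chain_network(p=6, beta=1.5, tau=-1.0):
    W = np.zeros((p, p))
    for i in range(p - 1):
        W[i, i + 1] = W[i + 1, i] = beta
    return make_net(W, np.full(p, tau))


@pytest.fixture(scope="session")
def chain6_net():
    return chain_network()


@pytest.fixture(scope="session")
def chain6_data(chain6_net):
    """n=2000 sample from the 6-node chain; reused by estimation tests."""
    return ig.gibbs_sample(chain6_net, ig.SimulationConfig(2000, 300, 11))


@pytest.fixture(scope="session")
def triangle_net():
    """3-node toy with mixed-sign edges for hand-arithmetic checks."""
    W = [[0.0, 0.5, -0.2], [0.5, 0.0, 0.0], [-0.2, 0.0, 0.0]]
    return make_net(W, [0.0, 0.0, 0.0], communities=["a", "b", "b"])
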