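import numpy as np
import pytest

from netfilters.netcore import Network, NodeValues, Partition


@pytest.fixture
def path_graph():
    """a - b - c path."""
    return Network.from_edges([("a", "b"), ("b", "c")])


@pytest.fixture
def star_graph():
    """Hub h with leaves l1..l3."""
    return Network.from_edges([("h", "l1"), ("h", "l2"), ("h", "l3")])


@pytest.fixture
def triangle():
    return Network.from_edges([("a", "b"), ("b", "c"), ("a", "c")])


@pytest.fixture
def two_cliques_bridge():
    """Two 4-cliques joined by a single bridge edge a3 - b0."""
    edges = []
    for grp in ("a", "b"):
        nodes = [f"{grp}{i}" for i in range(4)]
        edges += [(u, v) for i, u in enumerate(nodes) for v in nodes[i + 1 :]]
    edges.append(("a3", "b0"))
    return Network.from_edges(edges)


def random_graph(n: int, p: float, seed: int) -> Network:
    """Erdos-Renyi helper for oracle comparisons (guaranteed >= 1 edge)."""
    rng = np.random.default_rng(seed)
    nodes = [f"n{i:03d}" for i in range(n)]
    edges = [
        (nodes[i], nodes[j])
        for i in range(n)
        for j in range(i + 1, n)
        if rng.random() < p
    ]
    if not edges:
        edges = [(nodes[0], nodes[1])]
    return Network.from_edges(edges, nodes=nodes)


def random_values(net: Network, seed: int, mu: float = 0.0, sd: float = 1.0) -> NodeValues:
    rng = np.random.default_rng(seed)
    return NodeValues.from_array(net, rng.normal(mu, sd, net.n_nodes))
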