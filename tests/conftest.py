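import networkx as nx
import numpy as np
import pytest

from emopinion import SocialNetwork


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_network(edges, strengths=None, n=None):
    """Small explicit network for hand-checked scenarios."""
    g = nx.Graph()
    nodes = n if n is not None else (max(max(e) for e in edges) + 1)
    g.add_nodes_from(range(nodes))
    for idx, (u, v) in enumerate(edges):
        s = 1.0 if strengths is None else strengths[idx]
        g.add_edge(u, v, strength=float(s))
    return SocialNetwork(g)


@pytest.fixture
def star_network():
    """Node 0 connected to 1..3, unit strengths."""
    return make_network([(0, 1), (0, 2), (0, 3)])
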