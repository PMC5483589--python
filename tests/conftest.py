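import networkx as nx
import numpy as np
import pytest

from netsig.graph_core import SignalingNetwork


@pytest.fixture
def toy_network() -> SignalingNetwork:
    """Small signed network: a triangle plus a pendant and an isolated node."""
    return SignalingNetwork.from_edges(
        [
            ("A", "activation", "B"),
            ("B", "activation", "C"),
            ("C", "inhibition", "A"),
            ("C", "activation", "D"),
        ],
        extra_nodes=["E"],
        name="toy",
    )


def random_connected_graph(rng: np.random.Generator, n: int, p: float = 0.3) -> nx.Graph:
    """Erdős–Rényi graph resampled until connected (node names are letters)."""
    names = [chr(ord("A") + i) for i in range(n)]
    while True:
        g = nx.Graph()
        g.add_nodes_from(names)
        for i in range(n):
            for j in range(i + 1, n):
                if rng.random() < p:
                    g.add_edge(names[i], names[j])
        if nx.is_connected(g):
            return g
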