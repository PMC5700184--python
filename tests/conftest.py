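import numpy as np
import pytest
from hypothesis import settings

from modcart.core import BrainGraph, NodeSet

settings.register_profile("deterministic", derandomize=True, max_examples=60)
settings.load_profile("deterministic")


def graph_from_adjacency(adj, binary=None) -> BrainGraph:
    """Wrap a raw adjacency matrix in a BrainGraph with dummy coordinates."""
    adj = np.asarray(adj, dtype=float)
    n = adj.shape[0]
    coords = np.column_stack(
        [np.arange(n, dtype=float), np.zeros(n), np.zeros(n)]
    )
    if binary is None:
        binary = bool(np.all(np.isin(adj, (0.0, 1.0))))
    return BrainGraph(nodes=NodeSet(coords=coords), adjacency=adj, binary=binary)


def random_binary_graph(rng: np.random.Generator, n: int, p: float) -> BrainGraph:
    """Erdos-Renyi binary graph, guaranteed to contain at least one edge."""
    while True:
        upper = np.triu(rng.random((n, n)) < p, 1).astype(float)
        adj = upper + upper.T
        if adj.sum() > 0:
            return graph_from_adjacency(adj)


@pytest.fixture
def two_cliques() -> tuple[BrainGraph, np.ndarray]:
    """Two disjoint 10-cliques with their natural labels."""
    adj = np.zeros((20, 20))
    adj[:10, :10] = 1.0
    adj[10:, 10:] = 1.0
    np.fill_diagonal(adj, 0.0)
    labels = np.repeat([0, 1], 10)
    return graph_from_adjacency(adj), labels


@pytest.fixture
def two_triangles() -> tuple[BrainGraph, np.ndarray]:
    adj = np.zeros((6, 6))
    for a, b in [(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)]:
        adj[a, b] = adj[b, a] = 1.0
    return graph_from_adjacency(adj), np.repeat([0, 1], 3)
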