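import numpy as np
import pytest

from connectotier.graph_core import BinaryGraph, ConnectomeMatrix


def labels_for(n: int) -> tuple[str, ...]:
    return tuple(f"r{i:02d}" for i in range(n))


def graph_from_edges(n: int, edges) -> BinaryGraph:
    adj = np.zeros((n, n), dtype=int)
    for i, j in edges:
        adj[i, j] = adj[j, i] = 1
    return BinaryGraph(adjacency=adj, labels=labels_for(n))


def random_binary_graph(n: int, p: float, rng: np.random.Generator) -> BinaryGraph:
    upper = rng.random((n, n)) < p
    adj = np.triu(upper, 1).astype(int)
    return BinaryGraph(adjacency=adj + adj.T, labels=labels_for(n))


def random_weighted_connectome(
    n: int, density: float, rng: np.random.Generator
) -> ConnectomeMatrix:
    w = rng.random((n, n))
    mask = np.triu(rng.random((n, n)) < density, 1)
    mat = np.where(mask, w, 0.0)
    mat = np.triu(mat, 1)
    return ConnectomeMatrix(weights=mat + mat.T, labels=labels_for(n))


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def k4():
    return graph_from_edges(4, [(i, j) for i in range(4) for j in range(i + 1, 4)])


@pytest.fixture
def star5():
    return graph_from_edges(5, [(0, i) for i in range(1, 5)])


@pytest.fixture
def worked_graph():
    """Edges a-b, b-c, c-d, d-e, c-e: hierarchical complexity exactly 1/6."""
    return graph_from_edges(5, [(0, 1), (1, 2), (2, 3), (3, 4), (2, 4)])
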