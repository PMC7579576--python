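import itertools

import numpy as np
import pytest

from dmnqol.connectivity import BrainGraph, ConnectivityMatrix


def graph_from_edges(n, edges, labels=None):
    adj = np.zeros((n, n), dtype=np.int8)
    for u, v in edges:
        adj[u, v] = adj[v, u] = 1
    return BrainGraph(adjacency=adj, labels=labels or [])


def complete_graph(n):
    return graph_from_edges(n, itertools.combinations(range(n), 2))


def random_graph(n, p, seed):
    """Erdos-Renyi G(n, p) with a fixed seed."""
    rng = np.random.default_rng(seed)
    adj = np.zeros((n, n), dtype=np.int8)
    iu, ju = np.triu_indices(n, 1)
    mask = rng.random(len(iu)) < p
    adj[iu[mask], ju[mask]] = 1
    return BrainGraph(adjacency=adj | adj.T)


def block_connectivity(sizes=(6, 6, 12), r_within=0.9, r_between=0.0):
    """Exact block correlation matrix (no sampling noise)."""
    n = sum(sizes)
    vals = np.full((n, n), r_between)
    start = 0
    for s in sizes:
        vals[start:start + s, start:start + s] = r_within
        start += s
    np.fill_diagonal(vals, 1.0)
    return ConnectivityMatrix(values=vals)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
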