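"""Shared fixtures and the independent brute-force efficiency oracle.

The oracle computes all-pairs geodesic distances by Floyd–Warshall (a
different algorithm family than the package's BFS kernels) and evaluates
every efficiency measure directly from its defining sum, so implementation
and oracle share no code path.
"""

import numpy as np
import pytest

import thicknet as tn


# ---------------------------------------------------------------------------
# brute-force oracle

def oracle_distances(adj):
    """Floyd–Warshall all-pairs shortest paths on a 0/1 adjacency matrix."""
    n = adj.shape[0]
    d = np.full((n, n), np.inf)
    np.fill_diagonal(d, 0.0)
    d[adj > 0] = 1.0
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i, k] + d[k, j] < d[i, j]:
                    d[i, j] = d[i, k] + d[k, j]
    return d


def oracle_global_efficiency(adj):
    n = adj.shape[0]
    d = oracle_distances(adj)
    total = 0.0
    for i in range(n):
        for j in range(n):
            if i != j and np.isfinite(d[i, j]):
                total += 1.0 / d[i, j]
    return total / (n * (n - 1))


def oracle_nodal_efficiency(adj, i):
    n = adj.shape[0]
    d = oracle_distances(adj)
    total = 0.0
    for j in range(n):
        if j != i and np.isfinite(d[i, j]):
            total += 1.0 / d[i, j]
    return total / (n - 1)


def oracle_neighboring_efficiency(adj, i, convention="paper"):
    nbrs = [j for j in range(adj.shape[0]) if adj[i, j]]
    if len(nbrs) <= 1:
        return 0.0
    nodes = ([i] + nbrs) if convention == "paper" else nbrs
    sub = adj[np.ix_(nodes, nodes)]
    return oracle_global_efficiency(sub)


def oracle_local_efficiency(adj, convention="paper"):
    vals = [
        oracle_neighboring_efficiency(adj, i, convention)
        for i in range(adj.shape[0])
    ]
    return float(np.mean(vals))


def random_adjacency(rng, n, p):
    """Symmetric 0/1 adjacency with edge probability p, zero diagonal."""
    upper = np.triu((rng.random((n, n)) < p).astype(np.int8), 1)
    return upper + upper.T


# ---------------------------------------------------------------------------
# fixtures

@pytest.fixture(scope="session")
def small_cohort():
    """A 12-ROI, 10+10-subject cohort with one correlated block."""
    spec = tn.CohortSpec(
        n_group1=10, n_group2=10, n_rois=12, seed=42,
        blocks_group1=((tuple(range(6)), 0.5),),
        blocks_group2=((tuple(range(6)), 0.5),),
    )
    return tn.generate_cohort(spec)


@pytest.fixture(scope="session")
def small_grid():
    return tn.CostGrid.from_range(0.10, 0.40, 0.10)
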