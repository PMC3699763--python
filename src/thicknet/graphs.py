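"""Binary network construction: cost thresholding and null models.

Correlation matrices are binarized so that the resulting unweighted,
undirected graph has a prescribed *rewiring cost* (edge density)
``c = K / (N(N-1)/2)``: the K node pairs with the largest positive
correlations become edges.  Anti-correlations are never eligible as edges.
Cost-matched benchmark graphs come in two flavours: uniform random graphs
with exactly K edges, and deterministic 1-D ring lattices.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Sequence

import numpy as np

from .errors import DataError, SpecError

if TYPE_CHECKING:  # pragma: no cover
    from .covariance import CorrelationNetwork

__all__ = [
    "BinaryNetwork",
    "CostGrid",
    "binarize_at_cost",
    "build_cost_profile",
    "random_network",
    "lattice_network",
]

logger = logging.getLogger(__name__)


@dataclass
class BinaryNetwork:
    """Unweighted undirected graph as a symmetric 0/1 adjacency matrix.

    ``cost_nominal`` is the requested density; the achieved ``cost`` can be
    lower when too few positive correlations exist.
    """

    adjacency: np.ndarray
    group: str | None = None
    cost_nominal: float | None = None

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise DataError(f"adjacency must be square, got shape {a.shape}")
        if not np.array_equal(a, a.T):
            raise DataError("adjacency must be symmetric")
        if np.diagonal(a).any():
            raise DataError("adjacency diagonal must be zero (no self-loops)")
        if not np.isin(a, (0, 1)).all():
            raise DataError("adjacency entries must be 0 or 1")
        self.adjacency = a.astype(np.int8)

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2

    @property
    def cost(self) -> float:
        """Achieved cost 2K / (N(N-1))."""
        n = self.n_nodes
        if n < 2:
            return 0.0
        return 2.0 * self.n_edges / (n * (n - 1))

    def degrees(self) -> np.ndarray:
        return self.adjacency.sum(axis=0).astype(int)

    def edge_list(self) -> list[tuple[int, int]]:
        i, j = np.nonzero(np.triu(self.adjacency, 1))
        return list(zip(i.tolist(), j.tolist()))


@dataclass(frozen=True)
class CostGrid:
    """Strictly increasing grid of cost values in (0, 1)."""

    costs: tuple[float, ...]

    def __post_init__(self) -> None:
        c = np.asarray(self.costs, dtype=float)
        object.__setattr__(self, "costs", tuple(c.tolist()))
        if c.size == 0:
            raise SpecError("cost grid is empty")
        if (c <= 0).any() or (c >= 1).any():
            raise SpecError("all costs must lie strictly in (0, 1)")
        if not (np.diff(c) > 0).all():
            raise SpecError("costs must be strictly increasing")

    def __len__(self) -> int:
        return len(self.costs)

    def __iter__(self):
        return iter(self.costs)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.costs, dtype=float)

    @classmethod
    def from_range(cls, cost_min: float, cost_max: float, cost_step: float) -> "CostGrid":
        if cost_step <= 0:
            raise SpecError("cost_step must be positive")
        n = int(round((cost_max - cost_min) / cost_step))
        costs = np.round(cost_min + cost_step * np.arange(n + 1), 10)
        costs = costs[costs <= cost_max + 1e-12]
        return cls(tuple(costs.tolist()))

    @classmethod
    def default(cls) -> "CostGrid":
        """The standard grid: 0.01 to 0.50 in steps of 0.01 (50 costs)."""
        return cls.from_range(0.01, 0.50, 0.01)


def edge_count_for_cost(n_nodes: int, cost: float) -> int:
    """Target edge count K = round(c · N(N-1)/2), half away from zero."""
    m = n_nodes * (n_nodes - 1) // 2
    return int(np.floor(cost * m + 0.5))


def _ranked_positive_pairs(r: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Upper-triangular pairs with r > 0, sorted by descending r.

    Ties break in ascending (row, column) lexicographic order so the edge
    selection is deterministic across runs and platforms.
    """
    n = r.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    vals = r[iu, ju]
    pos = vals > 0
    iu, ju, vals = iu[pos], ju[pos], vals[pos]
    order = np.lexsort((ju, iu, -vals))
    return iu[order], ju[order]


def _adjacency_from_pairs(n: int, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
    a = np.zeros((n, n), dtype=np.int8)
    a[rows, cols] = 1
    a[cols, rows] = 1
    return a


def binarize_at_cost(net: "CorrelationNetwork", cost: float) -> BinaryNetwork:
    """Threshold a correlation matrix to a binary graph of the given cost.

    The ``K = round(cost · N(N-1)/2)`` largest positive correlations become
    edges.  Negative and zero correlations are never eligible; if fewer than
    K positive entries exist, all of them become edges and the achieved cost
    is lower than requested (logged as a warning).
    """
    if not 0 < cost < 1:
        raise SpecError(f"cost must lie in (0, 1), got {cost}")
    r = np.asarray(net.R, dtype=float)
    n = r.shape[0]
    k = edge_count_for_cost(n, cost)
    rows, cols = _ranked_positive_pairs(r)
    if len(rows) < k:
        logger.warning(
            "only %d positive correlations available for %d requested edges "
            "at cost %.3f; achieved cost will be lower",
            len(rows), k, cost,
        )
        k = len(rows)
    adj = _adjacency_from_pairs(n, rows[:k], cols[:k])
    return BinaryNetwork(adj, group=getattr(net, "group", None), cost_nominal=cost)


def build_cost_profile(net: "CorrelationNetwork", grid: CostGrid) -> list[BinaryNetwork]:
    """One binary network per grid cost, with nested (filtered) edge sets.

    The positive pairs are ranked once, so the edge set at a lower cost is
    by construction a subset of the edge set at any higher cost.
    """
    r = np.asarray(net.R, dtype=float)
    n = r.shape[0]
    rows, cols = _ranked_positive_pairs(r)
    nets = []
    for cost in grid:
        k = edge_count_for_cost(n, cost)
        if len(rows) < k:
            logger.warning(
                "only %d positive correlations for %d requested edges at cost %.3f",
                len(rows), k, cost,
            )
            k = len(rows)
        adj = _adjacency_from_pairs(n, rows[:k], cols[:k])
        nets.append(BinaryNetwork(adj, group=getattr(net, "group", None), cost_nominal=cost))
    return nets


def cost_profile_adjacencies(r: np.ndarray, costs: Sequence[float]) -> list[np.ndarray]:
    """Array-level fast path of :func:`build_cost_profile` (no validation).

    Used by the permutation engine where the BinaryNetwork wrapper overhead
    matters; the selection rule is identical.
    """
    n = r.shape[0]
    rows, cols = _ranked_positive_pairs(r)
    out = []
    for cost in costs:
        k = min(edge_count_for_cost(n, cost), len(rows))
        out.append(_adjacency_from_pairs(n, rows[:k], cols[:k]))
    return out


def random_network(n: int, k: int, seed=None) -> BinaryNetwork:
    """Uniform random graph with exactly ``k`` edges on ``n`` nodes.

    Edges are sampled uniformly without replacement from all unordered node
    pairs.  ``seed`` may be an int or a ``numpy.random.Generator``.
    """
    m = n * (n - 1) // 2
    if not 0 <= k <= m:
        raise SpecError(f"edge count {k} out of range [0, {m}] for {n} nodes")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    iu, ju = np.triu_indices(n, k=1)
    chosen = rng.choice(m, size=k, replace=False)
    adj = _adjacency_from_pairs(n, iu[chosen], ju[chosen])
    return BinaryNetwork(adj, group="random", cost_nominal=(k / m if m else None))


def _ring_edge_sequence(n: int):
    """Yield ring-lattice edges: all pairs at ring distance 1, then 2, ...

    Within one ring distance, edges appear in ascending node order starting
    from node 0, which defines how a partial final ring is filled.
    """
    for d in range(1, n // 2 + 1):
        limit = n if 2 * d != n else n // 2  # distance n/2 pairs each appear once
        for i in range(limit):
            yield i, (i + d) % n


def lattice_network(n: int, k: int) -> BinaryNetwork:
    """Deterministic 1-D ring lattice with exactly ``k`` edges.

    Rings of increasing distance are added in full; the final, partial ring
    is filled in ascending node order until exactly ``k`` edges are present.
    """
    m = n * (n - 1) // 2
    if not 0 <= k <= m:
        raise SpecError(f"edge count {k} out of range [0, {m}] for {n} nodes")
    adj = np.zeros((n, n), dtype=np.int8)
    count = 0
    for i, j in _ring_edge_sequence(n):
        if count == k:
            break
        adj[i, j] = adj[j, i] = 1
        count += 1
    return BinaryNetwork(adj, group="lattice", cost_nominal=(k / m if m else None))
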