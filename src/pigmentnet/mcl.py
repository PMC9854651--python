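"""Markov Cluster algorithm (MCL) on score-weighted networks.

MCL simulates flow on a graph by alternating two operations on a
column-stochastic transition matrix: *expansion* (matrix squaring, which
spreads flow along longer walks) and *inflation* (entrywise power followed
by column renormalization, which sharpens strong flows and prunes weak
ones). The process converges to a doubly idempotent matrix whose attractor
rows define the clusters. The inflation exponent controls granularity:
larger inflation yields more, smaller clusters.

This is a deliberate from-scratch dense implementation sized for networks
of a few hundred nodes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .io import NetworkClass, PPINetwork

logger = logging.getLogger(__name__)


@dataclass
class TransitionMatrix:
    """Column-stochastic matrix over a fixed node ordering."""

    matrix: np.ndarray
    node_order: tuple[str, ...]

    def __post_init__(self) -> None:
        n = len(self.node_order)
        if self.matrix.shape != (n, n):
            raise ConfigurationError("matrix shape does not match node order")
        if (self.matrix < 0).any():
            raise ConfigurationError("transition matrix has negative entries")
        colsums = self.matrix.sum(axis=0)
        if not np.allclose(colsums, 1.0, atol=1e-9):
            raise ConfigurationError("transition matrix columns do not sum to 1")


def build_transition_matrix(
    network: PPINetwork, self_loop: str | float = "max"
) -> TransitionMatrix:
    """Build the column-stochastic matrix of a score-weighted network.

    Adjacency entries are edge scores. Each node receives a self-loop
    before normalization — by default of weight equal to its maximum
    incident edge weight (the common MCL choice, which damps period-2
    oscillations); pass a float for a fixed weight. Isolated nodes get a
    unit self-loop so every column is stochastic.
    """
    if network.n_nodes == 0:
        raise ConfigurationError("cannot build a transition matrix for an empty network")
    order = tuple(sorted(network.graph.nodes))
    idx = {n: i for i, n in enumerate(order)}
    n = len(order)
    a = np.zeros((n, n), dtype=float)
    for u, v, d in network.graph.edges(data=True):
        w = float(d.get("score", 1.0))
        a[idx[u], idx[v]] = w
        a[idx[v], idx[u]] = w
    if self_loop == "max":
        loops = a.max(axis=0)
        loops[loops == 0.0] = 1.0
    else:
        loops = np.full(n, float(self_loop))
    np.fill_diagonal(a, loops)
    a /= a.sum(axis=0, keepdims=True)
    return TransitionMatrix(matrix=a, node_order=order)


@dataclass
class ClusterAssignment:
    """A partition of the network nodes, sorted by decreasing cluster size."""

    clusters: tuple[frozenset[str], ...]
    converged: bool = True
    n_iterations: int = 0

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for c in self.clusters:
            if seen & c:
                raise ConfigurationError("clusters overlap; not a partition")
            seen |= c

    @property
    def nodes(self) -> frozenset[str]:
        return frozenset().union(*self.clusters) if self.clusters else frozenset()

    def membership(self) -> dict[str, int]:
        """Node -> 1-based cluster id (clusters numbered by decreasing size)."""
        return {n: i for i, c in enumerate(self.clusters, start=1) for n in c}


def _normalize_columns(m: np.ndarray) -> np.ndarray:
    colsums = m.sum(axis=0, keepdims=True)
    colsums[colsums == 0.0] = 1.0
    return m / colsums


def _prune(m: np.ndarray, threshold: float) -> np.ndarray:
    """Zero entries below ``threshold`` but never a column's maximum."""
    keep = m >= threshold
    keep[m.argmax(axis=0), np.arange(m.shape[1])] = True
    return np.where(keep, m, 0.0)


def _clusters_from_limit(
    m: np.ndarray, order: Sequence[str], eps: float
) -> tuple[frozenset[str], ...]:
    """Read clusters from the (near-)idempotent limit matrix.

    Attractors are nodes with positive diagonal mass; each attractor row's
    support is a cluster; attractor systems with overlapping support are
    merged so the result is a partition. Nodes outside every attractor
    support (possible only before full convergence) become singletons.
    """
    n = len(order)
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x: int, y: int) -> None:
        rx, ry = find(x), find(y)
        if rx != ry:
            parent[ry] = rx

    attractors = [i for i in range(n) if m[i, i] > eps]
    assigned = np.zeros(n, dtype=bool)
    for i in attractors:
        support = np.flatnonzero(m[i] > eps)
        assigned[support] = True
        assigned[i] = True
        for j in support:
            union(i, j)
    groups: dict[int, set[str]] = {}
    for i in range(n):
        if assigned[i]:
            groups.setdefault(find(i), set()).add(order[i])
        else:
            groups[-i - 1] = {order[i]}  # unattached node -> singleton
    clusters = sorted(
        (frozenset(g) for g in groups.values()),
        key=lambda c: (-len(c), min(c)),
    )
    return tuple(clusters)


def mcl(
    tm: TransitionMatrix,
    inflation: float = 2.5,
    prune_threshold: float = 1e-5,
    max_iter: int = 200,
    tol: float = 1e-6,
) -> ClusterAssignment:
    """Run MCL and return the node partition.

    Iterates expansion (matrix squaring), inflation (entrywise power
    ``inflation`` then column renormalization), and pruning of entries
    below ``prune_threshold`` (protecting each column's maximum) followed
    by renormalization, until the largest entrywise change falls below
    ``tol`` or ``max_iter`` is reached. Non-convergence yields a result
    flagged ``converged=False``.
    """
    if inflation <= 1.0:
        raise ConfigurationError("inflation must be > 1")
    m = tm.matrix.copy()
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        prev = m
        m = m @ m
        m = np.power(m, inflation)
        m = _normalize_columns(m)
        m = _prune(m, prune_threshold)
        m = _normalize_columns(m)
        if np.max(np.abs(m - prev)) < tol:
            converged = True
            break
    if not converged:
        logger.warning("MCL did not converge within %d iterations", max_iter)
    clusters = _clusters_from_limit(m, tm.node_order, eps=prune_threshold)
    return ClusterAssignment(clusters=clusters, converged=converged, n_iterations=it)


def cluster_network(
    network: PPINetwork,
    inflation: float = 2.5,
    self_loop: str | float = "max",
    prune_threshold: float = 1e-5,
    max_iter: int = 200,
    tol: float = 1e-6,
) -> ClusterAssignment:
    """Convenience wrapper: transition matrix + MCL on a PPI network."""
    tm = build_transition_matrix(network, self_loop=self_loop)
    return mcl(tm, inflation=inflation, prune_threshold=prune_threshold,
               max_iter=max_iter, tol=tol)


def cluster_summary(
    assignment: ClusterAssignment,
    classes: Mapping[str, NetworkClass | str] | None = None,
) -> pd.DataFrame:
    """Per-cluster table: id (1..k by decreasing size), size, class composition.

    Class composition columns give the fraction of cluster members in each
    network class present anywhere in the assignment.
    """
    classes = {k: (v.value if isinstance(v, NetworkClass) else str(v))
               for k, v in (classes or {}).items()}
    rows = []
    all_classes = sorted({classes.get(n, NetworkClass.NONE.value)
                          for n in assignment.nodes}) if assignment.nodes else []
    for cid, cluster in enumerate(assignment.clusters, start=1):
        row: dict = {"cluster_id": cid, "size": len(cluster),
                     "members": ";".join(sorted(cluster))}
        for cls in all_classes:
            row[f"frac_{cls}"] = (
                sum(1 for n in cluster if classes.get(n, NetworkClass.NONE.value) == cls)
                / len(cluster)
            )
        rows.append(row)
    return pd.DataFrame(rows)
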