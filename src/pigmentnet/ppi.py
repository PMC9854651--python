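"""Confidence-filtered PPI networks: construction, expansion, edge categories.

The seed network is the subnetwork induced by the disease proteins on a
STRING-style scored edge table after filtering at a confidence threshold
(inclusive, default 0.700). Seeds left without any surviving edge are not
network nodes but are reported as unconnected. Expansion grows the seed
network greedily against a larger background interactome until a realized
edge-count target is exceeded.
"""

from __future__ import annotations

import logging
import math
from collections import Counter, defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd

from .errors import ConfigurationError
from .io import (
    NetworkClass,
    PPINetwork,
    ScoredEdgeTable,
    canonical_pair,
    canonical_symbol,
)

logger = logging.getLogger(__name__)


def round_half_up(x: float) -> int:
    """Round to nearest integer with ties going up (69.5 -> 70)."""
    return int(math.floor(x + 0.5))


def induced_subnetwork(
    edges: ScoredEdgeTable,
    seeds: Iterable[str],
    threshold: float = 0.700,
    classes: Mapping[str, NetworkClass] | None = None,
) -> PPINetwork:
    """Subnetwork induced by ``seeds`` after filtering at ``threshold``.

    Keeps edges with score >= threshold whose endpoints are both seeds.
    Nodes are the endpoints of surviving edges; degree-0 seeds are
    excluded from the graph but returned in ``unconnected_seeds``. Node
    classes come from ``classes`` (default NONE).
    """
    if not 0.0 <= threshold <= 1.0:
        raise ConfigurationError(f"threshold outside [0,1]: {threshold}")
    seed_set = {canonical_symbol(s) for s in seeds}
    if not seed_set:
        raise ConfigurationError("seed list is empty")
    graph = nx.Graph()
    for e in edges.edges:
        if e.score >= threshold and e.protein_a in seed_set and e.protein_b in seed_set:
            graph.add_edge(e.protein_a, e.protein_b, score=e.score)
    classes = classes or {}
    for n in graph.nodes:
        graph.nodes[n]["network_class"] = NetworkClass(
            classes.get(n, NetworkClass.NONE)
        ).value
        graph.nodes[n]["provenance"] = "SEED"
    unconnected = frozenset(seed_set - set(graph.nodes))
    return PPINetwork(graph=graph, unconnected_seeds=unconnected)


@dataclass(frozen=True)
class ConnectivitySummary:
    connected_fraction: int  # percent of seeds that are network nodes
    component_sizes: tuple[int, ...]  # decreasing


def connectivity_summary(network: PPINetwork, seeds: Iterable[str]) -> ConnectivitySummary:
    """Fraction of seeds inside the network (integer percent) and component sizes."""
    seed_set = {canonical_symbol(s) for s in seeds}
    if not seed_set:
        raise ConfigurationError("seed list is empty")
    pct = round_half_up(100.0 * network.n_nodes / len(seed_set))
    sizes = tuple(sorted((len(c) for c in nx.connected_components(network.graph)),
                         reverse=True))
    return ConnectivitySummary(connected_fraction=pct, component_sizes=sizes)


def expand_network(
    seed_network: PPINetwork,
    background: ScoredEdgeTable,
    threshold: float = 0.700,
    edge_target: int = 2000,
    classes: Mapping[str, NetworkClass] | None = None,
    criterion: str = "score",
) -> PPINetwork:
    """Greedily grow the seed network from a background interactome.

    At each step the non-member protein with the greatest summed score of
    above-threshold edges to current members is added (``criterion="count"``
    ranks by number of such edges instead); ties are broken by more edges,
    then lexically smaller symbol. After each addition every
    above-threshold background edge among members is included. Growth
    stops at the first state whose edge count exceeds ``edge_target``; if
    candidates run out first, the maximal reachable network is returned
    with a warning. Added nodes are flagged ``provenance="ADDED"`` and get
    class NONE unless present in ``classes``.
    """
    if criterion not in ("score", "count"):
        raise ConfigurationError(f"unknown expansion criterion: {criterion}")
    if not 0.0 <= threshold <= 1.0:
        raise ConfigurationError(f"threshold outside [0,1]: {threshold}")
    classes = classes or {}
    filtered = background.filter(threshold)
    adj: dict[str, dict[str, float]] = defaultdict(dict)
    for e in filtered.edges:
        adj[e.protein_a][e.protein_b] = e.score
        adj[e.protein_b][e.protein_a] = e.score

    graph = seed_network.graph.copy()
    members = set(graph.nodes)
    # the background may contain member-member edges absent from the seed file
    for a in members:
        for b, s in adj.get(a, {}).items():
            if b in members and not graph.has_edge(a, b):
                graph.add_edge(a, b, score=s)

    def done() -> bool:
        return graph.number_of_edges() > edge_target

    while not done():
        best = None  # (sum_score, n_edges, symbol)
        for cand in set().union(*(adj.get(m, {}).keys() for m in members)) - members if members else set():
            scores = [s for nbr, s in adj[cand].items() if nbr in members]
            if not scores:
                continue
            key = (sum(scores), len(scores)) if criterion == "score" else (len(scores), sum(scores))
            if best is None or key > best[0] or (key == best[0] and cand < best[1]):
                best = (key, cand)
        if best is None:
            logger.warning(
                "background exhausted at %d edges (< target %d); returning maximal network",
                graph.number_of_edges(), edge_target,
            )
            break
        cand = best[1]
        members.add(cand)
        graph.add_node(
            cand,
            network_class=NetworkClass(classes.get(cand, NetworkClass.NONE)).value,
            provenance="ADDED",
        )
        for nbr, s in adj[cand].items():
            if nbr in members:
                graph.add_edge(cand, nbr, score=s)
    for n in graph.nodes:
        graph.nodes[n].setdefault("network_class", NetworkClass.NONE.value)
        graph.nodes[n].setdefault("provenance", "SEED")
    return PPINetwork(graph=graph, unconnected_seeds=seed_network.unconnected_seeds)


@dataclass(frozen=True)
class EdgeCategoryCounts:
    """Edge count for one unordered pair of node classes."""

    category_pair: tuple[str, str]  # sorted class names, identical when same-class
    count: int


def categorize_edges(network: PPINetwork) -> list[EdgeCategoryCounts]:
    """Count edges by the unordered pair of their endpoint classes.

    Every node must carry a ``network_class`` (NONE allowed); counts over
    all category pairs sum to the total edge count. Sorted by decreasing
    count, then lexically.
    """
    counts: Counter = Counter()
    for u, v in network.graph.edges:
        cu = network.graph.nodes[u].get("network_class", NetworkClass.NONE.value)
        cv = network.graph.nodes[v].get("network_class", NetworkClass.NONE.value)
        counts[tuple(sorted((cu, cv)))] += 1
    return [
        EdgeCategoryCounts(category_pair=pair, count=c)
        for pair, c in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    ]


def edge_categories_frame(categories: list[EdgeCategoryCounts]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "class_a": [c.category_pair[0] for c in categories],
            "class_b": [c.category_pair[1] for c in categories],
            "count": [c.count for c in categories],
        }
    )


def new_edge_class_involvement(
    expanded: PPINetwork, seed_nodes: Iterable[str]
) -> dict[str, int]:
    """Among edges incident to at least one ADDED protein, count edges by
    involvement of each disease class (an edge with a HYPER endpoint counts
    toward HYPER, etc.; NONE-NONE edges count toward NONE)."""
    seed_set = set(seed_nodes)
    counts: Counter = Counter()
    for u, v in expanded.graph.edges:
        if u in seed_set and v in seed_set:
            continue
        cu = expanded.graph.nodes[u].get("network_class", NetworkClass.NONE.value)
        cv = expanded.graph.nodes[v].get("network_class", NetworkClass.NONE.value)
        if cu == cv == NetworkClass.NONE.value:
            counts[NetworkClass.NONE.value] += 1
        else:
            for c in {cu, cv} - {NetworkClass.NONE.value}:
                counts[c] += 1
    return dict(counts)
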