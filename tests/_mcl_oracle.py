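"""Independent reference implementation of Markov clustering for tests.

Deliberately written as a separate code path from the package: dense
textbook iteration with no pruning, and cluster read-out via BFS over the
support graph of the limit matrix rather than attractor bookkeeping. Used
only as an oracle to cross-check the package implementation on small
graphs.
"""

from __future__ import annotations

import numpy as np


def reference_mcl(graph, inflation: float, self_loop: str | float = "max",
                  max_iter: int = 300, tol: float = 1e-8) -> set[frozenset]:
    """Cluster a weighted networkx graph; returns a set of frozensets."""
    nodes = sorted(graph.nodes)
    index = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    m = np.zeros((n, n))
    for u, v, data in graph.edges(data=True):
        w = float(data.get("score", data.get("weight", 1.0)))
        m[index[u], index[v]] = w
        m[index[v], index[u]] = w
    for i in range(n):
        incident = m[i].max()
        m[i, i] = incident if (self_loop == "max" and incident > 0) else (
            1.0 if self_loop == "max" else float(self_loop))
    m = m / m.sum(axis=0)

    for _ in range(max_iter):
        nxt = np.linalg.matrix_power(m, 2) ** inflation
        nxt = nxt / nxt.sum(axis=0)
        if np.abs(nxt - m).max() < tol:
            m = nxt
            break
        m = nxt

    support = (m > 1e-6) | (m > 1e-6).T
    seen = [False] * n
    clusters = set()
    for start in range(n):
        if seen[start]:
            continue
        queue, comp = [start], set()
        seen[start] = True
        while queue:
            i = queue.pop()
            comp.add(nodes[i])
            for j in range(n):
                if not seen[j] and (support[i, j] or support[j, i]):
                    seen[j] = True
                    queue.append(j)
        clusters.add(frozenset(comp))
    return clusters
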