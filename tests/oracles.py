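"""Independent brute-force oracles used only by the test suite.

The bridge-centrality oracle is written against scipy's Dijkstra
distance matrix with an explicit shortest-path-count dynamic program —
a different code path from the networkx-based implementation it checks.
"""

from __future__ import annotations

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra

TOL = 1e-9


def _length_matrix(weights: np.ndarray) -> csr_matrix:
    p = weights.shape[0]
    rows, cols, vals = [], [], []
    for i in range(p):
        for j in range(p):
            if i != j and weights[i, j] != 0.0:
                rows.append(i)
                cols.append(j)
                vals.append(1.0 / abs(weights[i, j]))
    return csr_matrix((vals, (rows, cols)), shape=(p, p))


def _path_counts(weights: np.ndarray, dist: np.ndarray, source: int) -> np.ndarray:
    """Number of shortest paths from source to each node (DP by distance)."""
    p = weights.shape[0]
    sigma = np.zeros(p)
    sigma[source] = 1.0
    order = np.argsort(dist[source])
    for v in order:
        if v == source or not np.isfinite(dist[source, v]):
            continue
        total = 0.0
        for u in range(p):
            if weights[u, v] == 0.0 or not np.isfinite(dist[source, u]):
                continue
            if abs(dist[source, u] + 1.0 / abs(weights[u, v]) - dist[source, v]) < TOL:
                total += sigma[u]
        sigma[v] = total
    return sigma


def oracle_bridge_centrality(weights: np.ndarray, communities: np.ndarray) -> dict:
    """All four bridge indices plus EI by direct summation and DP path counts."""
    p = weights.shape[0]
    cross = communities[:, None] != communities[None, :]
    ei = weights.sum(axis=1)
    strength = np.array([np.abs(weights[i][cross[i]]).sum() for i in range(p)])
    bridge_ei = np.array([weights[i][cross[i]].sum() for i in range(p)])

    dist = dijkstra(_length_matrix(weights), directed=False)
    sigma = np.array([_path_counts(weights, dist, s) for s in range(p)])

    betweenness = np.zeros(p)
    for s in range(p):
        for t in range(s + 1, p):
            if not cross[s, t] or not np.isfinite(dist[s, t]) or sigma[s, t] == 0:
                continue
            for v in range(p):
                if v in (s, t) or not np.isfinite(dist[s, v]):
                    continue
                if abs(dist[s, v] + dist[v, t] - dist[s, t]) < TOL:
                    betweenness[v] += sigma[s, v] * sigma[t, v] / sigma[s, t]

    closeness = np.zeros(p)
    for i in range(p):
        d = dist[i][cross[i]]
        m = d.mean() if d.size else np.inf
        closeness[i] = 1.0 / m if np.isfinite(m) and m > 0 else 0.0

    return {
        "expected_influence": ei,
        "bridge_strength": strength,
        "bridge_expected_influence": bridge_ei,
        "bridge_betweenness": betweenness,
        "bridge_closeness": closeness,
    }


def oracle_bh(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, written from the definition."""
    pvals = np.asarray(pvals, dtype=float)
    m = pvals.size
    order = np.argsort(pvals, kind="stable")
    adjusted = np.empty(m)
    running_min = 1.0
    for rank_from_top in range(m - 1, -1, -1):
        i = order[rank_from_top]
        candidate = pvals[i] * m / (rank_from_top + 1)
        running_min = min(running_min, candidate)
        adjusted[i] = min(running_min, 1.0)
    return adjusted
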