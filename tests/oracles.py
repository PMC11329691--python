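"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written as plain loops over adjacency matrices — no
networkx, no vectorized shortcuts — so it stays independent of the code paths
it checks.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def loop_specificity(inj: np.ndarray, mask: np.ndarray) -> tuple[float, float]:
    """Voxel-by-voxel binarized and weighted specificity."""
    pos = 0
    pos_in = 0
    total = 0.0
    total_in = 0.0
    for idx in np.ndindex(inj.shape):
        v = float(inj[idx])
        if v > 0:
            pos += 1
            if mask[idx] == 1:
                pos_in += 1
        total += v
        if mask[idx] == 1:
            total_in += v
    return pos_in / pos, total_in / total


def floyd_warshall(adj: np.ndarray) -> np.ndarray:
    n = adj.shape[0]
    dist = np.full((n, n), math.inf)
    for i in range(n):
        dist[i, i] = 0.0
        for j in range(n):
            if i != j and adj[i, j]:
                dist[i, j] = 1.0
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if dist[i, k] + dist[k, j] < dist[i, j]:
                    dist[i, j] = dist[i, k] + dist[k, j]
    return dist


def _efficiency_from_dist(dist: np.ndarray) -> np.ndarray:
    n = dist.shape[0]
    eff = np.zeros(n)
    for i in range(n):
        for j in range(n):
            if i != j and math.isfinite(dist[i, j]):
                eff[i] += 1.0 / dist[i, j]
        if n > 1:
            eff[i] /= n - 1
    return eff


def brute_nodal_metrics(adj: np.ndarray) -> dict[str, np.ndarray]:
    """All six nodal metrics by direct enumeration on a binary directed graph."""
    adj = np.asarray(adj, dtype=int).copy()
    np.fill_diagonal(adj, 0)
    n = adj.shape[0]
    in_deg = adj.sum(axis=0).astype(float)
    out_deg = adj.sum(axis=1).astype(float)
    dc = in_deg + out_deg

    # Fagiolo directed clustering: triangles on A + A^T over possible triples.
    sym = adj + adj.T
    sym3 = sym @ sym @ sym
    bilateral = (adj @ adj).diagonal()  # reciprocated-edge count per node
    clustering = np.zeros(n)
    for i in range(n):
        denom = 2.0 * (dc[i] * (dc[i] - 1) - 2.0 * bilateral[i])
        if denom > 0:
            clustering[i] = sym3[i, i] / denom

    dist = floyd_warshall(adj)
    shortest = np.zeros(n)
    for i in range(n):
        ds = [dist[i, j] for j in range(n) if j != i and math.isfinite(dist[i, j])]
        shortest[i] = sum(ds) / len(ds) if ds else 0.0
    efficiency = _efficiency_from_dist(dist)

    local_eff = np.zeros(n)
    for i in range(n):
        nbrs = [j for j in range(n) if j != i and (adj[i, j] or adj[j, i])]
        k = len(nbrs)
        if k < 2:
            continue
        sub = adj[np.ix_(nbrs, nbrs)]
        dsub = floyd_warshall(sub)
        total = 0.0
        for a in range(k):
            for b in range(k):
                if a != b and math.isfinite(dsub[a, b]):
                    total += 1.0 / dsub[a, b]
        local_eff[i] = total / (k * (k - 1))

    betweenness = brute_betweenness(adj, dist)
    return {
        "in_degree": in_deg,
        "out_degree": out_deg,
        "degree_centrality": dc,
        "clustering": clustering,
        "shortest_path": shortest,
        "efficiency": efficiency,
        "local_efficiency": local_eff,
        "betweenness": betweenness,
    }


def brute_betweenness(adj: np.ndarray, dist: np.ndarray | None = None) -> np.ndarray:
    """Normalized betweenness via shortest-path counting (pair-dependency sums)."""
    n = adj.shape[0]
    if dist is None:
        dist = floyd_warshall(adj)
    # sigma[s, t]: number of shortest s→t paths, by dynamic programming on length.
    sigma = np.zeros((n, n))
    for s in range(n):
        sigma[s, s] = 1.0
        order = sorted(
            (t for t in range(n) if t != s and math.isfinite(dist[s, t])),
            key=lambda t: dist[s, t],
        )
        for t in order:
            sigma[s, t] = sum(
                sigma[s, u] for u in range(n) if adj[u, t] and dist[s, u] + 1 == dist[s, t]
            )
    bet = np.zeros(n)
    for s in range(n):
        for t in range(n):
            if s == t or not math.isfinite(dist[s, t]) or sigma[s, t] == 0:
                continue
            for v in range(n):
                if v in (s, t):
                    continue
                if math.isfinite(dist[s, v]) and math.isfinite(dist[v, t]):
                    if dist[s, v] + dist[v, t] == dist[s, t]:
                        bet[v] += sigma[s, v] * sigma[v, t] / sigma[s, t]
    if n > 2:
        bet /= (n - 1) * (n - 2)
    return bet


def exhaustive_permutation_pvalue(a, b) -> float:
    """Exact permutation p-value over all splits of the pooled values."""
    a = list(map(float, a))
    b = list(map(float, b))
    pooled = a + b
    na, n = len(a), len(pooled)
    obs = abs(sum(a) / na - sum(b) / len(b))
    count = 0
    total = 0
    for combo in itertools.combinations(range(n), na):
        total += 1
        left = [pooled[i] for i in combo]
        right = [pooled[i] for i in range(n) if i not in set(combo)]
        stat = abs(sum(left) / na - sum(right) / len(right))
        if stat >= obs - 1e-12:
            count += 1
    return count / total
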