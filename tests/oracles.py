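"""Brute-force oracles, independent of the library code they check.

Everything here is written directly from definitions: Floyd–Warshall with
path counting for distances and betweenness, bipartition enumeration for
the global minimum edge cut, direct triplet counting for transitivity.
Only usable for small graphs (n <= ~12); that is the point.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np


def floyd_warshall_with_counts(n: int, edges: list[tuple[int, int]]):
    """All-pairs shortest-path lengths and numbers of shortest paths."""
    inf = float("inf")
    d = np.full((n, n), inf)
    c = np.zeros((n, n))
    np.fill_diagonal(d, 0.0)
    np.fill_diagonal(c, 1.0)
    for u, v in edges:
        d[u, v] = d[v, u] = 1.0
        c[u, v] = c[v, u] = 1.0
    for k in range(n):
        for i in range(n):
            if i == k or d[i, k] == inf:
                continue
            for j in range(n):
                if j in (i, k) or d[k, j] == inf:
                    continue
                via = d[i, k] + d[k, j]
                if via < d[i, j]:
                    d[i, j] = via
                    c[i, j] = c[i, k] * c[k, j]
                elif via == d[i, j]:
                    c[i, j] += c[i, k] * c[k, j]
    return d, c


def brute_metrics(n: int, edges: list[tuple[int, int]]) -> dict[str, float]:
    """The ten topological characteristics, from definitions only.

    Path metrics use the largest connected component; degenerate graphs
    (n <= 1 or no edges) give 0 for path metrics, centralizations,
    clustering and connectance — same conventions as the implementation
    under test, stated independently here.
    """
    m = len(edges)
    out = {
        "node_number": float(n),
        "edge_number": float(m),
        "mean_degree": 2.0 * m / n if n else 0.0,
        "connectance": 2.0 * m / (n * (n - 1)) if n > 1 else 0.0,
    }
    if n <= 1 or m == 0:
        for k in (
            "average_path_length",
            "diameter",
            "edge_connectivity",
            "degree_centralization",
            "betweenness_centralization",
            "clustering_coefficient",
        ):
            out[k] = 0.0
        return out

    d, c = floyd_warshall_with_counts(n, edges)

    # connected components by reachability
    comps: list[set[int]] = []
    seen: set[int] = set()
    for i in range(n):
        if i in seen:
            continue
        comp = {j for j in range(n) if d[i, j] < float("inf")}
        comps.append(comp)
        seen |= comp
    lcc = sorted(max(comps, key=len))

    if len(lcc) > 1:
        pairs = [(i, j) for i, j in combinations(lcc, 2)]
        dists = [d[i, j] for i, j in pairs]
        out["average_path_length"] = float(np.mean(dists))
        out["diameter"] = float(np.max(dists))
    else:
        out["average_path_length"] = 0.0
        out["diameter"] = 0.0

    # global min edge cut: minimum crossing edges over all proper bipartitions
    if len(comps) > 1:
        out["edge_connectivity"] = 0.0
    else:
        nodes = list(range(n))
        best = m
        for r in range(1, n // 2 + 1):
            for side in combinations(nodes, r):
                s = set(side)
                crossing = sum(1 for u, v in edges if (u in s) != (v in s))
                best = min(best, crossing)
        out["edge_connectivity"] = float(best)

    deg = np.zeros(n)
    for u, v in edges:
        deg[u] += 1
        deg[v] += 1
    denom_deg = (n - 1) * (n - 2)
    out["degree_centralization"] = (
        float((deg.max() - deg).sum() / denom_deg) if denom_deg > 0 else 0.0
    )

    # betweenness: unordered pairs, endpoints excluded
    btw = np.zeros(n)
    for i, j in combinations(range(n), 2):
        if d[i, j] == float("inf") or c[i, j] == 0:
            continue
        for v in range(n):
            if v in (i, j):
                continue
            if d[i, v] + d[v, j] == d[i, j]:
                btw[v] += c[i, v] * c[v, j] / c[i, j]
    denom_btw = (n - 1) ** 2 * (n - 2) / 2.0
    out["betweenness_centralization"] = (
        float((btw.max() - btw).sum() / denom_btw) if denom_btw > 0 else 0.0
    )

    # transitivity: closed triplets / all triplets
    adj = np.zeros((n, n), dtype=bool)
    for u, v in edges:
        adj[u, v] = adj[v, u] = True
    triangles = sum(
        1 for a, b, cc in combinations(range(n), 3) if adj[a, b] and adj[b, cc] and adj[a, cc]
    )
    triplets = sum(int(k * (k - 1) / 2) for k in deg)
    out["clustering_coefficient"] = 3.0 * triangles / triplets if triplets else 0.0
    return out


def newman_girvan_q(n: int, edges: list[tuple[int, int]], membership: dict[int, int]) -> float:
    """Q = sum_i (e_ii - a_i^2) from the definition."""
    m = len(edges)
    comms = set(membership.values())
    q = 0.0
    for comm in comms:
        within = sum(1 for u, v in edges if membership[u] == comm and membership[v] == comm)
        ends = sum(1 for u, v in edges for x in (u, v) if membership[x] == comm)
        q += within / m - (ends / (2 * m)) ** 2
    return q


def anosim_r(dist: np.ndarray, labels: np.ndarray) -> float:
    """R = (mean between-group rank - mean within-group rank) / (M / 4)."""
    from scipy.stats import rankdata

    n = dist.shape[0]
    iu = np.triu_indices(n, k=1)
    ranks = rankdata(dist[iu])
    within = labels[iu[0]] == labels[iu[1]]
    m = n * (n - 1) / 2
    return (ranks[~within].mean() - ranks[within].mean()) / (m / 2.0)


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg from the formula: p * m / rank, cumulative min."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(adj[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


def spearman_midrank(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson correlation of mid-ranks."""
    from scipy.stats import rankdata

    rx, ry = rankdata(x), rankdata(y)
    return float(np.corrcoef(rx, ry)[0, 1])
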