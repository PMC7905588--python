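"""Independent brute-force reference implementations used only in tests.

Deliberately coded with different algorithms and data structures than the
package (Floyd-Warshall instead of BFS, plain edge dicts instead of the
network container) so that agreement is evidence, not tautology.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

INF = math.inf


def oracle_cohesion(nodes: list[str], edges: dict[frozenset, float],
                    aggregation: str = "prose") -> float:
    """1/(s*l) computed by direct summation and Floyd-Warshall distances."""
    if len(nodes) == 1:
        return INF
    if not edges:
        raise ValueError("no edges")
    strength = {v: 0.0 for v in nodes}
    degree = {v: 0 for v in nodes}
    for pair, w in edges.items():
        a, b = tuple(pair)
        strength[a] += w
        strength[b] += w
        degree[a] += 1
        degree[b] += 1
    if aggregation == "prose":
        s = sum(strength[v] / degree[v] for v in nodes if degree[v] > 0)
    else:
        s = sum(strength[v] * degree[v] for v in nodes if degree[v] > 0)

    idx = {v: i for i, v in enumerate(nodes)}
    n = len(nodes)
    d = [[INF] * n for _ in range(n)]
    for i in range(n):
        d[i][i] = 0.0
    for pair in edges:
        a, b = tuple(pair)
        d[idx[a]][idx[b]] = d[idx[b]][idx[a]] = 1.0
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i][k] + d[k][j] < d[i][j]:
                    d[i][j] = d[i][k] + d[k][j]
    dists = [d[i][j] for i in range(n) for j in range(n)
             if i != j and d[i][j] < INF]
    if not dists:
        raise ValueError("no connected pairs")
    l = sum(dists) / len(dists)
    return 1.0 / (s * l)


def oracle_contract(nodes: list[str], edges: dict[frozenset, float],
                    v: str) -> tuple[list[str], dict[frozenset, float]]:
    """Merge v with its neighbours; outside edges summed, internal dropped."""
    neighbours = {next(iter(pair - {v})) for pair in edges if v in pair}
    merged = neighbours | {v}
    new_node = "__merged__"
    new_nodes = [new_node] + [u for u in nodes if u not in merged]
    new_edges: dict[frozenset, float] = {}
    for pair, w in edges.items():
        a, b = tuple(pair)
        a2 = new_node if a in merged else a
        b2 = new_node if b in merged else b
        if a2 == b2:
            continue
        key = frozenset((a2, b2))
        new_edges[key] = new_edges.get(key, 0.0) + w
    return new_nodes, new_edges


def oracle_imc(nodes: list[str], edges: dict[frozenset, float], v: str,
               aggregation: str = "prose") -> float:
    c0 = oracle_cohesion(nodes, edges, aggregation)
    new_nodes, new_edges = oracle_contract(nodes, edges, v)
    if len(new_nodes) <= 1 or not new_edges:
        return 1.0
    cv = oracle_cohesion(new_nodes, new_edges, aggregation)
    return 1.0 - c0 / cv


def oracle_cooccurrence(X: np.ndarray) -> dict[frozenset, int]:
    """Pair counts by explicit loops over subjects and feature pairs."""
    n_subj, n_feat = X.shape
    counts: dict[frozenset, int] = {}
    for s in range(n_subj):
        positives = [j for j in range(n_feat) if X[s, j] == 1]
        for a, b in itertools.combinations(positives, 2):
            key = frozenset((a, b))
            counts[key] = counts.get(key, 0) + 1
    return counts


def oracle_canonical_correlations(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Canonical correlations via the generalized eigenvalue route.

    Eigenvalues of Sxx^-1 Sxy Syy^-1 Syx are the squared canonical
    correlations; solved directly with covariance matrices.
    """
    n = X.shape[0]
    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    Sxx = Xc.T @ Xc / (n - 1)
    Syy = Yc.T @ Yc / (n - 1)
    Sxy = Xc.T @ Yc / (n - 1)
    M = np.linalg.solve(Sxx, Sxy) @ np.linalg.solve(Syy, Sxy.T)
    eig = np.linalg.eigvals(M)
    r2 = np.sort(np.clip(eig.real, 0.0, 1.0))[::-1]
    m = min(X.shape[1], Y.shape[1])
    return np.sqrt(r2[:m])


def connected_edge_subsets(n: int):
    """Yield every labeled connected graph on nodes 0..n-1 as a frozenset of pairs."""
    all_pairs = list(itertools.combinations(range(n), 2))
    for mask in range(1, 2 ** len(all_pairs)):
        edges = [all_pairs[i] for i in range(len(all_pairs)) if mask >> i & 1]
        adj = {v: set() for v in range(n)}
        for a, b in edges:
            adj[a].add(b)
            adj[b].add(a)
        seen = {0}
        stack = [0]
        while stack:
            u = stack.pop()
            for w in adj[u]:
                if w not in seen:
                    seen.add(w)
                    stack.append(w)
        if len(seen) == n:
            yield edges
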