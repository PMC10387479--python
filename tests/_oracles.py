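"""Independent brute-force reference implementations used only by tests.

These deliberately avoid the code paths (and, where possible, the
libraries) they are checking: Spearman via explicit rank transform and the
Pearson formula, clustering via literal triangle counting, efficiency via
breadth-first search path enumeration, assortativity via an edge-list
Pearson correlation.
"""

from __future__ import annotations

import math
from collections import deque

import numpy as np


def rank_average_ties(x) -> list[float]:
    order = sorted(range(len(x)), key=lambda i: x[i])
    ranks = [0.0] * len(x)
    i = 0
    while i < len(x):
        j = i
        while j + 1 < len(x) and x[order[j + 1]] == x[order[i]]:
            j += 1
        avg = (i + j) / 2 + 1  # ranks are 1-based
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def pearson(x, y) -> float:
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sxx = sum((a - mx) ** 2 for a in x)
    syy = sum((b - my) ** 2 for b in y)
    return sxy / math.sqrt(sxx * syy)


def spearman(x, y) -> float:
    return pearson(rank_average_ties(list(x)), rank_average_ties(list(y)))


def degrees(adj: np.ndarray) -> list[int]:
    n = adj.shape[0]
    return [sum(1 for j in range(n) if adj[i, j]) for i in range(n)]


def mean_clustering(adj: np.ndarray) -> float:
    n = adj.shape[0]
    total = 0.0
    for i in range(n):
        nbrs = [j for j in range(n) if adj[i, j]]
        k = len(nbrs)
        if k < 2:
            continue
        links = sum(
            1
            for a in range(k)
            for b in range(a + 1, k)
            if adj[nbrs[a], nbrs[b]]
        )
        total += 2.0 * links / (k * (k - 1))
    return total / n


def global_efficiency(adj: np.ndarray) -> float:
    n = adj.shape[0]
    total = 0.0
    for s in range(n):
        dist = {s: 0}
        q = deque([s])
        while q:
            u = q.popleft()
            for v in range(n):
                if adj[u, v] and v not in dist:
                    dist[v] = dist[u] + 1
                    q.append(v)
        for t in range(n):
            if t != s and t in dist:
                total += 1.0 / dist[t]
    return total / (n * (n - 1))


def degree_assortativity(adj: np.ndarray) -> float:
    """Pearson correlation of endpoint degrees over both edge orientations."""
    k = degrees(adj)
    xs, ys = [], []
    n = adj.shape[0]
    for i in range(n):
        for j in range(n):
            if i != j and adj[i, j]:
                xs.append(k[i])
                ys.append(k[j])
    if not xs:
        raise ValueError("no edges")
    sx = len(set(xs))
    if sx == 1:
        return float("nan")
    return pearson(xs, ys)
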