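"""Independent brute-force oracles used to validate the implementation.

Everything here is written for clarity, not speed, and deliberately avoids
the code paths (and libraries) used by the package itself: shortest paths
by hand-rolled BFS, triangles and triples by exhaustive loops, betweenness
by enumerating every simple path.
"""

import itertools
from collections import deque

import numpy as np


def bfs_distances(a, source):
    n = a.shape[0]
    dist = [None] * n
    dist[source] = 0
    q = deque([source])
    while q:
        u = q.popleft()
        for v in range(n):
            if a[u, v] and dist[v] is None:
                dist[v] = dist[u] + 1
                q.append(v)
    return dist


def brute_global_metrics(a):
    """cp, lp, t, eg, eloc of a binary adjacency matrix, the slow way."""
    n = a.shape[0]
    deg = [int(a[i].sum()) for i in range(n)]

    tri = [0] * n
    for i in range(n):
        for j in range(n):
            for k in range(n):
                if j != i and k != i and k != j and a[i, j] and a[j, k] and a[i, k]:
                    tri[i] += 1
    tri = [t // 2 for t in tri]

    cp_vals = []
    for i in range(n):
        cp_vals.append(
            2 * tri[i] / (deg[i] * (deg[i] - 1)) if deg[i] >= 2 else 0.0
        )
    cp = sum(cp_vals) / n

    triples = sum(d * (d - 1) for d in deg) / 2
    n_triangles = sum(tri) / 3
    t = 3 * n_triangles / triples if triples else 0.0

    finite, inv = [], []
    for i, j in itertools.combinations(range(n), 2):
        d = bfs_distances(a, i)[j]
        if d is not None:
            finite.append(d)
            inv.append(1.0 / d)
        else:
            inv.append(0.0)
    lp = sum(finite) / len(finite) if finite else float("inf")
    eg = sum(inv) / len(inv) if inv else 0.0

    eloc_vals = []
    for i in range(n):
        nb = [j for j in range(n) if a[i, j]]
        if len(nb) < 2:
            eloc_vals.append(0.0)
            continue
        sub = a[np.ix_(nb, nb)]
        invs = []
        for u, v in itertools.combinations(range(len(nb)), 2):
            d = bfs_distances(sub, u)[v]
            invs.append(1.0 / d if d is not None else 0.0)
        eloc_vals.append(sum(invs) / len(invs))
    eloc = sum(eloc_vals) / n

    return {"cp": cp, "lp": lp, "t": t, "eg": eg, "eloc": eloc}


def brute_betweenness(a):
    """Raw betweenness by enumerating every simple path between every pair."""
    n = a.shape[0]
    bet = [0.0] * n
    for s, t in itertools.combinations(range(n), 2):
        paths = []

        def extend(path):
            u = path[-1]
            if u == t:
                paths.append(list(path))
                return
            for v in range(n):
                if a[u, v] and v not in path:
                    path.append(v)
                    extend(path)
                    path.pop()

        extend([s])
        if not paths:
            continue
        shortest = min(len(p) for p in paths)
        sp = [p for p in paths if len(p) == shortest]
        for p in sp:
            for v in p[1:-1]:
                bet[v] += 1.0 / len(sp)
    return bet


def ols_residuals_normal_equations(X, y):
    """Residuals via the normal equations (X'X)^-1 X'y."""
    beta = np.linalg.inv(X.T @ X) @ X.T @ y
    return y - X @ beta
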