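"""From-definition brute-force oracles, independent of the library code.

Everything here is written straight from the textbook definitions with plain
Python loops, deliberately sharing no code path with glysense, so agreement
between the two is evidence of correctness rather than of shared bugs.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize


def brute_knn_distances(X, k):
    """Distance of each row of X to its k-th nearest other row."""
    X = np.asarray(X, float)
    out = []
    for i in range(len(X)):
        d = sorted(np.linalg.norm(X[j] - X[i]) for j in range(len(X)) if j != i)
        out.append(d[k - 1])
    return np.array(out)


def _knn_index_sets(X, k):
    n = len(X)
    D = np.array([[np.linalg.norm(X[i] - X[j]) for j in range(n)] for i in range(n)])
    neigh = []
    for i in range(n):
        order = [j for j in np.argsort(D[i], kind="stable") if j != i]
        neigh.append(order[:k])
    return D, neigh


def brute_lof(X, k):
    """Local outlier factor from the definition (k-distance, reach-dist, lrd)."""
    X = np.asarray(X, float)
    n = len(X)
    D, neigh = _knn_index_sets(X, k)
    kdist = np.array([D[i][neigh[i][-1]] for i in range(n)])

    def reach(a, b):  # reachability distance of a w.r.t. b
        return max(kdist[b], D[a][b])

    lrd = np.array([
        1.0 / (np.mean([reach(i, b) for b in neigh[i]]) or np.inf)
        for i in range(n)
    ])
    return np.array([
        np.mean([lrd[b] for b in neigh[i]]) / lrd[i] for i in range(n)
    ])


def brute_cof(X, k):
    """Connectivity-based outlier factor from the definition.

    Set-based nearest path from each point through its k-neighbourhood;
    average chaining distance with linearly decreasing weights; COF is the
    ratio of a point's average chaining distance to the mean of its
    neighbours'.
    """
    X = np.asarray(X, float)
    n = len(X)
    D, neigh = _knn_index_sets(X, k)

    def ac_dist(i):
        in_set = [i]
        remaining = list(neigh[i])
        total = 0.0
        step = 1
        while remaining:
            best = None
            for g in in_set:
                for r in remaining:
                    if best is None or D[g][r] < best[0]:
                        best = (D[g][r], r)
            weight = 2.0 * (k + 1 - step) / (k * (k + 1))
            total += weight * best[0]
            in_set.append(best[1])
            remaining.remove(best[1])
            step += 1
        return total

    ac = np.array([ac_dist(i) for i in range(n)])
    return np.array([ac[i] / np.mean([ac[b] for b in neigh[i]]) for i in range(n)])


def point_segment_distance(z, a, b):
    z, a, b = map(np.asarray, (z, a, b))
    d = b - a
    denom = float(d @ d)
    t = 0.0 if denom == 0 else float(np.clip((z - a) @ d / denom, 0.0, 1.0))
    return float(np.linalg.norm(z - (a + t * d)))


def brute_mst_edges(X):
    """Prim's algorithm with plain loops; returns vertex-index edge pairs."""
    X = np.asarray(X, float)
    n = len(X)
    visited = [0]
    edges = []
    while len(visited) < n:
        best = None
        for u in visited:
            for v in range(n):
                if v in visited:
                    continue
                d = float(np.linalg.norm(X[u] - X[v]))
                if best is None or d < best[0]:
                    best = (d, u, v)
        edges.append((best[1], best[2]))
        visited.append(best[2])
    return edges


def brute_mst_score(X, Z):
    """Min distance of each row of Z to any MST edge segment."""
    edges = brute_mst_edges(X)
    X = np.asarray(X, float)
    return np.array([
        min(point_segment_distance(z, X[u], X[v]) for u, v in edges) for z in Z
    ])


def brute_nn_d(X, Z):
    """Nearest-neighbour description score from the definition."""
    X = np.asarray(X, float)
    out = []
    for z in Z:
        d1 = [np.linalg.norm(z - x) for x in X]
        i = int(np.argmin(d1))
        d2 = min(
            np.linalg.norm(X[i] - X[j]) for j in range(len(X)) if j != i
        )
        out.append(d1[i] / d2 if d2 > 0 else (0.0 if d1[i] <= 0 else np.inf))
    return np.array(out)


def slsqp_simplex_box_qp(Q, p, C):
    """General-purpose solve of min 1/2 a'Qa + p'a, sum(a)=1, 0<=a<=C."""
    n = len(p)
    res = minimize(
        lambda a: 0.5 * a @ Q @ a + p @ a,
        np.full(n, 1.0 / n),
        jac=lambda a: Q @ a + p,
        bounds=[(0.0, C)] * n,
        constraints=[{"type": "eq", "fun": lambda a: a.sum() - 1.0,
                      "jac": lambda a: np.ones(n)}],
        method="SLSQP",
        options={"ftol": 1e-14, "maxiter": 1000},
    )
    assert res.success, res.message
    return res.x, float(res.fun)
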