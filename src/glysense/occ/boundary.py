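"""Boundary and domain-based one-class models.

* :class:`SVDD` — support vector data description: the smallest Gaussian-
  kernel-space hypersphere around the target data; score is the kernel
  squared distance to the sphere centre minus R^2.
* :class:`IncSVDD` — the same description obtained by adding training points
  one at a time with a KKT check and exact re-optimisation; it converges to
  the identical (strictly convex) dual optimum as the batch solver.
* :class:`NuSVM` — one-class support vector machine: a hyperplane separating
  the data from the origin in kernel space; nu upper-bounds the training
  outlier fraction; score = rho - f(z).
* :class:`NNDescription` — nearest-neighbour description: score is the ratio
  of the distance to the nearest training point over that point's own
  nearest-neighbour distance.
* :class:`MSTDescription` — the entire minimum spanning tree of the training
  set is the domain; score is the Euclidean distance from a point to the
  nearest point on any tree edge (projection onto segments).

The SVDD and nu-SVM duals are quadratic programs over the simplex with box
constraints,

    min_a  1/2 a' Q a + p' a   s.t.  sum(a) = 1,  0 <= a_i <= C,

solved by sequential minimal optimisation (second-order working-set
selection with an incrementally maintained gradient).
"""

from __future__ import annotations

import numpy as np
from scipy.sparse.csgraph import minimum_spanning_tree
from scipy.spatial.distance import cdist
from sklearn.neighbors import NearestNeighbors

from .core import OneClassModel

_EPS = 1e-14


def rbf_kernel(A: np.ndarray, B: np.ndarray, sigma: float) -> np.ndarray:
    """Gaussian kernel K(a, b) = exp(-||a - b||^2 / sigma^2)."""
    if sigma <= 0:
        raise ValueError("kernel width sigma must be positive")
    return np.exp(-cdist(A, B, "sqeuclidean") / sigma**2)


def _feasible_start(n: int, C: float) -> np.ndarray:
    """A feasible point of {sum(a) = 1, 0 <= a <= C}."""
    if C * n < 1 - 1e-9:
        raise ValueError(f"infeasible box: C * n = {C * n:.3g} < 1")
    if 1.0 / n <= C:
        return np.full(n, 1.0 / n)
    alpha = np.zeros(n)
    full = int(1.0 / C)
    alpha[:full] = C
    alpha[full] = 1.0 - full * C
    return alpha


def solve_simplex_box_qp(
    Q: np.ndarray,
    p: np.ndarray,
    C: float,
    tol: float = 1e-10,
    max_iter: int = 200_000,
    alpha0: np.ndarray | None = None,
) -> np.ndarray:
    """SMO for min 1/2 a'Qa + p'a s.t. sum(a)=1, 0 <= a <= C.

    Working-set selection is second order: the first index minimises the
    gradient among coordinates below the upper bound, the partner maximises
    the per-pair objective decrease among coordinates above zero.  Stops
    when the first-order KKT violation falls below ``tol``.
    """
    n = p.size
    alpha = _feasible_start(n, C) if alpha0 is None else alpha0.astype(float).copy()
    g = Q @ alpha + p
    dQ = np.diag(Q).copy()
    inf = np.inf
    for _ in range(max_iter):
        g_up = np.where(alpha < C - _EPS, g, inf)
        lo_mask = alpha > _EPS
        i = int(np.argmin(g_up))
        viol = np.max(np.where(lo_mask, g, -inf)) - g[i]
        if viol < tol:
            break
        diff = g - g[i]
        quad = np.maximum(dQ[i] + dQ - 2.0 * Q[:, i], _EPS)
        gain = np.where(lo_mask & (diff > 0), diff**2 / quad, -inf)
        j = int(np.argmax(gain))
        step = diff[j] / quad[j]
        step = min(step, C - alpha[i], alpha[j])
        alpha[i] += step
        alpha[j] -= step
        g += step * (Q[:, i] - Q[:, j])
    return alpha


def qp_objective(Q: np.ndarray, p: np.ndarray, alpha: np.ndarray) -> float:
    return float(0.5 * alpha @ Q @ alpha + p @ alpha)


class SVDD(OneClassModel):
    """Support vector data description with a Gaussian kernel.

    ``C`` is the box constraint of the dual; when omitted it is set to
    ``max(1/(nu * n), 1/n)`` so a fraction of about ``nu`` of the training
    data may fall outside the sphere.
    """

    family = "boundary"
    name = "svdd"

    def __init__(self, sigma: float = 0.4, C: float | None = None,
                 nu: float = 0.05, tol: float = 1e-6):
        self.sigma = sigma
        self.C = C
        self.nu = nu
        self.tol = tol

    def _box(self, n: int) -> float:
        if self.C is not None:
            return float(self.C)
        return max(1.0 / (self.nu * n), 1.0 / n + 1e-12)

    def _solve(self, K: np.ndarray, C: float) -> np.ndarray:
        Q = 2.0 * K
        p = -np.diag(K).copy()
        return solve_simplex_box_qp(Q, p, C, tol=self.tol)

    def _finish(self, X: np.ndarray, K: np.ndarray, alpha: np.ndarray, C: float):
        self._X = X
        self.alpha_ = alpha
        self._aKa = float(alpha @ K @ alpha)
        self.dual_objective_ = qp_objective(2.0 * K, -np.diag(K), alpha)
        sv = alpha > 1e-8 * C
        margin = sv & (alpha < C - 1e-8 * C)
        which = margin if margin.any() else sv
        d2 = np.diag(K) - 2.0 * (K @ alpha) + self._aKa
        self.radius2_ = float(np.mean(d2[which]))
        return self

    def fit(self, X: np.ndarray) -> "SVDD":
        X = np.asarray(X, dtype=float)
        if len(X) < 2:
            raise ValueError("need at least 2 training objects")
        K = rbf_kernel(X, X, self.sigma)
        C = self._box(len(X))
        return self._finish(X, K, self._solve(K, C), C)

    def score(self, Z: np.ndarray) -> np.ndarray:
        self._check_fitted()
        Z = self._check_dim(Z)
        Kzx = rbf_kernel(Z, self._X, self.sigma)
        d2 = 1.0 - 2.0 * Kzx @ self.alpha_ + self._aKa
        return d2 - self.radius2_


class IncSVDD(SVDD):
    """SVDD fitted by incremental constraint addition.

    Points are presented one at a time; a new point that already satisfies
    the KKT conditions of the current solution leaves it untouched, otherwise
    the dual is re-optimised warm-started from the current multipliers.  The
    final description coincides with the batch :class:`SVDD` solution (the
    dual is strictly convex for a Gaussian kernel on distinct points).
    """

    name = "inc_svdd"

    def fit(self, X: np.ndarray) -> "IncSVDD":
        X = np.asarray(X, dtype=float)
        n = len(X)
        if n < 2:
            raise ValueError("need at least 2 training objects")
        C = self._box(n)
        K = rbf_kernel(X, X, self.sigma)
        # The box is only feasible once ceil(1/C) points are present.
        m = max(2, int(np.ceil(1.0 / C - 1e-12)))
        alpha = self._solve(K[:m, :m], C)
        for t in range(m, n):
            Kt = K[: t + 1, : t + 1]
            alpha = np.append(alpha, 0.0)
            g = Kt @ (2.0 * alpha) - np.diag(Kt)
            lam = -np.min(np.where(alpha[:t] < C - _EPS, g[:t], np.inf))
            if g[t] + lam >= -self.tol:  # KKT satisfied: keep the solution
                continue
            alpha = solve_simplex_box_qp(
                2.0 * Kt, -np.diag(Kt), C, tol=self.tol, alpha0=alpha
            )
        return self._finish(X, K, alpha, C)


class NuSVM(OneClassModel):
    """One-class nu-SVM (hyperplane description) with a Gaussian kernel."""

    family = "boundary"
    name = "nu_svm"

    def __init__(self, sigma: float = 0.4, nu: float = 0.05, tol: float = 1e-6):
        if not 0 < nu < 1:
            raise ValueError("nu must be in (0, 1)")
        self.sigma = sigma
        self.nu = nu
        self.tol = tol

    def fit(self, X: np.ndarray) -> "NuSVM":
        X = np.asarray(X, dtype=float)
        n = len(X)
        if n < 2:
            raise ValueError("need at least 2 training objects")
        K = rbf_kernel(X, X, self.sigma)
        C = 1.0 / (self.nu * n)
        alpha = solve_simplex_box_qp(K, np.zeros(n), C, tol=self.tol)
        self._X = X
        self.alpha_ = alpha
        self.dual_objective_ = qp_objective(K, np.zeros(n), alpha)
        g = K @ alpha
        margin = (alpha > 1e-8 * C) & (alpha < C - 1e-8 * C)
        if margin.any():
            self.rho_ = float(np.mean(g[margin]))
        else:
            lo = np.max(g[alpha > _EPS]) if (alpha > _EPS).any() else np.min(g)
            hi = np.min(g[alpha < C - _EPS]) if (alpha < C - _EPS).any() else np.max(g)
            self.rho_ = float(0.5 * (lo + hi))
        return self

    def score(self, Z: np.ndarray) -> np.ndarray:
        self._check_fitted()
        Z = self._check_dim(Z)
        return self.rho_ - rbf_kernel(Z, self._X, self.sigma) @ self.alpha_


class NNDescription(OneClassModel):
    """Nearest-neighbour data description.

    score(z) = ||z - NN(z)|| / ||NN(z) - NN(NN(z))||: the distance to the
    nearest training point, normalised by that point's own nearest-neighbour
    distance.  A zero denominator gives 0 when the numerator is also 0
    (duplicate of a duplicated point) and +inf otherwise.
    """

    family = "boundary"
    name = "nn_d"

    def fit(self, X: np.ndarray) -> "NNDescription":
        X = np.asarray(X, dtype=float)
        if len(X) < 2:
            raise ValueError("need at least 2 training objects")
        self._X = X
        self._nn = NearestNeighbors(n_neighbors=2).fit(X)
        # Each training point's distance to its nearest *other* point.
        d, _ = self._nn.kneighbors(X)
        self._own_nn_dist = d[:, 1]
        return self

    @staticmethod
    def _ratio(num: np.ndarray, den: np.ndarray) -> np.ndarray:
        out = np.empty(num.shape)
        zero = den <= 0
        out[~zero] = num[~zero] / den[~zero]
        out[zero] = np.where(num[zero] <= 0, 0.0, np.inf)
        return out

    def score(self, Z: np.ndarray) -> np.ndarray:
        self._check_fitted()
        Z = self._check_dim(Z)
        d, idx = self._nn.kneighbors(Z, n_neighbors=1)
        return self._ratio(d[:, 0], self._own_nn_dist[idx[:, 0]])

    def train_scores(self) -> np.ndarray:
        # Self-excluded: a training point's "nearest neighbour" is its
        # nearest other training point.
        d, idx = self._nn.kneighbors(self._X)
        return self._ratio(d[:, 1], self._own_nn_dist[idx[:, 1]])


class MSTDescription(OneClassModel):
    """Minimum-spanning-tree data description using the entire tree.

    The domain is the union of the MST edges (as line segments); the score of
    a point is its Euclidean distance to the nearest point on any edge, so
    training points and points on edges score 0.
    """

    family = "boundary"
    name = "mst"

    def fit(self, X: np.ndarray) -> "MSTDescription":
        X = np.asarray(X, dtype=float)
        if len(X) < 2:
            raise ValueError("need at least 2 training objects")
        self._X = X
        D = cdist(X, X)
        tree = minimum_spanning_tree(D).tocoo()
        self.edges_ = np.column_stack([tree.row, tree.col]).astype(int)
        return self

    def score(self, Z: np.ndarray) -> np.ndarray:
        self._check_fitted()
        Z = self._check_dim(Z)
        P1 = self._X[self.edges_[:, 0]]  # (m, d)
        P2 = self._X[self.edges_[:, 1]]
        d = P2 - P1
        len2 = np.maximum(np.einsum("md,md->m", d, d), _EPS)
        # t: projection parameter of each z onto each segment, clipped.
        diff = Z[:, None, :] - P1[None, :, :]  # (n, m, d)
        t = np.clip(np.einsum("nmd,md->nm", diff, d) / len2, 0.0, 1.0)
        proj = P1[None, :, :] + t[:, :, None] * d[None, :, :]
        dist = np.linalg.norm(Z[:, None, :] - proj, axis=2)
        return dist.min(axis=1)
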