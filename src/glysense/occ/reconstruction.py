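"""Reconstruction-based one-class models: score = reconstruction error.

* :class:`PCAOCC` keeps the minimal set of leading principal components whose
  cumulative explained variance reaches ``variance_fraction`` (default 0.67)
  and scores the squared distance to the retained subspace.
* :class:`KMeansOCC` scores the Euclidean distance to the nearest centroid.
* :class:`SOMOCC` trains a rectangular self-organising map by the batch rule
  with a linearly shrinking Gaussian neighbourhood and scores the distance to
  the best-matching prototype.
* :class:`AutoencoderOCC` is a small single-hidden-layer network (sigmoid
  hidden units, linear output) trained by full-batch gradient descent with
  momentum; the score is the squared reconstruction error.

All stochastic fits are seeded and run-to-run deterministic.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.cluster import KMeans

from .core import OneClassModel


class PCAOCC(OneClassModel):
    """Principal-component description (squared residual to the subspace)."""

    family = "reconstruction"
    name = "pca"

    def __init__(self, variance_fraction: float = 0.67):
        if not 0 < variance_fraction <= 1:
            raise ValueError("variance_fraction must be in (0, 1]")
        self.variance_fraction = variance_fraction

    def fit(self, X: np.ndarray) -> "PCAOCC":
        X = np.asarray(X, dtype=float)
        if len(X) < 2:
            raise ValueError("need at least 2 training objects")
        self._X = X
        self.mean_ = X.mean(axis=0)
        _, s, Vt = np.linalg.svd(X - self.mean_, full_matrices=False)
        var = s**2
        total = var.sum()
        if total <= 0:
            raise ValueError("zero-variance data: nothing to retain")
        ratios = np.cumsum(var) / total
        self.n_components_ = int(np.searchsorted(ratios, self.variance_fraction - 1e-12) + 1)
        self.explained_variance_ratio_ = var / total
        self.components_ = Vt[: self.n_components_]
        return self

    def score(self, Z: np.ndarray) -> np.ndarray:
        self._check_fitted()
        Z = self._check_dim(Z) - self.mean_
        proj = (Z @ self.components_.T) @ self.components_
        return np.sum((Z - proj) ** 2, axis=1)


class KMeansOCC(OneClassModel):
    """K-means description (distance to the nearest centroid)."""

    family = "reconstruction"
    name = "kmeans"

    def __init__(self, k: int = 5, seed: int = 0, n_init: int = 3):
        if k < 1:
            raise ValueError("k must be >= 1")
        self.k = k
        self.seed = seed
        self.n_init = n_init

    def fit(self, X: np.ndarray) -> "KMeansOCC":
        X = np.asarray(X, dtype=float)
        if len(X) < self.k:
            raise ValueError(f"k={self.k} exceeds n={len(X)}")
        self._X = X
        km = KMeans(
            n_clusters=self.k, init="k-means++", n_init=self.n_init,
            random_state=self.seed,
        ).fit(X)
        self.centroids_ = km.cluster_centers_
        self.inertia_ = float(km.inertia_)
        return self

    def score(self, Z: np.ndarray) -> np.ndarray:
        self._check_fitted()
        Z = self._check_dim(Z)
        return cdist(Z, self.centroids_).min(axis=1)


class SOMOCC(OneClassModel):
    """Self-organising-map description (distance to the best prototype).

    Batch SOM on a rectangular grid: every epoch each prototype moves to the
    neighbourhood-weighted mean of the data, with the Gaussian neighbourhood
    radius shrinking linearly from half the grid diagonal to 0.5.
    """

    family = "reconstruction"
    name = "som"

    def __init__(self, grid: tuple[int, int] = (5, 5), epochs: int = 100,
                 seed: int = 0):
        if min(grid) < 1:
            raise ValueError("grid dimensions must be >= 1")
        self.grid = tuple(grid)
        self.epochs = epochs
        self.seed = seed

    def fit(self, X: np.ndarray) -> "SOMOCC":
        X = np.asarray(X, dtype=float)
        if len(X) < 2:
            raise ValueError("need at least 2 training objects")
        self._X = X
        rng = np.random.default_rng(self.seed)
        rows, cols = self.grid
        m = rows * cols
        # Grid coordinates of each prototype, for the neighbourhood kernel.
        gx, gy = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
        coords = np.column_stack([gx.ravel(), gy.ravel()]).astype(float)
        grid_d2 = cdist(coords, coords, "sqeuclidean")
        proto = X[rng.choice(len(X), size=m, replace=len(X) < m)]
        proto = proto + rng.normal(0.0, 1e-6, proto.shape)  # break duplicates
        sigma0 = max(np.hypot(rows - 1, cols - 1) / 2.0, 0.5)
        for epoch in range(self.epochs):
            frac = epoch / max(self.epochs - 1, 1)
            sigma = sigma0 + (0.5 - sigma0) * frac
            bmu = cdist(X, proto, "sqeuclidean").argmin(axis=1)
            H = np.exp(-grid_d2[bmu] / (2.0 * sigma**2))  # (n, m)
            weight = H.sum(axis=0)
            upd = H.T @ X
            nonzero = weight > 1e-12
            proto[nonzero] = upd[nonzero] / weight[nonzero, None]
        self.prototypes_ = proto
        return self

    def score(self, Z: np.ndarray) -> np.ndarray:
        self._check_fitted()
        Z = self._check_dim(Z)
        return cdist(Z, self.prototypes_).min(axis=1)


class AutoencoderOCC(OneClassModel):
    """Tiny autoencoder description (squared reconstruction error).

    A single hidden layer of sigmoid units with a linear readout suffices for
    the 2-D inputs used here; training is full-batch gradient descent with
    momentum on the mean squared error, deterministically seeded.
    """

    family = "reconstruction"
    name = "autoencoder"

    def __init__(self, hidden: int = 3, epochs: int = 500, lr: float = 0.2,
                 momentum: float = 0.9, seed: int = 0):
        if hidden < 1:
            raise ValueError("hidden must be >= 1")
        self.hidden = hidden
        self.epochs = epochs
        self.lr = lr
        self.momentum = momentum
        self.seed = seed

    @staticmethod
    def _sigmoid(x: np.ndarray) -> np.ndarray:
        return 1.0 / (1.0 + np.exp(-np.clip(x, -30, 30)))

    def fit(self, X: np.ndarray) -> "AutoencoderOCC":
        X = np.asarray(X, dtype=float)
        if len(X) < 2:
            raise ValueError("need at least 2 training objects")
        self._X = X
        # Standardise internally so the learning rate is scale-free.
        self._mu = X.mean(axis=0)
        self._sd = np.where(X.std(axis=0) > 0, X.std(axis=0), 1.0)
        Xs = (X - self._mu) / self._sd
        n, d = Xs.shape
        rng = np.random.default_rng(self.seed)
        W1 = rng.normal(0.0, 1.0 / np.sqrt(d), (d, self.hidden))
        b1 = np.zeros(self.hidden)
        W2 = rng.normal(0.0, 1.0 / np.sqrt(self.hidden), (self.hidden, d))
        b2 = np.zeros(d)
        vel = [np.zeros_like(p) for p in (W1, b1, W2, b2)]
        for _ in range(self.epochs):
            H = self._sigmoid(Xs @ W1 + b1)
            Y = H @ W2 + b2
            err = Y - Xs  # (n, d)
            gW2 = H.T @ err / n
            gb2 = err.mean(axis=0)
            dH = (err @ W2.T) * H * (1.0 - H)
            gW1 = Xs.T @ dH / n
            gb1 = dH.mean(axis=0)
            for p, v, g in zip((W1, b1, W2, b2), vel, (gW1, gb1, gW2, gb2)):
                v *= self.momentum
                v -= self.lr * g
                p += v
        self._params = (W1, b1, W2, b2)
        return self

    def _reconstruct(self, Z: np.ndarray) -> np.ndarray:
        W1, b1, W2, b2 = self._params
        Zs = (Z - self._mu) / self._sd
        return self._sigmoid(Zs @ W1 + b1) @ W2 + b2

    def score(self, Z: np.ndarray) -> np.ndarray:
        self._check_fitted()
        Z = self._check_dim(Z)
        Zs = (Z - self._mu) / self._sd
        return np.sum((self._reconstruct(Z) - Zs) ** 2, axis=1)
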