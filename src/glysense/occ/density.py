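"""Density-based one-class models.

Scores are oriented so that higher = more anomalous: Mahalanobis distances
for the Gaussian family, negative log-likelihoods for the mixture and Parzen
families, neighbour distances for K-NN and the local outlier factor for LOF.
When scoring the *training* set (threshold calibration) the neighbour- and
kernel-based models exclude each point from its own neighbourhood, otherwise
e.g. the 1-NN training score would be identically zero and calibration would
collapse.
"""

from __future__ import annotations

import numpy as np
from scipy.special import logsumexp
from scipy.spatial.distance import cdist
from sklearn.covariance import MinCovDet
from sklearn.mixture import GaussianMixture
from sklearn.neighbors import LocalOutlierFactor, NearestNeighbors

from ..model_selection import loo_bandwidth, loo_bandwidth_per_dim
from .core import OneClassModel


class GaussianOCC(OneClassModel):
    """Normal Gaussian description: squared Mahalanobis distance score."""

    family = "density"
    name = "gaussian"

    def __init__(self, reg: float = 0.0):
        self.reg = reg

    def _fit_gauss(self, X: np.ndarray, mean: np.ndarray, cov: np.ndarray):
        cov = cov + self.reg * np.eye(X.shape[1])
        cond = np.linalg.cond(cov)
        if not np.isfinite(cond) or cond > 1e12:
            raise ValueError(
                "singular covariance; set a positive regularization reg"
            )
        self._X = X
        self.mean_ = mean
        self.cov_ = cov
        self._prec = np.linalg.inv(cov)
        return self

    def fit(self, X: np.ndarray) -> "GaussianOCC":
        X = np.asarray(X, dtype=float)
        if len(X) <= X.shape[1] and self.reg == 0:
            raise ValueError("n must exceed the dimension (or set reg > 0)")
        return self._fit_gauss(X, X.mean(axis=0), np.cov(X, rowvar=False))

    def score(self, Z: np.ndarray) -> np.ndarray:
        self._check_fitted()
        Z = self._check_dim(Z)
        diff = Z - self.mean_
        return np.einsum("nd,de,ne->n", diff, self._prec, diff)


class MCDGaussianOCC(GaussianOCC):
    """Gaussian description with FastMCD robust mean/covariance.

    The minimum covariance determinant estimate downweights contaminated
    training objects so a few outliers in the "normal" year do not inflate
    the description.
    """

    name = "mcd_gaussian"

    def __init__(self, support_fraction: float = 0.75, reg: float = 0.0,
                 seed: int = 0):
        super().__init__(reg=reg)
        self.support_fraction = support_fraction
        self.seed = seed

    def fit(self, X: np.ndarray) -> "MCDGaussianOCC":
        X = np.asarray(X, dtype=float)
        mcd = MinCovDet(
            support_fraction=self.support_fraction, random_state=self.seed
        ).fit(X)
        return self._fit_gauss(X, mcd.location_, mcd.covariance_)


class MixtureOCC(OneClassModel):
    """Mixture-of-Gaussians description: negative log-likelihood score."""

    family = "density"
    name = "mog"

    def __init__(self, m: int = 2, seed: int = 0, n_init: int = 10,
                 max_iter: int = 200, tol: float = 1e-6,
                 reg_covar: float = 1e-6):
        if m < 1:
            raise ValueError("m must be >= 1")
        self.m = m
        self.seed = seed
        self.n_init = n_init
        self.max_iter = max_iter
        self.tol = tol
        self.reg_covar = reg_covar

    def fit(self, X: np.ndarray) -> "MixtureOCC":
        X = np.asarray(X, dtype=float)
        self._X = X
        self._gmm = GaussianMixture(
            n_components=self.m,
            covariance_type="full",
            n_init=self.n_init,
            max_iter=self.max_iter,
            tol=self.tol,
            reg_covar=self.reg_covar,
            random_state=self.seed,
        ).fit(X)
        return self

    def score(self, Z: np.ndarray) -> np.ndarray:
        self._check_fitted()
        Z = self._check_dim(Z)
        return -self._gmm.score_samples(Z)


def _log_kde(sq_dists: np.ndarray, h: float, d: int, n_kernels: int) -> np.ndarray:
    """log of a spherical-Gaussian KDE given squared distances (n, n_kernels)."""
    log_norm = np.log(n_kernels) + 0.5 * d * np.log(2.0 * np.pi * h**2)
    return logsumexp(-sq_dists / (2.0 * h**2), axis=1) - log_norm


class ParzenOCC(OneClassModel):
    """Parzen window description with a shared spherical Gaussian kernel.

    The bandwidth ``h`` defaults to the leave-one-out maximum-likelihood
    choice on the training data.  Training scores are leave-one-out
    (each point excluded from its own kernel sum).
    """

    family = "density"
    name = "parzen"

    _chunk = 512  # score in blocks to bound the pairwise-distance memory

    def __init__(self, h: float | None = None):
        if h is not None and h <= 0:
            raise ValueError("bandwidth h must be positive")
        self.h = h

    def fit(self, X: np.ndarray) -> "ParzenOCC":
        X = np.asarray(X, dtype=float)
        if len(X) < 2:
            raise ValueError("need at least 2 training objects")
        self._X = X
        self.h_ = float(self.h) if self.h is not None else loo_bandwidth(X)
        return self

    def _neg_log_density(self, Z: np.ndarray, exclude_self: bool) -> np.ndarray:
        n, d = self._X.shape
        out = np.empty(len(Z))
        n_kernels = n - 1 if exclude_self else n
        for start in range(0, len(Z), self._chunk):
            block = Z[start:start + self._chunk]
            sq = cdist(block, self._X, "sqeuclidean")
            if exclude_self:
                idx = np.arange(start, start + len(block))
                sq[np.arange(len(block)), idx] = np.inf
            out[start:start + len(block)] = -_log_kde(sq, self.h_, d, n_kernels)
        return out

    def score(self, Z: np.ndarray) -> np.ndarray:
        self._check_fitted()
        return self._neg_log_density(self._check_dim(Z), exclude_self=False)

    def train_scores(self) -> np.ndarray:
        self._check_fitted()
        return self._neg_log_density(self._X, exclude_self=True)


class NaiveParzenOCC(OneClassModel):
    """Naive (independence) Parzen: product of per-dimension 1-D KDEs.

    Each dimension gets its own leave-one-out-selected bandwidth; the score
    is the negative sum of per-dimension log-densities.
    """

    family = "density"
    name = "naive_parzen"

    def __init__(self, h: np.ndarray | None = None):
        self.h = h

    def fit(self, X: np.ndarray) -> "NaiveParzenOCC":
        X = np.asarray(X, dtype=float)
        if len(X) < 2:
            raise ValueError("need at least 2 training objects")
        self._X = X
        if self.h is not None:
            self.h_ = np.asarray(self.h, dtype=float)
            if self.h_.shape != (X.shape[1],) or np.any(self.h_ <= 0):
                raise ValueError("h must be one positive bandwidth per dimension")
        else:
            self.h_ = loo_bandwidth_per_dim(X)
        return self

    def _neg_log_density(self, Z: np.ndarray, exclude_self: bool) -> np.ndarray:
        n = len(self._X)
        n_kernels = n - 1 if exclude_self else n
        total = np.zeros(len(Z))
        for j in range(self._X.shape[1]):
            sq = (Z[:, j][:, None] - self._X[:, j][None, :]) ** 2
            if exclude_self:
                sq[np.arange(len(Z)), np.arange(len(Z))] = np.inf
            total -= _log_kde(sq, float(self.h_[j]), 1, n_kernels)
        return total

    def score(self, Z: np.ndarray) -> np.ndarray:
        self._check_fitted()
        return self._neg_log_density(self._check_dim(Z), exclude_self=False)

    def train_scores(self) -> np.ndarray:
        self._check_fitted()
        return self._neg_log_density(self._X, exclude_self=True)


class KNNOCC(OneClassModel):
    """K-nearest-neighbour description: distance to the k-th training point."""

    family = "density"
    name = "knn"

    def __init__(self, k: int = 5):
        if k < 1:
            raise ValueError("k must be >= 1")
        self.k = k

    def fit(self, X: np.ndarray) -> "KNNOCC":
        X = np.asarray(X, dtype=float)
        if len(X) <= self.k:
            raise ValueError(f"need more than k={self.k} training objects")
        self._X = X
        self._nn = NearestNeighbors(n_neighbors=self.k + 1).fit(X)
        return self

    def score(self, Z: np.ndarray) -> np.ndarray:
        self._check_fitted()
        Z = self._check_dim(Z)
        d, _ = self._nn.kneighbors(Z, n_neighbors=self.k)
        return d[:, -1]

    def train_scores(self) -> np.ndarray:
        # k-th neighbour excluding the point itself.
        d, _ = self._nn.kneighbors(self._X, n_neighbors=self.k + 1)
        return d[:, -1]


class LOFOCC(OneClassModel):
    """One-class local outlier factor.

    LOF computed against the training set only: a test point is never
    inserted into the neighbour sets of the training points.  Training scores
    come from the fit (each training point excluded from its own
    neighbourhood).
    """

    family = "density"
    name = "lof"

    def __init__(self, k: int = 10):
        if k < 1:
            raise ValueError("k must be >= 1")
        self.k = k

    def fit(self, X: np.ndarray) -> "LOFOCC":
        X = np.asarray(X, dtype=float)
        if len(X) <= self.k:
            raise ValueError(f"need more than k={self.k} training objects")
        self._X = X
        self._lof = LocalOutlierFactor(n_neighbors=self.k, novelty=True).fit(X)
        return self

    def score(self, Z: np.ndarray) -> np.ndarray:
        self._check_fitted()
        Z = self._check_dim(Z)
        return -self._lof.score_samples(Z)

    def train_scores(self) -> np.ndarray:
        return -self._lof.negative_outlier_factor_
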