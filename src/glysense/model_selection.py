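"""Hyperparameter selection for one-class models.

Two selection schemes are provided:

* **Consistency selection** — among a grid of candidate hyperparameter
  values ordered from least to most complex, pick the most complex candidate
  whose cross-validated target-rejection rate stays within one binomial
  standard error of the design outlier fraction beta.  The intuition: make
  the description as tight as the data supports without rejecting more
  normal days than the design allows.
* **Leave-one-out likelihood** — for the Parzen family, the kernel bandwidth
  maximising the leave-one-out log-likelihood over a log-spaced grid (the
  naive variant optimises each dimension independently).

``fit_with_selection`` is the single entry point the evaluation protocol
uses: it knows each model's default grid and complexity ordering and returns
a fitted model with its hyperparameter chosen inside the supplied training
data only.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np
from scipy.special import logsumexp
from sklearn.model_selection import KFold


def consistency_select(
    factory: Callable[[object], "OneClassModel"],
    grid: Sequence,
    X: np.ndarray,
    beta: float,
    n_folds: int = 5,
    seed: int = 0,
) -> tuple[object, np.ndarray]:
    """Pick the most complex candidate whose rejection rate is consistent.

    ``grid`` must be ordered least -> most complex.  For each candidate the
    target-rejection rate is estimated by ``n_folds``-fold cross-validation
    on the target data with thresholds calibrated at ``beta`` on the
    training part; the chosen candidate is the most complex one whose rate
    does not exceed ``beta + sqrt(beta (1 - beta) / n)``.  If none
    qualifies the least complex candidate is returned.

    Returns ``(chosen_value, rejection_rates)``.
    """
    from .occ.core import calibrate_threshold

    grid = list(grid)
    if not grid:
        raise ValueError("empty hyperparameter grid")
    X = np.asarray(X, dtype=float)
    n = len(X)
    kf = KFold(n_splits=n_folds, shuffle=True, random_state=seed % 2**31)
    splits = list(kf.split(X))
    rates = np.empty(len(grid))
    for g, value in enumerate(grid):
        rejected = 0
        for tr, te in splits:
            model = factory(value).fit(X[tr])
            thr = calibrate_threshold(model.train_scores(), beta)
            rejected += int(np.sum(model.score(X[te]) > thr))
        rates[g] = rejected / n
    tol = beta + np.sqrt(beta * (1.0 - beta) / n)
    ok = np.flatnonzero(rates <= tol)
    chosen = grid[ok[-1]] if ok.size else grid[0]
    return chosen, rates


def _loo_loglik_1d_sq(sq: np.ndarray, h_grid: np.ndarray, d: int) -> np.ndarray:
    """LOO log-likelihoods for each bandwidth given squared distances (n, n)."""
    n = sq.shape[0]
    sq = sq.copy()
    np.fill_diagonal(sq, np.inf)
    lls = np.empty(len(h_grid))
    for i, h in enumerate(h_grid):
        log_p = (
            logsumexp(-sq / (2.0 * h**2), axis=1)
            - np.log(n - 1)
            - 0.5 * d * np.log(2.0 * np.pi * h**2)
        )
        lls[i] = log_p.sum()
    return lls


def _default_h_grid(scale: float, num: int = 40) -> np.ndarray:
    scale = max(scale, 1e-12)
    return np.geomspace(scale * 1e-2, scale * 10.0, num)


def loo_bandwidth(X: np.ndarray, grid: np.ndarray | None = None) -> float:
    """Shared spherical-kernel bandwidth maximising the LOO log-likelihood."""
    from scipy.spatial.distance import cdist

    X = np.asarray(X, dtype=float)
    if len(X) < 2:
        raise ValueError("need at least 2 points for leave-one-out selection")
    sq = cdist(X, X, "sqeuclidean")
    if np.all(sq < 1e-24):
        raise ValueError("degenerate data: all points identical")
    if grid is None:
        grid = _default_h_grid(float(np.std(X)))
    lls = _loo_loglik_1d_sq(sq, np.asarray(grid, dtype=float), X.shape[1])
    return float(grid[int(np.argmax(lls))])


def loo_bandwidth_per_dim(X: np.ndarray, grid: np.ndarray | None = None) -> np.ndarray:
    """Per-dimension LOO-optimal bandwidths (naive Parzen)."""
    X = np.asarray(X, dtype=float)
    hs = np.empty(X.shape[1])
    for j in range(X.shape[1]):
        col = X[:, j:j + 1]
        g = grid if grid is not None else _default_h_grid(float(np.std(col)))
        sq = (col - col.T) ** 2
        if np.all(sq < 1e-24):
            raise ValueError(f"degenerate data in dimension {j}")
        lls = _loo_loglik_1d_sq(sq, np.asarray(g, dtype=float), 1)
        hs[j] = g[int(np.argmax(lls))]
    return hs


#: Default consistency grids, ordered least -> most complex.  Kernel widths
#: shrink (tighter boundary = more complex); neighbour counts shrink (more
#: local = more complex); cluster/component counts grow.
_SIGMA_GRID = [1.6, 0.8, 0.4, 0.2, 0.1, 0.05]
_KMEANS_GRID = list(range(2, 11))
_MOG_GRID = [1, 2, 3, 4]


def _neighbor_grid(n: int) -> list[int]:
    kmax = max(min(25, n // 2), 1)
    return list(range(kmax, 0, -1))


def fit_with_selection(
    name: str,
    X: np.ndarray,
    beta: float,
    seed: int = 0,
    params: dict | None = None,
):
    """Fit a one-class model by name, selecting hyperparameters on ``X``.

    ``params`` overrides the model's tunable hyperparameter(s) and skips
    selection for them.  Models without a free hyperparameter (NN-d, MST —
    the entire tree is used — Gaussian, MCD-Gaussian, PCA at its fixed
    variance fraction, SOM, autoencoder) are fitted directly; the Parzen
    family uses leave-one-out bandwidths internally; everything else goes
    through consistency selection on its default grid.
    """
    from .occ import boundary, density, reconstruction

    params = dict(params or {})
    X = np.asarray(X, dtype=float)
    n = len(X)
    seed = int(seed) % 2**31

    def select(factory, grid):
        value, _ = consistency_select(factory, grid, X, beta, seed=seed)
        return factory(value).fit(X)

    if name in ("svdd", "inc_svdd", "nu_svm"):
        cls = {"svdd": boundary.SVDD, "inc_svdd": boundary.IncSVDD,
               "nu_svm": boundary.NuSVM}[name]
        extra = {k: v for k, v in params.items() if k != "sigma"}
        if "sigma" in params:
            return cls(sigma=params["sigma"], **extra).fit(X)
        return select(lambda s: cls(sigma=s, **extra), _SIGMA_GRID)
    if name == "nn_d":
        return boundary.NNDescription().fit(X)
    if name == "mst":
        return boundary.MSTDescription().fit(X)
    if name == "gaussian":
        return density.GaussianOCC(**params).fit(X)
    if name == "mcd_gaussian":
        return density.MCDGaussianOCC(seed=seed, **params).fit(X)
    if name == "mog":
        if "m" in params:
            return density.MixtureOCC(seed=seed, **params).fit(X)
        return select(lambda m: density.MixtureOCC(m=m, seed=seed, **params),
                      _MOG_GRID)
    if name == "parzen":
        return density.ParzenOCC(**params).fit(X)
    if name == "naive_parzen":
        return density.NaiveParzenOCC(**params).fit(X)
    if name in ("knn", "lof"):
        cls = {"knn": density.KNNOCC, "lof": density.LOFOCC}[name]
        if "k" in params:
            return cls(k=params["k"]).fit(X)
        return select(lambda k: cls(k=k), _neighbor_grid(n))
    if name == "pca":
        return reconstruction.PCAOCC(**params).fit(X)
    if name == "kmeans":
        if "k" in params:
            return reconstruction.KMeansOCC(seed=seed, **params).fit(X)
        grid = [k for k in _KMEANS_GRID if k <= (n * 4) // 5]  # fits CV folds
        return select(lambda k: reconstruction.KMeansOCC(k=k, seed=seed), grid)
    if name == "som":
        return reconstruction.SOMOCC(seed=seed, **params).fit(X)
    if name == "autoencoder":
        return reconstruction.AutoencoderOCC(seed=seed, **params).fit(X)
    raise ValueError(f"unknown model name {name!r}")


#: Model roster by family, in report order.
MODEL_FAMILIES = {
    "boundary": ["svdd", "inc_svdd", "nu_svm", "nn_d", "mst"],
    "density": ["gaussian", "mcd_gaussian", "mog", "parzen", "naive_parzen",
                "knn", "lof"],
    "reconstruction": ["pca", "kmeans", "som", "autoencoder"],
}

ALL_MODELS = [m for fam in MODEL_FAMILIES.values() for m in fam]
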