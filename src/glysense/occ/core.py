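"""Common one-class classification contract.

Every model in :mod:`glysense.occ` exposes ``fit(X)`` on target-only data and
``score(Z)`` returning anomaly scores with a uniform orientation: **higher
score = more anomalous** (density models return negative log-likelihoods).
A fitted model plus a decision threshold calibrated so that a fraction
``beta`` of the training target objects would be rejected forms a
:class:`FittedOCC`; objects scoring strictly above the threshold are
classified nontarget.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..features import NONTARGET, TARGET

#: Default training outlier fraction: 1% of the training target objects are
#: allowed to be rejected when the threshold is calibrated.
DEFAULT_BETA = 0.01


class OneClassModel:
    """Base class for one-class models (target-only fit, anomaly score)."""

    family: str = "unspecified"
    name: str = "unspecified"

    def fit(self, X: np.ndarray) -> "OneClassModel":  # pragma: no cover
        raise NotImplementedError

    def score(self, Z: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def train_scores(self) -> np.ndarray:
        """Anomaly scores of the training objects, for threshold calibration.

        Neighbour- and kernel-based models override this to exclude each
        training point from its own neighbourhood; the default rescoring is
        correct for parametric models.
        """
        return self.score(self._X)

    def _check_fitted(self) -> None:
        if not hasattr(self, "_X"):
            raise RuntimeError(f"{self.name}: fit before scoring")

    def _check_dim(self, Z: np.ndarray) -> np.ndarray:
        Z = np.atleast_2d(np.asarray(Z, dtype=float))
        if Z.shape[1] != self._X.shape[1]:
            raise ValueError(
                f"dimension mismatch: model fitted on {self._X.shape[1]}-d "
                f"data, got {Z.shape[1]}-d"
            )
        return Z


@dataclass
class FittedOCC:
    """A trained one-class model with its calibrated decision rule."""

    model: OneClassModel
    threshold: float
    beta: float

    @property
    def family(self) -> str:
        return self.model.family

    @property
    def name(self) -> str:
        return self.model.name

    def score(self, Z: np.ndarray) -> np.ndarray:
        return self.model.score(Z)

    def predict(self, Z: np.ndarray) -> np.ndarray:
        return classify(self.model.score(Z), self.threshold)


def calibrate_threshold(train_scores: np.ndarray, beta: float = DEFAULT_BETA) -> float:
    """Empirical (1 - beta)-quantile threshold on training anomaly scores.

    The threshold is the ``(n - floor(beta * n))``-th order statistic, so with
    distinct scores exactly ``floor(beta * n)`` training objects score
    strictly above it; ``beta = 0`` rejects nothing.
    """
    scores = np.asarray(train_scores, dtype=float)
    if scores.size == 0:
        raise ValueError("cannot calibrate a threshold on empty scores")
    if not np.all(np.isfinite(scores)):
        raise ValueError("training scores must be finite")
    if not 0 <= beta < 1:
        raise ValueError("beta must be in [0, 1)")
    n = scores.size
    n_reject = int(np.floor(beta * n))
    return float(np.sort(scores)[n - n_reject - 1])


def classify(scores: np.ndarray, threshold: float) -> np.ndarray:
    """Label scores: nontarget iff strictly above the threshold (ties pass)."""
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    scores = np.asarray(scores, dtype=float)
    return np.where(scores > threshold, NONTARGET, TARGET)


def fit_occ(model: OneClassModel, X: np.ndarray, beta: float = DEFAULT_BETA) -> FittedOCC:
    """Fit a model on target data and calibrate its threshold at ``beta``."""
    model.fit(np.asarray(X, dtype=float))
    threshold = calibrate_threshold(model.train_scores(), beta)
    return FittedOCC(model, threshold, beta)
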