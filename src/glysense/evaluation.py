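"""Cross-validated evaluation of the one-class detectors.

The protocol: the target (normal-day) objects are split into stratified
folds; in each of ``repetitions x folds`` rounds a model is trained on the
training folds' target objects only — optionally subsampled to emulate 1-4
months of data — with the min-max scaler and all hyperparameters fitted
inside the training part, and tested on the held-out target fold plus the
nontarget (infection) objects oversampled by random sampling with
replacement to the size of the held-out fold.  AUC, specificity and F1 are
aggregated as mean (SD) percentages over all rounds.

Metric conventions (asymmetric on purpose): specificity is the proportion of
nontarget (infection) objects correctly flagged; F1 treats the *target*
class as positive.  AUC ranks nontarget above target with half credit for
ties.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import KFold

from .features import NONTARGET, TARGET, LabeledDataset, apply_scaler, fit_scaler
from .model_selection import fit_with_selection
from .occ.core import DEFAULT_BETA, calibrate_threshold

#: Objects per month of data at daily granularity.
DAYS_PER_MONTH = 30

TIMING_SIZES = (240, 480, 720, 960, 1200, 1440, 1680, 1920, 2160, 2400, 2640, 2880)


@dataclass
class CVConfig:
    """Settings of the repeated stratified cross-validation protocol."""

    repetitions: int = 20
    folds: int = 5
    beta: float = DEFAULT_BETA
    oversample: bool = True
    seed: int = 0
    #: Training-fold subsample size in objects (None = use the full folds).
    sample_size: int | None = None

    def __post_init__(self) -> None:
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        if self.repetitions < 1:
            raise ValueError("repetitions must be >= 1")


def months_to_objects(months: int, granularity: str = "daily") -> int:
    """Objects corresponding to 1-4 months of data (30 days/month)."""
    per_day = 24 if granularity == "hourly" else 1
    return months * DAYS_PER_MONTH * per_day


@dataclass
class MetricsReport:
    """Per-round metrics of one model with mean (SD) summaries."""

    model: str
    table: pd.DataFrame  # one row per repetition x fold, columns auc/specificity/f1

    @property
    def mean(self) -> pd.Series:
        return self.table[["auc", "specificity", "f1"]].mean()

    @property
    def sd(self) -> pd.Series:
        return self.table[["auc", "specificity", "f1"]].std(ddof=1)

    def summary(self) -> dict[str, str]:
        """'mean (SD)' strings per metric, as reported in results tables."""
        return {
            m: f"{self.mean[m]:.1f} ({self.sd[m]:.1f})"
            for m in ("auc", "specificity", "f1")
        }


def oversample_nontarget(
    nontarget: np.ndarray, target_count: int, seed_or_rng=0
) -> np.ndarray:
    """Random oversampling with replacement up to ``target_count`` objects.

    When ``target_count >= n`` every original object appears at least once
    and the remainder is drawn with replacement; otherwise ``target_count``
    objects are drawn with replacement.
    """
    X = np.atleast_2d(np.asarray(nontarget, dtype=float))
    n = len(X)
    if n == 0:
        raise ValueError("no nontarget objects to oversample")
    rng = (
        seed_or_rng
        if isinstance(seed_or_rng, np.random.Generator)
        else np.random.default_rng(seed_or_rng)
    )
    if target_count >= n:
        extra = rng.integers(0, n, size=target_count - n)
        idx = np.concatenate([np.arange(n), extra])
    else:
        idx = rng.integers(0, n, size=target_count)
    rng.shuffle(idx)
    return X[idx]


def compute_metrics(
    scores: np.ndarray, labels: np.ndarray, threshold: float
) -> dict[str, float]:
    """AUC, specificity and F1 (all in %) from scores, labels and a threshold.

    AUC is the rank statistic with nontarget as the high-score class;
    specificity the fraction of nontarget objects scoring above the
    threshold; F1 the harmonic mean of precision and recall with target as
    the positive (accepted) class.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(set(labels.tolist())) < 2:
        raise ValueError("both target and nontarget objects are required")
    auc = roc_auc_score((labels == NONTARGET).astype(int), scores)

    accepted = scores <= threshold
    is_target = labels == TARGET
    tp = int(np.sum(accepted & is_target))
    fp = int(np.sum(accepted & ~is_target))
    fn = int(np.sum(~accepted & is_target))
    specificity = np.sum(~accepted & ~is_target) / np.sum(~is_target)
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return {
        "auc": 100.0 * auc,
        "specificity": 100.0 * float(specificity),
        "f1": 100.0 * f1,
    }


def run_cv(
    dataset: LabeledDataset,
    model: str,
    config: CVConfig | None = None,
    model_params: dict | None = None,
) -> MetricsReport:
    """Run the repeated-CV protocol for one model on a labelled dataset.

    The nontarget objects are never trained on; they are reused (oversampled)
    in the test set of every round.  Deterministic for a fixed
    ``config.seed``.
    """
    config = config or CVConfig()
    X = dataset.features
    Xt = X[dataset.labels == TARGET]
    Xn = X[dataset.labels == NONTARGET]
    if len(Xn) == 0:
        raise ValueError("no nontarget objects: nothing to detect")
    if len(Xt) < config.folds:
        raise ValueError("fewer target objects than folds")

    rows = []
    for rep in range(config.repetitions):
        kf = KFold(
            n_splits=config.folds,
            shuffle=True,
            random_state=(config.seed * 1_000_003 + rep) % 2**31,
        )
        for fold, (tr, te) in enumerate(kf.split(Xt)):
            rng = np.random.default_rng([config.seed, rep, fold])
            Xtr = Xt[tr]
            if config.sample_size is not None and config.sample_size < len(Xtr):
                pick = rng.choice(len(Xtr), size=config.sample_size, replace=False)
                Xtr = Xtr[pick]
            scaler = fit_scaler(Xtr)
            Xtr_s = apply_scaler(Xtr, scaler, clip=False)
            # No clipping: min-max scaling serves dimension comparability,
            # and squashing test objects into the training box would erase
            # the very excursions the detectors must see.
            Xte_s = apply_scaler(Xt[te], scaler, clip=False)
            n_over = len(te) if config.oversample else len(Xn)
            Xn_s = apply_scaler(
                oversample_nontarget(Xn, n_over, rng), scaler, clip=False
            )

            est = fit_with_selection(
                model, Xtr_s, config.beta,
                seed=int(rng.integers(2**31)), params=model_params,
            )
            thr = calibrate_threshold(est.train_scores(), config.beta)
            scores = np.concatenate([est.score(Xte_s), est.score(Xn_s)])
            labels = np.concatenate([
                np.full(len(te), TARGET), np.full(len(Xn_s), NONTARGET)
            ])
            row = compute_metrics(scores, labels, thr)
            row.update(repetition=rep, fold=fold)
            rows.append(row)
    return MetricsReport(model, pd.DataFrame(rows))


def timing_profile(
    model: str,
    sizes: tuple[int, ...] = TIMING_SIZES,
    runs: int = 3,
    seed: int = 0,
    model_params: dict | None = None,
) -> pd.DataFrame:
    """Wall-clock train/test durations on synthetic 2-D Gaussian data.

    Informational only — absolute numbers are hardware-dependent.  Returns
    one row per size with mean durations over ``runs`` runs.
    """
    rows = []
    for size in sizes:
        train_t, test_t = [], []
        for run in range(runs):
            rng = np.random.default_rng([seed, size, run])
            Xtr = rng.normal(size=(size, 2))
            Zte = rng.normal(size=(size, 2))
            t0 = time.perf_counter()
            est = fit_with_selection(model, Xtr, DEFAULT_BETA, seed=seed,
                                     params=model_params)
            t1 = time.perf_counter()
            est.score(Zte)
            t2 = time.perf_counter()
            train_t.append(t1 - t0)
            test_t.append(t2 - t1)
        rows.append({
            "size": size,
            "train_seconds": float(np.mean(train_t)),
            "test_seconds": float(np.mean(test_t)),
        })
    return pd.DataFrame(rows)
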