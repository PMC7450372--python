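"""Bivariate contextual features from an event log.

For each time bin k (a calendar day or a clock hour) the feature vector is

    x_k = (x_k1, x_k2)
    x_k1 = total bolus insulin / total carbohydrate in the bin,
    x_k2 = mean blood glucose over the readings in the bin (mg/dL),

followed by linear imputation of empty bins, an optional trailing 48-hour
moving average, and min-max scaling to [0, 1].  The insulin-to-carb ratio is
the ratio of bin *totals*, never an average of per-event ratios, so bins with
zero carbohydrate are flagged missing rather than infinite.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .events import EventLog

TARGET, NONTARGET = 0, 1

GRANULARITIES = ("daily", "hourly")

#: Moving-average window, in hours, used throughout.
SMOOTH_WINDOW_HOURS = 48


@dataclass
class FeatureSeries:
    """A contiguous time-indexed series of (ratio, mean BG) vectors.

    ``frame`` is indexed by bin start time with columns ``x1`` and ``x2``;
    missing bins are NaN until :func:`impute_missing` runs.  Provenance flags
    record what has been done to the series.
    """

    frame: pd.DataFrame
    granularity: str
    smoothed: bool = False
    scaled: bool = False
    scaler_params: dict[str, tuple[float, float]] | None = None

    def __post_init__(self) -> None:
        if self.granularity not in GRANULARITIES:
            raise ValueError(f"granularity must be one of {GRANULARITIES}")
        if list(self.frame.columns) != ["x1", "x2"]:
            raise ValueError("frame must have columns ['x1', 'x2']")

    @property
    def values(self) -> np.ndarray:
        """(n, 2) float array of feature vectors."""
        return self.frame.to_numpy(dtype=float)

    @property
    def samples_per_day(self) -> int:
        return 1 if self.granularity == "daily" else 24

    def __len__(self) -> int:
        return len(self.frame)


@dataclass
class LabeledDataset:
    """A feature series with per-bin target / nontarget labels."""

    series: FeatureSeries
    labels: np.ndarray  # 0 = target (normal), 1 = nontarget (infection)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.labels) != len(self.series):
            raise ValueError("labels and series lengths differ")

    @property
    def features(self) -> np.ndarray:
        return self.series.values

    @property
    def n_target(self) -> int:
        return int(np.sum(self.labels == TARGET))

    @property
    def n_nontarget(self) -> int:
        return int(np.sum(self.labels == NONTARGET))


def aggregate_bins(log: EventLog, granularity: str = "daily") -> FeatureSeries:
    """Aggregate an event log into (ratio, mean BG) bins.

    Daily bins are calendar days, hourly bins clock hours (half-open
    ``[start, start + bin)``).  Bins with zero carbohydrate (ratio undefined)
    or no BG reading are NaN, to be filled by :func:`impute_missing`.
    """
    if granularity not in GRANULARITIES:
        raise ValueError(f"granularity must be one of {GRANULARITIES}")
    if len(log.records) == 0:
        raise ValueError("event log is empty")
    freq = "D" if granularity == "daily" else "h"
    rec = log.records
    binned = rec["timestamp"].dt.floor(freq)
    bg = rec.loc[rec["channel"] == "bg"].groupby(binned)["value"].mean()
    bolus = rec.loc[rec["channel"] == "bolus"].groupby(binned)["value"].sum()
    carb = rec.loc[rec["channel"] == "carb"].groupby(binned)["value"].sum()

    # Bins cover whole calendar days (24 bins/day hourly).
    first = binned.min().normalize()
    last = binned.max().normalize()
    if granularity == "hourly":
        last = last + pd.Timedelta(hours=23)
    index = pd.date_range(first, last, freq=freq)
    if len(index) < 2:
        raise ValueError("log must span at least 2 bins")
    bolus = bolus.reindex(index)
    carb = carb.reindex(index)
    x1 = bolus / carb.where(carb > 0)  # zero-carb bins -> NaN, not inf
    x2 = bg.reindex(index)
    frame = pd.DataFrame({"x1": x1, "x2": x2}, index=index)
    return FeatureSeries(frame, granularity)


def impute_missing(series: FeatureSeries, max_missing: float = 0.5) -> FeatureSeries:
    """Fill missing bins: linear interpolation interior, nearest value at edges.

    Each dimension is imputed independently; interpolated values therefore lie
    between their neighbouring observations.  Raises if the fraction of
    missing bins in any dimension exceeds ``max_missing`` (default 0.5) —
    sparser series are considered too thin to analyse at that granularity.
    """
    frame = series.frame
    miss = frame.isna().mean()
    worst = float(miss.max())
    if worst > max_missing:
        raise ValueError(
            f"{worst:.0%} of bins missing (dimension {miss.idxmax()}); "
            f"more than the allowed {max_missing:.0%} — data too sparse"
        )
    filled = frame.interpolate(method="linear", limit_direction="both")
    return replace(series, frame=filled)


def smooth_series(
    series: FeatureSeries, window_hours: int = SMOOTH_WINDOW_HOURS
) -> FeatureSeries:
    """Trailing moving average over a ``window_hours`` window (default 48 h).

    The window is 2 samples at daily and 48 at hourly granularity.  The
    average is causal (uses the current and preceding bins only) so the
    series can drive prospective detection; the first bins are padded by
    partial averages (the first sample passes through unchanged).
    """
    if series.frame.isna().any().any():
        raise ValueError("impute before smoothing")
    window = max(1, window_hours * series.samples_per_day // 24)
    if window > len(series):
        raise ValueError(
            f"window of {window} samples longer than series of {len(series)}"
        )
    frame = series.frame.rolling(window, min_periods=1).mean()
    return replace(series, frame=frame, smoothed=True)


def scale_minmax(
    series: FeatureSeries,
    params: dict[str, tuple[float, float]] | None = None,
) -> FeatureSeries:
    """Min-max scale each dimension to [0, 1].

    Without ``params`` the per-dimension min/max are taken from the series
    itself and recorded in ``scaler_params``.  With ``params`` (e.g. fitted on
    a training fold) they are applied as-is and the result is clipped to
    [0, 1], so test data never leaks into the scaler.
    """
    if series.frame.isna().any().any():
        raise ValueError("impute before scaling")
    frame = series.frame.copy()
    fitted = params is None
    if fitted:
        params = {
            c: (float(frame[c].min()), float(frame[c].max())) for c in frame
        }
    for c in frame:
        lo, hi = params[c]
        if hi <= lo:
            raise ValueError(f"degenerate range in dimension {c}: min == max")
        frame[c] = (frame[c] - lo) / (hi - lo)
        if not fitted:
            frame[c] = frame[c].clip(0.0, 1.0)
    return replace(series, frame=frame, scaled=True, scaler_params=dict(params))


def unscale_minmax(series: FeatureSeries) -> FeatureSeries:
    """Invert :func:`scale_minmax` using the recorded scaler parameters."""
    if not series.scaled or series.scaler_params is None:
        raise ValueError("series is not scaled")
    frame = series.frame.copy()
    for c in frame:
        lo, hi = series.scaler_params[c]
        frame[c] = frame[c] * (hi - lo) + lo
    return replace(series, frame=frame, scaled=False, scaler_params=None)


def fit_scaler(X: np.ndarray) -> np.ndarray:
    """Per-column (min, max) of a raw feature array, shape (2, d)."""
    X = np.asarray(X, dtype=float)
    lo, hi = X.min(axis=0), X.max(axis=0)
    if np.any(hi <= lo):
        raise ValueError("degenerate feature range: min == max")
    return np.vstack([lo, hi])


def apply_scaler(X: np.ndarray, params: np.ndarray, clip: bool = True) -> np.ndarray:
    """Apply (min, max) scaling fitted by :func:`fit_scaler`, with clipping."""
    lo, hi = params
    out = (np.asarray(X, dtype=float) - lo) / (hi - lo)
    return np.clip(out, 0.0, 1.0) if clip else out


def build_dataset(series: FeatureSeries, log_or_periods) -> LabeledDataset:
    """Label each bin target / nontarget from the infection periods.

    A bin is nontarget exactly when its calendar day lies inside one of the
    (inclusive) infection periods.  Accepts an :class:`EventLog` or a bare
    list of ``(start, end)`` timestamps.
    """
    if isinstance(log_or_periods, EventLog):
        periods = log_or_periods.infection_periods
    else:
        periods = [(pd.Timestamp(s), pd.Timestamp(e)) for s, e in log_or_periods]
    days = series.frame.index.normalize()
    labels = np.full(len(series), TARGET)
    for start, end in periods:
        labels[(days >= start.normalize()) & (days <= end.normalize())] = NONTARGET
    return LabeledDataset(series, labels)
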