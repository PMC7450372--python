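"""Delimited-text formats for event logs and feature tables.

Event logs are CSV with header ``timestamp,channel,value`` (ISO-8601
timestamps; channels ``bg``/``bolus``/``carb``), accompanied by an
infection-periods CSV with header ``start,end`` (ISO dates, both endpoint
days inclusive).  Blood glucose is mg/dL internally; mmol/L inputs are
converted at ingestion.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .events import CHANNELS, MMOL_TO_MGDL, EventLog
from .features import LabeledDataset, FeatureSeries


def write_event_log(log: EventLog, path, periods_path=None) -> None:
    """Write an event log (and optionally its infection periods) as CSV."""
    out = log.records.copy()
    out["timestamp"] = out["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%S")
    out.to_csv(path, index=False)
    if periods_path is not None:
        rows = [
            {"start": s.strftime("%Y-%m-%d"), "end": e.strftime("%Y-%m-%d")}
            for s, e in log.infection_periods
        ]
        pd.DataFrame(rows, columns=["start", "end"]).to_csv(periods_path, index=False)


def read_event_log(path, periods_path=None, bg_unit: str = "mg/dL") -> EventLog:
    """Read an event log CSV (+ optional infection-periods CSV).

    ``bg_unit`` may be ``"mg/dL"`` (default) or ``"mmol/L"``; mmol/L glucose
    values are converted to mg/dL.  Malformed rows raise with their line
    number.
    """
    if bg_unit not in ("mg/dL", "mmol/L"):
        raise ValueError(f"unknown BG unit {bg_unit!r}")
    raw = pd.read_csv(path, dtype=str)
    expected = ["timestamp", "channel", "value"]
    if list(raw.columns) != expected:
        raise ValueError(f"{path}: expected header {expected}, got {list(raw.columns)}")
    ts = pd.to_datetime(raw["timestamp"], errors="coerce")
    val = pd.to_numeric(raw["value"], errors="coerce")
    for col, parsed in (("timestamp", ts), ("value", val)):
        bad = np.flatnonzero(parsed.isna().to_numpy())
        if bad.size:
            # +2: header line plus 1-based numbering.
            raise ValueError(f"{path}: malformed {col} on line {bad[0] + 2}")
    bad = np.flatnonzero(~raw["channel"].isin(CHANNELS).to_numpy())
    if bad.size:
        raise ValueError(
            f"{path}: unknown channel {raw['channel'].iloc[bad[0]]!r} "
            f"on line {bad[0] + 2}"
        )
    records = pd.DataFrame({"timestamp": ts, "channel": raw["channel"], "value": val})
    if bg_unit == "mmol/L":
        is_bg = records["channel"] == "bg"
        records.loc[is_bg, "value"] *= MMOL_TO_MGDL
    records = records.sort_values(["timestamp", "channel"], kind="stable")
    records = records.reset_index(drop=True)

    periods: list[tuple[pd.Timestamp, pd.Timestamp]] = []
    if periods_path is not None and Path(periods_path).exists():
        pf = pd.read_csv(periods_path, dtype=str)
        if len(pf) and list(pf.columns) != ["start", "end"]:
            raise ValueError(f"{periods_path}: expected header start,end")
        for i, row in pf.iterrows():
            s, e = pd.to_datetime(row["start"]), pd.to_datetime(row["end"])
            if pd.isna(s) or pd.isna(e) or e < s:
                raise ValueError(f"{periods_path}: malformed period on line {i + 2}")
            periods.append((s, e))
    return EventLog(records, periods)


def write_feature_table(dataset: LabeledDataset | FeatureSeries, path) -> None:
    """Write features as CSV with header ``k,x1,x2[,label]``."""
    series = dataset.series if isinstance(dataset, LabeledDataset) else dataset
    out = series.frame.copy()
    out.insert(0, "k", series.frame.index.strftime("%Y-%m-%dT%H:%M:%S"))
    if isinstance(dataset, LabeledDataset):
        out["label"] = np.where(dataset.labels == 1, "nontarget", "target")
    out.to_csv(path, index=False)


def read_feature_table(path) -> tuple[FeatureSeries, np.ndarray | None]:
    """Read a feature table written by :func:`write_feature_table`.

    Granularity is inferred from the index spacing.  Returns the series and
    the label array (None when the table is unlabelled).
    """
    raw = pd.read_csv(path, parse_dates=["k"]).set_index("k")
    labels = None
    if "label" in raw.columns:
        labels = (raw.pop("label") == "nontarget").astype(int).to_numpy()
    if list(raw.columns) != ["x1", "x2"]:
        raise ValueError(f"{path}: expected columns x1,x2 after k/label")
    step = raw.index[1] - raw.index[0] if len(raw) > 1 else pd.Timedelta(days=1)
    granularity = "hourly" if step <= pd.Timedelta(hours=1) else "daily"
    raw.index.name = None
    return FeatureSeries(raw, granularity), labels
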