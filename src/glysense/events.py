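"""Event-log container for self-recorded diabetes data.

An :class:`EventLog` holds one patient-year of time-stamped records on three
channels — blood glucose readings (``bg``, mg/dL), bolus insulin doses
(``bolus``, units) and carbohydrate intake (``carb``, grams) — together with
the self-reported infection periods (inclusive day intervals) that define the
nontarget class downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CHANNELS = ("bg", "bolus", "carb")

#: mg/dL per mmol/L for glucose (molar mass 180.16 g/mol).
MMOL_TO_MGDL = 18.016

#: Epoch used for synthetic patient-years; day index d maps to EPOCH + d days.
EPOCH = pd.Timestamp("2021-01-01")


@dataclass
class EventLog:
    """Time-stamped self-recorded events plus infection annotations.

    Parameters
    ----------
    records:
        DataFrame with columns ``timestamp`` (datetime64), ``channel``
        (one of ``bg``/``bolus``/``carb``) and ``value`` (float, positive).
    infection_periods:
        List of ``(start, end)`` timestamps; both endpoint *days* are part of
        the infection period (inclusive convention, so a 7-day episode
        starting on day 100 ends on day 106).
    """

    records: pd.DataFrame
    infection_periods: list[tuple[pd.Timestamp, pd.Timestamp]] = field(
        default_factory=list
    )

    def __post_init__(self) -> None:
        cols = set(self.records.columns)
        if not {"timestamp", "channel", "value"} <= cols:
            raise ValueError(
                "records must have columns timestamp, channel, value; got "
                f"{sorted(cols)}"
            )
        bad = set(self.records["channel"].unique()) - set(CHANNELS)
        if bad:
            raise ValueError(f"unknown channels: {sorted(bad)}")
        if (self.records["value"] <= 0).any():
            raise ValueError("record values must be positive")
        for ch in CHANNELS:
            ts = self.records.loc[self.records["channel"] == ch, "timestamp"]
            if not ts.is_monotonic_increasing:
                raise ValueError(f"timestamps not nondecreasing on channel {ch!r}")
        periods = sorted(self.infection_periods)
        for (s1, e1), (s2, _) in zip(periods, periods[1:]):
            if pd.Timestamp(s2).normalize() <= pd.Timestamp(e1).normalize():
                raise ValueError("infection periods overlap")
        self.infection_periods = [
            (pd.Timestamp(s), pd.Timestamp(e)) for s, e in periods
        ]

    def channel(self, name: str) -> pd.DataFrame:
        """Records of a single channel, time-ordered."""
        if name not in CHANNELS:
            raise ValueError(f"unknown channel {name!r}")
        return self.records[self.records["channel"] == name]

    def infection_day_mask(self, days: pd.DatetimeIndex) -> np.ndarray:
        """Boolean mask over calendar ``days`` that fall in an infection period."""
        days = days.normalize()
        mask = np.zeros(len(days), dtype=bool)
        for start, end in self.infection_periods:
            mask |= (days >= start.normalize()) & (days <= end.normalize())
        return mask

    def copy(self) -> "EventLog":
        return EventLog(self.records.copy(), list(self.infection_periods))
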