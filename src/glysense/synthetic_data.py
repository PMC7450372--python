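"""Seeded generator of synthetic patient-years of self-recorded diabetes data.

Real self-recorded data of the kind this package analyses (finger-stick blood
glucose, bolus insulin, carbohydrate registrations over a full year, with
self-reported infection periods) are donated and private, so this module
provides a generative stand-in whose *feature-level* behaviour matches what is
seen in such data:

* normal days cluster at a moderate insulin-to-carbohydrate ratio and a
  moderate mean blood glucose, forming an elliptical cloud in the
  (ratio, mean BG) plane;
* during an infection, blood glucose stays elevated even though the patient
  injects more insulin while eating less carbohydrate — i.e. both the ratio
  and the mean BG shift upwards for the episode's duration;
* a handful of rare-but-normal days occupy the off-diagonal "wellness
  quadrants" (e.g. heavy exercise replacing insulin needs: low ratio with
  normal/low glucose), which confuse purely density-based outlier detectors.

The generator is intentionally phenomenological: daily BG level is a Gaussian
around a basal level with AR(1) within-day readings, meals occur at fixed
times with jitter, and the bolus for each meal is carbs x a per-meal
insulin-to-carb ratio x lognormal noise.  No attempt is made to model
glucose-insulin physiology; see the methods note for what this does and does
not emulate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .events import EPOCH, EventLog

HORIZON_DAYS = 365

#: AR(1) coefficient and stationary SD (mg/dL) of within-day BG fluctuations.
_AR_PHI = 0.7
_AR_SD = 18.0

#: Lognormal sigma of multiplicative bolus dosing noise.
_BOLUS_NOISE_SD = 0.15

#: Quadrant-scenario placement, in (ratio, BG) units of (quantile anchor,
#: offset in SDs of the daily statistic).  Chosen so the events are jointly
#: rare (outside the marginal 5%/10% tails) yet inside a beta=0.01 one-class
#: boundary (joint Mahalanobis radius ~2.6-2.8 sigma); see docs/methods.md.
QUADRANT_SCENARIOS = {
    # Quadrant 1, "carb action": ate carbs without (full) bolus -> low ratio,
    # high BG.
    "carb_action": {"ratio_q": 0.05, "ratio_off": -0.5, "bg_q": 0.90, "bg_off": +0.35},
    # "Physical activity action": exercise replaced insulin -> low ratio,
    # low/normal BG.
    "pa_action": {"ratio_q": 0.05, "ratio_off": -0.5, "bg_q": 0.10, "bg_off": -0.35},
    # "Insulin action": large corrective boluses -> high ratio, low BG.
    "insulin_action": {"ratio_q": 0.95, "ratio_off": +0.5, "bg_q": 0.10, "bg_off": -0.35},
}

#: Within-scenario day-to-day jitter, in SDs of the daily statistic.
_QUADRANT_JITTER = 0.05


@dataclass
class PatientProfile:
    """Stationary (non-infected) regime of one simulated patient.

    Defaults describe an adult with type 1 diabetes on basal-bolus therapy:
    mean BG 120 mg/dL with 15 mg/dL day-to-day variation, four meals of
    ~50 g carbohydrate, and an insulin-to-carb ratio of 0.1 U/g (1 unit per
    10 g of carbohydrate), sampled per meal with SD 0.02 U/g.
    """

    basal_bg_mean: float = 120.0  # mg/dL
    bg_noise_sd: float = 15.0  # mg/dL, day-to-day SD of the daily BG level
    meals_per_day: int = 4
    carb_per_meal_mean: float = 50.0  # grams
    carb_per_meal_sd: float = 15.0
    insulin_carb_ratio_mean: float = 0.1  # units per gram
    insulin_carb_ratio_sd: float = 0.02
    bg_reading_rate: int = 5  # finger-stick readings per day
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.basal_bg_mean, self.carb_per_meal_mean,
               self.insulin_carb_ratio_mean) <= 0:
            raise ValueError("all means must be positive")
        if min(self.bg_noise_sd, self.carb_per_meal_sd,
               self.insulin_carb_ratio_sd) < 0:
            raise ValueError("SDs must be nonnegative")
        if self.meals_per_day < 1:
            raise ValueError("meals_per_day must be >= 1")
        if self.bg_reading_rate < 1:
            raise ValueError("bg_reading_rate must be >= 1")


@dataclass
class InfectionEpisode:
    """A step-change infection episode injected into a patient-year.

    During ``[start_day, start_day + duration_days)`` the daily BG level is
    shifted by ``bg_elevation`` mg/dL, every bolus is scaled by
    ``insulin_demand_multiplier`` (> 1: more insulin) and every carb intake by
    ``carb_reduction_factor`` (<= 1: less food) — the infection signature of
    elevated glucose despite more insulin and less carbohydrate.
    """

    start_day: int
    duration_days: int
    bg_elevation: float = 60.0  # mg/dL
    insulin_demand_multiplier: float = 1.6
    carb_reduction_factor: float = 0.7

    def __post_init__(self) -> None:
        if self.duration_days < 1:
            raise ValueError("duration_days must be >= 1")
        if not 0 <= self.start_day < HORIZON_DAYS:
            raise ValueError("episode must start within the simulated year")
        if self.start_day + self.duration_days > HORIZON_DAYS:
            raise ValueError("episode extends past the simulated year")
        if self.insulin_demand_multiplier <= 1:
            raise ValueError("insulin_demand_multiplier must be > 1")
        if not 0 < self.carb_reduction_factor <= 1:
            raise ValueError("carb_reduction_factor must be in (0, 1]")

    @property
    def end_day(self) -> int:
        """Last day index of the episode (inclusive)."""
        return self.start_day + self.duration_days - 1


def _check_episodes(episodes: list[InfectionEpisode]) -> list[InfectionEpisode]:
    eps = sorted(episodes, key=lambda e: e.start_day)
    for a, b in zip(eps, eps[1:]):
        if b.start_day <= a.end_day:
            raise ValueError(
                f"episodes overlap: one ends on day {a.end_day}, "
                f"the next starts on day {b.start_day}"
            )
    return eps


def generate_patient_year(
    profile: PatientProfile,
    episodes: list[InfectionEpisode] | None = None,
    seed: int | None = None,
) -> EventLog:
    """Simulate one 365-day patient-year with the given infection episodes.

    Deterministic for a fixed ``seed`` (defaults to ``profile.seed``).
    Returns an :class:`EventLog` whose ``infection_periods`` exactly match the
    episode intervals (inclusive day bounds).
    """
    episodes = _check_episodes(list(episodes or []))
    rng = np.random.default_rng(profile.seed if seed is None else seed)

    bg_shift = np.zeros(HORIZON_DAYS)
    ins_mult = np.ones(HORIZON_DAYS)
    carb_fact = np.ones(HORIZON_DAYS)
    for ep in episodes:
        sl = slice(ep.start_day, ep.start_day + ep.duration_days)
        bg_shift[sl] = ep.bg_elevation
        ins_mult[sl] = ep.insulin_demand_multiplier
        carb_fact[sl] = ep.carb_reduction_factor

    # Daily BG level: Normal(basal, sd) + episode elevation.
    day_level = (
        profile.basal_bg_mean
        + rng.normal(0.0, profile.bg_noise_sd, HORIZON_DAYS)
        + bg_shift
    )

    # Within-day AR(1) readings around the daily level, at roughly evenly
    # spaced waking hours with jitter.
    r = profile.bg_reading_rate
    base_hours = np.linspace(7.0, 22.0, r)
    jitter = rng.normal(0.0, 0.3, (HORIZON_DAYS, r))
    bg_hours = np.clip(base_hours[None, :] + jitter, 0.0, 23.99)
    bg_hours.sort(axis=1)
    resid = np.empty((HORIZON_DAYS, r))
    innov_sd = _AR_SD * np.sqrt(1.0 - _AR_PHI**2)
    resid[:, 0] = rng.normal(0.0, _AR_SD, HORIZON_DAYS)
    for t in range(1, r):
        resid[:, t] = _AR_PHI * resid[:, t - 1] + rng.normal(
            0.0, innov_sd, HORIZON_DAYS
        )
    bg_values = np.clip(day_level[:, None] + resid, 30.0, None)

    # Meals: fixed times with jitter; carbs truncated-normal, scaled down on
    # episode days; bolus = carbs x per-meal ratio x lognormal noise, scaled
    # up on episode days.
    m = profile.meals_per_day
    meal_base = np.linspace(8.0, 20.0, m)
    meal_hours = np.clip(
        meal_base[None, :] + rng.normal(0.0, 0.5, (HORIZON_DAYS, m)), 0.0, 23.99
    )
    meal_hours.sort(axis=1)
    carbs = np.maximum(
        rng.normal(profile.carb_per_meal_mean, profile.carb_per_meal_sd,
                   (HORIZON_DAYS, m)),
        5.0,
    ) * carb_fact[:, None]
    ratios = np.maximum(
        rng.normal(profile.insulin_carb_ratio_mean,
                   profile.insulin_carb_ratio_sd, (HORIZON_DAYS, m)),
        0.01,
    )
    dose_noise = rng.lognormal(0.0, _BOLUS_NOISE_SD, (HORIZON_DAYS, m))
    boluses = carbs * ratios * dose_noise * ins_mult[:, None]

    day_idx = np.arange(HORIZON_DAYS)
    frames = []
    for channel, hours, values in (
        ("bg", bg_hours, bg_values),
        ("bolus", meal_hours, boluses),
        ("carb", meal_hours, carbs),
    ):
        ts = (
            EPOCH
            + pd.to_timedelta(np.repeat(day_idx, hours.shape[1]), unit="D")
            + pd.to_timedelta(hours.ravel(), unit="h")
        )
        frames.append(
            pd.DataFrame(
                {"timestamp": ts, "channel": channel, "value": values.ravel()}
            )
        )
    records = (
        pd.concat(frames, ignore_index=True)
        .sort_values(["timestamp", "channel"], kind="stable")
        .reset_index(drop=True)
    )
    periods = [
        (EPOCH + pd.Timedelta(days=ep.start_day),
         EPOCH + pd.Timedelta(days=ep.end_day))
        for ep in episodes
    ]
    return EventLog(records, periods)


def _daily_stats(log: EventLog) -> pd.DataFrame:
    """Per-calendar-day insulin-to-carb ratio and mean BG from a log."""
    rec = log.records
    day = rec["timestamp"].dt.normalize()
    bg = rec[rec["channel"] == "bg"].groupby(day)["value"].mean()
    bolus = rec[rec["channel"] == "bolus"].groupby(day)["value"].sum()
    carb = rec[rec["channel"] == "carb"].groupby(day)["value"].sum()
    out = pd.DataFrame({"ratio": bolus / carb, "bg": bg})
    return out.dropna()


def inject_quadrant_events(
    log: EventLog,
    scenario_counts: dict[str, int],
    seed: int = 0,
) -> EventLog:
    """Insert rare-but-normal "wellness quadrant" days into a patient-year.

    Each requested event rewrites one non-infection day so that its daily
    (ratio, mean BG) statistic lands in the requested quadrant relative to
    the patient's own empirical distribution — e.g. ``insulin_action`` days
    exceed the 95th ratio percentile while mean BG falls below the 10th
    percentile.  The days stay *normal* (labelled target downstream): they
    represent behaviour, not illness.

    Raises ``ValueError`` when a scenario name is unknown or there are not
    enough free normal days.
    """
    unknown = set(scenario_counts) - set(QUADRANT_SCENARIOS)
    if unknown:
        raise ValueError(f"unknown quadrant scenarios: {sorted(unknown)}")
    total = sum(scenario_counts.values())
    if total == 0:
        return log.copy()

    rng = np.random.default_rng(seed)
    stats = _daily_stats(log)
    days = stats.index
    free = days[~log.infection_day_mask(pd.DatetimeIndex(days))]
    if len(free) < total:
        raise ValueError(
            f"need {total} free normal days, only {len(free)} available"
        )
    chosen = pd.DatetimeIndex(
        rng.choice(free.values, size=total, replace=False)
    )

    sd_ratio = float(stats["ratio"].std())
    sd_bg = float(stats["bg"].std())
    records = log.records.copy()
    rec_day = records["timestamp"].dt.normalize()

    pos = 0
    for name, count in scenario_counts.items():
        sc = QUADRANT_SCENARIOS[name]
        for _ in range(count):
            day = chosen[pos]
            pos += 1
            target_ratio = float(stats["ratio"].quantile(sc["ratio_q"])) + (
                sc["ratio_off"] + rng.normal(0.0, _QUADRANT_JITTER)
            ) * sd_ratio
            target_bg = float(stats["bg"].quantile(sc["bg_q"])) + (
                sc["bg_off"] + rng.normal(0.0, _QUADRANT_JITTER)
            ) * sd_bg
            target_ratio = max(target_ratio, 1e-3)
            target_bg = max(target_bg, 40.0)

            in_day = rec_day == day
            is_bolus = in_day & (records["channel"] == "bolus")
            is_bg = in_day & (records["channel"] == "bg")
            cur_ratio = float(stats.loc[day, "ratio"])
            cur_bg = float(stats.loc[day, "bg"])
            records.loc[is_bolus, "value"] *= target_ratio / cur_ratio
            records.loc[is_bg, "value"] = np.clip(
                records.loc[is_bg, "value"] + (target_bg - cur_bg), 30.0, None
            )
    return EventLog(records, list(log.infection_periods))
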