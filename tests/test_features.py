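import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from glysense.events import EventLog
from glysense.features import (FeatureSeries, NONTARGET, TARGET,
                               aggregate_bins, build_dataset, impute_missing,
                               scale_minmax, smooth_series, unscale_minmax)


def _log_from(rows, periods=()):
    rec = pd.DataFrame(rows, columns=["timestamp", "channel", "value"])
    rec["timestamp"] = pd.to_datetime(rec["timestamp"])
    return EventLog(rec, [(pd.Timestamp(s), pd.Timestamp(e)) for s, e in periods])


def _series(x1, x2, granularity="daily", **kw):
    index = pd.date_range("2021-01-01", periods=len(x1),
                          freq="D" if granularity == "daily" else "h")
    return FeatureSeries(pd.DataFrame({"x1": x1, "x2": x2}, index=index),
                         granularity, **kw)


class TestAggregate:
    def test_daily_ratio_and_mean_bg(self):
        log = _log_from([
            ("2021-01-01 08:00", "bolus", 4), ("2021-01-01 12:00", "bolus", 6),
            ("2021-01-01 08:00", "carb", 50), ("2021-01-01 12:00", "carb", 50),
            ("2021-01-01 09:00", "bg", 100), ("2021-01-01 13:00", "bg", 140),
            ("2021-01-02 08:00", "bolus", 5), ("2021-01-02 08:00", "carb", 50),
            ("2021-01-02 09:00", "bg", 120),
        ])
        s = aggregate_bins(log, "daily")
        # ratio of totals: (4 + 6) / (50 + 50)
        assert s.frame.iloc[0]["x1"] == pytest.approx(0.1)
        assert s.frame.iloc[0]["x2"] == pytest.approx(120.0)

    def test_zero_carb_day_flagged_missing_not_inf(self):
        log = _log_from([
            ("2021-01-01 08:00", "bolus", 4), ("2021-01-01 09:00", "bg", 100),
            ("2021-01-02 08:00", "bolus", 5), ("2021-01-02 08:00", "carb", 50),
            ("2021-01-02 09:00", "bg", 120),
        ])
        s = aggregate_bins(log, "daily")
        assert np.isnan(s.frame.iloc[0]["x1"])
        assert np.isfinite(s.frame.iloc[1]["x1"])

    def test_cardinality_daily_vs_hourly(self, patient_year_log):
        assert len(aggregate_bins(patient_year_log, "daily")) == 365
        assert len(aggregate_bins(patient_year_log, "hourly")) == 365 * 24

    def test_mass_preservation(self, patient_year_log):
        """Sums of bolus and carb over bins equal the log totals."""
        log = patient_year_log
        s = aggregate_bins(log, "daily")
        carb_total = log.channel("carb")["value"].sum()
        bolus_total = log.channel("bolus")["value"].sum()
        # reconstruct bin totals: x1 * carbs = bolus per day
        day = log.records["timestamp"].dt.normalize()
        carbs_by_day = log.records[log.records["channel"] == "carb"] \
            .groupby(day)["value"].sum().reindex(s.frame.index).fillna(0.0)
        assert np.isclose((s.frame["x1"] * carbs_by_day).sum(), bolus_total)
        assert np.isclose(carbs_by_day.sum(), carb_total)

    def test_single_bin_log_rejected(self):
        log = _log_from([("2021-01-01 08:00", "bg", 100)])
        with pytest.raises(ValueError, match="2 bins"):
            aggregate_bins(log, "daily")


class TestImpute:
    def test_midpoint_interpolation(self):
        s = _series([0.2, np.nan, 0.4], [100, 110, 120])
        out = impute_missing(s)
        assert out.frame["x1"].tolist() == pytest.approx([0.2, 0.3, 0.4])

    def test_identity_when_complete(self):
        s = _series([0.2, 0.3], [100, 110])
        pd.testing.assert_frame_equal(impute_missing(s).frame, s.frame)

    def test_leading_missing_backfilled(self):
        s = _series([np.nan, 0.3, 0.4], [100, 110, 120])
        assert impute_missing(s).frame["x1"].iloc[0] == pytest.approx(0.3)

    def test_too_sparse_rejected(self):
        s = _series([np.nan, np.nan, np.nan, 0.4], [100, 100, 100, 100])
        with pytest.raises(ValueError, match="too sparse"):
            impute_missing(s)

    def test_interior_values_within_neighbor_hull(self, rng):
        x = rng.random(50)
        x[10:13] = np.nan
        s = _series(x, np.full(50, 100.0))
        out = impute_missing(s).frame["x1"]
        assert out.iloc[10:13].between(min(x[9], x[13]), max(x[9], x[13])).all()


class TestSmooth:
    def test_constant_series_unchanged(self):
        s = _series([0.3] * 10, [100.0] * 10)
        pd.testing.assert_frame_equal(smooth_series(s).frame, s.frame)

    def test_two_sample_trailing_average(self):
        s = _series([1.0] * 4, [100, 140, 100, 140])
        out = smooth_series(s)
        assert out.frame["x2"].tolist() == pytest.approx([100, 120, 120, 120])

    def test_variance_reduced_on_white_noise(self, rng):
        x = rng.normal(size=1000)
        s = _series(x, rng.normal(size=1000) + 10, granularity="hourly")
        out = smooth_series(s)  # 48-sample window at hourly granularity
        assert out.frame["x1"].var() < s.frame["x1"].var()
        assert out.frame["x2"].var() < s.frame["x2"].var()

    def test_window_longer_than_series_rejected(self):
        s = _series([1.0], [100.0])
        with pytest.raises(ValueError, match="longer than series"):
            smooth_series(s)

    def test_output_length_preserved(self, rng):
        s = _series(rng.random(100), rng.random(100) + 1, granularity="hourly")
        assert len(smooth_series(s)) == 100


class TestScale:
    def test_basic_scaling(self):
        s = _series([0, 1, 2], [2, 4, 6])
        out = scale_minmax(s)
        assert out.frame["x2"].tolist() == pytest.approx([0, 0.5, 1])

    def test_degenerate_dimension_rejected(self):
        with pytest.raises(ValueError, match="min == max"):
            scale_minmax(_series([1, 1], [2, 4]))

    def test_training_params_applied_with_clipping(self):
        train = _series([0, 1, 2], [2, 4, 6])
        fitted = scale_minmax(train)
        test = _series([1, 1, 1], [2, 4, 8])
        out = scale_minmax(test, params=fitted.scaler_params)
        assert out.frame["x2"].iloc[-1] == pytest.approx(1.0)  # 8 clipped

    def test_round_trip(self, rng):
        s = _series(rng.random(20), rng.random(20) * 100 + 50)
        back = unscale_minmax(scale_minmax(s))
        np.testing.assert_allclose(back.frame.values, s.frame.values, atol=1e-12)

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(st.lists(st.floats(0, 1000), min_size=3, max_size=30, unique=True))
    def test_scaled_range_is_unit_interval(self, values):
        s = _series(list(range(len(values))), values)
        out = scale_minmax(s)
        assert out.frame["x2"].min() == pytest.approx(0.0)
        assert out.frame["x2"].max() == pytest.approx(1.0)


class TestLabels:
    def test_single_episode_counts(self, patient_year_log, daily_dataset):
        assert daily_dataset.n_target == 358
        assert daily_dataset.n_nontarget == 7

    def test_no_infection_all_target(self):
        s = _series([0.1, 0.2, 0.3], [100, 110, 120])
        ds = build_dataset(s, [])
        assert (ds.labels == TARGET).all()

    def test_hourly_episode_has_168_nontarget(self, patient_year_log):
        series = aggregate_bins(patient_year_log, "hourly")
        ds = build_dataset(series, patient_year_log)
        assert ds.n_nontarget == 7 * 24

    def test_partition(self, daily_dataset):
        assert daily_dataset.n_target + daily_dataset.n_nontarget == \
            len(daily_dataset.series)
        infected_days = daily_dataset.series.frame.index.normalize()
        mask = np.zeros(len(infected_days), bool)
        for s, e in [(pd.Timestamp("2021-05-31"), pd.Timestamp("2021-06-06"))]:
            mask |= (infected_days >= s) & (infected_days <= e)
        np.testing.assert_array_equal(daily_dataset.labels == NONTARGET, mask)
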