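"""Twilight extraction, drift correction and change-point segmentation."""

import datetime as dt

import numpy as np
import pandas as pd
import pytest

from twilighttrack import segmentation, solar, synthetic
from twilighttrack.synthetic import NoiseModel, TrackConfig, ZERO_NOISE


def _constant_series(n_days, lat=10.0, lon=9.0, a=-3.5, start=dt.date(2019, 1, 10)):
    rows = []
    for k in range(n_days):
        date = start + dt.timedelta(days=k)
        pair = solar.twilight_times(lat, lon, date, a)
        rows.append({"date": date, "sunrise_utc": pair.sunrise_utc,
                     "sunset_utc": pair.sunset_utc, "polar_flag": "none",
                     "missing": False})
    return pd.DataFrame(rows)


class TestExtractTwilights:
    def test_simple_day(self):
        ts = pd.date_range("2019-01-01", periods=288, freq="5min")
        light = [64.0 if 6.0 <= t.hour + t.minute / 60 <= 18.0 else -1.0 for t in ts]
        out = segmentation.extract_twilights_from_light(
            pd.DataFrame({"timestamp": ts, "light": light})
        )
        assert out.sunrise_utc.iloc[0] == pytest.approx(6.0, abs=5 / 60)
        assert out.sunset_utc.iloc[0] == pytest.approx(18.0, abs=5 / 60)

    def test_all_dark_day_flagged_missing(self):
        ts = pd.date_range("2019-01-01", periods=288, freq="5min")
        out = segmentation.extract_twilights_from_light(
            pd.DataFrame({"timestamp": ts, "light": -1.0})
        )
        assert out.missing.iloc[0]
        assert np.isnan(out.sunrise_utc.iloc[0])

    def test_empty_log_rejected(self):
        with pytest.raises(ValueError):
            segmentation.extract_twilights_from_light(
                pd.DataFrame({"timestamp": [], "light": []})
            )

    def test_unordered_log_rejected(self):
        ts = pd.to_datetime(["2019-01-02", "2019-01-01"])
        with pytest.raises(ValueError):
            segmentation.extract_twilights_from_light(
                pd.DataFrame({"timestamp": ts, "light": [1.0, 1.0]})
            )


class TestClockDrift:
    def test_zero_drift_identity(self):
        tw = _constant_series(10)
        out = segmentation.correct_clock_drift(tw, 0.0)
        pd.testing.assert_frame_equal(out, tw)

    def test_linear_interpolation(self):
        tw = _constant_series(101)
        out = segmentation.correct_clock_drift(tw, 10.0)
        shift = (tw.sunrise_utc - out.sunrise_utc) * 60.0
        assert shift.iloc[0] == pytest.approx(0.0)
        assert shift.iloc[50] == pytest.approx(5.0)
        assert shift.iloc[100] == pytest.approx(10.0)

    def test_roundtrip_with_simulated_drift(self):
        track = synthetic.simulate_track(TrackConfig(), seed=4)
        drifted, _ = synthetic.simulate_twilights(
            track, noise=NoiseModel(shade_mean=0, jitter_sd=0, clock_drift=12.0), seed=0
        )
        clean, _ = synthetic.simulate_twilights(track, noise=ZERO_NOISE, seed=0)
        fixed = segmentation.correct_clock_drift(drifted, 12.0)
        diff = ((fixed.sunrise_utc - clean.sunrise_utc) * 60.0).abs()
        assert diff.max() < 0.1


class TestDetectStationaryPeriods:
    def test_constant_series_is_one_period(self):
        labels = segmentation.detect_stationary_periods(_constant_series(30))
        assert (labels.state == "stationary").all()
        assert labels.period_id.nunique() == 1

    def test_two_site_longitude_jump(self):
        """A 10-degree relocation is found with the boundary within a day."""
        a = _constant_series(20, lon=0.0)
        b = _constant_series(20, lon=10.0, start=dt.date(2019, 1, 31))
        labels = segmentation.detect_stationary_periods(pd.concat([a, b], ignore_index=True))
        stat = labels[labels.state == "stationary"]
        assert stat.period_id.nunique() == 2
        first = stat[stat.period_id == 1]
        second = stat[stat.period_id == 2]
        assert abs((max(first.day) - dt.date(2019, 1, 29)).days) <= 1
        assert abs((min(second.day) - dt.date(2019, 1, 31)).days) <= 1

    def test_minimum_observed_relocation_detected(self):
        """Default thresholds separate a 4.2-degree (~17 min) shift."""
        a = _constant_series(15, lon=0.0)
        b = _constant_series(15, lon=4.2, start=dt.date(2019, 1, 26))
        labels = segmentation.detect_stationary_periods(pd.concat([a, b], ignore_index=True))
        assert labels[labels.state == "stationary"].period_id.nunique() == 2

    def test_invariant_to_constant_clock_offset(self):
        a = _constant_series(15, lon=0.0)
        b = _constant_series(15, lon=8.0, start=dt.date(2019, 1, 26))
        tw = pd.concat([a, b], ignore_index=True)
        shifted = tw.assign(sunrise_utc=tw.sunrise_utc + 0.5,
                            sunset_utc=tw.sunset_utc + 0.5)
        l0 = segmentation.detect_stationary_periods(tw)
        l1 = segmentation.detect_stationary_periods(shifted)
        pd.testing.assert_series_equal(l0.state, l1.state)
        pd.testing.assert_series_equal(l0.period_id, l1.period_id)

    def test_labels_partition_all_days(self):
        track = synthetic.simulate_track(TrackConfig(), seed=21)
        tw, _ = synthetic.simulate_twilights(track, noise=NoiseModel(), seed=2)
        labels = segmentation.detect_stationary_periods(tw)
        assert len(labels) == len(tw)
        assert set(labels.state) <= {"stationary", "migrating"}
        # stationary runs satisfy the 2-day minimum
        for _, grp in labels[labels.state == "stationary"].groupby("period_id"):
            assert len(grp) >= segmentation.MIN_STATIONARY_DAYS

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError):
            segmentation.detect_stationary_periods(_constant_series(1))

    def test_noise_free_recovery_of_simulated_sites(self):
        """Without noise the true segmentation is recovered nearly exactly."""
        track = synthetic.simulate_track(TrackConfig(country="Nigeria"), seed=2)
        tw, truth = synthetic.simulate_twilights(track, noise=ZERO_NOISE, seed=0)
        labels = segmentation.detect_stationary_periods(tw)
        merged = labels.merge(truth, left_on="day", right_on="date")
        valid = merged[merged.state_y == "stationary"]
        agree = (valid.state_x == "stationary").mean()
        assert agree > 0.97


class TestFlagEquinox:
    @pytest.mark.parametrize(
        "start,end,expected",
        [
            ((3, 18), (3, 21), True),
            ((6, 1), (6, 4), False),
            ((9, 14), (9, 16), True),
            ((3, 1), (3, 12), False),
            ((3, 10), (4, 2), True),
        ],
    )
    def test_window_intersection(self, start, end, expected):
        assert segmentation.flag_equinox(
            dt.date(2019, *start), dt.date(2019, *end)
        ) is expected

    def test_reversed_interval_rejected(self):
        with pytest.raises(ValueError):
            segmentation.flag_equinox(dt.date(2019, 5, 2), dt.date(2019, 5, 1))

    def test_synthetic_cohort_counts_match_truth(self):
        """Equinox-flagged legs equal a direct date-window computation."""
        count_op = count_direct = 0
        for seed in range(8):
            track = synthetic.simulate_track(TrackConfig(), seed=seed)
            for row in track.truth_table.itertuples():
                if segmentation.flag_equinox(row.depart, row.arrive):
                    count_op += 1
                windows = [(dt.date(row.depart.year, 3, 13), dt.date(row.depart.year, 3, 27)),
                           (dt.date(row.depart.year, 9, 15), dt.date(row.depart.year, 9, 29))]
                if any(row.depart <= w2 and row.arrive >= w1 for w1, w2 in windows):
                    count_direct += 1
        assert count_op == count_direct
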