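"""Great-circle arithmetic, site classification and annual summaries."""

import datetime as dt
import math

import numpy as np
import pytest

from twilighttrack import events, synthetic
from twilighttrack.events import (
    MigrationLeg,
    build_legs,
    classify_periods,
    dayval,
    haversine,
    julian_date,
    summarise_bird,
)
from twilighttrack.geolocation import StationaryPeriod


def _period(pid, start, end, lat, lon, cls="stopover"):
    return StationaryPeriod(
        id=pid, start=dayval(start), end=dayval(end, at_sunset=True),
        lat=lat, lon=lon, classification=cls,
    )


class TestHaversine:
    def test_identical_points(self):
        assert haversine(10.0, 20.0, 10.0, 20.0) == 0.0

    def test_half_circumference(self):
        # antipodal equatorial points: pi * R
        assert haversine(0, 0, 0, 180) == pytest.approx(math.pi * 6371.0, rel=1e-9)

    def test_equatorial_degree(self):
        assert haversine(0, 0, 0, 1) == pytest.approx(111.19, abs=0.01)


class TestJulianDate:
    @pytest.mark.parametrize(
        "date,expected",
        [
            (dt.date(2019, 4, 9), 99),
            (dt.date(2019, 1, 1), 1),
            (dt.date(2020, 12, 31), 366),
            (dt.date(2019, 12, 31), 365),
        ],
    )
    def test_day_of_year(self, date, expected):
        assert julian_date(date) == expected


NIGERIA = synthetic.COUNTRY_SITES["Nigeria"]


def _annual_periods():
    """A plausible annual cycle: main, secondary, stopovers, breeding, return."""
    return [
        _period(1, dt.date(2019, 1, 5), dt.date(2019, 2, 20), 9.9, 9.0),
        _period(2, dt.date(2019, 2, 22), dt.date(2019, 4, 15), 6.6, 4.9),
        _period(3, dt.date(2019, 4, 18), dt.date(2019, 4, 22), 20.0, 14.0),
        _period(4, dt.date(2019, 4, 26), dt.date(2019, 5, 2), 40.0, 22.0),
        _period(5, dt.date(2019, 5, 5), dt.date(2019, 8, 22), 55.0, 30.0),
        _period(6, dt.date(2019, 8, 26), dt.date(2019, 9, 5), 35.0, 28.0),
        _period(7, dt.date(2019, 9, 9), dt.date(2019, 10, 20), 9.8, 9.1),
    ]


class TestClassification:
    def test_planted_southwest_secondary_site(self):
        periods = classify_periods(_annual_periods(), *NIGERIA)
        by_id = {p.id: p.classification for p in periods}
        assert by_id[1] == "main_nonbreeding"
        assert by_id[2] == "secondary_nonbreeding"  # ~560 km southwest
        assert by_id[5] == "breeding"
        assert by_id[3] == by_id[4] == by_id[6] == "stopover"

    def test_small_shift_stays_main(self):
        """A ~100-km shift near the tagging site is within-site noise."""
        periods = _annual_periods()
        periods[1] = _period(2, dt.date(2019, 2, 22), dt.date(2019, 4, 15), 10.7, 9.3)
        out = classify_periods(periods, *NIGERIA)
        assert out[1].classification == "main_nonbreeding"

    def test_no_breeding_candidate_handled(self):
        periods = _annual_periods()[:3]  # tag failed in spring
        out = classify_periods(periods, *NIGERIA)
        assert all(p.classification != "breeding" for p in out)

    def test_secondary_displacement_recovered_on_cohort(self):
        """Planted secondary sites sit ~504 km from the tagging site."""
        cfg = synthetic.TrackConfig(country="Nigeria", secondary_site_prob=1.0)
        dists = []
        for seed in range(60):
            track = synthetic.simulate_track(cfg, seed=seed)
            sec = [s for s in track.sites if s.label == "secondary_nonbreeding"]
            main = track.sites[0]
            dists.extend(haversine(s.lat, s.lon, main.lat, main.lon) for s in sec)
        assert np.mean(dists) == pytest.approx(503.6, abs=60.0)


class TestSeasons:
    def test_leg_seasons_around_breeding(self):
        periods = classify_periods(_annual_periods(), *NIGERIA)
        legs = build_legs("b1", periods)
        seasons = {l.leg_id: l.season for l in legs}
        assert seasons[1] == "intra_african"  # main -> secondary
        assert seasons[2] == seasons[3] == seasons[4] == "spring"
        assert seasons[5] == seasons[6] == "autumn"

    def test_toggle_changes_spring_total_by_intra_african_component(self):
        periods = classify_periods(_annual_periods(), *NIGERIA)
        excl = build_legs("b1", periods, include_subsaharan=False)
        incl = build_legs("b1", periods, include_subsaharan=True)
        s_excl = sum(l.distance for l in excl if l.season == "spring")
        s_incl = sum(l.distance for l in incl if l.season == "spring")
        intra = sum(l.distance for l in excl if l.season == "intra_african")
        assert s_incl == pytest.approx(s_excl + intra)
        # excluding sub-Saharan periods never increases the spring totals
        assert s_excl <= s_incl

    def test_leg_speed_consistency(self):
        periods = classify_periods(_annual_periods(), *NIGERIA)
        for leg in build_legs("b1", periods):
            assert leg.duration >= 0.5
            assert leg.speed == pytest.approx(leg.distance / (24.0 * leg.duration))


class TestSummaries:
    def test_multi_site_distance_accounting(self):
        """Leg distances add linearly: 356 + 765 + 3538 = 4659 km."""
        legs = [
            MigrationLeg("b", i + 1, 0, 1, i, i + 1, d, 1.0, d / 24.0, "spring", False)
            for i, d in enumerate([356.0, 765.0, 3538.0])
        ]
        total = sum(l.distance for l in legs)
        assert total == pytest.approx(4659.0)

    def test_summary_totals_and_phenology(self):
        periods = classify_periods(_annual_periods(), *NIGERIA)
        legs = build_legs("b1", periods)
        s = summarise_bird("b1", "Nigeria", periods, legs, completeness="full")
        spring = [l for l in legs if l.season == "spring"]
        autumn = [l for l in legs if l.season == "autumn"]
        assert s.total_distance_spring == pytest.approx(sum(l.distance for l in spring))
        assert s.total_distance_autumn == pytest.approx(sum(l.distance for l in autumn))
        assert s.n_stopovers_spring == 2
        assert s.n_stopovers_autumn == 1
        assert s.depart_nonbreeding == julian_date(dt.date(2019, 4, 15))
        assert s.arrive_breeding == julian_date(dt.date(2019, 5, 5))
        assert s.depart_breeding == julian_date(dt.date(2019, 8, 22))
        assert s.arrive_nonbreeding == julian_date(dt.date(2019, 9, 9))
        # ordered phenology
        assert (s.depart_nonbreeding < s.arrive_breeding
                < s.depart_breeding < s.arrive_nonbreeding)

    def test_spring_total_at_least_direct_distance(self):
        """Summed leg distances respect the triangle inequality."""
        periods = classify_periods(_annual_periods(), *NIGERIA)
        legs = build_legs("b1", periods)
        s = summarise_bird("b1", "Nigeria", periods, legs)
        sec = next(p for p in periods if p.classification == "secondary_nonbreeding")
        breeding = next(p for p in periods if p.classification == "breeding")
        direct = haversine(sec.lat, sec.lon, breeding.lat, breeding.lon)
        assert s.total_distance_spring >= direct - 1e-6

    def test_duration_accounting_identity(self):
        """Leg + stopover durations add up to the end-to-end duration."""
        periods = classify_periods(_annual_periods(), *NIGERIA)
        legs = build_legs("b1", periods)
        spring = [l for l in legs if l.season == "spring"]
        leg_total = sum(l.duration for l in spring)
        stop_total = sum(
            p.duration for p in periods
            if spring[0].end <= p.start and p.end <= spring[-1].start
        )
        end_to_end = spring[-1].end - spring[0].start
        assert leg_total + stop_total == pytest.approx(end_to_end)

    def test_single_leg_migration(self):
        periods = [
            _period(1, dt.date(2019, 1, 5), dt.date(2019, 4, 10), 9.9, 9.0),
            _period(2, dt.date(2019, 4, 20), dt.date(2019, 8, 1), 50.0, 30.0),
        ]
        periods = classify_periods(periods, *NIGERIA)
        legs = build_legs("b1", periods)
        s = summarise_bird("b1", "Nigeria", periods, legs, completeness="to_breeding")
        assert s.n_stopovers_spring == 0
        assert s.total_distance_spring == pytest.approx(
            haversine(9.9, 9.0, 50.0, 30.0)
        )
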