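"""Population statistics: spread, ranges, loop contrast, flight arithmetic."""

import math
from itertools import combinations

import numpy as np
import pytest

from twilighttrack import stats
from twilighttrack.events import haversine
from twilighttrack.stats import (
    convex_range,
    fuel_budget,
    leg_speed,
    loop_contrast,
    migratory_spread,
    pool_resighting,
    range_overlap,
    stationary_hours_per_day,
)


class TestMigratorySpread:
    def test_two_points(self):
        pts = [(0.0, 0.0), (0.0, 2.0)]
        d = haversine(0, 0, 0, 2)
        sp = migratory_spread(pts, n_resamples=500, seed=0)
        assert sp.mean_pairwise_km == pytest.approx(d)
        assert sp.ci_low_km == pytest.approx(d)
        assert sp.ci_high_km == pytest.approx(d)

    def test_identical_points(self):
        sp = migratory_spread([(10.0, 10.0)] * 4, n_resamples=100, seed=0)
        assert sp.mean_pairwise_km == 0.0

    def test_three_point_mean_against_enumeration(self):
        # collinear equatorial points 100 and 300 km from the origin give
        # pairwise distances 100/200/300 km
        deg = 100.0 / haversine(0, 0, 0, 1)
        pts = [(0.0, 0.0), (0.0, deg), (0.0, 3 * deg)]
        brute = np.mean([haversine(*a, *b) for a, b in combinations(pts, 2)])
        assert brute == pytest.approx(200.0, rel=1e-4)
        sp = migratory_spread(pts, n_resamples=10_000, seed=1)
        assert sp.mean_pairwise_km == pytest.approx(brute, rel=1e-9)
        assert 100.0 <= sp.ci_low_km <= sp.ci_high_km <= 300.0

    def test_single_point_rejected(self):
        with pytest.raises(ValueError):
            migratory_spread([(0.0, 0.0)])

    def test_resampling_quantiles_converge(self):
        rng = np.random.default_rng(3)
        pts = [(float(la), float(lo)) for la, lo in
               zip(rng.uniform(50, 65, 12), rng.uniform(10, 40, 12))]
        small = migratory_spread(pts, n_resamples=1000, seed=5)
        large = migratory_spread(pts, n_resamples=100_000, seed=5)
        assert small.ci_low_km == pytest.approx(large.ci_low_km, rel=0.02)
        assert small.ci_high_km == pytest.approx(large.ci_high_km, rel=0.02)


class TestConvexRange:
    def test_one_degree_box_area(self):
        pts = [(-0.5, -0.5), (-0.5, 0.5), (0.5, -0.5), (0.5, 0.5)]
        rp = convex_range(pts)
        # exact spherical quadrangle area
        exact = 6371.0 ** 2 * math.radians(1.0) * 2 * math.sin(math.radians(0.5))
        assert rp.area_km2 == pytest.approx(exact, rel=0.005)

    def test_collinear_points_rejected(self):
        with pytest.raises(ValueError):
            convex_range([(0.0, 0.0), (0.0, 1.0), (0.0, 2.0)])

    def test_interior_point_leaves_hull_unchanged(self):
        pts = [(-0.5, -0.5), (-0.5, 0.5), (0.5, -0.5), (0.5, 0.5)]
        rp1 = convex_range(pts)
        rp2 = convex_range(pts + [(0.0, 0.0)])
        assert rp2.area_km2 == pytest.approx(rp1.area_km2, rel=1e-9)


class TestRangeOverlap:
    def test_identical_polygons(self):
        rp = convex_range([(-1.0, -1.0), (-1.0, 1.0), (1.0, 1.0), (1.0, -1.0)])
        assert range_overlap(rp, rp) == pytest.approx((1.0, 1.0, 1.0))

    def test_disjoint_polygons(self):
        a = convex_range([(0.0, 0.0), (0.0, 1.0), (1.0, 0.0)])
        b = convex_range([(10.0, 10.0), (10.0, 11.0), (11.0, 10.0)])
        assert range_overlap(a, b) == (0.0, 0.0, 0.0)

    def test_half_overlap(self):
        """B equals the left half of A -> fractions (0.5, 1, 0.5)."""
        a = convex_range([(-1.0, -2.0), (-1.0, 2.0), (1.0, 2.0), (1.0, -2.0)])
        b = convex_range([(-1.0, -2.0), (-1.0, 0.0), (1.0, 0.0), (1.0, -2.0)])
        fa, fb, fu = range_overlap(a, b)
        assert fa == pytest.approx(0.5, abs=0.01)
        assert fb == pytest.approx(1.0, abs=0.01)
        assert fu == pytest.approx(0.5, abs=0.01)

    def test_union_fraction_bounded(self):
        a = convex_range([(0.0, 0.0), (0.0, 2.0), (2.0, 2.0), (2.0, 0.0)])
        b = convex_range([(1.0, 1.0), (1.0, 3.0), (3.0, 3.0), (3.0, 1.0)])
        fa, fb, fu = range_overlap(a, b)
        assert 0.0 <= fu <= min(fa, fb) <= 1.0


class TestLoopContrast:
    def test_identical_longitudes_null(self):
        records = [(f"b{i}", season, 20.0 + i)
                   for i in range(5) for season in ("spring", "autumn")]
        out = loop_contrast(records, n_permutations=200, seed=0)
        assert out["group_delta_lon"] == 0.0
        assert out["p_value"] > 0.5

    def test_planted_shift_recovered(self):
        """A +7.8 degree autumn shift is recovered and significant."""
        rng = np.random.default_rng(4)
        records = []
        for i in range(12):
            base = rng.uniform(15, 30)
            for _ in range(3):
                records.append((f"b{i}", "spring", base + rng.normal(0, 1.5)))
                records.append((f"b{i}", "autumn", base + 7.8 + rng.normal(0, 1.5)))
        out = loop_contrast(records, n_permutations=500, seed=0)
        assert out["group_delta_lon"] == pytest.approx(7.8, abs=1.0)
        assert out["p_value"] < 0.01

    def test_bird_missing_a_season_excluded(self):
        records = [("b1", "spring", 10.0), ("b1", "autumn", 12.0),
                   ("b2", "spring", 11.0)]
        out = loop_contrast(records, n_permutations=50, seed=0)
        assert out["n_birds"] == 1
        assert out["excluded_birds"] == ["b2"]

    def test_all_birds_one_season_rejected(self):
        with pytest.raises(ValueError):
            loop_contrast([("b1", "spring", 10.0)], n_permutations=10)


class TestFlightArithmetic:
    def test_stationary_hours_liberia_spring(self):
        assert stationary_hours_per_day(2008.0, 3.1, 43.0) == pytest.approx(8.9, abs=0.05)

    def test_stationary_hours_nigeria_spring(self):
        assert stationary_hours_per_day(2411.0, 3.1, 43.0) == pytest.approx(5.9, abs=0.05)

    def test_zero_when_flying_the_whole_leg(self):
        assert stationary_hours_per_day(43.0 * 24.0 * 2.0, 2.0, 43.0) == 0.0

    def test_negative_clipped_with_warning(self):
        with pytest.warns(UserWarning):
            assert stationary_hours_per_day(5000.0, 1.0, 43.0) == 0.0

    def test_leg_speed_average_whinchat(self):
        assert leg_speed(2043.0, 3.1) == pytest.approx(27.5, abs=0.05)

    def test_leg_speed_fastest_bird(self):
        assert leg_speed(5054.0, 7.0) == pytest.approx(30.1, abs=0.05)

    def test_zero_distance(self):
        assert leg_speed(0.0, 3.0) == 0.0


class TestFuelBudget:
    def test_daily_gain_fastest_bird(self):
        """12 g gained over a 7-day journey is 1.7 g per day."""
        out = fuel_budget(5000.0, 7.0, departure_load=13.0, lean_mass=13.0)
        assert out["extra_mass_needed_g"] == pytest.approx(12.0)
        assert out["daily_gain_g"] == pytest.approx(1.7, abs=0.05)
        assert out["deposition_rate"] == pytest.approx(0.13, abs=0.005)

    def test_full_load_needs_nothing(self):
        out = fuel_budget(5000.0, 7.0, departure_load=25.0)
        assert out["extra_mass_needed_g"] == 0.0

    def test_linear_scaling(self):
        out = fuel_budget(2500.0, 5.0)
        assert out["required_fuel_g"] == pytest.approx(12.5)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            fuel_budget(-1.0, 5.0)


class TestPooledResighting:
    STUDIES = [(16, 37, 10, 36), (74, 279, 39, 130), (10, 43, 10, 49), (9, 32, 19, 66)]

    def test_pooled_tagged_rate(self):
        out = pool_resighting(self.STUDIES)
        assert out["pooled_tagged_pct"] == pytest.approx(27.8, abs=0.05)

    def test_pooled_control_rate(self):
        out = pool_resighting(self.STUDIES)
        assert out["pooled_control_pct"] == pytest.approx(27.9, abs=0.05)

    def test_single_study(self):
        out = pool_resighting([(5, 10, 5, 10)])
        assert out["pooled_control_pct"] == 50.0
        assert out["difference_pct"] == 0.0
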