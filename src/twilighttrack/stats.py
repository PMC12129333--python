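"""Population-level movement statistics.

Migratory spread with a randomization CI, minimum-convex-polygon breeding
ranges and their overlap, the loop-migration longitude contrast with a
within-bird permutation test, and the closed-form flight-time and fuel
arithmetic used to partition migration legs into flying and stationary
hours.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
from shapely.geometry import Polygon, MultiPoint

from .events import haversine, EARTH_RADIUS_KM

__all__ = [
    "SpreadEstimate",
    "RangePolygon",
    "FlightBudget",
    "migratory_spread",
    "convex_range",
    "range_overlap",
    "loop_contrast",
    "stationary_hours_per_day",
    "leg_speed",
    "fuel_budget",
    "pool_resighting",
    "DEFAULT_FLIGHT_SPEED_KMH",
    "FUEL_PER_5000KM_G",
]

#: radar-measured flight speed of a migrating chat-sized passerine.
DEFAULT_FLIGHT_SPEED_KMH = 43.0

#: extra body reserves (g) needed to cover ~5000 km of flight.
FUEL_PER_5000KM_G = 25.0


@dataclass(frozen=True)
class SpreadEstimate:
    mean_pairwise_km: float
    ci_low_km: float
    ci_high_km: float
    n_points: int
    n_resamples: int


@dataclass(frozen=True)
class RangePolygon:
    """Convex hull of a point cloud with its equal-area km^2 area.

    ``vertices`` are (lat, lon) pairs; the area is computed on a Lambert
    azimuthal equal-area projection centred on the points' centroid, so
    km^2 values are comparable across ranges of millions of km^2 without
    spherical-polygon machinery.
    """

    vertices: tuple
    area_km2: float
    n_points: int
    center: tuple  # (lat, lon) of the projection centre


@dataclass(frozen=True)
class FlightBudget:
    flight_speed: float = DEFAULT_FLIGHT_SPEED_KMH  # km/h
    leg_distance: float = 0.0  # km
    leg_duration: float = 0.0  # days
    fuel_per_5000km: float = FUEL_PER_5000KM_G  # g
    lean_mass: float = math.nan  # g, no universal default


def migratory_spread(
    points: Sequence[tuple[float, float]],
    n_resamples: int = 10_000,
    seed: int = 0,
) -> SpreadEstimate:
    """Mean pairwise great-circle distance between breeding locations.

    The point estimate is the mean over *all* unordered pairs; the CI is
    the randomization interval from ``n_resamples`` randomly selected
    pairs (drawn with replacement from the distinct unordered pairs),
    using the 2.5th/97.5th order statistics (the 250th and 9750th values
    for the default 10,000 resamples).
    """
    pts = list(points)
    if len(pts) < 2:
        raise ValueError("migratory spread needs at least 2 points")
    pair_d = np.array(
        [haversine(a[0], a[1], b[0], b[1]) for a, b in combinations(pts, 2)]
    )
    rng = np.random.default_rng(seed)
    draws = np.sort(pair_d[rng.integers(0, pair_d.size, size=n_resamples)])
    k_low = max(int(round(0.025 * n_resamples)) - 1, 0)
    k_high = min(int(round(0.975 * n_resamples)) - 1, n_resamples - 1)
    return SpreadEstimate(
        mean_pairwise_km=float(pair_d.mean()),
        ci_low_km=float(draws[k_low]),
        ci_high_km=float(draws[k_high]),
        n_points=len(pts),
        n_resamples=n_resamples,
    )


def _laea_project(lats, lons, center_lat, center_lon):
    """Lambert azimuthal equal-area projection to km coordinates."""
    phi = np.radians(np.asarray(lats, float))
    lam = np.radians(np.asarray(lons, float))
    phi0 = math.radians(center_lat)
    lam0 = math.radians(center_lon)
    c = 1.0 + np.sin(phi0) * np.sin(phi) + np.cos(phi0) * np.cos(phi) * np.cos(lam - lam0)
    k = np.sqrt(2.0 / c)
    x = EARTH_RADIUS_KM * k * np.cos(phi) * np.sin(lam - lam0)
    y = EARTH_RADIUS_KM * k * (
        np.cos(phi0) * np.sin(phi) - np.sin(phi0) * np.cos(phi) * np.cos(lam - lam0)
    )
    return x, y


def convex_range(points: Sequence[tuple[float, float]]) -> RangePolygon:
    """Minimum convex polygon of (lat, lon) points with equal-area km^2."""
    pts = [(float(a), float(b)) for a, b in points]
    distinct = sorted(set(pts))
    if len(distinct) < 3:
        raise ValueError(f"convex range needs >= 3 distinct points, got {len(distinct)}")
    lats = [p[0] for p in pts]
    lons = [p[1] for p in pts]
    c_lat, c_lon = float(np.mean(lats)), float(np.mean(lons))
    x, y = _laea_project(lats, lons, c_lat, c_lon)
    hull = MultiPoint(list(zip(x, y))).convex_hull
    if hull.geom_type != "Polygon":
        raise ValueError(
            f"degenerate geometry: {len(distinct)} distinct points are collinear"
        )
    # back-report hull vertices in geographic coordinates
    verts = []
    hx, hy = hull.exterior.coords.xy
    for xx, yy in zip(hx[:-1], hy[:-1]):
        verts.append(_laea_unproject(xx, yy, c_lat, c_lon))
    return RangePolygon(
        vertices=tuple(verts),
        area_km2=float(hull.area),
        n_points=len(pts),
        center=(c_lat, c_lon),
    )


def _laea_unproject(x, y, center_lat, center_lon):
    rho = math.hypot(x, y)
    if rho == 0.0:
        return center_lat, center_lon
    c = 2.0 * math.asin(min(1.0, rho / (2.0 * EARTH_RADIUS_KM)))
    phi0 = math.radians(center_lat)
    lat = math.asin(
        math.cos(c) * math.sin(phi0) + y * math.sin(c) * math.cos(phi0) / rho
    )
    lon = math.radians(center_lon) + math.atan2(
        x * math.sin(c),
        rho * math.cos(c) * math.cos(phi0) - y * math.sin(c) * math.sin(phi0),
    )
    return math.degrees(lat), math.degrees(lon)


def range_overlap(
    poly_a: RangePolygon, poly_b: RangePolygon
) -> tuple[float, float, float]:
    """Intersection fractions (overlap/A, overlap/B, overlap/union).

    Both polygons are re-projected on a common equal-area centre midway
    between their own centres so the intersection is computed in one
    plane.  Disjoint polygons give zeros.
    """
    c_lat = 0.5 * (poly_a.center[0] + poly_b.center[0])
    c_lon = 0.5 * (poly_a.center[1] + poly_b.center[1])

    def as_poly(rp: RangePolygon) -> Polygon:
        lats = [v[0] for v in rp.vertices]
        lons = [v[1] for v in rp.vertices]
        x, y = _laea_project(lats, lons, c_lat, c_lon)
        return Polygon(zip(x, y))

    a, b = as_poly(poly_a), as_poly(poly_b)
    inter = a.intersection(b).area
    union = a.union(b).area
    if a.area == 0.0 or b.area == 0.0:
        return 0.0, 0.0, 0.0
    return inter / a.area, inter / b.area, (inter / union if union else 0.0)


def loop_contrast(
    stopovers: Sequence[tuple[str, str, float]],
    n_permutations: int = 1000,
    seed: int = 0,
) -> dict:
    """Seasonal longitude contrast: is the autumn route east of spring?

    ``stopovers`` are (bird_id, season, longitude) records with season
    ``spring`` or ``autumn``.  The per-bird statistic is mean(autumn
    longitudes) - mean(spring longitudes); the group statistic is the mean
    over birds; significance is assessed by permuting season labels
    *within* each bird (preserving per-bird sample sizes), two-sided, with
    the observed statistic included in the null set.  Birds missing a
    season are excluded and reported.
    """
    rng = np.random.default_rng(seed)
    by_bird: dict[str, dict[str, list[float]]] = {}
    for bird, season, lon in stopovers:
        if season not in ("spring", "autumn"):
            continue
        by_bird.setdefault(bird, {"spring": [], "autumn": []})[season].append(float(lon))
    included, excluded = [], []
    for bird, d in by_bird.items():
        if d["spring"] and d["autumn"]:
            included.append(bird)
        else:
            excluded.append(bird)
    if not included:
        raise ValueError("no bird has stopovers in both seasons")
    deltas = {}
    pools = {}
    for bird in included:
        d = by_bird[bird]
        deltas[bird] = float(np.mean(d["autumn"]) - np.mean(d["spring"]))
        pools[bird] = (np.array(d["spring"] + d["autumn"]), len(d["spring"]))
    observed = float(np.mean(list(deltas.values())))
    perm_stats = np.empty(n_permutations)
    for i in range(n_permutations):
        vals = []
        for bird in included:
            pool, n_spring = pools[bird]
            perm = rng.permutation(pool)
            vals.append(perm[n_spring:].mean() - perm[:n_spring].mean())
        perm_stats[i] = np.mean(vals)
    p = (1.0 + np.sum(np.abs(perm_stats) >= abs(observed))) / (n_permutations + 1.0)
    return {
        "per_bird_delta_lon": deltas,
        "group_delta_lon": observed,
        "p_value": float(p),
        "n_birds": len(included),
        "excluded_birds": excluded,
        "n_permutations": n_permutations,
    }


def stationary_hours_per_day(
    leg_distance: float,
    leg_duration: float,
    flight_speed: float = DEFAULT_FLIGHT_SPEED_KMH,
) -> float:
    """Hours per day of a migration leg spent not flying.

    Computed as 24 x (observed leg duration - predicted flying time at
    ``flight_speed``) / observed duration.  A leg faster than the assumed
    flight speed would give a negative value; it is clipped to 0 with a
    warning since it indicates an underestimated flight speed.
    """
    if leg_duration <= 0 or flight_speed <= 0:
        raise ValueError("duration and flight speed must be positive")
    duration_h = leg_duration * 24.0
    stationary = 24.0 * (duration_h - leg_distance / flight_speed) / duration_h
    if stationary < 0.0:
        import warnings

        warnings.warn(
            f"leg of {leg_distance:.0f} km in {leg_duration:.1f} d implies flight "
            f"faster than {flight_speed} km/h; clipping stationary time to 0"
        )
        return 0.0
    return stationary


def leg_speed(distance: float, duration: float) -> float:
    """Ground speed over a migration leg in km/h (duration in days)."""
    if duration <= 0:
        raise ValueError("duration must be positive")
    return distance / (24.0 * duration)


def fuel_budget(
    distance: float,
    journey_days: float,
    fuel_per_5000km: float = FUEL_PER_5000KM_G,
    departure_load: float = 0.0,
    lean_mass: float = math.nan,
) -> dict:
    """Linear fuel arithmetic for a migration journey.

    Fuel requirement scales linearly with distance (``fuel_per_5000km``
    grams per 5000 km).  The extra mass to be gained en route is the
    requirement minus what was carried at departure; ``daily_gain``
    spreads it over the journey; ``deposition_rate`` expresses the daily
    gain as a fraction of lean mass (NaN when lean mass is not supplied —
    it has no universal default for a small chat).
    """
    if distance < 0 or journey_days <= 0 or fuel_per_5000km <= 0:
        raise ValueError("inputs must be positive")
    required = fuel_per_5000km * distance / 5000.0
    extra = max(required - departure_load, 0.0)
    daily = extra / journey_days
    rate = daily / lean_mass if lean_mass and not math.isnan(lean_mass) else math.nan
    return {
        "required_fuel_g": required,
        "extra_mass_needed_g": extra,
        "daily_gain_g": daily,
        "deposition_rate": rate,
    }


def pool_resighting(
    counts: Sequence[tuple[int, int, int, int]]
) -> dict:
    """Pooled resighting rates for control vs tagged groups across studies.

    ``counts`` rows are (control_resighted, control_total, tagged_resighted,
    tagged_total).  Returns per-study and pooled percentages (pooled =
    summed resighted / summed totals) and their difference.
    """
    c_res = c_tot = t_res = t_tot = 0
    per_study = []
    for cr, ct, tr, tt in counts:
        if ct <= 0 or tt <= 0:
            raise ValueError("totals must be positive")
        per_study.append((100.0 * cr / ct, 100.0 * tr / tt))
        c_res += cr
        c_tot += ct
        t_res += tr
        t_tot += tt
    pooled_c = 100.0 * c_res / c_tot
    pooled_t = 100.0 * t_res / t_tot
    return {
        "per_study_pct": per_study,
        "pooled_control_pct": pooled_c,
        "pooled_tagged_pct": pooled_t,
        "difference_pct": pooled_t - pooled_c,
    }
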