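"""Simulated annual migrations and the twilight series a geolocator records.

The generator emulates the study design of an Afro-Palearctic songbird
tracked by archival light loggers: a main sub-Saharan non-breeding site
near 8-10 degN (with an optional secondary non-breeding site used by about
a quarter of birds, displaced ~500 km), a spring migration of several
stopovers to a breeding site at 45-70 degN, a ~110-day breeding period,
and an autumn return whose stopovers may be shifted east of the spring
corridor (loop migration).  Twilights are produced by the forward solar
model at the (great-circle interpolated) daily position, then degraded by
one-sided shading noise (shading can only delay apparent sunrise and
advance apparent sunset), symmetric jitter, linear clock drift, missing
days, and optional tag failure part-way through the year.  Ground-truth
site/leg labels are returned alongside, so every downstream stage can be
scored against the truth.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .events import haversine
from .solar import twilight_times

__all__ = [
    "SimSite",
    "NoiseModel",
    "SimTrack",
    "TrackConfig",
    "simulate_track",
    "simulate_twilights",
    "render_light_log",
    "simulate_cohort",
    "COUNTRY_SITES",
    "COMPLETENESS_MIX",
]

#: tagging-site coordinates of the two study populations (lat, lon).
COUNTRY_SITES = {
    "Nigeria": (9.8659, 8.9686),
    "Liberia": (8.1190, -9.9760),
}

#: per-country longitude envelope of the breeding range.
BREEDING_LON_RANGES = {"Nigeria": (25.0, 50.0), "Liberia": (5.0, 35.0)}

#: eastward shift (degrees) of autumn stopovers relative to the spring
#: corridor; the Nigerian population shows a clear clockwise loop.
AUTUMN_LON_SHIFT = {"Nigeria": 7.8, "Liberia": 2.8}

#: cohort completeness mix (full, to_breeding, failed_spring, failed_autumn)
#: out of 64 tags.
COMPLETENESS_MIX = {"full": 41, "to_breeding": 9, "failed_spring": 13, "failed_autumn": 1}


@dataclass(frozen=True)
class SimSite:
    label: str  # main_nonbreeding | secondary_nonbreeding | stopover | breeding
    lat: float
    lon: float
    arrive: dt.date
    depart: dt.date

    def __post_init__(self):
        if self.depart < self.arrive:
            raise ValueError(f"site departs {self.depart} before arriving {self.arrive}")


@dataclass(frozen=True)
class NoiseModel:
    """Twilight error model of a light logger.

    ``shade_mean`` is the mean of an exponential one-sided error that only
    delays sunrise / advances sunset (vegetation or weather shading the
    sensor); ``jitter_sd`` a small symmetric Gaussian error (clipped at
    4 sd so the one-sidedness of shading dominates); ``clock_drift`` the
    minutes the tag clock has gained by the end of the deployment.
    """

    shade_mean: float = 8.0  # minutes
    jitter_sd: float = 2.0  # minutes
    missing_day_prob: float = 0.0
    clock_drift: float = 0.0  # minutes over deployment

    def __post_init__(self):
        if self.shade_mean < 0:
            raise ValueError("shade_mean must be >= 0")
        if not 0 <= self.missing_day_prob < 1:
            raise ValueError("missing_day_prob must be in [0, 1)")


ZERO_NOISE = NoiseModel(shade_mean=0.0, jitter_sd=0.0)


@dataclass
class SimTrack:
    bird_id: str
    country: str
    sites: list[SimSite]
    completeness: str = "full"
    failure_date: Optional[dt.date] = None

    @property
    def truth_table(self) -> pd.DataFrame:
        """Per-leg true distance (km) and duration (half days)."""
        rows = []
        for k in range(len(self.sites) - 1):
            a, b = self.sites[k], self.sites[k + 1]
            rows.append(
                {
                    "leg_id": k + 1,
                    "from_label": a.label,
                    "to_label": b.label,
                    "depart": a.depart,
                    "arrive": b.arrive,
                    "distance_km": haversine(a.lat, a.lon, b.lat, b.lon),
                    "duration_days": (b.arrive.toordinal() - a.depart.toordinal()) - 0.5,
                }
            )
        return pd.DataFrame(rows)

    @property
    def start(self) -> dt.date:
        return self.sites[0].arrive

    @property
    def end(self) -> dt.date:
        last = self.sites[-1].depart
        return min(last, self.failure_date) if self.failure_date else last


@dataclass(frozen=True)
class TrackConfig:
    """Study conditions for one simulated annual cycle."""

    country: str = "Nigeria"
    year: int = 2019
    main_site: Optional[tuple[float, float]] = None
    breeding_lat_range: tuple[float, float] = (45.0, 70.0)
    breeding_lon_range: Optional[tuple[float, float]] = None
    n_stopovers_max: int = 6
    typical_leg_km: float = 2043.0  # mean migration-leg distance emulated
    secondary_site_prob: float = 0.25
    secondary_displacement_km: float = 503.6
    secondary_displacement_sd_km: float = 120.0
    spring_departure_mean: tuple[int, int] = (4, 9)  # Apr 9 (+delay for Nigeria)
    nigeria_departure_delay_days: float = 8.3
    departure_sd_days: float = 5.0
    breeding_duration_mean: float = 109.0
    breeding_duration_sd: float = 7.0
    stopover_duration_mean_spring: float = 5.0
    stopover_duration_mean_autumn: float = 8.0
    travel_speed_kmh: float = 27.5  # ground speed within a leg, incl. daily rests
    autumn_lon_shift: Optional[float] = None  # default per-country loop shift
    stopover_lon_jitter: float = 1.5  # degrees
    min_site_lon_gap: float = 4.2  # degrees, minimum observed relocation
    allow_secondary: bool = True


def _gc_interpolate(lat1, lon1, lat2, lon2, frac):
    """Point a fraction ``frac`` along the great circle between two points."""
    p1 = np.radians([lat1, lon1])
    p2 = np.radians([lat2, lon2])
    v1 = np.array(
        [np.cos(p1[0]) * np.cos(p1[1]), np.cos(p1[0]) * np.sin(p1[1]), np.sin(p1[0])]
    )
    v2 = np.array(
        [np.cos(p2[0]) * np.cos(p2[1]), np.cos(p2[0]) * np.sin(p2[1]), np.sin(p2[0])]
    )
    omega = math.acos(np.clip(np.dot(v1, v2), -1.0, 1.0))
    if omega < 1e-12:
        return lat1, lon1
    v = (math.sin((1 - frac) * omega) * v1 + math.sin(frac * omega) * v2) / math.sin(omega)
    lat = math.degrees(math.asin(np.clip(v[2], -1.0, 1.0)))
    lon = math.degrees(math.atan2(v[1], v[0]))
    return lat, lon


def _leg_gap_days(dist_km: float, speed_kmh: float) -> int:
    """Whole days between departure evening and arrival morning."""
    dur = max(0.5, round(dist_km / (speed_kmh * 24.0) * 2.0) / 2.0)
    return max(1, int(math.ceil(dur + 0.5)))


def simulate_track(config: TrackConfig = TrackConfig(), seed: int = 0) -> SimTrack:
    """One reproducible annual migration (same seed, same track)."""
    rng = np.random.default_rng(seed)
    country = config.country
    if country not in COUNTRY_SITES and config.main_site is None:
        raise ValueError(f"unknown country {country!r} and no main_site given")
    main_lat, main_lon = config.main_site or COUNTRY_SITES[country]
    lon_lo, lon_hi = config.breeding_lon_range or BREEDING_LON_RANGES.get(
        country, (5.0, 50.0)
    )
    lat_lo, lat_hi = config.breeding_lat_range
    if lat_lo > lat_hi or lon_lo > lon_hi:
        raise ValueError("infeasible breeding ranges")
    loop_shift = (
        config.autumn_lon_shift
        if config.autumn_lon_shift is not None
        else AUTUMN_LON_SHIFT.get(country, 0.0)
    )

    year = config.year
    tag_date = dt.date(year, 1, 5)
    m, d = config.spring_departure_mean
    depart_mean = dt.date(year, m, d).toordinal()
    if country == "Nigeria":
        depart_mean += config.nigeria_departure_delay_days
    depart_ord = int(round(rng.normal(depart_mean, config.departure_sd_days)))
    depart_spring = dt.date.fromordinal(depart_ord)

    sites: list[SimSite] = []
    # --- non-breeding phase (main + optional secondary site) -------------
    use_secondary = config.allow_secondary and rng.random() < config.secondary_site_prob
    if use_secondary:
        disp = max(
            260.0,
            rng.normal(config.secondary_displacement_km, config.secondary_displacement_sd_km),
        )
        # Liberian birds shift north (shortening the crossing); Nigerian
        # birds mostly move southwest, per geographic availability.
        if country == "Liberia" or rng.random() < 0.1:
            bearing = rng.uniform(-30.0, 30.0)  # northward
        else:
            bearing = rng.uniform(225.0, 270.0)  # west-southwestward
        dlat = disp / 111.19 * math.cos(math.radians(bearing))
        dlon = disp / (111.19 * math.cos(math.radians(main_lat))) * math.sin(
            math.radians(bearing)
        )
        sec_lat = float(np.clip(main_lat + dlat, 4.0, 17.0))
        sec_lon = main_lon + dlon
        move_date = dt.date.fromordinal(
            int(rng.integers(dt.date(year, 2, 10).toordinal(), dt.date(year, 3, 10).toordinal()))
        )
        gap = _leg_gap_days(haversine(main_lat, main_lon, sec_lat, sec_lon),
                            config.travel_speed_kmh)
        sites.append(SimSite("main_nonbreeding", main_lat, main_lon, tag_date, move_date))
        sites.append(
            SimSite(
                "secondary_nonbreeding",
                sec_lat,
                sec_lon,
                move_date + dt.timedelta(days=gap),
                depart_spring,
            )
        )
    else:
        sites.append(SimSite("main_nonbreeding", main_lat, main_lon, tag_date, depart_spring))

    # --- breeding site ----------------------------------------------------
    breed_lat = float(rng.uniform(lat_lo, lat_hi))
    breed_lon = float(rng.uniform(lon_lo, lon_hi))

    def route(end_lat, end_lon, n_stops_cap, stop_mean, lon_shift, when):
        """Append stopovers and a terminal site along a great-circle corridor.

        Stopovers are spaced so legs come out near the study's typical
        ~2,000 km, and consecutive sites are kept at least
        ``min_site_lon_gap`` degrees of longitude apart (the minimum
        relocation observed in this study system, the smallest shift
        reliably readable from twilight curves); waypoints that would
        crowd below that spacing are dropped.
        """
        nonlocal sites
        cur = sites[-1]
        total = haversine(cur.lat, cur.lon, end_lat, end_lon)
        n_by_dist = round(total / config.typical_leg_km) - 1 + int(rng.integers(0, 2))
        n_by_lon = int(abs(end_lon - cur.lon) // (config.min_site_lon_gap + 0.5)) - 1
        n_stops = int(np.clip(min(n_by_dist, n_by_lon), 1, n_stops_cap))
        fracs = [
            (i + 1) / (n_stops + 1) + rng.uniform(-0.3, 0.3) / (n_stops + 1)
            for i in range(n_stops)
        ]
        waypoints = []
        for f in fracs:
            wlat, wlon = _gc_interpolate(cur.lat, cur.lon, end_lat, end_lon, float(f))
            wlon += lon_shift + rng.normal(0.0, config.stopover_lon_jitter)
            waypoints.append((wlat, wlon))
        spaced = []
        prev_lon = cur.lon
        for wlat, wlon in waypoints:
            if (
                abs(wlon - prev_lon) >= config.min_site_lon_gap
                and abs(end_lon - wlon) >= config.min_site_lon_gap
            ):
                spaced.append((wlat, wlon))
                prev_lon = wlon
        waypoints = spaced + [(end_lat, end_lon)]
        date = cur.depart
        for i, (wlat, wlon) in enumerate(waypoints):
            prev = sites[-1]
            gap = _leg_gap_days(
                haversine(prev.lat, prev.lon, wlat, wlon), config.travel_speed_kmh
            )
            arrive = date + dt.timedelta(days=gap)
            last = i == len(waypoints) - 1
            if last:
                sites.append(SimSite(when, wlat, wlon, arrive, arrive))  # depart set later
                return
            stay = max(2, int(round(rng.gamma(2.0, stop_mean / 2.0))))
            depart = arrive + dt.timedelta(days=stay)
            sites.append(SimSite("stopover", wlat, wlon, arrive, depart))
            date = depart

    route(breed_lat, breed_lon, config.n_stopovers_max,
          config.stopover_duration_mean_spring, 0.0, "breeding")
    breed_stay = max(60, int(round(rng.normal(config.breeding_duration_mean,
                                              config.breeding_duration_sd))))
    b = sites[-1]
    sites[-1] = replace(b, depart=b.arrive + dt.timedelta(days=breed_stay))

    route(main_lat, main_lon, config.n_stopovers_max,
          config.stopover_duration_mean_autumn, loop_shift, "final_nonbreeding")
    f = sites[-1]
    sites[-1] = replace(
        f, label="main_nonbreeding", depart=f.arrive + dt.timedelta(days=45)
    )
    return SimTrack(bird_id=f"sim{seed:05d}", country=country, sites=sites)


def truncate_track(track: SimTrack, completeness: str, rng: np.random.Generator) -> SimTrack:
    """Apply a tag-failure date matching a completeness category."""
    breeding = next(s for s in track.sites if s.label == "breeding")
    if completeness == "full":
        failure = None
    elif completeness == "to_breeding":
        mid = breeding.arrive.toordinal() + 10
        failure = dt.date.fromordinal(int(rng.integers(mid, breeding.depart.toordinal())))
    elif completeness == "failed_spring":
        dep = track.sites[0].depart.toordinal()
        failure = dt.date.fromordinal(
            int(rng.integers(dep + 2, breeding.arrive.toordinal() - 1))
        )
    elif completeness == "failed_autumn":
        failure = dt.date.fromordinal(
            int(rng.integers(breeding.depart.toordinal() + 2,
                             track.sites[-1].arrive.toordinal() - 1))
        )
    else:
        raise ValueError(f"unknown completeness category {completeness!r}")
    return replace_track(track, completeness=completeness, failure_date=failure)


def replace_track(track: SimTrack, **kw) -> SimTrack:
    return SimTrack(
        bird_id=kw.get("bird_id", track.bird_id),
        country=kw.get("country", track.country),
        sites=kw.get("sites", track.sites),
        completeness=kw.get("completeness", track.completeness),
        failure_date=kw.get("failure_date", track.failure_date),
    )


def _position_on(track: SimTrack, date: dt.date):
    """(lat, lon, state, index): the bird's whereabouts on a calendar day."""
    for i, s in enumerate(track.sites):
        if s.arrive <= date <= s.depart:
            return s.lat, s.lon, "stationary", i
    for i in range(len(track.sites) - 1):
        a, b = track.sites[i], track.sites[i + 1]
        if a.depart < date < b.arrive:
            frac = (date.toordinal() - a.depart.toordinal()) / (
                b.arrive.toordinal() - a.depart.toordinal()
            )
            lat, lon = _gc_interpolate(a.lat, a.lon, b.lat, b.lon, frac)
            return lat, lon, "migrating", i + 1
    raise ValueError(f"{date} outside track span")


def simulate_twilights(
    track: SimTrack,
    sun_elevation: float = -3.5,
    noise: NoiseModel = ZERO_NOISE,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Render the twilight series a tag would record along a track.

    Returns ``(twilights, truth)``: the twilight table (date, sunrise_utc,
    sunset_utc, polar_flag, missing) and the ground-truth day labels
    (date, state, site_or_leg, lat, lon).  Shading noise only delays
    sunrise and advances sunset; jitter is symmetric but clipped; drift is
    linear over the deployment.
    """
    rng = np.random.default_rng(seed)
    days = pd.date_range(track.start, track.end, freq="D").date
    n = len(days)
    tw_rows, truth_rows = [], []
    for k, date in enumerate(days):
        lat, lon, state, idx = _position_on(track, date)
        truth_rows.append({"date": date, "state": state, "site_or_leg": idx,
                           "lat": lat, "lon": lon})
        pair = twilight_times(lat, lon, date, sun_elevation)
        if pair.polar_flag != "none":
            tw_rows.append({"date": date, "sunrise_utc": math.nan,
                            "sunset_utc": math.nan, "polar_flag": pair.polar_flag,
                            "missing": False})
            continue
        if noise.missing_day_prob and rng.random() < noise.missing_day_prob:
            tw_rows.append({"date": date, "sunrise_utc": math.nan,
                            "sunset_utc": math.nan, "polar_flag": "none",
                            "missing": True})
            continue
        shade_sr = rng.exponential(noise.shade_mean) if noise.shade_mean else 0.0
        shade_ss = rng.exponential(noise.shade_mean) if noise.shade_mean else 0.0
        jit_sr = jit_ss = 0.0
        if noise.jitter_sd:
            jit_sr, jit_ss = np.clip(
                rng.normal(0.0, noise.jitter_sd, size=2),
                -4 * noise.jitter_sd, 4 * noise.jitter_sd,
            )
        drift = noise.clock_drift * (k / max(n - 1, 1))
        sr = pair.sunrise_utc + (shade_sr + jit_sr + drift) / 60.0
        ss = pair.sunset_utc + (-shade_ss + jit_ss + drift) / 60.0
        tw_rows.append({"date": date, "sunrise_utc": sr, "sunset_utc": ss,
                        "polar_flag": "none", "missing": False})
    return pd.DataFrame(tw_rows), pd.DataFrame(truth_rows)


def render_light_log(
    twilights: pd.DataFrame, sample_minutes: int = 5, max_light: float = 64.0
) -> pd.DataFrame:
    """Raw light-log records (timestamp, light) from a twilight table.

    Each day is sampled on a regular grid; records between sunrise and
    sunset carry full light (``max_light``), full darkness is written as
    the logger floor value -1 (so that the conventional threshold of -1
    treats any reading above the floor as genuine daylight).  Missing or
    polar-night days produce all-dark days; polar-day days are fully lit.
    """
    dark = -1.0
    rows = []
    step = sample_minutes / 60.0
    for r in twilights.itertuples(index=False):
        date = pd.Timestamp(r.date)
        flag = getattr(r, "polar_flag", "none")
        for h in np.arange(0.0, 24.0, step):
            if flag == "polar_day":
                light = max_light
            elif flag == "polar_night" or getattr(r, "missing", False):
                light = dark
            else:
                light = max_light if r.sunrise_utc <= h <= r.sunset_utc else dark
            rows.append((date + pd.Timedelta(hours=h), light))
    return pd.DataFrame(rows, columns=["timestamp", "light"])


def simulate_cohort(
    n_birds: int = 64,
    seed: int = 0,
    config: TrackConfig = TrackConfig(),
    noise: NoiseModel = NoiseModel(),
    liberia_fraction: float = 0.25,
    completeness_mix: Optional[dict] = COMPLETENESS_MIX,
) -> list[tuple[SimTrack, pd.DataFrame, pd.DataFrame]]:
    """Simulate a study cohort: (track, twilights, truth) per bird.

    With the default 64 birds the completeness mix is applied exactly
    (41 full / 9 to-breeding / 13 failed-spring / 1 failed-autumn);
    otherwise categories are assigned proportionally.  A quarter of tags
    come from the Liberian site, matching the study's 16/48 split.
    """
    rng = np.random.default_rng(seed)
    if completeness_mix:
        cats = [c for c, k in completeness_mix.items() for _ in range(k)]
        total = len(cats)
        if n_birds != total:
            probs = np.array([completeness_mix[c] for c in completeness_mix]) / total
            cats = list(rng.choice(list(completeness_mix), size=n_birds, p=probs))
        else:
            rng.shuffle(cats)
    else:
        cats = ["full"] * n_birds
    n_lib = int(round(liberia_fraction * n_birds))
    countries = ["Liberia"] * n_lib + ["Nigeria"] * (n_birds - n_lib)
    rng.shuffle(countries)
    out = []
    for i in range(n_birds):
        bird_seed = int(rng.integers(0, 2**31 - 1))
        cfg = replace(config, country=countries[i])
        track = simulate_track(cfg, seed=bird_seed)
        track = truncate_track(track, cats[i], rng)
        track = replace_track(track, bird_id=f"bird{i:03d}")
        tw, truth = simulate_twilights(track, noise=noise, seed=bird_seed + 1)
        out.append((track, tw, truth))
    return out
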