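"""Per-leg migration event tables and per-bird annual summaries.

Builds the row-per-migration-leg structure used for population comparisons:
each leg records the great-circle distance and half-day-resolution duration
between consecutive stationary periods, a season label, and equinox
proximity; per-bird summaries aggregate totals, stopover counts and
phenology (Julian dates of departures and arrivals).

Half-day convention: instants are float day values ``date.toordinal() +
0.0`` (sunrise) or ``+ 0.5`` (sunset), so durations subtract exactly.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .geolocation import StationaryPeriod
from .segmentation import flag_equinox

__all__ = [
    "MigrationLeg",
    "AnnualSummary",
    "haversine",
    "julian_date",
    "classify_periods",
    "assign_season",
    "build_legs",
    "summarise_bird",
    "dayval",
    "dayval_to_date",
    "SAHARA_LAT",
    "MIN_SECONDARY_DISPLACEMENT_KM",
    "BREEDING_LAT_FLOOR",
]

EARTH_RADIUS_KM = 6371.0

#: stationary periods south of this latitude count as sub-Saharan.
SAHARA_LAT = 18.0

#: minimum great-circle displacement (km) from the tagging site for a
#: sub-Saharan stationary period to count as a distinct non-breeding site.
MIN_SECONDARY_DISPLACEMENT_KM = 250.0

#: latitude floor for breeding-site candidates (European breeding range).
BREEDING_LAT_FLOOR = 35.0


def dayval(date: dt.date, at_sunset: bool = False) -> float:
    """Float day value at half-day resolution (sunrise = .0, sunset = .5)."""
    return date.toordinal() + (0.5 if at_sunset else 0.0)


def dayval_to_date(value: float) -> dt.date:
    return dt.date.fromordinal(int(value))


def haversine(lat1: float, lon1: float, lat2: float, lon2: float) -> float:
    """Great-circle distance in km on a sphere of radius 6371 km."""
    p1, p2 = math.radians(lat1), math.radians(lat2)
    dphi = p2 - p1
    dlam = math.radians(lon2 - lon1)
    h = math.sin(dphi / 2.0) ** 2 + math.cos(p1) * math.cos(p2) * math.sin(dlam / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * math.asin(min(1.0, math.sqrt(h)))


def julian_date(date: dt.date) -> int:
    """Day of year (Jan 1 = 1; leap years honoured)."""
    return date.timetuple().tm_yday


@dataclass(frozen=True)
class MigrationLeg:
    """Movement between two consecutive stationary periods."""

    bird_id: str
    leg_id: int
    start: float  # dayval, half-day resolution
    end: float
    from_period_id: int
    to_period_id: int
    distance: float  # km
    duration: float  # days
    speed: float  # km/h
    season: str  # spring | autumn | intra_african
    equinox_flag: bool


@dataclass
class AnnualSummary:
    bird_id: str
    country: str
    completeness: str  # full | to_breeding | failed_spring | failed_autumn
    total_distance_spring: float = math.nan
    total_distance_autumn: float = math.nan
    n_stopovers_spring: int = 0
    n_stopovers_autumn: int = 0
    total_duration_spring: float = math.nan
    total_duration_autumn: float = math.nan
    depart_nonbreeding: Optional[int] = None
    arrive_breeding: Optional[int] = None
    depart_breeding: Optional[int] = None
    arrive_nonbreeding: Optional[int] = None
    breeding_duration: float = math.nan
    breeding_lat: float = math.nan
    breeding_lon: float = math.nan


def classify_periods(
    periods: Sequence[StationaryPeriod],
    tagging_lat: float,
    tagging_lon: float,
    sahara_lat: float = SAHARA_LAT,
    min_displacement: float = MIN_SECONDARY_DISPLACEMENT_KM,
    breeding_lat_floor: float = BREEDING_LAT_FLOOR,
    min_secondary_days: float = 2.0,
) -> list[StationaryPeriod]:
    """Classify located stationary periods along one bird's annual cycle.

    * ``main_nonbreeding`` — the period containing the tagging site.  The
      first period of the deployment is always main (the bird was tagged
      there, the one place its location is certain, however noisy the
      light-based estimate); later pre-crossing periods within
      ``min_displacement`` of the tagging site are within-site shifts,
      not new sites, and stay main as well.
    * ``secondary_nonbreeding`` — sub-Saharan periods (lat < ``sahara_lat``)
      at least ``min_displacement`` km from the tagging site, occurring
      before the Sahara crossing and lasting ``min_secondary_days`` or more.
    * ``breeding`` — the longest period at lat > ``breeding_lat_floor``.
    * everything else — ``stopover``.
    """
    periods = sorted(periods, key=lambda p: p.start)
    out = []
    # Sahara crossing = first period at/above sahara_lat
    crossing_idx = next(
        (i for i, p in enumerate(periods) if not math.isnan(p.lat) and p.lat >= sahara_lat),
        len(periods),
    )
    breeding_idx = None
    best_dur = 0.0
    for i, p in enumerate(periods):
        if not math.isnan(p.lat) and p.lat > breeding_lat_floor and p.duration > best_dur:
            breeding_idx, best_dur = i, p.duration
    for i, p in enumerate(periods):
        d_tag = (
            haversine(p.lat, p.lon, tagging_lat, tagging_lon)
            if not math.isnan(p.lat)
            else math.inf
        )
        at_tagging_site = d_tag < min_displacement or (
            not math.isnan(p.lon)
            and abs(p.lon - tagging_lon) < 2.5
            and (math.isnan(p.lat) or p.lat < sahara_lat)
        )
        if i == breeding_idx:
            cls = "breeding"
        elif i == 0 or (i < crossing_idx and at_tagging_site):
            cls = "main_nonbreeding"
        elif breeding_idx is not None and i > breeding_idx and at_tagging_site:
            # the post-breeding return to the tagging site
            cls = "main_nonbreeding"
        elif (
            i < crossing_idx
            and not math.isnan(p.lat)
            and p.lat < sahara_lat
            and d_tag >= min_displacement
            and p.duration >= min_secondary_days
        ):
            cls = "secondary_nonbreeding"
        else:
            cls = "stopover"
        out.append(replace(p, classification=cls))
    return out


def assign_season(
    leg_start: float,
    leg_end: float,
    periods: Sequence[StationaryPeriod],
    include_subsaharan: bool = False,
) -> str:
    """Season of a leg given the classified stationary periods around it.

    Spring runs from the departure from the last sub-Saharan site to the
    breeding arrival; autumn from the breeding departure back to the main
    non-breeding arrival.  Earlier moves between sub-Saharan sites are
    ``intra_african`` unless ``include_subsaharan`` relabels them spring.
    """
    periods = sorted(periods, key=lambda p: p.start)
    breeding = [p for p in periods if p.classification == "breeding"]
    breeding_start = breeding[0].start if breeding else math.inf
    breeding_end = breeding[0].end if breeding else math.inf
    # departure from the last sub-Saharan site before the crossing
    subsaharan = [
        p
        for p in periods
        if p.start < breeding_start
        and not math.isnan(p.lat)
        and p.lat < SAHARA_LAT
    ]
    if subsaharan:
        spring_start = subsaharan[-1].end
    else:
        spring_start = -math.inf
    if breeding and leg_start >= breeding_end:
        return "autumn"
    if leg_start >= spring_start and leg_end <= breeding_start:
        return "spring"
    if not breeding and leg_start >= spring_start:
        return "spring"
    return "spring" if include_subsaharan else "intra_african"


def build_legs(
    bird_id: str,
    periods: Sequence[StationaryPeriod],
    include_subsaharan: bool = False,
) -> list[MigrationLeg]:
    """Legs between consecutive located stationary periods."""
    periods = sorted(periods, key=lambda p: p.start)
    legs = []
    for k in range(len(periods) - 1):
        a, b = periods[k], periods[k + 1]
        start, end = a.end, b.start
        duration = max(end - start, 0.5)
        if math.isnan(a.lat) or math.isnan(b.lat):
            dist = math.nan
        else:
            dist = haversine(a.lat, a.lon, b.lat, b.lon)
        legs.append(
            MigrationLeg(
                bird_id=bird_id,
                leg_id=k + 1,
                start=start,
                end=end,
                from_period_id=a.id,
                to_period_id=b.id,
                distance=dist,
                duration=duration,
                speed=(dist / (24.0 * duration)) if not math.isnan(dist) else math.nan,
                season=assign_season(start, end, periods, include_subsaharan),
                equinox_flag=flag_equinox(dayval_to_date(start), dayval_to_date(end)),
            )
        )
    return legs


def summarise_bird(
    bird_id: str,
    country: str,
    periods: Sequence[StationaryPeriod],
    legs: Sequence[MigrationLeg],
    completeness: str = "full",
    exclude_subsaharan: bool = True,
) -> AnnualSummary:
    """Season totals, stopover counts and phenology for one bird.

    With ``exclude_subsaharan`` (the default) intra-African legs and the
    sub-Saharan stationary periods before the Sahara crossing are left out
    of the spring totals, so spring starts at the departure from the last
    sub-Saharan site.  Totals are sums of leg distances; durations run
    end-to-end (departure to arrival) and therefore include stopovers.
    """
    periods = sorted(periods, key=lambda p: p.start)
    s = AnnualSummary(bird_id=bird_id, country=country, completeness=completeness)
    breeding = next((p for p in periods if p.classification == "breeding"), None)
    if breeding is not None:
        s.breeding_lat, s.breeding_lon = breeding.lat, breeding.lon
        s.breeding_duration = breeding.duration

    spring = [
        l
        for l in legs
        if l.season == "spring" or (not exclude_subsaharan and l.season == "intra_african")
    ]
    autumn = [l for l in legs if l.season == "autumn"]
    if spring:
        s.total_distance_spring = float(np.nansum([l.distance for l in spring]))
        s.total_duration_spring = spring[-1].end - spring[0].start
        s.n_stopovers_spring = max(len(spring) - 1, 0)
        s.depart_nonbreeding = julian_date(dayval_to_date(spring[0].start))
        if breeding is not None and spring[-1].to_period_id == breeding.id:
            s.arrive_breeding = julian_date(dayval_to_date(spring[-1].end))
    if autumn:
        s.total_distance_autumn = float(np.nansum([l.distance for l in autumn]))
        s.total_duration_autumn = autumn[-1].end - autumn[0].start
        s.n_stopovers_autumn = max(len(autumn) - 1, 0)
        if breeding is not None and autumn[0].from_period_id == breeding.id:
            s.depart_breeding = julian_date(dayval_to_date(autumn[0].start))
        if completeness in ("full",):
            s.arrive_nonbreeding = julian_date(dayval_to_date(autumn[-1].end))
    return s


def legs_to_frame(legs: Sequence[MigrationLeg]) -> pd.DataFrame:
    """Event table: one row per migration leg."""
    return pd.DataFrame(
        [
            {
                "bird_id": l.bird_id,
                "leg_id": l.leg_id,
                "start": _iso_halfday(l.start),
                "end": _iso_halfday(l.end),
                "from_period_id": l.from_period_id,
                "to_period_id": l.to_period_id,
                "distance_km": l.distance,
                "duration_days": l.duration,
                "speed_kmh": l.speed,
                "season": l.season,
                "equinox_flag": l.equinox_flag,
            }
            for l in legs
        ]
    )


def _iso_halfday(value: float) -> str:
    date = dayval_to_date(value)
    return f"{date.isoformat()}T{'12:00' if value % 1 else '00:00'}"
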