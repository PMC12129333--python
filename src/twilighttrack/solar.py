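"""Forward and inverse solar geometry for threshold geolocation.

Uses the Spencer (1971) Fourier series for solar declination and the
equation of time, as adopted by the NOAA low-precision solar calculator.
Stated accuracy is about 0.1-0.3 degrees in declination and under a minute
in the equation of time, far finer than the 100-500 km positional accuracy
of light-level geolocation itself.

Conventions
-----------
* All times are decimal hours UTC.  Sunset may exceed 24 h so that a
  twilight pair stays ordered when a day's dark period straddles midnight
  UTC (far-east longitudes).
* Equation of time follows the NOAA sign: positive values mean the true
  sun crosses the local meridian *before* mean noon.
* The sun elevation angle ``a`` is the solar altitude (usually negative)
  at which the tag's light sensor registers twilight.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass
from typing import Literal, Optional

import numpy as np

__all__ = [
    "SolarAngles",
    "TwilightPair",
    "solar_declination",
    "equation_of_time",
    "twilight_times",
    "longitude_from_twilights",
    "latitude_from_daylength",
]

PolarFlag = Literal["none", "polar_day", "polar_night"]

#: |declination| can never exceed the obliquity of the ecliptic.
MAX_DECLINATION = 23.45

#: days within this |declination| band are flagged equinox-degenerate
#: for latitude estimation (~9 days either side of each equinox).
EQUINOX_DECLINATION_DEG = 3.5


@dataclass(frozen=True)
class SolarAngles:
    """Solar geometry for one date (all angles in degrees, EoT in minutes)."""

    date: dt.date
    declination: float
    equation_of_time: float
    hour_angle: float
    sun_elevation: float


@dataclass(frozen=True)
class TwilightPair:
    """One day's sunrise/sunset observation (decimal hours UTC)."""

    date: dt.date
    sunrise_utc: float
    sunset_utc: float
    polar_flag: PolarFlag = "none"

    @property
    def day_length(self) -> float:
        return self.sunset_utc - self.sunrise_utc

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.sunrise_utc + self.sunset_utc)


def _fractional_year(date: dt.date, hour: float = 12.0) -> float:
    """Fractional year angle (radians) at a given UTC hour of the date."""
    year_days = 366.0 if _is_leap(date.year) else 365.0
    doy = date.timetuple().tm_yday
    return 2.0 * math.pi / year_days * (doy - 1 + (hour - 12.0) / 24.0)


def _is_leap(year: int) -> bool:
    return year % 4 == 0 and (year % 100 != 0 or year % 400 == 0)


def solar_declination(date: dt.date) -> float:
    """Solar declination in degrees (Spencer series, accuracy ~0.3 deg)."""
    g = _fractional_year(date)
    decl = (
        0.006918
        - 0.399912 * math.cos(g)
        + 0.070257 * math.sin(g)
        - 0.006758 * math.cos(2 * g)
        + 0.000907 * math.sin(2 * g)
        - 0.002697 * math.cos(3 * g)
        + 0.00148 * math.sin(3 * g)
    )
    return math.degrees(decl)


def equation_of_time(date: dt.date) -> float:
    """Equation of time in minutes (true solar noon earlier when positive)."""
    g = _fractional_year(date)
    return 229.18 * (
        0.000075
        + 0.001868 * math.cos(g)
        - 0.032077 * math.sin(g)
        - 0.014615 * math.cos(2 * g)
        - 0.040849 * math.sin(2 * g)
    )


def _cos_hour_angle(lat: float, declination: float, sun_elevation: float) -> float:
    phi = math.radians(lat)
    delta = math.radians(declination)
    a = math.radians(sun_elevation)
    denom = math.cos(phi) * math.cos(delta)
    if denom == 0.0:
        return math.inf
    return (math.sin(a) - math.sin(phi) * math.sin(delta)) / denom


def twilight_times(
    lat: float, lon: float, date: dt.date, sun_elevation: float
) -> TwilightPair:
    """Times when the sun crosses ``sun_elevation`` at (lat, lon) on a date.

    Solves ``cos H = (sin a - sin phi sin delta) / (cos phi cos delta)`` and
    converts the hour angle H to UTC clock times via the equation of time
    and the 4 min-per-degree longitude offset.  Polar day/night is reported
    through ``polar_flag`` (with sunrise/sunset set to NaN), never raised.
    """
    if not -90.0 <= lat <= 90.0:
        raise ValueError(f"latitude {lat} outside [-90, 90]")
    if not -180.0 < lon <= 180.0:
        raise ValueError(f"longitude {lon} outside (-180, 180]")
    delta = solar_declination(date)
    cos_h = _cos_hour_angle(lat, delta, sun_elevation)
    if cos_h < -1.0:
        return TwilightPair(date, math.nan, math.nan, "polar_day")
    if cos_h > 1.0:
        return TwilightPair(date, math.nan, math.nan, "polar_night")
    half_day = math.degrees(math.acos(cos_h)) / 15.0  # hours
    noon = 12.0 - lon / 15.0 - equation_of_time(date) / 60.0
    return TwilightPair(date, noon - half_day, noon + half_day, "none")


def longitude_from_twilights(pair: TwilightPair) -> float:
    """Longitude (degrees east) from the midpoint of a twilight pair.

    The twilight midpoint is local solar noon; each degree of longitude
    shifts both twilights (and their midpoint) by exactly 4 minutes.
    """
    if pair.polar_flag != "none":
        raise ValueError(f"cannot estimate longitude on a {pair.polar_flag} day")
    noon = pair.midpoint
    lon = 15.0 * (12.0 - equation_of_time(pair.date) / 60.0 - noon)
    # wrap into (-180, 180]
    lon = (lon + 180.0) % 360.0 - 180.0
    return 180.0 if lon == -180.0 else lon


def latitude_from_daylength(
    day_length: float,
    date: dt.date,
    sun_elevation: float,
    hemisphere_hint: Optional[float] = None,
    lat_bounds: tuple[float, float] = (-89.9, 89.9),
    tol: float = 1e-4,
) -> tuple[Optional[float], str]:
    """Latitude from day length, or ``(None, reason)`` when degenerate.

    Solves ``sin a = sin phi sin delta + cos phi cos delta cos H`` for phi,
    with H = 7.5 deg/h x day_length, by bisection on bracketing intervals
    found on a 0.25-degree scan of ``lat_bounds`` (tolerance ``tol`` deg).

    Returns a ``(latitude, flag)`` tuple where flag is one of ``"ok"``,
    ``"equinox"`` (|declination| < 3.5 deg: day length is ~independent of
    latitude so the solution is unstable and withheld) or ``"no_solution"``
    (polar conditions).  When two roots exist the one nearest
    ``hemisphere_hint`` (a latitude in degrees; default the northern root,
    matching a Palearctic study system) is returned.
    """
    if not 0.0 < day_length < 24.0:
        raise ValueError(f"day length {day_length} outside (0, 24)")
    delta = solar_declination(date)
    if abs(delta) < EQUINOX_DECLINATION_DEG:
        return None, "equinox"
    h = math.radians(7.5 * day_length)
    sin_a = math.sin(math.radians(sun_elevation))
    sd, cd = math.sin(math.radians(delta)), math.cos(math.radians(delta))

    def g(phi_deg: float) -> float:
        phi = math.radians(phi_deg)
        return math.sin(phi) * sd + math.cos(phi) * cd * math.cos(h) - sin_a

    lo, hi = lat_bounds
    grid = np.arange(lo, hi + 0.25, 0.25)
    vals = np.array([g(p) for p in grid])
    roots: list[float] = []
    for i in range(len(grid) - 1):
        if vals[i] == 0.0:
            roots.append(float(grid[i]))
        elif vals[i] * vals[i + 1] < 0.0:
            a_, b_ = float(grid[i]), float(grid[i + 1])
            while b_ - a_ > tol:
                m = 0.5 * (a_ + b_)
                if g(a_) * g(m) <= 0.0:
                    b_ = m
                else:
                    a_ = m
            roots.append(0.5 * (a_ + b_))
    if not roots:
        return None, "no_solution"
    if len(roots) == 1:
        return roots[0], "ok"
    if hemisphere_hint is not None:
        return min(roots, key=lambda r: abs(r - hemisphere_hint)), "ok"
    return max(roots), "ok"
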