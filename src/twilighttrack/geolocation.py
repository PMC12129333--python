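"""Threshold geolocation: sun-elevation calibration and period locations.

The sun elevation angle at which a tag's light sensor registers twilight
is unknown a priori (it depends on sensor, habitat shading and weather).
It is calibrated at the tagging site — the only place the bird's location
is certain — and that single angle is then applied to every stationary
period of the deployment, which keeps between-period comparisons free of
systematic bias even though individual locations carry error.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import solar
from .solar import TwilightPair, latitude_from_daylength, longitude_from_twilights

__all__ = [
    "CalibrationResult",
    "StationaryPeriod",
    "calibrate_sun_elevation",
    "locate_stationary_period",
    "daily_positions",
    "LAT_SEARCH_BOUNDS",
    "SUN_ELEVATION_BOUNDS",
]

#: plausible latitude envelope for an Afro-Palearctic songbird system.
LAT_SEARCH_BOUNDS = (-40.0, 80.0)

#: calibration search bounds for the sun elevation angle (degrees).
SUN_ELEVATION_BOUNDS = (-9.0, 3.0)


@dataclass(frozen=True)
class CalibrationResult:
    sun_elevation: float  # calibrated angle a*
    rms_position_error: float  # km at the calibration site
    median_position_error: float  # km (the minimised quantity)
    n_days: int


@dataclass
class StationaryPeriod:
    """A located >=2-day stationary segment of one bird's track."""

    id: int
    start: float  # half-day value (events.dayval)
    end: float
    lat: float = math.nan
    lon: float = math.nan
    lat_se: float = math.nan
    lon_se: float = math.nan
    n_days_used: int = 0
    equinox_flag: bool = False
    arctic_excluded_days: int = 0
    classification: str = "stopover"

    @property
    def duration(self) -> float:
        return self.end - self.start


def _pairs_from_frame(twilights: pd.DataFrame) -> list[TwilightPair]:
    pairs = []
    for row in twilights.itertuples(index=False):
        date = row.date
        if not isinstance(date, dt.date) or isinstance(date, dt.datetime):
            date = pd.Timestamp(date).date()
        flag = getattr(row, "polar_flag", "none")
        if flag != "none":
            # polar days carry no twilight times but must be counted
            pairs.append(TwilightPair(date, math.nan, math.nan, flag))
            continue
        if getattr(row, "missing", False) or (
            isinstance(row.sunrise_utc, float) and math.isnan(row.sunrise_utc)
        ):
            continue
        pairs.append(TwilightPair(date, row.sunrise_utc, row.sunset_utc, flag))
    return pairs


def daily_positions(
    twilights: pd.DataFrame,
    sun_elevation: float,
    lat_bounds: tuple[float, float] = LAT_SEARCH_BOUNDS,
    hemisphere_hint: float | None = None,
) -> pd.DataFrame:
    """Per-day threshold positions (lon from midpoint, lat from day length).

    Polar-flagged days yield no position at all; equinox-degenerate days
    yield a longitude but no latitude.
    """
    rows = []
    for p in _pairs_from_frame(twilights):
        if p.polar_flag != "none":
            rows.append((p.date, math.nan, math.nan, p.polar_flag))
            continue
        lon = longitude_from_twilights(p)
        lat, flag = latitude_from_daylength(
            p.day_length,
            p.date,
            sun_elevation,
            hemisphere_hint=hemisphere_hint,
            lat_bounds=lat_bounds,
        )
        rows.append((p.date, lat if lat is not None else math.nan, lon,
                     "none" if flag == "ok" else flag))
    return pd.DataFrame(rows, columns=["date", "lat", "lon", "flag"])


def calibrate_sun_elevation(
    twilights: pd.DataFrame,
    known_lat: float,
    known_lon: float,
    bounds: tuple[float, float] = SUN_ELEVATION_BOUNDS,
    step: float = 0.1,
    min_days: int = 10,
) -> CalibrationResult:
    """Grid-search the sun elevation angle that best locates a known site.

    For each candidate angle on a ``step``-degree grid the daily threshold
    positions are computed from the calibration twilights and the angle
    minimising the *median* great-circle distance to the known site wins
    (median for robustness to shading outliers).  Requires at least
    ``min_days`` non-equinox, non-polar days.
    """
    from .events import haversine  # deferred: events imports this module

    pairs = [p for p in _pairs_from_frame(twilights) if p.polar_flag == "none"]
    usable = [
        p
        for p in pairs
        if abs(solar.solar_declination(p.date)) >= solar.EQUINOX_DECLINATION_DEG
    ]
    if len(usable) < min_days:
        raise ValueError(
            f"only {len(usable)} usable calibration days (need >= {min_days})"
        )
    angles = np.arange(bounds[0], bounds[1] + step / 2.0, step)
    best = None
    for a in angles:
        dists = []
        for p in usable:
            lon = longitude_from_twilights(p)
            lat, flag = latitude_from_daylength(
                p.day_length, p.date, a, hemisphere_hint=known_lat
            )
            if flag != "ok":
                continue
            dists.append(haversine(lat, lon, known_lat, known_lon))
        if not dists:
            continue
        med = float(np.median(dists))
        if best is None or med < best[1]:
            rms = float(np.sqrt(np.mean(np.square(dists))))
            best = (float(a), med, rms, len(dists))
    if best is None:
        raise ValueError("no candidate angle produced any valid positions")
    a_star, med, rms, n = best
    return CalibrationResult(
        sun_elevation=a_star,
        rms_position_error=rms,
        median_position_error=med,
        n_days=n,
    )


def locate_stationary_period(
    twilights: pd.DataFrame,
    sun_elevation: float,
    period: StationaryPeriod,
    lat_bounds: tuple[float, float] = LAT_SEARCH_BOUNDS,
    hemisphere_hint: float | None = None,
) -> StationaryPeriod:
    """Fill a period's location fields from the twilights inside it.

    The period location is the median of the daily threshold positions;
    standard errors are sd/sqrt(n) per axis.  Polar-day days are excluded
    from any location calculation (for an Arctic breeder only the shoulder
    days of the period contribute); equinox-degenerate days are excluded
    from latitude only, since longitude stays reliable through equinox.
    """
    from .segmentation import flag_equinox

    pos = daily_positions(
        twilights, sun_elevation, lat_bounds=lat_bounds, hemisphere_hint=hemisphere_hint
    )
    arctic_excluded = int((pos["flag"].isin(("polar_day", "polar_night"))).sum())
    lons = pos["lon"].dropna().to_numpy()
    lats = pos["lat"].dropna().to_numpy()
    if lons.size == 0:
        raise ValueError(f"period {period.id}: no valid longitude days")
    period.lon = float(np.median(lons))
    period.lon_se = float(np.std(lons, ddof=1) / np.sqrt(lons.size)) if lons.size > 1 else 0.0
    if lats.size:
        period.lat = float(np.median(lats))
        period.lat_se = (
            float(np.std(lats, ddof=1) / np.sqrt(lats.size)) if lats.size > 1 else 0.0
        )
    else:
        period.lat = math.nan
        period.lat_se = math.nan
    period.n_days_used = int(lons.size)
    period.arctic_excluded_days = arctic_excluded
    from .events import dayval_to_date

    period.equinox_flag = flag_equinox(
        dayval_to_date(period.start), dayval_to_date(period.end)
    )
    return period
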