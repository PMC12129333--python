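"""Independent solar-position oracle for cross-checking the forward model.

Implements the classical low-accuracy solar position algorithm from the
astronomical literature (geometric mean longitude / anomaly, equation of
centre, apparent longitude with nutation correction, true obliquity),
which is an entirely different series from the Fourier fit used by the
package.  Declination accuracy ~0.01 deg, equation of time ~0.1 min.
"""

import datetime as dt
import math


def _julian_day(date: dt.date, hour_ut: float = 12.0) -> float:
    y, m, d = date.year, date.month, date.day + hour_ut / 24.0
    if m <= 2:
        y -= 1
        m += 12
    a = y // 100
    b = 2 - a + a // 4
    return int(365.25 * (y + 4716)) + int(30.6001 * (m + 1)) + d + b - 1524.5


def solar_position(date: dt.date, hour_ut: float = 12.0):
    """(declination deg, equation of time minutes) at the given UT hour."""
    t = (_julian_day(date, hour_ut) - 2451545.0) / 36525.0
    l0 = (280.46646 + 36000.76983 * t + 0.0003032 * t * t) % 360.0
    m = math.radians(357.52911 + 35999.05029 * t - 0.0001537 * t * t)
    e = 0.016708634 - 0.000042037 * t - 0.0000001267 * t * t
    c = (
        (1.914602 - 0.004817 * t - 0.000014 * t * t) * math.sin(m)
        + (0.019993 - 0.000101 * t) * math.sin(2 * m)
        + 0.000289 * math.sin(3 * m)
    )
    true_lon = l0 + c
    omega = math.radians(125.04 - 1934.136 * t)
    app_lon = math.radians(true_lon - 0.00569 - 0.00478 * math.sin(omega))
    eps0 = 23.0 + (26.0 + 21.448 / 60.0) / 60.0 - (
        46.8150 * t + 0.00059 * t * t - 0.001813 * t ** 3
    ) / 3600.0
    eps = math.radians(eps0 + 0.00256 * math.cos(omega))
    decl = math.degrees(math.asin(math.sin(eps) * math.sin(app_lon)))
    y = math.tan(eps / 2.0) ** 2
    l0r = math.radians(l0)
    eot = 4.0 * math.degrees(
        y * math.sin(2 * l0r)
        - 2 * e * math.sin(m)
        + 4 * e * y * math.sin(m) * math.cos(2 * l0r)
        - 0.5 * y * y * math.sin(4 * l0r)
        - 1.25 * e * e * math.sin(2 * m)
    )
    return decl, eot


def twilight_times_oracle(lat: float, lon: float, date: dt.date, elevation: float):
    """Sunrise/sunset (decimal hours UTC) when the sun crosses ``elevation``.

    Same threshold geometry as the package but driven by the independent
    ephemeris above; returns None for polar conditions.
    """
    decl, eot = solar_position(date)
    phi, delta, a = map(math.radians, (lat, decl, elevation))
    cos_h = (math.sin(a) - math.sin(phi) * math.sin(delta)) / (
        math.cos(phi) * math.cos(delta)
    )
    if abs(cos_h) > 1.0:
        return None
    half_day = math.degrees(math.acos(cos_h)) / 15.0
    noon = 12.0 - lon / 15.0 - eot / 60.0
    return noon - half_day, noon + half_day
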