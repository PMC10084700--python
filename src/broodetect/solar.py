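"""Sun elevation and the civil-dark night flag.

Implements the standard low-precision NOAA solar-position equations (as used
in the NOAA solar calculator): geometric mean longitude and anomaly of the
sun, equation of center, apparent longitude, corrected obliquity,
declination, equation of time, hour angle, and finally elevation with the
standard atmospheric-refraction correction.  Accuracy is a few hundredths of
a degree over the 20th–21st century, far inside the ±0.5° needed here.

Night is defined as the sun more than 6° below the horizon (civil dark);
everything else — including twilight — counts as daylight for the
light-level rule.
"""

from __future__ import annotations

from datetime import datetime, timezone

import numpy as np

NIGHT_ELEVATION_DEG = -6.0

#: Study-site coordinates (temperate and desert populations).
SITE_NL = (48.99, 14.38)
SITE_RWL = (24.83, 55.36)


def _to_julian_day(utc) -> np.ndarray:
    """UTC timestamps (datetime, datetime64, or arrays thereof) → Julian day."""
    if isinstance(utc, datetime):
        if utc.tzinfo is not None:
            utc = utc.astimezone(timezone.utc).replace(tzinfo=None)
        utc = np.datetime64(utc, "ns")
    arr = np.asarray(utc, dtype="datetime64[ns]")
    # Unix epoch 1970-01-01T00:00 UTC is JD 2440587.5
    seconds = arr.astype("datetime64[ns]").astype(np.int64) / 1e9
    return 2440587.5 + seconds / 86400.0


def sun_elevation(utc, lat: float, lon: float) -> np.ndarray | float:
    """Sun elevation in degrees above the horizon at ``utc`` for a site.

    Parameters
    ----------
    utc
        Absolute UTC time(s): ``datetime``, ``numpy.datetime64`` or an array.
    lat, lon
        Site coordinates in degrees (east-positive longitude).
    """
    if not -90.0 <= lat <= 90.0:
        raise ValueError(f"latitude {lat} out of range")
    jd = _to_julian_day(utc)
    t = (jd - 2451545.0) / 36525.0  # Julian centuries since J2000.0

    l0 = np.mod(280.46646 + t * (36000.76983 + 0.0003032 * t), 360.0)
    m = 357.52911 + t * (35999.05029 - 0.0001537 * t)
    ecc = 0.016708634 - t * (0.000042037 + 0.0000001267 * t)
    mr = np.radians(m)
    center = (
        np.sin(mr) * (1.914602 - t * (0.004817 + 0.000014 * t))
        + np.sin(2 * mr) * (0.019993 - 0.000101 * t)
        + np.sin(3 * mr) * 0.000289
    )
    true_long = l0 + center
    omega = np.radians(125.04 - 1934.136 * t)
    app_long = true_long - 0.00569 - 0.00478 * np.sin(omega)

    obliq0 = 23.0 + (26.0 + (21.448 - t * (46.815 + t * (0.00059 - 0.001813 * t))) / 60.0) / 60.0
    obliq = obliq0 + 0.00256 * np.cos(omega)
    obl_r = np.radians(obliq)

    decl = np.arcsin(np.sin(obl_r) * np.sin(np.radians(app_long)))

    vary = np.tan(obl_r / 2.0) ** 2
    l0r = np.radians(l0)
    eqtime_min = 4.0 * np.degrees(
        vary * np.sin(2 * l0r)
        - 2.0 * ecc * np.sin(mr)
        + 4.0 * ecc * vary * np.sin(mr) * np.cos(2 * l0r)
        - 0.5 * vary**2 * np.sin(4 * l0r)
        - 1.25 * ecc**2 * np.sin(2 * mr)
    )

    minutes_utc = np.mod(jd - 0.5, 1.0) * 1440.0
    true_solar_min = np.mod(minutes_utc + eqtime_min + 4.0 * lon, 1440.0)
    hour_angle = true_solar_min / 4.0 - 180.0

    lat_r = np.radians(lat)
    cos_zen = np.sin(lat_r) * np.sin(decl) + np.cos(lat_r) * np.cos(decl) * np.cos(
        np.radians(hour_angle)
    )
    zen = np.degrees(np.arccos(np.clip(cos_zen, -1.0, 1.0)))
    elev = 90.0 - zen

    elev = elev + _refraction_deg(elev)
    elev = np.clip(elev, -90.0, 90.0)
    return float(elev) if np.ndim(elev) == 0 else elev


def _refraction_deg(elev_deg: np.ndarray) -> np.ndarray:
    """NOAA piecewise atmospheric-refraction correction (degrees)."""
    e = np.asarray(elev_deg, dtype=float)
    te = np.tan(np.radians(np.where(np.abs(e) < 1e-9, 1e-9, e)))
    corr = np.zeros_like(e)
    hi = e > 85.0
    mid = (e > 5.0) & ~hi
    low = (e > -0.575) & ~hi & ~mid
    deep = ~(hi | mid | low)
    corr = np.where(
        mid, (58.1 / te - 0.07 / te**3 + 0.000086 / te**5) / 3600.0, corr
    )
    corr = np.where(
        low,
        (1735.0 + e * (-518.2 + e * (103.4 + e * (-12.79 + e * 0.711)))) / 3600.0,
        corr,
    )
    corr = np.where(deep, (-20.774 / te) / 3600.0, corr)
    return corr


def night_flag(elevation) -> np.ndarray | bool:
    """True iff the sun is more than 6° below the horizon (elevation < −6°)."""
    flag = np.asarray(elevation, dtype=float) < NIGHT_ELEVATION_DEG
    return bool(flag) if np.ndim(flag) == 0 else flag
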