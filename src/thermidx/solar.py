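"""Solar position geometry for radiant-flux decomposition.

Implements the Fourier-series solar declination and equation of time
(Spencer-type coefficients, as used in the NOAA solar position procedure),
the hour angle in local solar time, the cosine of the solar zenith angle

    cos(theta) = sin(delta) sin(phi) + cos(delta) cos(phi) cos(h),

its interval average over an accumulation step, and the projected area
factor f_p of a rotationally symmetric standing human body.

All angles are in radians unless a name says otherwise.  The hour-angle
convention is fixed here: h = 0 at local solar noon, negative in the
morning, positive in the afternoon.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from datetime import datetime, timedelta, timezone

import numpy as np

__all__ = [
    "SolarGeometry",
    "solar_declination",
    "equation_of_time_minutes",
    "hour_angle",
    "cos_zenith",
    "mean_cos_zenith",
    "projected_area_factor",
]

logger = logging.getLogger(__name__)

# Fourier coefficients of the declination series (radians) and of the
# equation of time (minutes), both functions of the fractional year gamma.
# Recorded explicitly so results are reproducible bit-for-bit.
_DECL_COEF = (0.006918, -0.399912, 0.070257, -0.006758, 0.000907, -0.002697, 0.00148)
_EOT_COEF = (0.000075, 0.001868, -0.032077, -0.014615, -0.040849)

#: Maximum f_p of the standing-body model (value of the leading factor).
FP_MAX = 0.308


@dataclass
class SolarGeometry:
    """Solar position diagnostics for one grid cell and one interval."""

    latitude_rad: float
    longitude_deg: float
    declination_rad: float
    hour_angle_rad: float
    cos_zenith: float
    mean_cos_zenith: float
    f_p: float


def _fractional_year(day_of_year, hour_utc=12.0):
    """Fractional year gamma in radians (365-day convention)."""
    return 2.0 * np.pi / 365.0 * (np.asarray(day_of_year, dtype=float) - 1.0
                                  + (np.asarray(hour_utc, dtype=float) - 12.0) / 24.0)


def solar_declination(day_of_year):
    """Solar declination delta (radians) from the day of year (1-366).

    Fourier-series fit in the fractional year; accurate to ~0.0006 rad,
    which is ample for hourly radiant-flux work.
    """
    doy = np.asarray(day_of_year)
    if np.any((doy < 1) | (doy > 366)):
        raise ValueError(f"day_of_year must be in 1..366, got {day_of_year!r}")
    g = _fractional_year(doy)
    a0, a1, b1, a2, b2, a3, b3 = _DECL_COEF
    decl = (a0 + a1 * np.cos(g) + b1 * np.sin(g)
            + a2 * np.cos(2 * g) + b2 * np.sin(2 * g)
            + a3 * np.cos(3 * g) + b3 * np.sin(3 * g))
    return decl if decl.shape else float(decl)


def equation_of_time_minutes(day_of_year, hour_utc=12.0):
    """Equation of time (minutes): apparent minus mean solar time."""
    g = _fractional_year(day_of_year, hour_utc)
    c0, c1, c2, c3, c4 = _EOT_COEF
    eot = 229.18 * (c0 + c1 * np.cos(g) + c2 * np.sin(g)
                    + c3 * np.cos(2 * g) + c4 * np.sin(2 * g))
    return eot if np.asarray(eot).shape else float(eot)


def _normalize_longitude(longitude_deg):
    """Map longitudes from [-180, 360) onto (-180, 180]."""
    lon = np.asarray(longitude_deg, dtype=float)
    out = np.where(lon > 180.0, lon - 360.0, lon)
    return out if out.shape else float(out)


def hour_angle(time_utc: datetime, longitude_deg):
    """Hour angle h (radians) at a UTC instant for the given longitude.

    True solar time = UTC + 4 min/deg * longitude + equation of time;
    h = (true solar minutes - 720) converted at 15 deg per hour.  Zero at
    local solar noon, negative before, positive after.
    """
    if time_utc.tzinfo is not None:
        time_utc = time_utc.astimezone(timezone.utc).replace(tzinfo=None)
    lon = _normalize_longitude(longitude_deg)
    doy = time_utc.timetuple().tm_yday
    hour = time_utc.hour + time_utc.minute / 60.0 + time_utc.second / 3600.0
    eot = equation_of_time_minutes(doy, hour)
    true_solar_min = hour * 60.0 + 4.0 * np.asarray(lon) + eot
    h = np.deg2rad((true_solar_min - 720.0) / 4.0)
    # wrap to (-pi, pi] so mornings stay negative across the date line
    h = (h + np.pi) % (2.0 * np.pi) - np.pi
    return h if np.asarray(h).shape else float(h)


def cos_zenith(latitude_rad, declination_rad, hour_angle_rad):
    """cos(theta) = sin d sin phi + cos d cos phi cos h, clipped to [-1, 1]."""
    phi = np.asarray(latitude_rad, dtype=float)
    c = (np.sin(declination_rad) * np.sin(phi)
         + np.cos(declination_rad) * np.cos(phi) * np.cos(hour_angle_rad))
    c = np.clip(c, -1.0, 1.0)
    return c if np.asarray(c).shape else float(c)


def mean_cos_zenith(latitude_rad, longitude_deg, interval_start: datetime,
                    interval_end: datetime, n_substeps: int = 60):
    """Average of max(cos(theta), 0) over an interval.

    The direct beam scaled by 1/cos(theta) blows up near the terminator;
    averaging the clipped cosine across the accumulation interval (sampled
    at ``n_substeps`` sub-interval midpoints) gives the effective cosine
    consistent with an interval-accumulated flux.  Returns 0 when the sun
    is below the horizon throughout.
    """
    if interval_end <= interval_start:
        raise ValueError("interval_end must be after interval_start")
    if n_substeps < 2:
        raise ValueError("n_substeps must be >= 2")
    total = (interval_end - interval_start).total_seconds()
    lat = np.asarray(latitude_rad, dtype=float)
    acc = np.zeros(np.broadcast(lat, np.asarray(longitude_deg)).shape)
    for k in range(n_substeps):
        t = interval_start + timedelta(seconds=(k + 0.5) * total / n_substeps)
        decl = solar_declination(t.timetuple().tm_yday)
        h = hour_angle(t, longitude_deg)
        acc += np.maximum(cos_zenith(latitude_rad, decl, h), 0.0)
    acc /= n_substeps
    return acc if acc.shape else float(acc)


def projected_area_factor(theta_rad):
    """Projected area factor f_p of a standing person at zenith angle theta.

    f_p = 0.308 cos{ (pi/2 - theta) [1 - (90 - 180 theta/pi)^2 / 48402] }

    with theta in radians; the squared term is the solar elevation in
    degrees.  Valid for theta in [0, pi/2]; out-of-range angles are clamped
    to the boundary (a sun below the horizon casts no direct beam on the
    body) and logged.
    """
    theta = np.asarray(theta_rad, dtype=float)
    n_bad = int(np.sum((theta < 0.0) | (theta > np.pi / 2)))
    if n_bad:
        logger.warning("projected_area_factor: clamped %d zenith angles to [0, pi/2]", n_bad)
        theta = np.clip(theta, 0.0, np.pi / 2)
    elev_deg = 90.0 - np.rad2deg(theta)
    fp = FP_MAX * np.cos((np.pi / 2 - theta) * (1.0 - elev_deg ** 2 / 48402.0))
    return fp if fp.shape else float(fp)
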