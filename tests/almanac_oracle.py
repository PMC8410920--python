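"""Independent solar-position oracle for the tests.

Low-precision astronomical-almanac algorithm (ecliptic longitude, right
ascension and sidereal time; Michalsky-style), entirely different in
formulation from the Fourier-series declination / equation-of-time route
the package uses.  Accurate to roughly 0.01 degrees over recent decades,
ample for cross-checking hourly solar geometry.
"""

from __future__ import annotations

import math
from datetime import datetime, timezone


def _days_since_j2000(t: datetime) -> float:
    if t.tzinfo is not None:
        t = t.astimezone(timezone.utc).replace(tzinfo=None)
    epoch = datetime(2000, 1, 1, 12, 0, 0)
    return (t - epoch).total_seconds() / 86400.0


def solar_position(t: datetime, longitude_deg: float):
    """(declination_rad, hour_angle_rad) from the almanac algorithm.

    Hour angle uses the same convention as the package: 0 at local solar
    noon, negative morning, positive afternoon.
    """
    n = _days_since_j2000(t)
    L = math.radians((280.460 + 0.9856474 * n) % 360.0)       # mean longitude
    g = math.radians((357.528 + 0.9856003 * n) % 360.0)       # mean anomaly
    lam = L + math.radians(1.915) * math.sin(g) + math.radians(0.020) * math.sin(2 * g)
    eps = math.radians(23.439 - 0.0000004 * n)                # obliquity
    decl = math.asin(math.sin(eps) * math.sin(lam))
    ra = math.atan2(math.cos(eps) * math.sin(lam), math.cos(lam))  # radians

    ut_hours = n % 1.0 * 24.0 + 12.0  # hours since previous UT midnight
    gmst = (6.697375 + 0.0657098242 * (n - ut_hours / 24.0) + 1.0027379 * ut_hours) % 24.0
    lmst = (gmst + longitude_deg / 15.0) % 24.0
    ha = math.radians(lmst * 15.0) - ra
    ha = (ha + math.pi) % (2.0 * math.pi) - math.pi
    return decl, ha


def cos_zenith_oracle(t: datetime, latitude_deg: float, longitude_deg: float) -> float:
    decl, ha = solar_position(t, longitude_deg)
    phi = math.radians(latitude_deg)
    return (math.sin(decl) * math.sin(phi)
            + math.cos(decl) * math.cos(phi) * math.cos(ha))
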