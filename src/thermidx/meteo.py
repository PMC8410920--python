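"""Humidity and wind derivations from raw 2-m / 10-m forcing.

Vapour pressure uses the Magnus form over water with WMO constants
(6.112 hPa, 17.62, 243.12 degC); relative humidity is the ratio of the
saturation pressures at dewpoint and air temperature.  Wind is reduced
from the 10-m measurement height with a logarithmic profile over a
roughness length of 0.01 m.
"""

from __future__ import annotations

import logging

import numpy as np

__all__ = [
    "vapor_pressure_from_dewpoint",
    "relative_humidity",
    "wind_speed",
    "wind_at_height",
    "celsius",
]

logger = logging.getLogger(__name__)

_MAGNUS_A = 6.112   # hPa
_MAGNUS_B = 17.62
_MAGNUS_C = 243.12  # degC

#: Default roughness length (m) for the body-height wind reduction.
Z0_DEFAULT = 0.01


def celsius(T_kelvin):
    """Kelvin to degrees Celsius."""
    return np.asarray(T_kelvin, dtype=float) - 273.15


def vapor_pressure_from_dewpoint(Td):
    """Water vapour pressure e (hPa) from dewpoint temperature (K).

    Saturation vapour pressure over water at Td, Magnus form
    e = 6.112 exp(17.62 t / (243.12 + t)) with t in degC.
    """
    Td = np.asarray(Td, dtype=float)
    if np.any((Td < 150.0) | (Td > 350.0)):
        raise ValueError("dewpoint outside plausible range [150, 350] K")
    t = Td - 273.15
    e = _MAGNUS_A * np.exp(_MAGNUS_B * t / (_MAGNUS_C + t))
    return e if e.shape else float(e)


def relative_humidity(Ta, Td):
    """Relative humidity (%) from air and dewpoint temperature (K).

    RH = 100 e(Td) / e(Ta), capped at 100.  Gridded products occasionally
    carry Td marginally above Ta; such supersaturation is clipped to 100%
    and logged rather than raised.
    """
    Ta = np.asarray(Ta, dtype=float)
    Td = np.asarray(Td, dtype=float)
    n_super = int(np.sum(Td > Ta))
    if n_super:
        logger.warning("relative_humidity: %d cells with Td > Ta clipped to saturation", n_super)
    rh = 100.0 * vapor_pressure_from_dewpoint(np.minimum(Td, Ta)) / vapor_pressure_from_dewpoint(Ta)
    rh = np.minimum(rh, 100.0)
    return rh if np.asarray(rh).shape else float(rh)


def wind_speed(u, v):
    """Scalar wind speed (m/s) from eastward/northward components."""
    s = np.hypot(np.asarray(u, dtype=float), np.asarray(v, dtype=float))
    return s if s.shape else float(s)


def wind_at_height(V_zr, z, z_r=10.0, z0=Z0_DEFAULT):
    """Reduce wind from reference height z_r to height z, log profile.

    V(z) = V(z_r) log(z/z0) / log(z_r/z0), roughness length z0 (default
    0.01 m).  Used to obtain the 1.2-m wind the net effective temperature
    requires from the 10-m forcing wind.
    """
    if z <= z0 or z_r <= z0 or z0 <= 0:
        raise ValueError("need z, z_r > z0 > 0 for the log wind profile")
    V = np.asarray(V_zr, dtype=float)
    out = V * np.log(z / z0) / np.log(z_r / z0)
    return out if out.shape else float(out)
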