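"""The twelve human thermal-stress indices.

Three UTCI variants (unshaded outdoor, outdoor shaded, indoor) evaluated
with the operational 6th-order polynomial approximation, and eight
empirical indices: apparent temperature (AT), environmental stress index
(ESI), heat index (HI), Humidex, net effective temperature (NET),
simplified indoor wet-bulb globe temperature (WBGT), Stull's wet-bulb
temperature (WBT) and the wind chill temperature (WCT).  The mean radiant
temperature lives in :mod:`thermidx.mrt`.

All functions are vectorized over numpy arrays and return degC.  Input
conventions follow the standard index definitions: Ta in degC, vapour
pressure e in hPa, RH in %, winds in m/s (WCT converts to km/h
internally), global horizontal shortwave SR in W m-2.

UTCI inputs are clamped to the polynomial's published validity region
(Ta in [-50, 50] degC, va in [0.5, 17] m/s, e <= 50 hPa, MRT - Ta in
[-30, 70] K); every clamp is recorded in an optional QC mask.  The
polynomial coefficients are shipped as a data file
(``data/utci_coefficients.csv``, 210 terms, sha256-checksummed at load).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

__all__ = [
    "utci", "utci_outdoor_shaded", "utci_indoor",
    "apparent_temperature", "environment_stress_index", "heat_index",
    "humidex", "net_effective_temperature", "wbgt_simplified",
    "wbt_stull", "wind_chill_temperature", "QCMask",
    "UTCI_VALIDITY", "INDEX_NAMES",
]

#: The twelve output indices in dataset order.
INDEX_NAMES = ("UTCI", "UTCI3", "UTCI2", "AT", "ESI", "HI",
               "Humidex", "MRT", "NET", "WBT", "WBGT", "WCT")

#: Published validity region of the UTCI polynomial regression.
UTCI_VALIDITY = {
    "Ta": (-50.0, 50.0),      # degC
    "Va10": (0.5, 17.0),      # m/s
    "e": (0.0, 50.0),         # hPa
    "dMRT": (-30.0, 70.0),    # MRT - Ta, K
}

_UTCI_COEF_SHA256 = "e17c3c01a52deb2f02fb0af42c23ca52a19f125c2f6480793d8f39478f3fb3f6"

_REFERENCE_WIND = 0.5  # m/s, the reference-environment 10-m wind


@dataclass
class QCMask:
    """Per-element counts/flags of validity clamps applied to UTCI inputs."""

    clamped: np.ndarray | None = None  # boolean, True where any input was clamped
    n_clamped: int = 0
    events: dict = field(default_factory=dict)

    def record(self, name: str, mask) -> None:
        mask = np.asarray(mask, dtype=bool)
        n = int(mask.sum())
        if n:
            self.events[name] = self.events.get(name, 0) + n
        if self.clamped is None:
            self.clamped = mask.copy()
        else:
            self.clamped = self.clamped | mask
        self.n_clamped = int(self.clamped.sum())


def _load_utci_coefficients():
    text = (resources.files("thermidx") / "data" / "utci_coefficients.csv").read_text()
    digest = hashlib.sha256(text.encode()).hexdigest()
    if digest != _UTCI_COEF_SHA256:
        raise RuntimeError("UTCI coefficient table corrupted (checksum mismatch)")
    rows = [ln.split(",") for ln in text.strip().splitlines()[1:]]
    expo = np.array([[int(r[0]), int(r[1]), int(r[2]), int(r[3])] for r in rows])
    coef = np.array([float(r[4]) for r in rows])
    if len(coef) != 210:
        raise RuntimeError("UTCI coefficient table must have 210 terms")
    return expo, coef

_UTCI_EXPO, _UTCI_COEF = _load_utci_coefficients()


def _clamp(x, lo, hi, name, qc: QCMask | None):
    x = np.asarray(x, dtype=float)
    out_of_range = (x < lo) | (x > hi)
    if qc is not None:
        qc.record(name, out_of_range)
    return np.clip(x, lo, hi)


def utci(Ta, Va10, e, MRT, qc: QCMask | None = None):
    """Universal thermal climate index (degC), unshaded outdoor variant.

    6th-order polynomial regression UTCI = Ta + f(Ta, va, pa, MRT - Ta)
    with pa = e/10 kPa.  Inputs outside the published validity region are
    clamped to it; pass a :class:`QCMask` to record where.
    """
    Ta = np.asarray(Ta, dtype=float)
    dmrt = np.asarray(MRT, dtype=float) - Ta
    Ta_c = _clamp(Ta, *UTCI_VALIDITY["Ta"], name="Ta", qc=qc)
    va_c = _clamp(Va10, *UTCI_VALIDITY["Va10"], name="Va10", qc=qc)
    e_c = _clamp(e, *UTCI_VALIDITY["e"], name="e", qc=qc)
    d_c = _clamp(dmrt, *UTCI_VALIDITY["dMRT"], name="dMRT", qc=qc)
    pa = e_c / 10.0

    # powers up to 6 for each regressor, then one dot product over terms
    def powers(x):
        x = np.asarray(x, dtype=float)
        p = np.empty((7,) + x.shape)
        p[0] = 1.0
        for k in range(1, 7):
            p[k] = p[k - 1] * x
        return p

    pt, pv, pd, pp = powers(Ta_c), powers(va_c), powers(d_c), powers(pa)
    i, j, k, l = _UTCI_EXPO.T
    monomials = pt[i] * pv[j] * pd[k] * pp[l]     # (210, ...) broadcast
    offset = np.tensordot(_UTCI_COEF, monomials, axes=(0, 0))
    out = Ta_c + offset
    return out if np.asarray(out).shape else float(out)


def utci_outdoor_shaded(Ta, Va10, e, qc: QCMask | None = None):
    """Outdoor-shaded UTCI: radiation ignored by setting MRT = Ta."""
    return utci(Ta, Va10, e, np.asarray(Ta, dtype=float), qc=qc)


def utci_indoor(Ta, e, qc: QCMask | None = None):
    """Indoor UTCI: MRT = Ta and the reference wind of 0.5 m/s."""
    Ta = np.asarray(Ta, dtype=float)
    return utci(Ta, np.broadcast_to(_REFERENCE_WIND, Ta.shape) if Ta.shape
                else _REFERENCE_WIND, e, Ta, qc=qc)


def apparent_temperature(Ta, e, Va10):
    """Apparent temperature (degC): AT = Ta + 0.33 e - 0.7 Va - 4.

    Shade/no-radiation form for an adult walking outdoors.
    """
    out = (np.asarray(Ta, dtype=float) + 0.33 * np.asarray(e, dtype=float)
           - 0.7 * np.asarray(Va10, dtype=float) - 4.0)
    return out if np.asarray(out).shape else float(out)


def environment_stress_index(Ta, RH, SR):
    """Environmental stress index (degC), a WBGT surrogate.

    ESI = 0.63 Ta - 0.03 RH + 0.002 SR + 0.0054 Ta RH - 0.073/(0.1 + SR)
    with SR the global (direct + diffuse) horizontal shortwave in W m-2.
    """
    Ta = np.asarray(Ta, dtype=float)
    RH = np.asarray(RH, dtype=float)
    SR = np.asarray(SR, dtype=float)
    out = (0.63 * Ta - 0.03 * RH + 0.002 * SR + 0.0054 * Ta * RH
           - 0.073 / (0.1 + SR))
    return out if np.asarray(out).shape else float(out)


def heat_index(Ta, RH):
    """Heat index (degC) from Ta (degC) and RH (%).

    Works in Fahrenheit internally: the simple average formula is
    evaluated first and, where it reaches 80 F, replaced by the Rothfusz
    regression with the low-RH (RH < 13%, 80-112 F) and high-RH
    (RH > 85%, 80-87 F) adjustments; the result is converted back to degC.
    """
    T = np.asarray(Ta, dtype=float) * 9.0 / 5.0 + 32.0  # degF
    RH = np.asarray(RH, dtype=float)

    simple = 0.5 * (T + 61.0 + (T - 68.0) * 1.2 + RH * 0.094)

    roth = (-42.379 + 2.04901523 * T + 10.14333127 * RH
            - 0.22475541 * T * RH - 0.00683783 * T ** 2
            - 0.05481717 * RH ** 2 + 0.00122874 * T ** 2 * RH
            + 0.00085282 * T * RH ** 2 - 0.00000199 * T ** 2 * RH ** 2)
    low = (RH < 13.0) & (T >= 80.0) & (T <= 112.0)
    adj_low = (13.0 - RH) / 4.0 * np.sqrt(np.clip(17.0 - np.abs(T - 95.0), 0.0, None) / 17.0)
    high = (RH > 85.0) & (T >= 80.0) & (T <= 87.0)
    adj_high = (RH - 85.0) / 10.0 * (87.0 - T) / 5.0
    roth = roth - np.where(low, adj_low, 0.0) + np.where(high, adj_high, 0.0)

    hi_f = np.where(simple >= 80.0, roth, simple)
    out = (hi_f - 32.0) * 5.0 / 9.0
    return out if np.asarray(out).shape else float(out)


def humidex(Ta, e):
    """Humidex (degC): Ta + 0.5555 (e - 10), e in hPa."""
    out = np.asarray(Ta, dtype=float) + 0.5555 * (np.asarray(e, dtype=float) - 10.0)
    return out if np.asarray(out).shape else float(out)


def net_effective_temperature(Ta, RH, Va12):
    """Net effective temperature (degC); wind at 1.2 m height.

    NET = 37 - (37 - Ta) / (0.68 - 0.0014 RH + 1/(1.76 + 1.4 Va^0.75))
             - 0.29 Ta (1 - 0.01 RH)
    """
    Ta = np.asarray(Ta, dtype=float)
    RH = np.asarray(RH, dtype=float)
    Va = np.asarray(Va12, dtype=float)
    denom = 0.68 - 0.0014 * RH + 1.0 / (1.76 + 1.4 * Va ** 0.75)
    out = 37.0 - (37.0 - Ta) / denom - 0.29 * Ta * (1.0 - 0.01 * RH)
    return out if np.asarray(out).shape else float(out)


def wbgt_simplified(Ta, e):
    """Simplified (indoor) wet-bulb globe temperature (degC).

    WBGT = 0.567 Ta + 0.393 e + 3.94 — the two-variable approximation
    used when natural wet-bulb and globe temperatures are unavailable.
    """
    out = 0.567 * np.asarray(Ta, dtype=float) + 0.393 * np.asarray(e, dtype=float) + 3.94
    return out if np.asarray(out).shape else float(out)


def wbt_stull(Ta, RH, qc: QCMask | None = None):
    """Wet-bulb temperature (degC) by Stull's single-equation fit.

    Valid for RH in [5, 99] % and Ta in [-20, 50] degC; outside that box
    the value is still computed but flagged in the QC mask.
    """
    Ta = np.asarray(Ta, dtype=float)
    RH = np.asarray(RH, dtype=float)
    if qc is not None:
        qc.record("wbt_validity", (RH < 5.0) | (RH > 99.0) | (Ta < -20.0) | (Ta > 50.0))
    out = (Ta * np.arctan(0.151977 * np.sqrt(RH + 8.313659))
           + np.arctan(Ta + RH) - np.arctan(RH - 1.676331)
           + 0.00391838 * RH ** 1.5 * np.arctan(0.023101 * RH)
           - 4.686035)
    return out if np.asarray(out).shape else float(out)


def wind_chill_temperature(Ta, Va10):
    """Wind chill temperature (degC); 10-m wind in m/s (km/h internally).

    WCT = 13.12 + 0.6215 Ta - 11.37 V^0.16 + 0.3965 Ta V^0.16, V in km/h.
    Computed everywhere (the dataset publishes it year-round); the index
    is only meaningful for cold, windy conditions.
    """
    Ta = np.asarray(Ta, dtype=float)
    V = np.asarray(Va10, dtype=float) * 3.6
    v16 = V ** 0.16
    out = 13.12 + 0.6215 * Ta - 11.37 * v16 + 0.3965 * Ta * v16
    return out if np.asarray(out).shape else float(out)
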