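"""Accumulated-radiation handling and flux decomposition.

Reanalysis radiation comes as accumulations in J m-2.  Two conventions
exist: the land rerun stores the accumulation since the daily reset
(``era5land``), the parent product stores per-step accumulations
(``era5``).  After de-accumulation and division by the 3600-s step the
hourly fluxes are decomposed into the five components the mean-radiant-
temperature formula needs:

    D_sw = ssrd - fdir            (isotropic diffuse shortwave)
    R_sw = ssrd - ssr             (surface-reflected shortwave)
    D_lw = strd                   (downwelling longwave)
    U_lw = strd - str             (upwelling longwave; str is net = down - up)
    I_sw = fdir / mean_cos_zenith (direct beam normal to the sun)

The direct-beam division is guarded near the terminator: below a cosine
threshold the beam is set to zero instead of dividing by a vanishing
cosine.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

__all__ = ["RadiationComponents", "ClipCounter", "deaccumulate", "to_flux",
           "decompose_fluxes", "COS_ZENITH_EPS"]

logger = logging.getLogger(__name__)

#: Twilight guard: below this interval-mean cosine the direct beam is zeroed.
COS_ZENITH_EPS = 0.01

_SECONDS_PER_HOUR = 3600.0

# negatives larger than this (in magnitude, W m-2 or J m-2) count as physical
# inconsistencies; smaller ones are float round-off, clipped silently
_NUMERICAL_TOL = 1e-9


@dataclass
class ClipCounter:
    """Counts of physical-consistency clips applied during processing."""

    negative_deaccumulated: int = 0
    fdir_above_ssrd: int = 0
    negative_component: int = 0

    def total(self) -> int:
        return (self.negative_deaccumulated + self.fdir_above_ssrd
                + self.negative_component)

    def update(self, other: "ClipCounter") -> None:
        self.negative_deaccumulated += other.negative_deaccumulated
        self.fdir_above_ssrd += other.fdir_above_ssrd
        self.negative_component += other.negative_component


@dataclass
class RadiationComponents:
    """The five W m-2 fluxes entering the MRT formula."""

    I_sw: np.ndarray  # direct beam normal to the sun
    D_sw: np.ndarray  # diffuse shortwave
    R_sw: np.ndarray  # surface-reflected shortwave
    D_lw: np.ndarray  # downwelling longwave
    U_lw: np.ndarray  # upwelling longwave
    clips: ClipCounter = field(default_factory=ClipCounter)


def deaccumulate(series, convention: str = "era5land", *, axis: int = 0,
                 reset_length: int = 24, tolerance: float = 1e-6,
                 non_negative: bool = True, clips: ClipCounter | None = None):
    """Convert accumulated J m-2 series to per-hour J m-2 increments.

    ``series`` holds consecutive hourly values along ``axis``; each block of
    ``reset_length`` steps forms one accumulation window (one forecast day).
    Under ``era5land`` the stored value is the accumulation since the window
    start, so the hourly increment is the first difference within each
    window (the first step passes through).  Under ``era5`` values are
    already per-step and pass through unchanged.

    For inherently non-negative fluxes (all shortwave, downward longwave)
    decreases within a window beyond ``tolerance`` (relative to the window
    maximum) raise a data-quality error, and negative increments from
    round-off are clipped to zero (counted when beyond round-off).  Pass
    ``non_negative=False`` for net fluxes such as net thermal radiation,
    whose increments are legitimately negative: no monotonicity check, no
    clipping.
    """
    a = np.asarray(series, dtype=float)
    if convention == "era5":
        out = a.copy()
    elif convention == "era5land":
        a = np.moveaxis(a, axis, 0)
        n = a.shape[0]
        out = np.empty_like(a)
        for start in range(0, n, reset_length):
            block = a[start:start + reset_length]
            inc = np.diff(block, axis=0, prepend=np.zeros((1,) + block.shape[1:]))
            if non_negative:
                scale = np.maximum(np.max(np.abs(block)), 1.0)
                if np.any(inc < -tolerance * scale):
                    raise ValueError(
                        "non-monotone accumulated series within a reset window")
            out[start:start + reset_length] = inc
        out = np.moveaxis(out, 0, axis)
    else:
        raise ValueError(f"unknown accumulation convention {convention!r}")
    if non_negative:
        neg = out < -_NUMERICAL_TOL
        if np.any(neg):
            if clips is not None:
                clips.negative_deaccumulated += int(np.sum(neg))
            logger.info("deaccumulate: clipped %d negative increments", int(np.sum(neg)))
        out = np.maximum(out, 0.0)
    return out


def to_flux(hourly_J_per_m2):
    """Hourly accumulation (J m-2 over a 3600-s step) to mean flux (W m-2)."""
    return np.asarray(hourly_J_per_m2, dtype=float) / _SECONDS_PER_HOUR


def decompose_fluxes(ssrd, ssr, strd, str_, fdir, mean_cos_zenith,
                     eps: float = COS_ZENITH_EPS) -> RadiationComponents:
    """Split hourly W m-2 fluxes into the five MRT radiation components.

    All inputs are horizontal-plane fluxes except the output ``I_sw``,
    which is the direct beam normal to the sun: fdir / mean_cos_zenith,
    zeroed where the interval-mean cosine is below ``eps`` (twilight
    guard).  Physically inconsistent inputs (fdir > ssrd, negative
    differences) are clipped to the consistent boundary and counted.
    """
    clips = ClipCounter()
    ssrd = np.asarray(ssrd, dtype=float)
    ssr = np.asarray(ssr, dtype=float)
    strd = np.asarray(strd, dtype=float)
    str_ = np.asarray(str_, dtype=float)
    fdir = np.asarray(fdir, dtype=float)
    mu = np.asarray(mean_cos_zenith, dtype=float)

    over = fdir > ssrd + _NUMERICAL_TOL
    if np.any(over):
        clips.fdir_above_ssrd += int(np.sum(over))
        logger.info("decompose_fluxes: clipped %d cells with fdir > ssrd", int(np.sum(over)))
    fdir = np.minimum(fdir, ssrd)

    D_sw = ssrd - fdir
    R_sw = ssrd - ssr
    D_lw = strd
    U_lw = strd - str_
    with np.errstate(divide="ignore", invalid="ignore"):
        I_sw = np.where(mu > eps, fdir / np.where(mu > eps, mu, 1.0), 0.0)

    comps = {}
    for name, val in (("I_sw", I_sw), ("D_sw", D_sw), ("R_sw", R_sw),
                      ("D_lw", D_lw), ("U_lw", U_lw)):
        neg = val < -_NUMERICAL_TOL
        if np.any(neg):
            clips.negative_component += int(np.sum(neg))
            logger.info("decompose_fluxes: clipped %d negative %s values",
                        int(np.sum(neg)), name)
        comps[name] = np.maximum(val, 0.0)
    return RadiationComponents(clips=clips, **comps)
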