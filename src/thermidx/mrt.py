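"""Mean radiant temperature of an upright person on an unshaded plain.

The body absorbs the direct solar beam weighted by the projected area
factor f_p, the isotropic diffuse and ground-reflected shortwave and the
two longwave streams each weighted by the solid-angle factor f_a = 0.5
(flat ground: half the view is sky, half is surface):

    MRT = { (1/sigma) [ (a_k/e_p)(f_p I_sw + f_a D_sw + f_a R_sw)
                        + f_a (D_lw + U_lw) ] }^0.25  -  offset

with a_k = 0.7 the shortwave absorption coefficient of the clothed body,
e_p = 0.97 its longwave emissivity, and sigma the Stefan-Boltzmann
constant.  The Kelvin offset is 273.5 by default — the value the source
dataset convention prints — with 273.15 available via the constants
object.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["BodyRadiationConstants", "mean_radiant_temperature", "SIGMA"]

SIGMA = 5.67e-8  # Stefan-Boltzmann constant, W m-2 K-4


@dataclass(frozen=True)
class BodyRadiationConstants:
    """Radiative constants of the standard standing human body."""

    sigma: float = SIGMA
    alpha_k: float = 0.7      # shortwave absorption coefficient
    eps_p: float = 0.97       # body longwave emissivity
    f_a: float = 0.5          # solid-angle factor, sky and surface each
    kelvin_offset: float = 273.5  # dataset-convention offset (273.15 optional)


DEFAULT_CONSTANTS = BodyRadiationConstants()


def mean_radiant_temperature(rad, f_p, const: BodyRadiationConstants = DEFAULT_CONSTANTS):
    """MRT (degC) from the five radiation components and f_p.

    ``rad`` is a RadiationComponents (or any object with I_sw, D_sw, R_sw,
    D_lw, U_lw attributes in W m-2); ``f_p`` the projected area factor.
    All components must be non-negative, making the bracketed term
    non-negative; a negative bracket indicates corrupted inputs and raises.
    """
    f_p = np.asarray(f_p, dtype=float)
    sw = (const.alpha_k / const.eps_p) * (
        f_p * np.asarray(rad.I_sw, dtype=float)
        + const.f_a * np.asarray(rad.D_sw, dtype=float)
        + const.f_a * np.asarray(rad.R_sw, dtype=float))
    lw = const.f_a * (np.asarray(rad.D_lw, dtype=float)
                      + np.asarray(rad.U_lw, dtype=float))
    bracket = (sw + lw) / const.sigma
    if np.any(bracket < 0):
        raise ArithmeticError("negative radiant load: inputs violate non-negativity")
    mrt = np.power(bracket, 0.25) - const.kelvin_offset
    return mrt if np.asarray(mrt).shape else float(mrt)
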