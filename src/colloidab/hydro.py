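"""Hydrodynamic functions linking structure to collective diffusion.

DLS on an interacting colloidal suspension measures the short-time
collective diffusion coefficient D_c = D_0 H(0)/S(0), where H(0) is the
hydrodynamic function at zero wavevector (proportional to the sedimentation
coefficient) and S(0) the osmotic compressibility factor.  The apparent
hydrodynamic radius from a Stokes-Einstein inversion of D_c is therefore
R_h,app/R_h,0 = S(0)/H(0).

H(0) is computed here in the pairwise-additive far-field approximation: the
two-body Rotne-Prager mobility, angle-averaged, contributes a/r per
neighbour (the r^-3 source-dipole terms vanish in the trace), and the
divergent backflow is renormalised Batchelor-style, leaving

    H(0) = 1 + 4 pi rho a int_0^inf r (g(r) - 1) dr,      a = sigma/2.

For hard spheres this gives the dilute slope -6 phi, close to Batchelor's
exact -6.55 phi; the approximation is only trusted up to phi ~ 0.05.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .oz_solver import CorrelationSet, carnahan_starling_s0

__all__ = [
    "HydroResult",
    "h_of_zero_pairwise",
    "h_zero_hs",
    "rh_app_ratio",
    "h_exp_zero",
    "PAIRWISE_PHI_LIMIT",
]

#: Volume fraction above which the pairwise-additive H(0) is unreliable.
PAIRWISE_PHI_LIMIT = 0.05


@dataclass(frozen=True)
class HydroResult:
    """H(0), the collective-diffusion ratio D_c/D_0 = H(0)/S(0), and the
    apparent hydrodynamic radius ratio R_h,app/R_h,0 = S(0)/H(0)."""

    h_zero: float
    d_collective_over_d0: float
    rh_app_ratio: float


def h_of_zero_pairwise(corr: CorrelationSet, phi: float,
                       sigma_hs: float) -> float:
    """Pairwise-additive H(0) from a converged g(r).

    Emits a warning above the documented validity bound phi <= 0.05.
    """
    if phi > PAIRWISE_PHI_LIMIT:
        warnings.warn(
            f"pairwise-additive H(0) requested at phi={phi:.3f} > "
            f"{PAIRWISE_PHI_LIMIT}; result is extrapolated beyond its "
            "validity bound", stacklevel=2)
    r = corr.r_grid
    g = corr.g_of_r
    rho = corr.rho
    a = 0.5 * sigma_hs
    integral = float(np.trapezoid(r * (g - 1.0), r))
    return 1.0 + 4.0 * math.pi * rho * a * integral


def h_zero_hs(phi: float) -> float:
    """Phenomenological hard-sphere H(0) = (1 + 1.45 phi) S_hs^CS(0).

    Built from the virial expansion D_c ~ D_0 (1 + k_D phi) with k_D = 1.45
    combined with the Carnahan-Starling compressibility; its dilute slope is
    1.45 - 8 = -6.55, the Batchelor value.
    """
    if not 0 <= phi < 0.5:
        raise ValueError("phi must be in [0, 0.5)")
    return (1.0 + 1.45 * phi) * carnahan_starling_s0(phi)


def rh_app_ratio(s_zero: float, h_zero: float) -> float:
    """Apparent hydrodynamic radius ratio R_h,app/R_h,0 = S(0)/H(0) = D_0/D_c."""
    if s_zero <= 0 or h_zero <= 0:
        raise ValueError("S(0) and H(0) must be positive")
    return s_zero / h_zero


def h_exp_zero(s_exp_zero: float, rh_ratio_measured: float) -> float:
    """Experimental H(0) = S_exp(0) / (R_h,app/R_h,0)."""
    if s_exp_zero <= 0 or rh_ratio_measured <= 0:
        raise ValueError("inputs must be positive")
    return s_exp_zero / rh_ratio_measured


def hydro_result(s_zero: float, h_zero: float) -> HydroResult:
    return HydroResult(h_zero=h_zero,
                       d_collective_over_d0=h_zero / s_zero,
                       rh_app_ratio=rh_app_ratio(s_zero, h_zero))
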