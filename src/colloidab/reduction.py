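"""Reduction of raw scattering observables to derived quantities.

Covers the standard light/X-ray scattering analysis chain for protein
solutions: second-order cumulant fits of DLS autocorrelation functions and
the Stokes-Einstein apparent hydrodynamic radius; excess Rayleigh ratios and
apparent molecular weights from SLS; experimental effective structure
factors from concentration-normalised SAXS intensities divided by a dilute
form-factor measurement; tracer-microrheology relative viscosities; the
effective charge from electrophoretic mobility through Henry's function; and
the chi-square comparison grid between measured and simulated structure
factors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.constants import Boltzmann, elementary_charge
from scipy.optimize import least_squares

from .model_core import SolutionConditions

__all__ = [
    "Correlogram",
    "ScatteringCurve",
    "OpticalConstants",
    "ElectrokineticParams",
    "CumulantFit",
    "cumulant_fit",
    "apparent_hydrodynamic_radius",
    "apparent_molecular_weight",
    "saxs_structure_factor",
    "microrheology_viscosity",
    "henry_function",
    "zeff_from_mobility",
    "mobility_from_zeff",
    "chi_square",
]


@dataclass
class Correlogram:
    """DLS intensity autocorrelation function g2(t) with its metadata."""

    lag_times: np.ndarray          # s, strictly increasing
    g2_values: np.ndarray
    q: float                       # nm^-1
    temperature: float = 298.15    # K
    solvent_viscosity: float = 0.8904  # mPa s

    def __post_init__(self) -> None:
        self.lag_times = np.asarray(self.lag_times, dtype=float)
        self.g2_values = np.asarray(self.g2_values, dtype=float)
        if np.any(np.diff(self.lag_times) <= 0):
            raise ValueError("lag times must be strictly increasing")


@dataclass
class ScatteringCurve:
    """SAXS/SLS intensity table I(q) with concentration metadata."""

    q_values: np.ndarray           # nm^-1, strictly increasing
    intensities: np.ndarray        # arbitrary units
    concentration: float           # mg/mL
    kind_tag: str = "saxs"

    def __post_init__(self) -> None:
        self.q_values = np.asarray(self.q_values, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if np.any(np.diff(self.q_values) <= 0):
            raise ValueError("q must be strictly increasing")
        # reduced structure-factor tables may carry NaN-masked points
        if self.kind_tag != "structure_factor" and \
                not np.all(np.isfinite(self.intensities)):
            raise ValueError("intensities must be finite")


@dataclass(frozen=True)
class OpticalConstants:
    """Optical constants of the SLS experiment.

    The toluene Rayleigh ratio is instrument- and wavelength-specific and
    must be supplied; 1.35e-5 cm^-1 is a common literature value for
    vertical/vertical geometry at 633 nm.
    """

    dn_dc: float = 0.194                 # mL/mg
    vacuum_wavelength: float = 660.0     # nm
    solvent_refractive_index: float = 1.333
    toluene_refractive_index: float = 1.496
    toluene_rayleigh_ratio: float = 1.35e-5  # cm^-1

    def optical_constant(self) -> float:
        """K = 4 pi^2 n_sol^2 (dn/dc)^2 / (N_A lambda_0^4) in
        cm^2 mol g^-2 (with dn/dc in mL/g and lambda in cm)."""
        from scipy.constants import Avogadro
        n = self.solvent_refractive_index
        dndc = self.dn_dc * 1e3          # mL/mg -> mL/g
        lam = self.vacuum_wavelength * 1e-7  # nm -> cm
        return 4.0 * math.pi**2 * n**2 * dndc**2 / (Avogadro * lam**4)


@dataclass(frozen=True)
class ElectrokineticParams:
    """Electrophoresis inputs: hydrodynamic radius for the friction factor,
    Stern-layer radius a_zeta = R_hs + 0.18 nm (counterion radius), and the
    measured mobility in cm^2/(V s)."""

    hydrodynamic_radius: float = 5.4   # nm
    stern_radius: float = 5.18         # nm
    mobility: float = 0.0              # cm^2 / (V s)


@dataclass(frozen=True)
class CumulantFit:
    gamma: float        # first cumulant, s^-1
    mu2: float          # second cumulant, s^-2
    beta: float         # coherence factor
    baseline: float


def cumulant_fit(data: Correlogram, order: int = 2) -> CumulantFit:
    """Nonlinear least-squares cumulant fit of g2(t).

    Model: g2(t) = B + beta * exp(-2 Gamma t + mu2 t^2); ``order=1`` fixes
    mu2 = 0.  The initial decay rate is taken from the half-decay lag.
    """
    if order not in (1, 2):
        raise ValueError("order must be 1 or 2")
    t = data.lag_times
    y = data.g2_values
    if len(t) < 10:
        raise ValueError("need at least 10 lag points spanning the decay")
    b0 = float(np.median(y[-max(3, len(y) // 10):]))
    beta0 = float(max(y[0] - b0, 1e-6))
    decay = (y - b0) / beta0
    below = np.nonzero(decay < 0.5)[0]
    if len(below) == 0 or below[0] == 0:
        raise RuntimeError("correlogram does not decay; cannot fit cumulants")
    gamma0 = math.log(2.0) / (2.0 * t[below[0]])

    def model(p):
        g, m2, be, ba = p
        return ba + be * np.exp(-2.0 * g * t + (m2 if order == 2 else 0.0)
                                * t * t)

    def resid(p):
        return model(p) - y

    p0 = np.array([gamma0, 0.0, beta0, b0])
    sol = least_squares(resid, p0, method="trf",
                        bounds=([0, -np.inf, 0, -np.inf],
                                [np.inf, np.inf, np.inf, np.inf]))
    if not sol.success:
        raise RuntimeError(f"cumulant fit failed: {sol.message}")
    g, m2, be, ba = sol.x
    return CumulantFit(gamma=float(g), mu2=float(m2 if order == 2 else 0.0),
                       beta=float(be), baseline=float(ba))


def apparent_hydrodynamic_radius(gamma: float, q: float,
                                 conditions: SolutionConditions) -> float:
    """Stokes-Einstein apparent hydrodynamic radius in nm.

    D_app = Gamma / q^2 (q in nm^-1, Gamma in s^-1);
    R_h,app = k_B T / (6 pi eta D_app).
    """
    if gamma <= 0 or q <= 0:
        raise ValueError("gamma and q must be positive")
    d_app = gamma / q**2 * 1e-18        # nm^2/s -> m^2/s
    eta = conditions.solvent_viscosity * 1e-3   # mPa s -> Pa s
    r_m = Boltzmann * conditions.temperature / (6.0 * math.pi * eta * d_app)
    return r_m * 1e9


def apparent_molecular_weight(sample_intensity: float,
                              toluene_intensity: float,
                              solvent_intensity: float,
                              concentration: float,
                              optics: OpticalConstants) -> float:
    """Apparent molecular weight from one SLS intensity record (g/mol).

    Excess Rayleigh ratio
    R = (I_sample - I_solvent)/I_toluene * (n_sol/n_tol)^2 * R_tol;
    M_w,app = R / (K c) with c in g/mL.  For an interacting solution
    M_w,app = M_w S_eff(0).
    """
    if concentration <= 0:
        raise ValueError("concentration must be positive")
    excess = sample_intensity - solvent_intensity
    if excess <= 0:
        raise ValueError("non-positive excess scattering intensity")
    ratio = (optics.solvent_refractive_index
             / optics.toluene_refractive_index) ** 2
    rayleigh = excess / toluene_intensity * ratio * \
        optics.toluene_rayleigh_ratio
    k = optics.optical_constant()
    c_g_ml = concentration * 1e-3
    return rayleigh / (k * c_g_ml)


def saxs_structure_factor(curve_c: ScatteringCurve,
                          curve_form: ScatteringCurve) -> ScatteringCurve:
    """Experimental effective structure factor
    S(q) = [I(q)/c] / [I_0(q)/c_0], with the dilute curve interpolated onto
    the concentrated q-grid.  Points with non-positive form intensity are
    masked (NaN)."""
    q = curve_c.q_values
    if (q[0] < curve_form.q_values[0] - 1e-12
            or q[-1] > curve_form.q_values[-1] + 1e-12):
        raise ValueError("form-factor curve does not cover the sample q-grid")
    form = np.interp(q, curve_form.q_values, curve_form.intensities)
    norm_c = curve_c.intensities / curve_c.concentration
    norm_0 = form / curve_form.concentration
    with np.errstate(divide="ignore", invalid="ignore"):
        s = np.where(norm_0 > 0, norm_c / norm_0, np.nan)
    return ScatteringCurve(q, s, curve_c.concentration, "structure_factor")


def microrheology_viscosity(gamma_sample: float,
                            gamma_reference: float) -> float:
    """Relative viscosity from tracer DLS: eta_r = Gamma_ref / Gamma_sample
    (Stokes-Einstein, same tracer, q and T in both measurements)."""
    if gamma_sample <= 0 or gamma_reference <= 0:
        raise ValueError("relaxation rates must be positive")
    return gamma_reference / gamma_sample


def henry_function(x: float) -> float:
    """Henry's function in the classic convention, f(0) = 1 (Hueckel) to
    f(inf) = 3/2 (Smoluchowski), via the Swan-Furst closed-form approximant

        f(x) = 1 + 1 / [ 2 (1 + 2.5 / (x (1 + 2 e^{-x})))^3 ].
    """
    if x < 0:
        raise ValueError("kappa*a must be >= 0")
    if x == 0:
        return 1.0
    return 1.0 + 0.5 / (1.0 + 2.5 / (x * (1.0 + 2.0 * math.exp(-x)))) ** 3


def _mobility_factor(kappa_a: float) -> float:
    """Charge-to-mobility factor f'(kappa a) = (2/3) f_Henry(kappa a) /
    (1 + kappa a): the Debye-Hueckel relation between the surface (zeta)
    potential and the charge contributes the 1/(1 + kappa a) screening of
    the effective charge seen by the flow."""
    return (2.0 / 3.0) * henry_function(kappa_a) / (1.0 + kappa_a)


def zeff_from_mobility(params: ElectrokineticParams,
                       conditions: SolutionConditions,
                       kappa: float) -> float:
    """Effective charge (elementary charges) from electrophoretic mobility.

    Z_eff = mu_e f / (e f'(kappa a_zeta)) with friction f = 6 pi eta R_h and
    f' the mobility factor above; kappa in nm^-1.
    """
    eta = conditions.solvent_viscosity * 1e-3
    friction = 6.0 * math.pi * eta * params.hydrodynamic_radius * 1e-9
    mobility_si = params.mobility * 1e-4   # cm^2/(V s) -> m^2/(V s)
    fprime = _mobility_factor(kappa * params.stern_radius)
    return mobility_si * friction / (elementary_charge * fprime)


def mobility_from_zeff(z_eff: float, params: ElectrokineticParams,
                       conditions: SolutionConditions,
                       kappa: float) -> float:
    """Forward model: mobility in cm^2/(V s) for a given effective charge."""
    eta = conditions.solvent_viscosity * 1e-3
    friction = 6.0 * math.pi * eta * params.hydrodynamic_radius * 1e-9
    fprime = _mobility_factor(kappa * params.stern_radius)
    return z_eff * elementary_charge * fprime / friction * 1e4


def chi_square(measured_q: np.ndarray, measured_s: np.ndarray,
               simulated_q: np.ndarray, simulated_s: np.ndarray,
               weights: Optional[np.ndarray] = None) -> float:
    """Per-point mean square deviation between measured and simulated
    structure factors; the simulated table is interpolated onto the measured
    q-grid.  Optional per-point inverse-variance weights."""
    measured_q = np.asarray(measured_q, float)
    measured_s = np.asarray(measured_s, float)
    if (measured_q[0] < simulated_q[0] - 1e-9
            or measured_q[-1] > simulated_q[-1] + 1e-9):
        raise ValueError("simulated table does not cover the measured q-grid")
    sim = np.interp(measured_q, simulated_q, simulated_s)
    d2 = (measured_s - sim) ** 2
    if weights is not None:
        d2 = d2 * np.asarray(weights, float)
    return float(np.nanmean(d2))
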