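"""Ornstein-Zernike integral-equation engine for the spherical colloid model.

Solves the OZ relation h = c + rho c*h for a hard-core pair potential with a
Yukawa repulsion and power-law attraction tail, closed with Percus-Yevick
(PY), hypernetted-chain (HNC) or the thermodynamically self-consistent
Rogers-Young (RY) closure.  RY interpolates between PY (short range) and HNC
(long range) through the mixing function f(r) = 1 - exp(-xi r); the mixing
parameter xi is tuned until the virial and compressibility routes to the
osmotic pressure derivative agree.

The radial Fourier transforms use the type-I discrete sine transform on a
uniform grid, the classic numerical machinery for one-component OZ solvers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.fft import dst
from scipy.optimize import brentq

from .model_core import PairPotentialParams, pair_potential

__all__ = [
    "SolverSettings",
    "CorrelationSet",
    "ConvergenceError",
    "solve_oz",
    "s_zero",
    "carnahan_starling_s0",
]


class ConvergenceError(RuntimeError):
    def __init__(self, message: str, residual: float = math.nan):
        super().__init__(message)
        self.residual = residual


@dataclass(frozen=True)
class SolverSettings:
    """Numerical parameters of the OZ solve.

    ``n_grid`` should be a power of two; ``r_max`` defaults to 40 sigma.
    """

    n_grid: int = 4096
    r_max: Optional[float] = None
    picard_mixing: float = 0.5
    tolerance: float = 1e-9
    max_iterations: int = 50000

    def __post_init__(self) -> None:
        if self.n_grid & (self.n_grid - 1):
            raise ValueError("n_grid must be a power of two")
        if not 0 < self.picard_mixing <= 1:
            raise ValueError("picard_mixing must be in (0, 1]")


@dataclass
class CorrelationSet:
    """Paired r-space / q-space correlation tables from a converged OZ solve."""

    r_grid: np.ndarray
    q_grid: np.ndarray
    g_of_r: np.ndarray
    c_of_r: np.ndarray
    s_of_q: np.ndarray
    s_zero: float
    closure_tag: str
    rho: float
    sigma_hs: float
    converged: bool = True
    ry_mixing_parameter: Optional[float] = None

    @property
    def phi(self) -> float:
        return self.rho * math.pi * self.sigma_hs**3 / 6.0

    def contact_value(self) -> float:
        """g(sigma+) by quadratic extrapolation of the first points outside
        the core."""
        mask = self.r_grid >= self.sigma_hs
        r, g = self.r_grid[mask][:6], self.g_of_r[mask][:6]
        coef = np.polyfit(r - self.sigma_hs, g, 2)
        return float(coef[-1])


def _closure_g(closure: str, bfac: np.ndarray, gamma: np.ndarray,
               fmix: Optional[np.ndarray]) -> np.ndarray:
    """Closure relation: g(r) from the Boltzmann factor and the indirect
    correlation gamma = h - c.  bfac = exp(-beta V), exactly 0 inside the
    hard core so g = 0 there for every closure."""
    if closure == "py":
        return bfac * (1.0 + gamma)
    if closure == "hnc":
        with np.errstate(over="ignore"):
            return bfac * np.exp(gamma)
    if closure == "ry":
        with np.errstate(over="ignore"):
            expm = np.expm1(fmix * gamma)
        out = bfac * (1.0 + np.where(fmix > 1e-12, expm / np.where(
            fmix > 1e-12, fmix, 1.0), gamma))
        return out
    raise ValueError(f"unknown closure {closure!r}")


def _solve_fixed(params: PairPotentialParams, rho: float, closure: str,
                 settings: SolverSettings, xi: Optional[float],
                 c_init: Optional[np.ndarray] = None):
    """Picard iteration of OZ + closure at fixed RY mixing parameter."""
    n = settings.n_grid
    r_max = settings.r_max or 40.0 * params.sigma_hs
    # place the hard-core boundary halfway between grid points: the jump in
    # g(r) at sigma is then integrated at second order instead of first
    dr0 = r_max / (n + 1)
    m = max(1, round(params.sigma_hs / dr0 - 0.5))
    dr = params.sigma_hs / (m + 0.5)
    i = np.arange(1, n + 1)
    r = i * dr
    dq = math.pi / ((n + 1) * dr)
    q = i * dq

    v = pair_potential(r, params)
    with np.errstate(over="ignore", under="ignore"):
        bfac = np.where(v > 300.0, 0.0, np.exp(-np.minimum(v, 300.0)))
    fmix = None if xi is None else -np.expm1(-xi * r)

    c = c_init if c_init is not None else bfac - 1.0
    mix = settings.picard_mixing
    resid = math.inf
    for _ in range(settings.max_iterations):
        # forward transform  c_hat(q) = 4 pi / q * int r c sin(qr) dr
        ch = 2.0 * math.pi * dr / q * dst(r * c, type=1)
        denom = 1.0 - rho * ch
        if np.any(denom <= 0):
            # unphysical intermediate; damp harder
            mix = max(0.05, mix * 0.5)
            c = 0.5 * c
            continue
        gh = rho * ch * ch / denom
        gamma = dq / (4.0 * math.pi**2 * r) * dst(q * gh, type=1)
        g = _closure_g(closure, bfac, gamma, fmix)
        c_new = g - 1.0 - gamma
        resid = float(np.max(np.abs(c_new - c)))
        c = (1.0 - mix) * c + mix * c_new
        if resid < settings.tolerance:
            break
    else:
        raise ConvergenceError(
            f"OZ/{closure} did not converge (residual {resid:.2e})", resid)

    ch = 2.0 * math.pi * dr / q * dst(r * c, type=1)
    hh = ch / (1.0 - rho * ch)
    s = 1.0 + rho * hh
    gamma = dq / (4.0 * math.pi**2 * r) * dst(q * (hh - ch), type=1)
    g = _closure_g(closure, bfac, gamma, fmix)
    return r, q, g, c, s, v


def _s0_compressibility(r: np.ndarray, g: np.ndarray, rho: float) -> float:
    return 1.0 + 4.0 * math.pi * rho * float(np.trapezoid((g - 1.0) * r * r, r))


def _virial_dpdrho(params: PairPotentialParams, closure: str,
                   settings: SolverSettings, xi: Optional[float],
                   rho: float, drho: float) -> float:
    """d(beta P_virial)/d rho by central finite difference.

    beta P / rho = 1 + (2 pi/3) rho g(sigma+) sigma^3
                 - (2 pi/3) rho int_sigma^inf beta V'(r) g(r) r^3 dr
    with the hard-core delta handled through the contact value.
    """
    sig = params.sigma_hs

    def pressure(rho_i: float) -> float:
        r, q, g, c, s, v = _solve_fixed(params, rho_i, closure, settings, xi)
        corr = CorrelationSet(r, q, g, c, s, math.nan, closure, rho_i, sig)
        gc = corr.contact_value()
        mask = r >= sig
        rr, gg = r[mask], g[mask]
        dv = np.gradient(v[mask], rr)
        integ = float(np.trapezoid(dv * gg * rr**3, rr))
        bp_over_rho = (1.0 + (2.0 * math.pi / 3.0) * rho_i *
                       (gc * sig**3 - integ))
        return rho_i * bp_over_rho

    return (pressure(rho + drho) - pressure(rho - drho)) / (2.0 * drho)


def solve_oz(params: PairPotentialParams, rho: float, closure: str = "ry",
             settings: Optional[SolverSettings] = None) -> CorrelationSet:
    """Solve the OZ equation at number density rho (nm^-3).

    closure is one of ``"py"``, ``"hnc"``, ``"ry"``.  For RY the mixing
    parameter is bracketed and bisected until the virial and compressibility
    routes to d(beta P)/d rho agree to ~0.5%; if the self-consistency
    condition cannot be bracketed (it degenerates when PY and HNC already
    coincide, e.g. at very low density) the solution closest to consistency
    is returned.
    """
    settings = settings or SolverSettings()
    closure = closure.lower()
    phi = rho * math.pi * params.sigma_hs**3 / 6.0
    if phi >= 0.55:
        raise ValueError(f"volume fraction {phi:.3f} too high for the solver")

    if closure != "ry":
        r, q, g, c, s, _ = _solve_fixed(params, rho, closure, settings, None)
        s0 = _s0_compressibility(r, g, rho)
        return CorrelationSet(r, q, g, c, s, s0, closure, rho,
                              params.sigma_hs)

    def mismatch(xi: float) -> float:
        drho = max(1e-3 * rho, 1e-9)
        dpdr = _virial_dpdrho(params, closure, settings, xi, rho, drho)
        r, q, g, c, s, _ = _solve_fixed(params, rho, closure, settings, xi)
        s0 = _s0_compressibility(r, g, rho)
        return dpdr - 1.0 / s0

    sig = params.sigma_hs
    xis = np.array([0.05, 0.2, 0.5, 1.0, 2.0, 5.0, 15.0]) / sig
    vals = []
    xi_star = None
    for lo, hi in zip(xis[:-1], xis[1:]):
        try:
            flo = vals[-1] if vals else mismatch(lo)
        except ConvergenceError:
            flo = math.nan
        try:
            fhi = mismatch(hi)
        except ConvergenceError:
            fhi = math.nan
        vals.append(fhi)
        if np.isfinite(flo) and np.isfinite(fhi) and flo * fhi < 0:
            xi_star = brentq(mismatch, lo, hi, xtol=1e-3 / sig, rtol=1e-3)
            break
    if xi_star is None:
        finite = [(abs(f), x) for f, x in zip(vals, xis[1:]) if np.isfinite(f)]
        if not finite:
            raise ConvergenceError("RY self-consistency search failed")
        xi_star = min(finite)[1]

    r, q, g, c, s, _ = _solve_fixed(params, rho, closure, settings, xi_star)
    s0 = _s0_compressibility(r, g, rho)
    return CorrelationSet(r, q, g, c, s, s0, "ry", rho, params.sigma_hs,
                          ry_mixing_parameter=xi_star)


def s_zero(corr: CorrelationSet) -> float:
    """S(0) through the compressibility route 1 + 4 pi rho int (g-1) r^2 dr.

    Refuses unconverged input; consistent with the q->0 extrapolation of
    S(q) by construction of the solver.
    """
    if not corr.converged:
        raise ValueError("refusing to integrate an unconverged solution")
    return _s0_compressibility(corr.r_grid, corr.g_of_r, corr.rho)


def carnahan_starling_s0(phi: float) -> float:
    """Hard-sphere S(0) from the Carnahan-Starling equation of state:

    S_hs(0) = (1 - phi)^4 / [(1 + 2 phi)^2 + phi^3 (phi - 4)]
    """
    if not 0 <= phi < 0.55:
        raise ValueError("phi must be in [0, 0.55)")
    return (1.0 - phi) ** 4 / ((1.0 + 2.0 * phi) ** 2 + phi**3 * (phi - 4.0))
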