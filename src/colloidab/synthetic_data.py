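"""Forward models generating every observable the reduction pipeline consumes.

Each generator is the measurable image of exactly one reduction operation:
DLS correlograms from a known collective diffusion coefficient, SAXS
intensity series from a known S(q) and form factor, SLS intensity records
from a known S_eff(0), electrophoretic mobilities from a known effective
charge, and relative-viscosity series from the sticky-sphere/cluster chain.
With the noise level at zero, generator followed by reduction is the
identity; at the default 2% noise it emulates a well-behaved bench
instrument.  All randomness flows from one seeded generator per call.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from scipy.constants import Boltzmann

from . import hydro, model_core, oz_solver, reduction, rheology
from .model_core import PairPotentialParams, SolutionConditions
from .reduction import Correlogram, OpticalConstants, ScatteringCurve

__all__ = [
    "GroundTruth",
    "gen_correlogram",
    "gen_saxs_series",
    "gen_sls_series",
    "gen_mobility",
    "gen_viscosity_series",
    "sphere_form_factor",
]


@dataclass
class GroundTruth:
    """Known-truth description from which observables are generated."""

    potential: PairPotentialParams
    conditions: SolutionConditions
    model_tag: str = "sphere"
    noise_level: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_level < 0:
            raise ValueError("noise level must be >= 0")

    def rng(self, salt: int = 0) -> np.random.Generator:
        return np.random.default_rng((self.seed, salt))


def sphere_form_factor(q, radius: float):
    """Form factor of a homogeneous sphere, P(0) = 1."""
    q = np.asarray(q, float)
    x = q * radius
    with np.errstate(invalid="ignore", divide="ignore"):
        amp = np.where(x > 1e-8,
                       3.0 * (np.sin(x) - x * np.cos(x)) / np.maximum(x, 1e-300)**3,
                       1.0)
    return amp**2


def _structure_state(truth: GroundTruth, c: float, closure: str = "hnc"):
    """S(0) and H(0) of the truth model at concentration c."""
    cond = truth.conditions.with_concentration(c)
    params = PairPotentialParams.from_conditions(
        cond, sigma_hs=truth.potential.sigma_hs,
        z_eff=truth.potential.z_eff,
        epsilon_a=truth.potential.epsilon_a,
        alpha=truth.potential.alpha)
    rho = cond.protein_number_density_nm3
    phi = rho * math.pi * params.sigma_hs**3 / 6.0
    corr = oz_solver.solve_oz(params, rho, closure)
    import warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        h0 = hydro.h_of_zero_pairwise(corr, phi, params.sigma_hs)
    return corr, corr.s_zero, h0


def gen_correlogram(truth: GroundTruth, q: float, c: float, *,
                    rh0: float = 5.4, n_lags: int = 80,
                    s_zero: Optional[float] = None,
                    h_zero: Optional[float] = None,
                    mu2_rel: float = 0.0, beta: float = 0.9,
                    baseline: float = 1.0) -> Correlogram:
    """DLS correlogram g2(t) = B + beta exp(-2 Gamma t + mu2 t^2).

    Gamma = D_c q^2 with D_c = D_0 H(0)/S(0) for the truth model at
    concentration c; ``mu2_rel`` sets mu2/Gamma^2 (normalised
    polydispersity variance).  Lag grid is log-spaced around the decay
    time; noise is additive Gaussian on g2 of magnitude noise_level*beta.
    """
    if s_zero is None or h_zero is None:
        _, s_zero, h_zero = _structure_state(truth, c)
    cond = truth.conditions
    eta = cond.solvent_viscosity * 1e-3
    d0 = Boltzmann * cond.temperature / (6.0 * math.pi * eta * rh0 * 1e-9)
    d0_nm = d0 * 1e18                    # nm^2/s
    gamma = d0_nm * (h_zero / s_zero) * q**2
    t_half = math.log(2.0) / (2.0 * gamma)
    t = np.logspace(math.log10(t_half / 100.0), math.log10(t_half * 50.0),
                    n_lags)
    mu2 = mu2_rel * gamma**2
    g2 = baseline + beta * np.exp(-2.0 * gamma * t + mu2 * t * t)
    rng = truth.rng(1)
    g2 = g2 + truth.noise_level * beta * rng.standard_normal(n_lags)
    return Correlogram(t, g2, q, cond.temperature, cond.solvent_viscosity)


def gen_saxs_series(truth: GroundTruth, concentrations: Sequence[float],
                    q_grid: np.ndarray, *,
                    structure_tables: Optional[Sequence[np.ndarray]] = None,
                    form_factor_fn: Optional[Callable] = None,
                    amplitude: float = 1.0,
                    include_form_curve: bool = True):
    """SAXS intensity series I(q) = A c P(q) S_eff(q) (1 + noise).

    ``structure_tables`` (one S(q) array per concentration, on ``q_grid``)
    overrides the internal integral-equation evaluation; this is how 9-bead
    Monte Carlo structure factors are injected.  A dilute form-factor curve
    at c0 = 1 mg/mL (S = 1) is prepended by convention.
    """
    q_grid = np.asarray(q_grid, float)
    if form_factor_fn is None:
        form_factor_fn = lambda q: sphere_form_factor(
            q, truth.potential.sigma_hs / 2.0)
    pq = form_factor_fn(q_grid)
    rng = truth.rng(2)
    curves = []
    if include_form_curve:
        i0 = amplitude * 1.0 * pq
        i0 = i0 * (1.0 + truth.noise_level * rng.standard_normal(len(q_grid)))
        curves.append(ScatteringCurve(q_grid, i0, 1.0, "saxs"))
    for k, c in enumerate(concentrations):
        if structure_tables is not None:
            s = np.asarray(structure_tables[k], float)
        else:
            corr, _, _ = _structure_state(truth, c)
            s = np.interp(q_grid, corr.q_grid, corr.s_of_q)
        i = amplitude * c * pq * s
        i = i * (1.0 + truth.noise_level * rng.standard_normal(len(q_grid)))
        curves.append(ScatteringCurve(q_grid, i, c, "saxs"))
    return curves


def gen_sls_series(truth: GroundTruth, concentrations: Sequence[float], *,
                   optics: Optional[OpticalConstants] = None,
                   s_zeros: Optional[Sequence[float]] = None,
                   toluene_intensity: float = 1.0,
                   solvent_intensity: float = 0.05):
    """Per-concentration SLS intensity records with M_w,app = M_1 S_eff(0).

    Returns a list of dicts with the three raw intensities plus metadata;
    :func:`colloidab.reduction.apparent_molecular_weight` reduces each
    record back to M_w,app.
    """
    optics = optics or OpticalConstants()
    m1 = truth.conditions.protein_molecular_weight
    rng = truth.rng(3)
    ratio = (optics.solvent_refractive_index
             / optics.toluene_refractive_index) ** 2
    k = optics.optical_constant()
    records = []
    for i, c in enumerate(concentrations):
        s0 = (s_zeros[i] if s_zeros is not None
              else _structure_state(truth, c)[1])
        rayleigh = k * (c * 1e-3) * m1 * s0
        excess = rayleigh / optics.toluene_rayleigh_ratio / ratio \
            * toluene_intensity
        sample = solvent_intensity + excess * (
            1.0 + truth.noise_level * rng.standard_normal())
        records.append({
            "concentration": c,
            "sample_intensity": float(sample),
            "toluene_intensity": toluene_intensity,
            "solvent_intensity": solvent_intensity,
            "s_zero_true": float(s0),
        })
    return records


def gen_mobility(truth: GroundTruth, z_zeta: float, *,
                 electro: Optional[reduction.ElectrokineticParams] = None
                 ) -> reduction.ElectrokineticParams:
    """Electrophoretic mobility record for a known zeta-level effective
    charge, mu_e = Z e f'(kappa a)/f (+ noise)."""
    electro = electro or reduction.ElectrokineticParams()
    cond = truth.conditions
    kappa = model_core.debye_kappa(cond, z_zeta, truth.potential.sigma_hs)
    mu = reduction.mobility_from_zeff(z_zeta, electro, cond, kappa)
    rng = truth.rng(4)
    mu = mu * (1.0 + truth.noise_level * rng.standard_normal())
    return reduction.ElectrokineticParams(
        hydrodynamic_radius=electro.hydrodynamic_radius,
        stern_radius=electro.stern_radius, mobility=float(mu))


def gen_viscosity_series(truth: GroundTruth,
                         concentrations: Sequence[float], *,
                         phi_max: float = 0.58,
                         cluster_schedule: Optional[Callable[[float], float]]
                         = None,
                         cluster_params: Optional[rheology.ClusterParams]
                         = None,
                         sticky: bool = True):
    """Relative-viscosity series (c, phi, B2*, tau_b, eta_r).

    Without a cluster schedule, eta_r follows the sticky-sphere chain with
    B2* recomputed at every concentration (screening is concentration
    dependent); with one, <s>_n(c) inflates the Quemada volume fraction
    through the fractal mapping.  Concentrations whose volume fraction
    reaches phi_max truncate the series with a warning entry.
    """
    rng = truth.rng(5)
    rows = []
    for c in concentrations:
        cond = truth.conditions.with_concentration(c)
        params = PairPotentialParams.from_conditions(
            cond, sigma_hs=truth.potential.sigma_hs,
            z_eff=truth.potential.z_eff,
            epsilon_a=truth.potential.epsilon_a,
            alpha=truth.potential.alpha)
        rho_ml = model_core.number_density(c, cond.protein_molecular_weight)
        phi = model_core.volume_fraction(rho_ml, params.sigma_hs)
        virial = model_core.b2_normalized(params)
        if cluster_schedule is not None:
            base = cluster_params or rheology.ClusterParams()
            s_n = max(1.0, cluster_schedule(c))
            cp = rheology.ClusterParams(
                fractal_dimension=base.fractal_dimension,
                mean_aggregation_number=s_n,
                monomer_radius=base.monomer_radius,
                monomer_charge=base.monomer_charge)
            phi_eff = rheology.cluster_volume_fraction(phi, cp)
            if phi_eff >= phi_max:
                rows.append({"concentration": c, "phi": phi,
                             "b2_star": virial.b2_star,
                             "tau_b": virial.stickiness,
                             "eta_r": math.inf, "truncated": True})
                break
            eta = rheology.quemada(phi_eff, phi_max)
        elif sticky:
            if phi >= phi_max:
                rows.append({"concentration": c, "phi": phi,
                             "b2_star": virial.b2_star,
                             "tau_b": virial.stickiness,
                             "eta_r": math.inf, "truncated": True})
                break
            eta = rheology.sticky_viscosity(phi, virial.stickiness, phi_max)
        else:
            eta = rheology.quemada(phi, phi_max)
        eta = eta * (1.0 + truth.noise_level * rng.standard_normal())
        rows.append({"concentration": c, "phi": phi,
                     "b2_star": virial.b2_star, "tau_b": virial.stickiness,
                     "eta_r": float(eta), "truncated": False})
    return rows
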