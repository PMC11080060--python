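"""Relative-viscosity models: Quemada hard spheres, sticky-sphere correction,
and the fractal-cluster mapping.

The zero-shear relative viscosity of a hard-sphere suspension is described
by the phenomenological Quemada form eta_r = (1 - phi/phi_max)^-2 with
phi_max ~ 0.58.  Weak attractions raise the viscosity; this is captured
semi-empirically through the Baxter stickiness parameter tau_b obtained by
matching the normalised second virial coefficient B2* = 1 - 1/(4 tau_b).
Self-assembly into open fractal clusters inflates the effective hard-sphere
volume fraction (phi_cluster = phi <s>_n^{3/d_F - 1}); inverting the Quemada
curve for a measured viscosity therefore yields a mean aggregation number.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

from scipy.optimize import brentq

from . import model_core, oz_solver

__all__ = [
    "ClusterParams",
    "quemada",
    "sticky_viscosity",
    "cluster_volume_fraction",
    "invert_cluster_size",
    "cluster_apparent_s0",
    "STICKY_COEFF",
]

#: Coefficient of the semi-empirical sticky-sphere viscosity correction.
STICKY_COEFF = 1.9


@dataclass(frozen=True)
class ClusterParams:
    """Fractal-cluster description of a self-assembled suspension.

    Clusters of aggregation number s act as effective spheres of radius
    R_1 s^{1/d_F}; charges are taken as additive (Z_cluster = Z_1 <s>_n,
    an assumption that overestimates charge effects for large clusters).
    """

    fractal_dimension: float = 2.2
    mean_aggregation_number: float = 1.0
    weight_mean_aggregation: Optional[float] = None
    monomer_radius: float = 5.0
    monomer_charge: float = 20.0

    def __post_init__(self) -> None:
        if not 1.0 < self.fractal_dimension <= 3.0:
            raise ValueError("fractal dimension must be in (1, 3]")
        if self.mean_aggregation_number < 1:
            raise ValueError("mean aggregation number must be >= 1")
        if self.weight_mean_aggregation is None:
            object.__setattr__(self, "weight_mean_aggregation",
                               2.0 * self.mean_aggregation_number)
        if self.weight_mean_aggregation < self.mean_aggregation_number:
            raise ValueError("<s>_w must be >= <s>_n")


def quemada(phi: float, phi_max: float = 0.58) -> float:
    """Quemada relative viscosity eta_r = (1 - phi/phi_max)^-2."""
    if phi < 0:
        raise ValueError("phi must be >= 0")
    if phi >= phi_max:
        raise ValueError(f"phi={phi:.3f} >= phi_max={phi_max}: "
                         "viscosity diverges at dynamical arrest")
    return (1.0 - phi / phi_max) ** -2


def sticky_viscosity(phi: float, tau_b: float,
                     phi_max: float = 0.58) -> float:
    """Sticky-sphere relative viscosity.

    eta_r = eta_r^hs(phi) [1 + correction(phi, tau_b)] with the
    semi-empirical correction C phi^2 / [tau_b (1 - phi/phi_max)]: it
    vanishes in the hard-sphere limit tau_b -> inf and at phi -> 0 and is
    strictly decreasing in tau_b.
    """
    if tau_b <= 0:
        raise ValueError("tau_b must be positive")
    base = quemada(phi, phi_max)
    if math.isinf(tau_b):
        return base
    corr = STICKY_COEFF * phi * phi / (tau_b * (1.0 - phi / phi_max))
    return base * (1.0 + corr)


def cluster_volume_fraction(phi: float, params: ClusterParams) -> float:
    """Effective cluster hard-sphere volume fraction
    phi_cluster = phi <s>_n^{3/d_F - 1}; open clusters (d_F < 3) inflate
    the excluded volume, compact ones (d_F = 3) conserve it."""
    s = params.mean_aggregation_number
    return phi * s ** (3.0 / params.fractal_dimension - 1.0)


def invert_cluster_size(eta_r_measured: float, phi: float,
                        params: ClusterParams,
                        phi_max: float = 0.58) -> float:
    """Mean aggregation number explaining a measured relative viscosity.

    Solves quemada(phi_cluster) = eta_r for phi_cluster, then inverts the
    fractal mapping.  A viscosity at or below the monomer curve returns 1
    (no clusters).
    """
    if eta_r_measured <= quemada(phi, phi_max):
        return 1.0
    phi_cluster = phi_max * (1.0 - eta_r_measured ** -0.5)
    expo = 3.0 / params.fractal_dimension - 1.0
    if expo == 0:
        raise ValueError("d_F = 3: cluster size unidentifiable from "
                         "viscosity (volume conserved)")
    return (phi_cluster / phi) ** (1.0 / expo)


def cluster_apparent_s0(params: ClusterParams, rho_monomer: float,
                        conditions: model_core.SolutionConditions,
                        *, epsilon_a: float = 0.0, alpha: float = 90.0,
                        closure: str = "hnc",
                        settings: Optional[oz_solver.SolverSettings] = None,
                        ) -> float:
    """Apparent S(0) of a cluster suspension: <s>_w S_eff(0).

    The effective suspension has spheres of radius R_1 <s>_n^{1/d_F},
    charge Z_1 <s>_n, and number density rho/<s>_n, interacting through the
    same composite potential at cluster scale; S_eff(0) comes from the
    integral-equation solver.  Non-interacting clusters give exactly <s>_w.
    """
    s_n = params.mean_aggregation_number
    s_w = params.weight_mean_aggregation
    sigma_cl = 2.0 * params.monomer_radius * s_n ** (1.0 /
                                                     params.fractal_dimension)
    z_cl = params.monomer_charge * s_n
    rho_cl = rho_monomer / s_n
    if z_cl == 0 and epsilon_a == 0 and rho_cl * sigma_cl**3 < 1e-8:
        return s_w
    # screening is set by the microion environment of the monomers
    # (counterion density Z_cl rho_cl = Z_1 rho is unchanged by clustering)
    pp = model_core.PairPotentialParams(
        sigma_hs=sigma_cl, z_eff=z_cl, epsilon_a=epsilon_a, alpha=alpha,
        kappa=model_core.debye_kappa(conditions, params.monomer_charge,
                                     2.0 * params.monomer_radius),
        bjerrum=model_core.bjerrum_length(conditions))
    corr = oz_solver.solve_oz(pp, rho_cl, closure, settings)
    return s_w * corr.s_zero
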