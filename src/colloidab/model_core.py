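"""Solution conditions, unit conversions and the composite effective pair potential.

This module holds the physics shared by every other part of the package: a
description of the solvent/electrolyte state, the concentration-dependent
Debye screening parameter (including the counterion and free-volume terms),
the composite pair potential between two antibody molecules modelled as
charged, weakly attractive hard spheres, and its second virial coefficient.

Units convention throughout the package: lengths in nm, energies in units of
k_B*T, number densities in nm^-3 unless a function explicitly documents
another unit (e.g. the mL^-1 density printed by light-scattering software).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import yaml
from scipy.constants import Avogadro, Boltzmann, elementary_charge, epsilon_0
from scipy.integrate import quad

__all__ = [
    "OVERLAP_ENERGY",
    "SolutionConditions",
    "PairPotentialParams",
    "VirialResult",
    "bjerrum_length",
    "number_density",
    "number_density_nm3",
    "volume_fraction",
    "debye_kappa",
    "ionic_strength_to_density",
    "pair_potential",
    "b2_normalized",
    "stickiness_from_b2star",
    "b2star_from_stickiness",
]

#: Sentinel energy (in k_B T) returned for hard-core overlap.  It is finite so
#: that array arithmetic stays well-defined, but large enough that
#: exp(-OVERLAP_ENERGY) underflows to exactly 0.0 in double precision.
OVERLAP_ENERGY = 1.0e4


class InvalidConditionsError(ValueError):
    """Raised for non-physical solution conditions or potential parameters."""


def ionic_strength_to_density(ionic_strength_mM: float) -> float:
    """Number density (nm^-3) of EACH ion species of a monovalent electrolyte
    at the given ionic strength in mM (mol/m^3 equivalently mmol/L)."""
    return ionic_strength_mM * 1e-3 * Avogadro / 1e24


@dataclass(frozen=True)
class SolutionConditions:
    """Thermodynamic and electrolyte state of an antibody solution.

    Parameters
    ----------
    temperature : float
        Absolute temperature in K.
    relative_permittivity : float
        Relative dielectric constant of the solvent.
    solvent_viscosity : float
        Solvent viscosity in mPa s (water at 25 C: 0.8904).
    salt_number_density : float
        Number density of added monovalent salt ion pairs, nm^-3
        (one value per species; the screening formula counts both signs).
    buffer_ion_number_density : float
        Number density of dissociated monovalent buffer ion pairs, nm^-3.
    protein_concentration : float
        Protein weight concentration in mg/mL.
    protein_molecular_weight : float
        Protein molecular weight in g/mol.
    """

    temperature: float = 298.15
    relative_permittivity: float = 78.4
    solvent_viscosity: float = 0.8904
    salt_number_density: float = 0.0
    buffer_ion_number_density: float = 0.0
    protein_concentration: float = 0.0
    protein_molecular_weight: float = 148000.0

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise InvalidConditionsError("temperature must be positive")
        if self.relative_permittivity <= 1:
            raise InvalidConditionsError("relative permittivity must exceed 1")
        if min(self.salt_number_density, self.buffer_ion_number_density,
               self.protein_concentration) < 0:
            raise InvalidConditionsError("densities must be non-negative")
        if self.protein_molecular_weight <= 0:
            raise InvalidConditionsError("molecular weight must be positive")

    @classmethod
    def from_ionic_strengths(cls, *, salt_mM: float = 0.0, buffer_mM: float = 0.0,
                             **kwargs) -> "SolutionConditions":
        """Build conditions from monovalent ionic strengths in mM."""
        return cls(
            salt_number_density=ionic_strength_to_density(salt_mM),
            buffer_ion_number_density=ionic_strength_to_density(buffer_mM),
            **kwargs,
        )

    @classmethod
    def from_yaml(cls, path) -> "SolutionConditions":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**data)

    def with_concentration(self, c: float) -> "SolutionConditions":
        return replace(self, protein_concentration=c)

    @property
    def protein_number_density_nm3(self) -> float:
        return number_density_nm3(self.protein_concentration,
                                  self.protein_molecular_weight)


@dataclass(frozen=True)
class PairPotentialParams:
    """Parameters of the composite charged-sphere pair potential.

    The potential is the sum of a hard core at ``sigma_hs``, a DLVO
    screened-Coulomb (Yukawa) repulsion for an effective surface charge
    ``z_eff``, and a steep power-law attraction of contact depth
    ``epsilon_a`` (k_B T) and exponent ``alpha``::

        beta V(r) = inf                                           r < sigma
                  = Z^2 L_B e^{kappa sigma} e^{-kappa r}
                    / [(1 + kappa sigma/2)^2 r]
                    - eps_a (sigma/r)^alpha                       r >= sigma
    """

    sigma_hs: float
    z_eff: float
    epsilon_a: float = 0.0
    alpha: float = 90.0
    kappa: float = 0.0
    bjerrum: float = 0.7149

    def __post_init__(self) -> None:
        if self.sigma_hs <= 0:
            raise InvalidConditionsError("sigma_hs must be positive")
        if self.alpha <= 3:
            raise InvalidConditionsError(
                "attraction exponent must exceed 3 for an integrable tail")
        if self.kappa < 0 or self.epsilon_a < 0:
            raise InvalidConditionsError("kappa and epsilon_a must be >= 0")

    @classmethod
    def from_conditions(cls, conditions: SolutionConditions, *, sigma_hs: float,
                        z_eff: float, epsilon_a: float = 0.0,
                        alpha: float = 90.0) -> "PairPotentialParams":
        """Derive the screening parameter and Bjerrum length from conditions."""
        return cls(
            sigma_hs=sigma_hs,
            z_eff=z_eff,
            epsilon_a=epsilon_a,
            alpha=alpha,
            kappa=debye_kappa(conditions, z_eff, sigma_hs),
            bjerrum=bjerrum_length(conditions),
        )


@dataclass(frozen=True)
class VirialResult:
    """Second virial coefficient of a pair potential.

    ``b2`` and ``b2_hs`` are in nm^3; ``b2_star = b2/b2_hs``;
    ``stickiness`` is the adhesive-sphere parameter tau_b defined through
    B2* = 1 - 1/(4 tau_b) (infinite when B2* >= 1, i.e. no net stickiness).
    """

    b2: float
    b2_hs: float
    b2_star: float
    stickiness: float


def bjerrum_length(conditions: SolutionConditions) -> float:
    """Bjerrum length e^2 / (4 pi eps0 eps_r k_B T) in nm.

    Water at 25 C (eps_r = 78.4) gives 0.714 nm: the separation at which two
    elementary charges interact with thermal energy.
    """
    eps_r = conditions.relative_permittivity
    if eps_r <= 0:
        raise InvalidConditionsError("permittivity must be positive")
    lb_m = elementary_charge**2 / (
        4 * math.pi * epsilon_0 * eps_r * Boltzmann * conditions.temperature)
    return lb_m * 1e9


def number_density(c: float, molecular_weight: float) -> float:
    """Particle number density in mL^-1 for weight concentration c (mg/mL).

    1 mg/mL at 148 kDa corresponds to 4.068e15 particles per mL.
    """
    if molecular_weight <= 0:
        raise InvalidConditionsError("molecular weight must be positive")
    if c < 0:
        raise InvalidConditionsError("concentration must be >= 0")
    return c * 1e-3 * Avogadro / molecular_weight


def number_density_nm3(c: float, molecular_weight: float) -> float:
    """Particle number density in nm^-3 (1 mL = 1e21 nm^3)."""
    return number_density(c, molecular_weight) / 1e21


def volume_fraction(rho_per_ml: float, sigma_hs: float) -> float:
    """Hard-sphere volume fraction phi = rho * pi sigma^3 / 6.

    ``rho_per_ml`` is in mL^-1 and ``sigma_hs`` in nm.
    """
    if rho_per_ml < 0 or sigma_hs <= 0:
        raise InvalidConditionsError("rho >= 0 and sigma_hs > 0 required")
    rho_nm3 = rho_per_ml / 1e21
    return rho_nm3 * math.pi * sigma_hs**3 / 6.0


def debye_kappa(conditions: SolutionConditions, z_eff: float,
                sigma_hs: float) -> float:
    """Concentration-dependent inverse Debye screening length in nm^-1.

    kappa^2 = 4 pi L_B (|Z_eff| rho + 2 rho_s + 2 rho_b) / (1 - phi)

    The |Z_eff| rho term counts the monovalent counterions released by the
    protein itself; salt and buffer contribute both ion signs (2 rho); the
    1/(1 - phi) factor restricts the microions to the free volume outside the
    proteins.  Finite microion size is ignored.
    """
    rho = conditions.protein_number_density_nm3
    phi = volume_fraction(rho * 1e21, sigma_hs)
    if phi >= 1:
        raise InvalidConditionsError(
            f"protein volume fraction {phi:.3f} >= 1: screening diverges")
    lb = bjerrum_length(conditions)
    ionic = (abs(z_eff) * rho
             + 2.0 * conditions.salt_number_density
             + 2.0 * conditions.buffer_ion_number_density)
    return math.sqrt(4.0 * math.pi * lb * ionic / (1.0 - phi))


def _repulsion_prefactor(params: PairPotentialParams) -> float:
    x = params.kappa * params.sigma_hs
    return (params.z_eff**2 * params.bjerrum * math.exp(x)
            / (1.0 + 0.5 * x) ** 2)


def pair_potential(r, params: PairPotentialParams):
    """Composite pair potential beta*V(r) in k_B T; r in nm (scalar or array).

    Returns the hard-core overlap sentinel ``OVERLAP_ENERGY`` for r < sigma;
    downstream Boltzmann factors exp(-V) then evaluate to exactly 0.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("separation must be positive")
    pref = _repulsion_prefactor(params)
    with np.errstate(over="ignore"):
        v_r = pref * np.exp(-params.kappa * r) / r
        v_a = -params.epsilon_a * (params.sigma_hs / r) ** params.alpha
    out = np.where(r < params.sigma_hs, OVERLAP_ENERGY, v_r + v_a)
    return out if out.ndim else float(out)


def b2_normalized(params: PairPotentialParams) -> VirialResult:
    """Second virial coefficient B2 = 2 pi int (1 - e^{-V}) r^2 dr.

    The hard-core part is analytic, B2_hs = 2 pi sigma^3 / 3; the tail over
    [sigma, inf) is evaluated by adaptive quadrature with extra break points
    bracketing the narrow power-law well near contact.
    """
    if params.epsilon_a > 0 and params.alpha <= 3:
        raise InvalidConditionsError("divergent attraction integral")
    sig = params.sigma_hs
    b2_hs = 2.0 * math.pi * sig**3 / 3.0

    def integrand(r: float) -> float:
        return (1.0 - math.exp(-pair_potential(r, params))) * r * r

    # the well of a (sigma/r)^alpha attraction decays over ~ sigma/alpha
    w = sig / params.alpha
    pts = [sig + w, sig + 5 * w, sig + 25 * w, 1.5 * sig, 2 * sig, 5 * sig]
    upper = max(50.0 * sig, (20.0 / params.kappa if params.kappa > 0 else 0.0))
    tail, _ = quad(integrand, sig, upper,
                   points=[p for p in pts if p < upper],
                   limit=500, epsabs=1e-8 * b2_hs, epsrel=1e-10)
    b2 = b2_hs + 2.0 * math.pi * tail
    b2_star = b2 / b2_hs
    return VirialResult(b2=b2, b2_hs=b2_hs, b2_star=b2_star,
                        stickiness=stickiness_from_b2star(b2_star))


def stickiness_from_b2star(b2_star: float) -> float:
    """Baxter stickiness tau_b with B2* = 1 - 1/(4 tau_b).

    B2* >= 1 means no net stickiness: tau_b is unbounded (returns inf).
    """
    if b2_star >= 1.0:
        return math.inf
    return 1.0 / (4.0 * (1.0 - b2_star))


def b2star_from_stickiness(tau_b: float) -> float:
    """Inverse of :func:`stickiness_from_b2star`."""
    if tau_b <= 0:
        raise ValueError("tau_b must be positive")
    return 1.0 - 1.0 / (4.0 * tau_b)
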