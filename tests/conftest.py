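import math

import numpy as np
import pytest

from colloidab import model_core as mc
from colloidab.oz_solver import SolverSettings


@pytest.fixture(scope="session")
def water_25c():
    """Buffer-only solvent at 25 C (7 mM ionic strength, no added salt)."""
    return mc.SolutionConditions.from_ionic_strengths(buffer_mM=7.0)


@pytest.fixture(scope="session")
def high_salt():
    """50 mM NaCl added on top of the 7 mM buffer (57 mM total)."""
    return mc.SolutionConditions.from_ionic_strengths(salt_mM=50.0,
                                                      buffer_mM=7.0)


@pytest.fixture(scope="session")
def mab_potential(water_25c):
    """The charged-sphere model used throughout: sigma_hs = 10 nm,
    Z_eff = 20, at low ionic strength with no attraction."""
    cond = water_25c.with_concentration(20.0)
    return mc.PairPotentialParams.from_conditions(
        cond, sigma_hs=10.0, z_eff=20.0, epsilon_a=0.0)


@pytest.fixture(scope="session")
def fast_settings():
    """Coarse solver grid adequate for 1e-3-level checks."""
    return SolverSettings(n_grid=2048)


def hs_params(sigma=10.0):
    return mc.PairPotentialParams(sigma_hs=sigma, z_eff=0.0, epsilon_a=0.0,
                                  kappa=0.0)


def rho_for_phi(phi, sigma=10.0):
    return phi * 6.0 / (math.pi * sigma**3)


@pytest.fixture(scope="session")
def hard_sphere():
    return hs_params


@pytest.fixture(scope="session")
def phi_to_rho():
    return rho_for_phi
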