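import math

import numpy as np
import pytest

from colloidab import model_core as mc
from colloidab import reduction as rd


def _make_correlogram(gamma, mu2=0.0, beta=0.9, baseline=1.0, q=0.0207,
                      noise=0.0, rng=None, n=80):
    t_half = math.log(2) / (2 * gamma)
    t = np.logspace(math.log10(t_half / 100), math.log10(t_half * 50), n)
    g2 = baseline + beta * np.exp(-2 * gamma * t + mu2 * t * t)
    if noise:
        g2 = g2 * (1 + noise * rng.standard_normal(n))
    return rd.Correlogram(t, g2, q)


class TestCumulantFit:
    def test_exact_single_exponential(self):
        fit = rd.cumulant_fit(_make_correlogram(3.5e4), order=2)
        assert fit.gamma == pytest.approx(3.5e4, rel=1e-6)
        assert fit.beta == pytest.approx(0.9, rel=1e-6)
        assert fit.baseline == pytest.approx(1.0, rel=1e-6)

    def test_first_order_fixes_mu2(self):
        fit = rd.cumulant_fit(_make_correlogram(1e4), order=1)
        assert fit.mu2 == 0.0
        assert fit.gamma == pytest.approx(1e4, rel=1e-5)

    def test_polydisperse_mixture_second_cumulant(self):
        # two-exponential mixture: g1 = sum w_i exp(-G_i t); the cumulant
        # expansion gives Gamma = <G> and mu2 = variance of the rate
        # distribution
        g1v, g2v, w = 2.0e4, 4.0e4, 0.5
        mean = w * g1v + (1 - w) * g2v
        var = w * g1v**2 + (1 - w) * g2v**2 - mean**2
        t_half = math.log(2) / (2 * mean)
        t = np.logspace(math.log10(t_half / 50), math.log10(t_half * 2), 120)
        g1 = w * np.exp(-g1v * t) + (1 - w) * np.exp(-g2v * t)
        corr = rd.Correlogram(t, 1.0 + 0.9 * g1**2, 0.0207)
        fit = rd.cumulant_fit(corr, order=2)
        assert fit.gamma == pytest.approx(mean, rel=0.03)
        assert fit.mu2 / fit.gamma**2 == pytest.approx(var / mean**2,
                                                       rel=0.05)

    def test_noise_bias_below_one_percent(self):
        rng = np.random.default_rng(42)
        gammas = []
        for _ in range(50):
            corr = _make_correlogram(3.0e4, noise=0.01, rng=rng)
            gammas.append(rd.cumulant_fit(corr, order=2).gamma)
        assert abs(np.mean(gammas) / 3.0e4 - 1.0) < 0.01

    def test_non_decaying_data_rejected(self):
        t = np.logspace(-6, -2, 40)
        corr = rd.Correlogram(t, np.full(40, 1.9), 0.0207)
        with pytest.raises(RuntimeError):
            rd.cumulant_fit(corr)


class TestApparentHydrodynamicRadius:
    def test_round_trip_54_nm_sphere(self):
        from scipy.constants import Boltzmann
        cond = mc.SolutionConditions()
        d0 = (Boltzmann * cond.temperature
              / (6 * math.pi * cond.solvent_viscosity * 1e-3 * 5.4e-9))
        q = 0.0207
        gamma = d0 * 1e18 * q**2
        assert rd.apparent_hydrodynamic_radius(gamma, q, cond) == \
            pytest.approx(5.4, rel=1e-9)

    def test_q_squared_cancellation(self):
        cond = mc.SolutionConditions()
        d_nm = 4e7
        r1 = rd.apparent_hydrodynamic_radius(d_nm * 0.02**2, 0.02, cond)
        r2 = rd.apparent_hydrodynamic_radius(d_nm * 0.04**2, 0.04, cond)
        assert r1 == pytest.approx(r2, rel=1e-12)

    def test_inverse_proportionality_in_viscosity(self):
        thin = mc.SolutionConditions(solvent_viscosity=0.4452)
        thick = mc.SolutionConditions(solvent_viscosity=0.8904)
        r_thin = rd.apparent_hydrodynamic_radius(3e4, 0.0207, thin)
        r_thick = rd.apparent_hydrodynamic_radius(3e4, 0.0207, thick)
        # R_h,app = kT/(6 pi eta D): inversely proportional to viscosity
        assert r_thin == pytest.approx(2 * r_thick, rel=1e-12)


class TestApparentMolecularWeight:
    def _forward(self, mw_app, c, optics):
        ratio = (optics.solvent_refractive_index
                 / optics.toluene_refractive_index) ** 2
        rayleigh = optics.optical_constant() * (c * 1e-3) * mw_app
        excess = rayleigh / optics.toluene_rayleigh_ratio / ratio
        return excess + 0.05

    def test_ideal_solution(self):
        optics = rd.OpticalConstants()
        sample = self._forward(148000.0, 20.0, optics)
        assert rd.apparent_molecular_weight(sample, 1.0, 0.05, 20.0,
                                            optics) == \
            pytest.approx(148000.0, rel=1e-9)

    def test_interacting_solution_halves(self):
        optics = rd.OpticalConstants()
        sample = self._forward(0.5 * 148000.0, 50.0, optics)
        assert rd.apparent_molecular_weight(sample, 1.0, 0.05, 50.0,
                                            optics) == \
            pytest.approx(74000.0, rel=1e-9)

    def test_optical_constant_proportional_to_dndc_squared(self):
        k1 = rd.OpticalConstants(dn_dc=0.194).optical_constant()
        k2 = rd.OpticalConstants(dn_dc=0.194 * math.sqrt(2)).optical_constant()
        assert k2 == pytest.approx(2 * k1, rel=1e-12)

    def test_negative_excess_flagged(self):
        with pytest.raises(ValueError):
            rd.apparent_molecular_weight(0.01, 1.0, 0.05, 20.0,
                                         rd.OpticalConstants())


class TestSaxsStructureFactor:
    def test_identical_curves_give_unity(self):
        q = np.linspace(0.05, 3.0, 100)
        i = np.exp(-q)
        out = rd.saxs_structure_factor(
            rd.ScatteringCurve(q, i, 10.0), rd.ScatteringCurve(q, i, 10.0))
        assert np.allclose(out.intensities, 1.0)

    def test_recovers_injected_structure_factor(self):
        q = np.linspace(0.05, 3.0, 200)
        p = np.exp(-(q * 3) ** 2 / 3)
        s = 1 + 0.4 * np.sin(3 * q) / (3 * q)
        sample = rd.ScatteringCurve(q, 5.0 * 30.0 * p * s, 30.0)
        form = rd.ScatteringCurve(q, 5.0 * 1.0 * p, 1.0)
        out = rd.saxs_structure_factor(sample, form)
        assert np.allclose(out.intensities, s, rtol=1e-12)

    def test_concentration_normalization_invariance(self):
        q = np.linspace(0.05, 2.0, 50)
        i = np.exp(-q)
        base = rd.saxs_structure_factor(
            rd.ScatteringCurve(q, i, 10.0), rd.ScatteringCurve(q, i, 1.0))
        scaled = rd.saxs_structure_factor(
            rd.ScatteringCurve(q, 2 * i, 20.0), rd.ScatteringCurve(q, i, 1.0))
        assert np.allclose(base.intensities, scaled.intensities)

    def test_nonpositive_form_masked(self):
        q = np.linspace(0.05, 2.0, 50)
        form_i = np.exp(-q)
        form_i[10] = 0.0
        out = rd.saxs_structure_factor(
            rd.ScatteringCurve(q, np.exp(-q), 5.0),
            rd.ScatteringCurve(q, form_i, 1.0))
        assert np.isnan(out.intensities[10])


class TestMicrorheology:
    def test_equal_rates(self):
        assert rd.microrheology_viscosity(1e4, 1e4) == 1.0

    def test_three_fold_slowdown(self):
        assert rd.microrheology_viscosity(1e4, 3e4) == pytest.approx(3.0)


class TestHenryFunction:
    def test_hueckel_limit(self):
        assert rd.henry_function(0.0) == 1.0
        assert rd.henry_function(1e-6) == pytest.approx(1.0, abs=1e-6)

    def test_smoluchowski_limit(self):
        assert rd.henry_function(1e6) == pytest.approx(1.5, abs=1e-4)

    def test_monotone_increasing(self):
        x = np.linspace(0.01, 50, 500)
        f = np.array([rd.henry_function(v) for v in x])
        assert np.all(np.diff(f) > 0)


class TestZeffFromMobility:
    @pytest.mark.parametrize("ionic_mM,mobility,expected,tol", [
        (7.0, 0.6427e-4, 12.6, 0.2),
        (57.0, 0.3539e-4, 13.4, 1.1),
    ])
    def test_measured_mobilities(self, ionic_mM, mobility, expected, tol):
        cond = mc.SolutionConditions.from_ionic_strengths(salt_mM=ionic_mM)
        kappa = mc.debye_kappa(cond, 0.0, 10.8)
        params = rd.ElectrokineticParams(mobility=mobility)
        z = rd.zeff_from_mobility(params, cond, kappa)
        assert z == pytest.approx(expected, abs=tol)

    def test_linear_in_mobility(self):
        cond = mc.SolutionConditions.from_ionic_strengths(salt_mM=7.0)
        kappa = mc.debye_kappa(cond, 0.0, 10.8)
        z1 = rd.zeff_from_mobility(
            rd.ElectrokineticParams(mobility=0.3e-4), cond, kappa)
        z2 = rd.zeff_from_mobility(
            rd.ElectrokineticParams(mobility=0.6e-4), cond, kappa)
        assert z2 == pytest.approx(2 * z1, rel=1e-12)

    def test_forward_model_round_trip(self):
        cond = mc.SolutionConditions.from_ionic_strengths(salt_mM=20.0)
        kappa = mc.debye_kappa(cond, 0.0, 10.8)
        params = rd.ElectrokineticParams()
        mu = rd.mobility_from_zeff(15.0, params, cond, kappa)
        back = rd.zeff_from_mobility(
            rd.ElectrokineticParams(mobility=mu), cond, kappa)
        assert back == pytest.approx(15.0, rel=1e-12)


class TestChiSquare:
    def test_identical_tables(self):
        q = np.linspace(0.1, 2.0, 30)
        s = 1 + np.sin(q)
        assert rd.chi_square(q, s, q, s) == 0.0

    def test_constant_offset(self):
        q = np.linspace(0.1, 2.0, 30)
        s = np.ones(30)
        assert rd.chi_square(q, s + 0.2, q, s) == pytest.approx(0.04,
                                                                rel=1e-12)

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValueError):
            rd.chi_square(np.array([0.1, 5.0]), np.ones(2),
                          np.array([0.2, 2.0]), np.ones(2))
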