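import math

import numpy as np
import pytest

from colloidab import model_core as mc
from colloidab import ninebead_mc as nb


class TestGeometry:
    def test_radius_of_gyration(self):
        model = nb.build_geometry(1.0)
        assert model.radius_of_gyration == pytest.approx(1.7297, abs=1e-3)

    def test_tangent_circle_diameter(self):
        model = nb.build_geometry(1.0)
        centroid = model.bead_centers[:3].mean(axis=0)
        reach = np.linalg.norm(model.bead_centers - centroid, axis=1).max()
        assert 2 * (reach + 0.5) == pytest.approx(6.16, abs=0.01)

    def test_consecutive_beads_tangent(self):
        model = nb.build_geometry(2.89)
        c = model.bead_centers
        # central triangle pairs plus each appended bead to its predecessor
        pairs = [(0, 1), (0, 2), (1, 2), (0, 3), (3, 4), (1, 5), (5, 6),
                 (2, 7), (7, 8)]
        for a, b in pairs:
            assert np.linalg.norm(c[a] - c[b]) == pytest.approx(
                2.89, abs=1e-12)

    def test_mirror_symmetry_about_leg_axis(self):
        c = nb.build_geometry(1.0).bead_centers
        mirrored = c * np.array([-1.0, 1.0, 1.0])
        # the bead set (not the ordering) is invariant under x -> -x
        d = np.linalg.norm(c[:, None, :] - mirrored[None, :, :], axis=-1)
        assert np.all(d.min(axis=1) < 1e-12)

    def test_com_at_origin_and_planar(self):
        c = nb.build_geometry(3.0).bead_centers
        assert np.allclose(c.mean(axis=0), 0.0, atol=1e-12)
        assert np.allclose(c[:, 2], 0.0)


class TestBeadForRg:
    def test_measured_antibody_rg(self):
        assert nb.bead_for_rg(5.0) == pytest.approx(2.89, abs=5e-3)

    def test_identity_scale(self):
        assert nb.bead_for_rg(nb.RG_COEFF) == pytest.approx(1.0, rel=1e-12)

    def test_round_trip(self):
        for target in (1.0, 4.3, 5.0):
            model = nb.build_geometry(nb.bead_for_rg(target))
            assert model.radius_of_gyration == pytest.approx(target,
                                                             abs=1e-6)


class TestBox:
    def test_printed_formula(self):
        # N_p = 1000, M_w = 148 kDa, c = 150 mg/mL
        assert nb.box_from_concentration(150.0, 1000, 148000.0) == \
            pytest.approx(117.9, abs=0.1)

    def test_halving_concentration_doubles_volume(self):
        l1 = nb.box_from_concentration(100.0, 500, 148000.0)
        l2 = nb.box_from_concentration(50.0, 500, 148000.0)
        assert l2**3 == pytest.approx(2 * l1**3, rel=1e-12)

    def test_single_molecule_box_is_inverse_density(self):
        l = nb.box_from_concentration(20.0, 1, 148000.0)
        rho = mc.number_density_nm3(20.0, 148000.0)
        assert l**3 == pytest.approx(1.0 / rho, rel=1e-9)


class TestBeadPairEnergy:
    def test_overlap(self):
        m = nb.build_geometry(2.89, bead_charge=3.0)
        assert nb.bead_pair_energy(1.0, m, 0.3, 0.714) >= 1e8

    def test_per_bead_charge_for_z28(self):
        m = nb.build_geometry(2.89, bead_charge=28.0 / 9.0)
        assert m.bead_charge == pytest.approx(3.111, abs=1e-3)
        assert m.total_charge() == pytest.approx(28.0, rel=1e-12)

    def test_far_field_superposition(self):
        # weakly screened: the summed bead-bead Yukawa approaches the
        # Yukawa of the total charge placed at the molecular COM
        kappa, lb = 0.02, 0.7149
        m = nb.build_geometry(2.89, bead_charge=28.0 / 9.0)
        c1 = m.bead_centers
        errs = []
        for r in (40.0, 60.0, 90.0):
            c2 = m.bead_centers + np.array([0.0, 0.0, r])
            d = np.linalg.norm(c1[:, None, :] - c2[None, :, :], axis=-1)
            e_sum = nb.bead_pair_energy(d, m, kappa, lb).sum()
            x = kappa * m.bead_diameter
            pref = m.bead_charge**2 * lb * math.exp(x) / (1 + x / 2) ** 2
            point = 81 * pref * math.exp(-kappa * r) / r
            errs.append(abs(e_sum / point - 1.0))
            assert e_sum == pytest.approx(point, rel=0.05)
        # the multipole correction dies off with separation
        assert errs[-1] < errs[0]


class TestFormFactor:
    def test_normalization(self):
        m = nb.build_geometry(2.89)
        assert nb.form_factor(m, 0.0) == pytest.approx(1.0, rel=1e-12)

    def test_guinier_radius(self):
        m = nb.build_geometry(2.89)
        rg = m.radius_of_gyration
        q = np.linspace(0.01, 0.3 / rg, 40)
        p = nb.form_factor(m, q)
        slope = np.polyfit(q**2, np.log(p), 1)[0]
        assert math.sqrt(-3 * slope) == pytest.approx(rg, rel=5e-3)

    def test_orientation_average_oracle(self):
        # Monte-Carlo average of |F(q_vec)|^2 over random orientations
        m = nb.build_geometry(2.89)
        rng = np.random.default_rng(7)
        dirs = rng.normal(size=(10000, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        for q in (0.2, 0.6, 1.2):
            phases = q * dirs @ m.bead_centers.T
            f2 = (np.abs(np.exp(1j * phases).sum(axis=1)) ** 2 / 81).mean()
            assert nb.form_factor(m, q) == pytest.approx(f2, abs=1.5e-2)


@pytest.fixture(scope="module")
def dilute_onebead_run():
    sigma = 10.0
    model = nb.single_bead_model(sigma)
    phi = 1e-4
    rho = phi * 6 / (math.pi * sigma**3)
    n_mol = 40
    box = (n_mol / rho) ** (1 / 3)
    return nb.run_mc(model, n_molecules=n_mol, box_length=box, sweeps=4000,
                     seed=11, kappa=0.0, bjerrum=0.7149, save_every=10)


class TestMonteCarlo:
    def test_ideal_gas_structure(self, dilute_onebead_run):
        s_cm, s_eff = nb.structure_factors(dilute_onebead_run, nsq_max=27)
        dev = np.abs(s_cm.s_values - 1.0) / s_cm.standard_errors
        assert np.mean(dev < 3.0) > 0.9
        # for a 1-bead molecule the two estimators are identical
        assert np.allclose(s_cm.s_values, s_eff.s_values, atol=1e-10)

    def test_seed_determinism(self):
        model = nb.build_geometry(2.89, bead_charge=2.0)
        kwargs = dict(n_molecules=16, box_length=60.0, sweeps=500, seed=42,
                      kappa=0.3, bjerrum=0.7149, save_every=10)
        t1 = nb.run_mc(model, **kwargs)
        t2 = nb.run_mc(model, **kwargs)
        assert np.array_equal(t1.com, t2.com)
        assert np.array_equal(t1.quaternions, t2.quaternions)
        t3 = nb.run_mc(model, **{**kwargs, "seed": 43})
        assert not np.array_equal(t1.com, t3.com)

    def test_energy_bookkeeping(self):
        model = nb.build_geometry(2.89, bead_charge=28 / 9,
                                  bead_attraction=0.5)
        traj = nb.run_mc(model, n_molecules=24, box_length=50.0,
                         sweeps=3000, seed=5, kappa=0.28, bjerrum=0.7149,
                         save_every=50)
        assert traj.energy_drift < 1e-8

    def test_no_overlaps_in_trajectory(self):
        model = nb.build_geometry(2.89, bead_charge=2.0)
        traj = nb.run_mc(model, n_molecules=16, box_length=40.0, sweeps=500,
                         seed=3, kappa=0.3, bjerrum=0.7149, save_every=25)
        beads = traj.bead_positions(traj.n_frames - 1)
        L = traj.box_length
        sig = model.bead_diameter
        flat = beads.reshape(-1, 3)
        ids = np.repeat(np.arange(traj.n_molecules), model.n_beads)
        d = flat[:, None, :] - flat[None, :, :]
        d -= L * np.round(d / L)
        dist = np.linalg.norm(d, axis=-1)
        different = ids[:, None] != ids[None, :]
        assert dist[different].min() >= sig * (1 - 1e-12)

    def test_packing_error_at_impossible_density(self):
        model = nb.build_geometry(2.89)
        with pytest.raises(RuntimeError):
            nb.run_mc(model, n_molecules=100, box_length=10.0, sweeps=10,
                      seed=1, kappa=0.0, bjerrum=0.7)


class TestStructureFactorEstimator:
    def test_direct_double_sum_oracle(self, dilute_onebead_run):
        """The accumulated estimator equals a brute-force |sum exp(iq.r)|^2
        over the stored configurations."""
        traj = dilute_onebead_run
        s_cm, _ = nb.structure_factors(traj, nsq_max=8)
        L = traj.box_length
        shells = [1, 2, 3, 4, 5, 6, 8]
        per_frame = np.zeros((traj.n_frames, len(shells)))
        for f in range(traj.n_frames):
            pts = traj.com[f]
            for si, nsq in enumerate(shells):
                vals = []
                nmax = int(math.isqrt(nsq))
                for nx in range(-nmax, nmax + 1):
                    for ny in range(-nmax, nmax + 1):
                        for nz in range(-nmax, nmax + 1):
                            if nx * nx + ny * ny + nz * nz != nsq:
                                continue
                            qv = 2 * math.pi / L * np.array([nx, ny, nz])
                            amp = np.exp(1j * pts @ qv).sum()
                            vals.append(abs(amp) ** 2 / len(pts))
                per_frame[f, si] = np.mean(vals)
        expected = per_frame.mean(axis=0)
        assert np.allclose(s_cm.s_values, expected, rtol=1e-10, atol=1e-10)

    def test_estimators_converge_at_low_q(self):
        model = nb.build_geometry(2.89, bead_charge=28 / 9)
        L = nb.box_from_concentration(30.0, 32, 148000.0)
        traj = nb.run_mc(model, n_molecules=32, box_length=L, sweeps=4000,
                         seed=9, kappa=0.28, bjerrum=0.7149, save_every=20)
        s_cm, s_eff = nb.structure_factors(traj, nsq_max=12)
        for k in range(2):
            se = math.hypot(s_cm.standard_errors[k],
                            s_eff.standard_errors[k])
            assert abs(s_cm.s_values[k] - s_eff.s_values[k]) < 3 * se + 0.02


class TestDecoupling:
    def test_single_bead_beta_is_one(self, dilute_onebead_run):
        s_cm, _ = nb.structure_factors(dilute_onebead_run, nsq_max=12)
        dec = nb.decoupling_sq(s_cm, nb.single_bead_model(10.0))
        assert np.allclose(dec.s_values, s_cm.s_values, atol=1e-9)

    def test_low_q_limit_beta_to_one(self):
        m = nb.build_geometry(2.89)
        q = np.array([1e-4, 2.0])
        mean_f, mean_f2 = nb._amplitude_moments(m, q)
        beta = mean_f**2 / mean_f2
        assert beta[0] == pytest.approx(1.0, abs=1e-6)
        assert beta[1] < 0.9

    def test_requires_cm_estimator(self, dilute_onebead_run):
        _, s_eff = nb.structure_factors(dilute_onebead_run, nsq_max=8)
        with pytest.raises(ValueError):
            nb.decoupling_sq(s_eff, nb.single_bead_model(10.0))


class TestPairPMF:
    def test_no_interactions_flat_pmf(self):
        model = nb.build_geometry(2.89)
        r, pmf, se, flat = nb.pmf_two_body(model, 0.0, 0.7149, seed=2,
                                           n_bins=30, max_steps=12_000_000)
        far = r > 2.5 * model.bead_diameter * nb.DY_COEFF / 2
        # hard core only: PMF is zero wherever configurations exist at all
        assert np.nanmax(np.abs(pmf[far])) < 0.15

    def test_repulsive_pmf_monotone_at_low_ionic_strength(self):
        model = nb.build_geometry(2.89, bead_charge=28 / 9,
                                  bead_attraction=0.0)
        r, pmf, se, flat = nb.pmf_two_body(model, 0.12, 0.7149, seed=4,
                                           n_bins=40, max_steps=8_000_000)
        # screened Coulomb dominates: monotonically repulsive toward contact
        sel = (r > 6.0) & (r < 40.0)
        rr, pp = r[sel], pmf[sel]
        assert pp[0] > pp[-1] + 1.0
        # allow small statistical wiggles on top of monotone decrease
        assert np.all(np.diff(pp) < 0.25)
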