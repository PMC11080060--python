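"""Rigid-body Monte Carlo for the 9-bead Y-shaped antibody model.

An antibody is coarse-grained as nine tangent hard beads arranged in a planar
Y: three central beads in an equilateral triangle, a leg of two appended
beads, and two arms of two appended beads each, the arm axes at 60 deg to
each other and 150 deg to the leg.  Each bead carries 1/9 of the molecular
effective charge and interacts through a screened Coulomb repulsion plus a
steep power-law attraction; the molecule moves as a rigid body.

The module provides the geometry constructor, Metropolis sampling in a cubic
periodic box (translation + rotation moves), center-of-mass and effective
structure-factor estimators with block-averaged errors, the orientation-
averaged form factor, the decoupling approximation, and flat-histogram
(Wang-Landau) sampling of the two-body potential of mean force.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from numba import njit
from scipy.constants import Avogadro

__all__ = [
    "BeadModel",
    "Configuration",
    "Trajectory",
    "SqEstimate",
    "build_geometry",
    "bead_for_rg",
    "box_from_concentration",
    "bead_pair_energy",
    "run_mc",
    "structure_factors",
    "form_factor",
    "decoupling_sq",
    "pmf_two_body",
    "RG_COEFF",
    "DY_COEFF",
]

_OVERLAP = 1.0e8


def _unit_geometry() -> np.ndarray:
    """Bead centers of the Y at unit bead diameter, center of mass at origin.

    Central equilateral triangle of side 1 with its centroid at the origin
    and the leg vertex on -y; the leg appends two tangent beads along -y;
    the arms append two tangent beads each along the 60 and 120 degree
    directions, so the arm axes make 150 deg with the leg axis and 60 deg
    with each other.
    """
    s3 = math.sqrt(3.0)
    a = np.array([0.0, -1.0 / s3, 0.0])
    b = np.array([0.5, 0.5 / s3, 0.0])
    c = np.array([-0.5, 0.5 / s3, 0.0])
    leg_dir = np.array([0.0, -1.0, 0.0])
    arm_r = np.array([math.cos(math.pi / 3), math.sin(math.pi / 3), 0.0])
    arm_l = np.array([-math.cos(math.pi / 3), math.sin(math.pi / 3), 0.0])
    beads = [a, b, c]
    beads += [a + k * leg_dir for k in (1, 2)]
    beads += [b + k * arm_r for k in (1, 2)]
    beads += [c + k * arm_l for k in (1, 2)]
    centers = np.array(beads)
    return centers - centers.mean(axis=0)


_UNIT = _unit_geometry()

#: Radius of gyration of the 9 bead centers in units of the bead diameter.
RG_COEFF = float(np.sqrt((_UNIT**2).sum(axis=1).mean()))

#: Diameter (in bead diameters) of the circle centered at the central-triangle
#: centroid and tangent to the outermost bead surface.
_centroid = _UNIT[:3].mean(axis=0)
DY_COEFF = float(2.0 * (np.linalg.norm(_UNIT - _centroid, axis=1).max() + 0.5))


@dataclass(frozen=True)
class BeadModel:
    """Rigid bead model of one molecule (body frame, center of mass at origin).

    ``bead_charge`` is the charge per bead in elementary charges (the 9-bead
    Y uses Z_eff/9); ``bead_attraction`` the contact depth of the power-law
    attraction in k_B T, acting at the bead scale.
    """

    bead_diameter: float
    bead_centers: np.ndarray
    bead_charge: float = 0.0
    bead_attraction: float = 0.0
    attraction_exponent: float = 90.0

    @property
    def n_beads(self) -> int:
        return len(self.bead_centers)

    @property
    def radius_of_gyration(self) -> float:
        com = self.bead_centers.mean(axis=0)
        return float(np.sqrt(((self.bead_centers - com) ** 2)
                             .sum(axis=1).mean()))

    @property
    def enclosing_radius(self) -> float:
        """Distance from the COM to the outermost bead surface."""
        return float(np.linalg.norm(self.bead_centers, axis=1).max()
                     + 0.5 * self.bead_diameter)

    def total_charge(self) -> float:
        return self.bead_charge * self.n_beads


def build_geometry(sigma_bead: float, *, bead_charge: float = 0.0,
                   bead_attraction: float = 0.0,
                   attraction_exponent: float = 90.0) -> BeadModel:
    """Construct the 9-bead Y at bead diameter ``sigma_bead`` (nm).

    The construction is pinned by two geometric invariants that are asserted
    at build time: Rg = 1.7297 sigma (to 1e-3) and tangent-circle diameter
    6.155 sigma; consecutive beads are exactly tangent.
    """
    if sigma_bead <= 0:
        raise ValueError("sigma_bead must be positive")
    centers = _UNIT * sigma_bead
    assert abs(RG_COEFF - 1.7297) < 1e-3
    assert abs(DY_COEFF - 6.16) < 1e-2
    return BeadModel(bead_diameter=sigma_bead, bead_centers=centers,
                     bead_charge=bead_charge, bead_attraction=bead_attraction,
                     attraction_exponent=attraction_exponent)


def single_bead_model(sigma: float, *, charge: float = 0.0,
                      attraction: float = 0.0,
                      attraction_exponent: float = 90.0) -> BeadModel:
    """One-bead 'molecule': reduces the engine to a simple sphere fluid,
    used to cross-validate against the integral-equation solver."""
    return BeadModel(bead_diameter=sigma,
                     bead_centers=np.zeros((1, 3)),
                     bead_charge=charge, bead_attraction=attraction,
                     attraction_exponent=attraction_exponent)


def bead_for_rg(rg_target: float) -> float:
    """Bead diameter that matches a measured radius of gyration.

    R_g = 5.0 nm gives sigma_bead = 2.89 nm.
    """
    if rg_target <= 0:
        raise ValueError("radius of gyration must be positive")
    return rg_target / RG_COEFF


def box_from_concentration(c: float, n_molecules: int,
                           molecular_weight: float) -> float:
    """Cubic box edge L (nm) holding ``n_molecules`` at concentration c
    (mg/mL): V = N_p M_w / (c N_A 1e-27) in Angstrom^3."""
    if c <= 0:
        raise ValueError("concentration must be positive")
    v_a3 = n_molecules * molecular_weight / (c * Avogadro * 1e-27)
    return v_a3 ** (1.0 / 3.0) / 10.0


def bead_pair_energy(r, model: BeadModel, kappa: float, bjerrum: float):
    """Bead-bead pair energy in k_B T at center distance r (nm).

    Hard overlap inside the bead diameter; outside, a screened Coulomb term
    for the per-bead charge plus the power-law attraction scaled to the bead
    diameter (same functional form as the molecular-scale potential).
    """
    r = np.asarray(r, dtype=float)
    sig = model.bead_diameter
    x = kappa * sig
    pref = (model.bead_charge**2 * bjerrum * math.exp(x)
            / (1.0 + 0.5 * x) ** 2)
    with np.errstate(over="ignore", divide="ignore"):
        v = (pref * np.exp(-kappa * r) / r
             - model.bead_attraction * (sig / r) ** model.attraction_exponent)
    out = np.where(r < sig, _OVERLAP, v)
    return out if out.ndim else float(out)


def _energy_table(model: BeadModel, kappa: float, bjerrum: float,
                  r_cut: float, n_tab: int = 32768):
    """Tabulated bead pair energy on a uniform r grid over [sigma, r_cut]."""
    sig = model.bead_diameter
    r = np.linspace(sig, r_cut, n_tab)
    v = bead_pair_energy(r, model, kappa, bjerrum)
    v = np.ascontiguousarray(v, dtype=np.float64)
    v[-1] = 0.0
    return v, sig, (r_cut - sig) / (n_tab - 1)


# ----------------------------------------------------------------------
# numba kernels
# ----------------------------------------------------------------------

@njit(cache=True, inline="always")
def _pair_v(r2, sig2, tab, tab_r0, tab_dr, r_cut2):
    if r2 >= r_cut2:
        return 0.0
    if r2 < sig2:
        return _OVERLAP
    r = math.sqrt(r2)
    x = (r - tab_r0) / tab_dr
    j = int(x)
    if j >= tab.shape[0] - 1:
        return 0.0
    f = x - j
    return tab[j] * (1.0 - f) + tab[j + 1] * f


@njit(cache=True, inline="always")
def _min_image(d, L):
    return d - L * round(d / L)


@njit(cache=True)
def _mol_energy(i, beads, com, L, tab, tab_r0, tab_dr, r_cut, sig2,
                screen2):
    """Interaction energy of molecule i with all others (min image)."""
    n_mol, n_b = beads.shape[0], beads.shape[1]
    e = 0.0
    r_cut2 = r_cut * r_cut
    for j in range(n_mol):
        if j == i:
            continue
        dx = _min_image(com[i, 0] - com[j, 0], L)
        dy = _min_image(com[i, 1] - com[j, 1], L)
        dz = _min_image(com[i, 2] - com[j, 2], L)
        if dx * dx + dy * dy + dz * dz > screen2:
            continue
        for a in range(n_b):
            for b in range(n_b):
                bx = _min_image(beads[i, a, 0] - beads[j, b, 0], L)
                by = _min_image(beads[i, a, 1] - beads[j, b, 1], L)
                bz = _min_image(beads[i, a, 2] - beads[j, b, 2], L)
                e += _pair_v(bx * bx + by * by + bz * bz, sig2, tab,
                             tab_r0, tab_dr, r_cut2)
                if e >= _OVERLAP:
                    return e
    return e


@njit(cache=True)
def _total_energy(beads, com, L, tab, tab_r0, tab_dr, r_cut, sig2, screen2):
    n_mol = beads.shape[0]
    e = 0.0
    for i in range(n_mol):
        e += _mol_energy(i, beads, com, L, tab, tab_r0, tab_dr, r_cut,
                         sig2, screen2)
    return 0.5 * e


@njit(cache=True, inline="always")
def _quat_mult(p, q, out):
    out[0] = p[0] * q[0] - p[1] * q[1] - p[2] * q[2] - p[3] * q[3]
    out[1] = p[0] * q[1] + p[1] * q[0] + p[2] * q[3] - p[3] * q[2]
    out[2] = p[0] * q[2] - p[1] * q[3] + p[2] * q[0] + p[3] * q[1]
    out[3] = p[0] * q[3] + p[1] * q[2] - p[2] * q[1] + p[3] * q[0]


@njit(cache=True)
def _rotate_body(quat, body, com_x, com_y, com_z, out):
    """Place body-frame beads into the world frame at COM, rotating by quat."""
    w, x, y, z = quat[0], quat[1], quat[2], quat[3]
    r00 = 1 - 2 * (y * y + z * z)
    r01 = 2 * (x * y - w * z)
    r02 = 2 * (x * z + w * y)
    r10 = 2 * (x * y + w * z)
    r11 = 1 - 2 * (x * x + z * z)
    r12 = 2 * (y * z - w * x)
    r20 = 2 * (x * z - w * y)
    r21 = 2 * (y * z + w * x)
    r22 = 1 - 2 * (x * x + y * y)
    for b in range(body.shape[0]):
        bx, by, bz = body[b, 0], body[b, 1], body[b, 2]
        out[b, 0] = com_x + r00 * bx + r01 * by + r02 * bz
        out[b, 1] = com_y + r10 * bx + r11 * by + r12 * bz
        out[b, 2] = com_z + r20 * bx + r21 * by + r22 * bz


@njit(cache=True)
def _random_rotation_quat(amp, out):
    ax = np.random.normal(0.0, 1.0)
    ay = np.random.normal(0.0, 1.0)
    az = np.random.normal(0.0, 1.0)
    norm = math.sqrt(ax * ax + ay * ay + az * az) + 1e-300
    ang = (np.random.random() * 2.0 - 1.0) * amp
    s = math.sin(0.5 * ang)
    out[0] = math.cos(0.5 * ang)
    out[1] = s * ax / norm
    out[2] = s * ay / norm
    out[3] = s * az / norm


@njit(cache=True)
def _mc_kernel(com, quat, beads, body, L, tab, tab_r0, tab_dr, r_cut,
               sig2, screen2, sweeps, burn_in, save_every, seed,
               dmax0, rotmax0):
    np.random.seed(seed)
    n_mol = com.shape[0]
    n_b = body.shape[0]
    dmax = dmax0
    rotmax = rotmax0
    n_save = (sweeps - burn_in) // save_every
    saved_com = np.empty((n_save, n_mol, 3))
    saved_quat = np.empty((n_save, n_mol, 4))
    energies = np.empty(n_save)
    acc_t = 0
    try_t = 0
    acc_r = 0
    try_r = 0
    new_beads = np.empty((n_b, 3))
    qnew = np.empty(4)
    dq = np.empty(4)
    e_run = _total_energy(beads, com, L, tab, tab_r0, tab_dr, r_cut, sig2,
                          screen2)
    max_drift = 0.0
    k_save = 0
    for sweep in range(sweeps):
        for _ in range(n_mol):
            i = np.random.randint(n_mol)
            e_old = _mol_energy(i, beads, com, L, tab, tab_r0, tab_dr,
                                r_cut, sig2, screen2)
            if np.random.random() < 0.5:
                try_t += 1
                ox, oy, oz = com[i, 0], com[i, 1], com[i, 2]
                nx = ox + (np.random.random() * 2 - 1) * dmax
                ny = oy + (np.random.random() * 2 - 1) * dmax
                nz = oz + (np.random.random() * 2 - 1) * dmax
                nx -= L * math.floor(nx / L)
                ny -= L * math.floor(ny / L)
                nz -= L * math.floor(nz / L)
                shift_x, shift_y, shift_z = nx - ox, ny - oy, nz - oz
                for b in range(n_b):
                    new_beads[b, 0] = beads[i, b, 0] + shift_x
                    new_beads[b, 1] = beads[i, b, 1] + shift_y
                    new_beads[b, 2] = beads[i, b, 2] + shift_z
                old = beads[i].copy()
                ocx, ocy, ocz = com[i, 0], com[i, 1], com[i, 2]
                beads[i] = new_beads
                com[i, 0], com[i, 1], com[i, 2] = nx, ny, nz
                e_new = _mol_energy(i, beads, com, L, tab, tab_r0, tab_dr,
                                    r_cut, sig2, screen2)
                de = e_new - e_old
                if de <= 0.0 or np.random.random() < math.exp(-de):
                    acc_t += 1
                    e_run += de
                else:
                    beads[i] = old
                    com[i, 0], com[i, 1], com[i, 2] = ocx, ocy, ocz
            else:
                try_r += 1
                _random_rotation_quat(rotmax, dq)
                _quat_mult(dq, quat[i], qnew)
                qn = math.sqrt(qnew[0] ** 2 + qnew[1] ** 2 + qnew[2] ** 2
                               + qnew[3] ** 2)
                for k in range(4):
                    qnew[k] /= qn
                _rotate_body(qnew, body, com[i, 0], com[i, 1], com[i, 2],
                             new_beads)
                old = beads[i].copy()
                qold = quat[i].copy()
                beads[i] = new_beads
                quat[i] = qnew
                e_new = _mol_energy(i, beads, com, L, tab, tab_r0, tab_dr,
                                    r_cut, sig2, screen2)
                de = e_new - e_old
                if de <= 0.0 or np.random.random() < math.exp(-de):
                    acc_r += 1
                    e_run += de
                else:
                    beads[i] = old
                    quat[i] = qold
        # step-size tuning during burn-in only, then frozen
        if sweep < burn_in and sweep % 50 == 49:
            if try_t > 0:
                frac = acc_t / try_t
                dmax = min(max(dmax * (0.5 + frac / 0.8), 0.01 * dmax0),
                           L / 4.0)
            if try_r > 0:
                frac = acc_r / try_r
                rotmax = min(max(rotmax * (0.5 + frac / 0.8), 0.001), math.pi)
            acc_t = try_t = acc_r = try_r = 0
        if sweep % 1000 == 999:
            e_full = _total_energy(beads, com, L, tab, tab_r0, tab_dr,
                                   r_cut, sig2, screen2)
            drift = abs(e_full - e_run) / max(abs(e_full), 1.0)
            if drift > max_drift:
                max_drift = drift
            e_run = e_full
        if sweep >= burn_in and (sweep - burn_in) % save_every == 0 \
                and k_save < n_save:
            saved_com[k_save] = com
            saved_quat[k_save] = quat
            energies[k_save] = e_run
            k_save += 1
    acc_frac_t = acc_t / try_t if try_t else 0.0
    acc_frac_r = acc_r / try_r if try_r else 0.0
    return (saved_com[:k_save], saved_quat[:k_save], energies[:k_save],
            acc_frac_t, acc_frac_r, max_drift, dmax, rotmax)


@njit(cache=True)
def _grow_configuration(n_mol, body, L, sig2, seed, max_tries):
    """Random sequential insertion of non-overlapping rigid molecules."""
    np.random.seed(seed)
    n_b = body.shape[0]
    com = np.empty((n_mol, 3))
    quat = np.empty((n_mol, 4))
    beads = np.empty((n_mol, n_b, 3))
    new_beads = np.empty((n_b, 3))
    q = np.empty(4)
    placed = 0
    tries = 0
    while placed < n_mol:
        tries += 1
        if tries > max_tries:
            return com, quat, beads, placed
        cx = np.random.random() * L
        cy = np.random.random() * L
        cz = np.random.random() * L
        _random_rotation_quat(math.pi, q)
        qn = math.sqrt(q[0] ** 2 + q[1] ** 2 + q[2] ** 2 + q[3] ** 2)
        for k in range(4):
            q[k] /= qn
        _rotate_body(q, body, cx, cy, cz, new_beads)
        ok = True
        for j in range(placed):
            for a in range(n_b):
                for b in range(n_b):
                    dx = _min_image(new_beads[a, 0] - beads[j, b, 0], L)
                    dy = _min_image(new_beads[a, 1] - beads[j, b, 1], L)
                    dz = _min_image(new_beads[a, 2] - beads[j, b, 2], L)
                    if dx * dx + dy * dy + dz * dz < sig2:
                        ok = False
                        break
                if not ok:
                    break
            if not ok:
                break
        if ok:
            com[placed, 0], com[placed, 1], com[placed, 2] = cx, cy, cz
            quat[placed] = q
            beads[placed] = new_beads
            placed += 1
    return com, quat, beads, placed


@dataclass
class Configuration:
    """One periodic-box state: positions wrapped into [0, L), unit
    quaternions, no inter-molecular bead overlap."""

    box_length: float
    molecule_positions: np.ndarray
    molecule_orientations: np.ndarray
    rng_seed: int = 0


@dataclass
class Trajectory:
    """Saved production frames of an MC run."""

    model: BeadModel
    box_length: float
    com: np.ndarray           # (n_frames, N, 3)
    quaternions: np.ndarray   # (n_frames, N, 4)
    energies: np.ndarray
    acceptance_translation: float
    acceptance_rotation: float
    energy_drift: float
    kappa: float
    bjerrum: float
    seed: int
    burn_in: int = 0

    @property
    def n_frames(self) -> int:
        return len(self.com)

    @property
    def n_molecules(self) -> int:
        return self.com.shape[1]

    def bead_positions(self, frame: int) -> np.ndarray:
        """(N, n_beads, 3) world-frame bead centers of one frame."""
        out = np.empty((self.n_molecules, self.model.n_beads, 3))
        body = self.model.bead_centers
        for i in range(self.n_molecules):
            _rotate_body(self.quaternions[frame, i], body,
                         self.com[frame, i, 0], self.com[frame, i, 1],
                         self.com[frame, i, 2], out[i])
        return out


@dataclass
class SqEstimate:
    """Spherically averaged structure factor on the lattice q-grid 2 pi/L * n
    with block-averaged standard errors."""

    q_grid: np.ndarray
    s_values: np.ndarray
    standard_errors: np.ndarray
    estimator_tag: str


def run_mc(model: BeadModel, *, n_molecules: int, box_length: float,
           sweeps: int, seed: int, kappa: float, bjerrum: float,
           burn_in: Optional[int] = None, save_every: int = 50,
           r_cut: Optional[float] = None) -> Trajectory:
    """Metropolis sampling of N rigid molecules in a cubic periodic box.

    Per sweep, N single-molecule moves are attempted (translation or
    rotation with equal probability); maximum step sizes are tuned toward
    ~40% acceptance during burn-in and then frozen.  A fixed seed makes the
    trajectory bit-reproducible.  Raises if an overlap-free start cannot be
    grown by random insertion.
    """
    if burn_in is None:
        burn_in = max(sweeps // 5, min(1000, sweeps // 2))
    sig = model.bead_diameter
    if r_cut is None:
        r_cut = box_length / 2.0
    r_cut = min(r_cut, box_length / 2.0)
    tab, tab_r0, tab_dr = _energy_table(model, kappa, bjerrum, r_cut)
    screen = r_cut + 2.0 * model.enclosing_radius
    body = np.ascontiguousarray(model.bead_centers)
    com, quat, beads, placed = _grow_configuration(
        n_molecules, body, box_length, sig * sig, seed,
        max_tries=200 * n_molecules)
    if placed < n_molecules:
        raise RuntimeError(
            f"could not grow an overlap-free start ({placed}/{n_molecules} "
            "molecules placed); volume fraction too high")
    (saved_com, saved_quat, energies, acc_t, acc_r, drift, _, _) = _mc_kernel(
        com, quat, beads, body, box_length, tab, tab_r0, tab_dr, r_cut,
        sig * sig, screen * screen, sweeps, burn_in, save_every, seed,
        0.3 * sig, 0.5)
    return Trajectory(model=model, box_length=box_length, com=saved_com,
                      quaternions=saved_quat, energies=energies,
                      acceptance_translation=acc_t, acceptance_rotation=acc_r,
                      energy_drift=drift, kappa=kappa, bjerrum=bjerrum,
                      seed=seed, burn_in=burn_in)


# ----------------------------------------------------------------------
# structure-factor estimators
# ----------------------------------------------------------------------

def _lattice_shells(nsq_max: int):
    """Integer wavevectors grouped by |n|^2 <= nsq_max (n != 0)."""
    nmax = int(math.isqrt(nsq_max))
    vecs = []
    for nx in range(-nmax, nmax + 1):
        for ny in range(-nmax, nmax + 1):
            for nz in range(-nmax, nmax + 1):
                nsq = nx * nx + ny * ny + nz * nz
                if 0 < nsq <= nsq_max:
                    vecs.append((nsq, nx, ny, nz))
    vecs.sort()
    arr = np.array(vecs, dtype=np.int64)
    shells = np.unique(arr[:, 0])
    return arr, shells


@njit(cache=True)
def _sq_frame(points, vecs, shells, L, out):
    """Accumulate |sum_j exp(i q.r_j)|^2 per shell for one frame."""
    two_pi_over_l = 2.0 * math.pi / L
    n_pts = points.shape[0]
    out[:] = 0.0
    counts = np.zeros(shells.shape[0], dtype=np.int64)
    shell_idx = 0
    for k in range(vecs.shape[0]):
        nsq = vecs[k, 0]
        while shells[shell_idx] != nsq:
            shell_idx += 1
        qx = two_pi_over_l * vecs[k, 1]
        qy = two_pi_over_l * vecs[k, 2]
        qz = two_pi_over_l * vecs[k, 3]
        re = 0.0
        im = 0.0
        for j in range(n_pts):
            phase = (qx * points[j, 0] + qy * points[j, 1]
                     + qz * points[j, 2])
            re += math.cos(phase)
            im += math.sin(phase)
        out[shell_idx] += re * re + im * im
        counts[shell_idx] += 1
    for s in range(shells.shape[0]):
        out[s] /= counts[s]


def _block_stats(per_frame: np.ndarray, n_blocks: int = 10):
    n = len(per_frame)
    n_blocks = max(2, min(n_blocks, n))
    edges = np.linspace(0, n, n_blocks + 1).astype(int)
    means = np.array([per_frame[a:b].mean(axis=0)
                      for a, b in zip(edges[:-1], edges[1:])])
    mean = means.mean(axis=0)
    se = means.std(axis=0, ddof=1) / math.sqrt(n_blocks)
    return mean, np.maximum(se, 1e-12)


def structure_factors(traj: Trajectory, nsq_max: int = 108,
                      n_blocks: int = 10):
    """Center-of-mass and effective structure factors of a trajectory.

    S_cm(q): molecular mass centers as point scatterers, normalized by N.
    S_eff(q): every bead a point scatterer, normalized by N n_b^2 P_Y(q), so
    that uncorrelated molecules give 1.  q is sampled on multiples of
    2 pi/L, spherically averaged over all lattice vectors in each |n|^2
    shell; errors by block averaging over frames.
    """
    if traj.n_frames < 4:
        raise ValueError("trajectory too short after burn-in")
    vecs, shells = _lattice_shells(nsq_max)
    L = traj.box_length
    q = 2.0 * math.pi / L * np.sqrt(shells.astype(float))
    n_mol = traj.n_molecules
    n_b = traj.model.n_beads
    cm_frames = np.empty((traj.n_frames, len(shells)))
    eff_frames = np.empty((traj.n_frames, len(shells)))
    buf = np.empty(len(shells))
    for f in range(traj.n_frames):
        _sq_frame(np.ascontiguousarray(traj.com[f]), vecs, shells, L, buf)
        cm_frames[f] = buf / n_mol
        beads = traj.bead_positions(f).reshape(-1, 3)
        _sq_frame(np.ascontiguousarray(beads), vecs, shells, L, buf)
        eff_frames[f] = buf / (n_mol * n_b * n_b)
    pq = form_factor(traj.model, q)
    cm_mean, cm_se = _block_stats(cm_frames, n_blocks)
    eff_mean, eff_se = _block_stats(eff_frames / pq, n_blocks)
    return (SqEstimate(q, cm_mean, cm_se, "cm"),
            SqEstimate(q, eff_mean, eff_se, "effective"))


def form_factor(model: BeadModel, q):
    """Orientation-averaged point-scatterer form factor (Debye sum):

    P(q) = (1/n^2) sum_ij sinc(q r_ij),   P(0) = 1.
    """
    q = np.atleast_1d(np.asarray(q, dtype=float))
    if np.any(q < 0):
        raise ValueError("q must be >= 0")
    centers = model.bead_centers
    diff = centers[:, None, :] - centers[None, :, :]
    rij = np.sqrt((diff**2).sum(axis=-1))
    x = q[:, None, None] * rij[None, :, :]
    with np.errstate(invalid="ignore"):
        sinc = np.where(x > 1e-12, np.sin(x) / np.where(x > 1e-12, x, 1.0),
                        1.0)
    p = sinc.sum(axis=(1, 2)) / centers.shape[0] ** 2
    return p if p.shape != (1,) else float(p[0])


def _amplitude_moments(model: BeadModel, q: np.ndarray,
                       n_dirs: int = 1024):
    """<|F|> and <|F|^2> over scattering directions (Fibonacci sphere)."""
    i = np.arange(n_dirs)
    ga = math.pi * (3.0 - math.sqrt(5.0))
    z = 1.0 - 2.0 * (i + 0.5) / n_dirs
    rho = np.sqrt(1.0 - z * z)
    dirs = np.stack([rho * np.cos(ga * i), rho * np.sin(ga * i), z], axis=1)
    centers = model.bead_centers
    phases = q[:, None, None] * (dirs @ centers.T)[None, :, :]
    f = np.exp(1j * phases).sum(axis=2) / centers.shape[0]
    return np.abs(f).mean(axis=1), (np.abs(f) ** 2).mean(axis=1)


def decoupling_sq(s_cm: SqEstimate, model: BeadModel) -> SqEstimate:
    """Decoupling approximation S_eff(q) = 1 + beta(q) (S_cm(q) - 1) with
    beta = <|F|>^2/<|F|^2>; exact for spherically symmetric scatterers and
    in the q -> 0 limit, increasingly poor near the structure-factor peak
    for anisotropic molecules."""
    if s_cm.estimator_tag != "cm":
        raise ValueError("decoupling applies to the center-of-mass estimator")
    mean_f, mean_f2 = _amplitude_moments(model, s_cm.q_grid)
    beta = mean_f**2 / mean_f2
    return SqEstimate(s_cm.q_grid, 1.0 + beta * (s_cm.s_values - 1.0),
                      np.abs(beta) * s_cm.standard_errors, "effective")


# ----------------------------------------------------------------------
# two-body potential of mean force (flat-histogram sampling)
# ----------------------------------------------------------------------

@njit(cache=True)
def _pair_config_energy(b1, b2, tab, tab_r0, tab_dr, sig2, r_cut2):
    e = 0.0
    for a in range(b1.shape[0]):
        for b in range(b2.shape[0]):
            dx = b1[a, 0] - b2[b, 0]
            dy = b1[a, 1] - b2[b, 1]
            dz = b1[a, 2] - b2[b, 2]
            e += _pair_v(dx * dx + dy * dy + dz * dz, sig2, tab, tab_r0,
                         tab_dr, r_cut2)
            if e >= _OVERLAP:
                return e
    return e


@njit(cache=True)
def _wl_kernel(body, tab, tab_r0, tab_dr, sig2, r_cut2, r_lo, r_hi, n_bins,
               seed, lnf_init, lnf_final, flatness, max_steps, rotmax):
    np.random.seed(seed)
    n_b = body.shape[0]
    dr_bin = (r_hi - r_lo) / n_bins
    lnw = np.zeros(n_bins)
    hist = np.zeros(n_bins, dtype=np.int64)
    b1 = np.empty((n_b, 3))
    b2 = np.empty((n_b, 3))
    b_trial = np.empty((n_b, 3))
    q1 = np.array([1.0, 0.0, 0.0, 0.0])
    q2 = np.array([1.0, 0.0, 0.0, 0.0])
    qtmp = np.empty(4)
    dq = np.empty(4)
    _rotate_body(q1, body, 0.0, 0.0, 0.0, b1)
    z = 0.5 * (r_lo + r_hi)
    _rotate_body(q2, body, 0.0, 0.0, z, b2)
    e_cur = _pair_config_energy(b1, b2, tab, tab_r0, tab_dr, sig2, r_cut2)
    while e_cur >= _OVERLAP:
        z = r_lo + np.random.random() * (r_hi - r_lo)
        _rotate_body(q2, body, 0.0, 0.0, z, b2)
        e_cur = _pair_config_energy(b1, b2, tab, tab_r0, tab_dr, sig2,
                                    r_cut2)
    lnf = lnf_init
    steps = 0
    dz_max = 0.25 * (r_hi - r_lo)
    while lnf > lnf_final and steps < max_steps:
        steps += 1
        kind = np.random.randint(3)
        bin_old = int((z - r_lo) / dr_bin)
        if bin_old >= n_bins:
            bin_old = n_bins - 1
        if kind == 0:
            # rotate molecule 1 in place
            _random_rotation_quat(rotmax, dq)
            _quat_mult(dq, q1, qtmp)
            qn = math.sqrt(qtmp[0]**2 + qtmp[1]**2 + qtmp[2]**2 + qtmp[3]**2)
            for k in range(4):
                qtmp[k] /= qn
            _rotate_body(qtmp, body, 0.0, 0.0, 0.0, b_trial)
            e_new = _pair_config_energy(b_trial, b2, tab, tab_r0, tab_dr,
                                        sig2, r_cut2)
            de = e_new - e_cur
            if de <= 0.0 or np.random.random() < math.exp(-de):
                q1 = qtmp.copy()
                b1 = b_trial.copy()
                e_cur = e_new
            bin_new = bin_old
        elif kind == 1:
            # rotate molecule 2 about its center of mass
            _random_rotation_quat(rotmax, dq)
            _quat_mult(dq, q2, qtmp)
            qn = math.sqrt(qtmp[0]**2 + qtmp[1]**2 + qtmp[2]**2 + qtmp[3]**2)
            for k in range(4):
                qtmp[k] /= qn
            _rotate_body(qtmp, body, 0.0, 0.0, z, b_trial)
            e_new = _pair_config_energy(b1, b_trial, tab, tab_r0, tab_dr,
                                        sig2, r_cut2)
            de = e_new - e_cur
            if de <= 0.0 or np.random.random() < math.exp(-de):
                q2 = qtmp.copy()
                b2 = b_trial.copy()
                e_cur = e_new
            bin_new = bin_old
        else:
            # translate molecule 2 along z with the flat-histogram bias
            z_new = z + (np.random.random() * 2.0 - 1.0) * dz_max
            if z_new < r_lo or z_new >= r_hi:
                bin_new = bin_old
            else:
                bin_new = int((z_new - r_lo) / dr_bin)
                _rotate_body(q2, body, 0.0, 0.0, z_new, b_trial)
                e_new = _pair_config_energy(b1, b_trial, tab, tab_r0,
                                            tab_dr, sig2, r_cut2)
                arg = -(e_new - e_cur) + lnw[bin_old] - lnw[bin_new]
                if arg >= 0.0 or np.random.random() < math.exp(arg):
                    z = z_new
                    b2 = b_trial.copy()
                    e_cur = e_new
                else:
                    bin_new = bin_old
        bin_cur = int((z - r_lo) / dr_bin)
        if bin_cur >= n_bins:
            bin_cur = n_bins - 1
        lnw[bin_cur] += lnf
        hist[bin_cur] += 1
        if steps % 10000 == 0:
            hmin = hist.min()
            hmean = hist.mean()
            if hmean > 0 and hmin > flatness * hmean:
                lnf *= 0.5
                hist[:] = 0
    flat = hist.min() / max(hist.mean(), 1.0)
    return lnw, lnf, flat, z


@njit(cache=True)
def _wl_production(body, tab, tab_r0, tab_dr, sig2, r_cut2, r_lo, r_hi,
                   n_bins, lnw, z0, n_steps, n_blocks, rotmax):
    """Fixed-weight sampling with the converged WL bias; per-block visit
    histograms for error analysis.  RNG state continues from the WL stage."""
    n_b = body.shape[0]
    dr_bin = (r_hi - r_lo) / n_bins
    hist = np.zeros((n_blocks, n_bins))
    b1 = np.empty((n_b, 3))
    b2 = np.empty((n_b, 3))
    b_trial = np.empty((n_b, 3))
    q1 = np.array([1.0, 0.0, 0.0, 0.0])
    q2 = np.array([1.0, 0.0, 0.0, 0.0])
    qtmp = np.empty(4)
    dq = np.empty(4)
    z = z0
    _rotate_body(q1, body, 0.0, 0.0, 0.0, b1)
    _rotate_body(q2, body, 0.0, 0.0, z, b2)
    e_cur = _pair_config_energy(b1, b2, tab, tab_r0, tab_dr, sig2, r_cut2)
    dz_max = 0.25 * (r_hi - r_lo)
    per_block = n_steps // n_blocks
    for blk in range(n_blocks):
        for _ in range(per_block):
            kind = np.random.randint(3)
            if kind == 0:
                _random_rotation_quat(rotmax, dq)
                _quat_mult(dq, q1, qtmp)
                qn = math.sqrt(qtmp[0]**2 + qtmp[1]**2 + qtmp[2]**2
                               + qtmp[3]**2)
                for k in range(4):
                    qtmp[k] /= qn
                _rotate_body(qtmp, body, 0.0, 0.0, 0.0, b_trial)
                e_new = _pair_config_energy(b_trial, b2, tab, tab_r0,
                                            tab_dr, sig2, r_cut2)
                de = e_new - e_cur
                if de <= 0.0 or np.random.random() < math.exp(-de):
                    q1 = qtmp.copy()
                    b1 = b_trial.copy()
                    e_cur = e_new
            elif kind == 1:
                _random_rotation_quat(rotmax, dq)
                _quat_mult(dq, q2, qtmp)
                qn = math.sqrt(qtmp[0]**2 + qtmp[1]**2 + qtmp[2]**2
                               + qtmp[3]**2)
                for k in range(4):
                    qtmp[k] /= qn
                _rotate_body(qtmp, body, 0.0, 0.0, z, b_trial)
                e_new = _pair_config_energy(b1, b_trial, tab, tab_r0,
                                            tab_dr, sig2, r_cut2)
                de = e_new - e_cur
                if de <= 0.0 or np.random.random() < math.exp(-de):
                    q2 = qtmp.copy()
                    b2 = b_trial.copy()
                    e_cur = e_new
            else:
                z_new = z + (np.random.random() * 2.0 - 1.0) * dz_max
                if r_lo <= z_new < r_hi:
                    bin_old = int((z - r_lo) / dr_bin)
                    bin_new = int((z_new - r_lo) / dr_bin)
                    _rotate_body(q2, body, 0.0, 0.0, z_new, b_trial)
                    e_new = _pair_config_energy(b1, b_trial, tab, tab_r0,
                                                tab_dr, sig2, r_cut2)
                    arg = -(e_new - e_cur) + lnw[bin_old] - lnw[bin_new]
                    if arg >= 0.0 or np.random.random() < math.exp(arg):
                        z = z_new
                        b2 = b_trial.copy()
                        e_cur = e_new
            bin_cur = int((z - r_lo) / dr_bin)
            if bin_cur >= n_bins:
                bin_cur = n_bins - 1
            hist[blk, bin_cur] += 1.0
    return hist


def pmf_two_body(model: BeadModel, kappa: float, bjerrum: float, seed: int,
                 *, n_bins: int = 60, r_lo: Optional[float] = None,
                 r_hi: Optional[float] = None, lnf_final: float = 2e-4,
                 max_steps: int = 30_000_000,
                 production_steps: int = 4_000_000, n_blocks: int = 8):
    """Two-body potential of mean force by Wang-Landau flat-histogram
    sampling of the center-of-mass distance.

    One molecule rotates in place at the origin; the second rotates and
    translates along z between ``r_lo`` and ``r_hi``.  The ln-f schedule
    halves on 80% histogram flatness down to ``lnf_final``; a fixed-weight
    production stage then refines the free-energy profile and provides
    block-analysis errors.  PMF(r) = -(ln w + ln h) anchored to zero at the
    largest sampled distance.

    Returns (r_centers, pmf, standard_errors, flatness); flatness is the
    min/mean visit ratio of the production histogram, below ~0.5 the step
    budget should be raised.
    """
    sig = model.bead_diameter
    d_y = 2.0 * model.enclosing_radius
    if r_lo is None:
        r_lo = max(0.2 * sig, d_y * 0.15)
    if r_hi is None:
        r_hi = 4.0 * d_y
    r_cut = r_hi + d_y + sig
    tab, tab_r0, tab_dr = _energy_table(model, kappa, bjerrum, r_cut)
    body = np.ascontiguousarray(model.bead_centers)
    lnw, lnf, _, z_last = _wl_kernel(
        body, tab, tab_r0, tab_dr, sig * sig, r_cut * r_cut, r_lo, r_hi,
        n_bins, seed, 0.5, lnf_final, 0.8, max_steps, 1.2)
    hist = _wl_production(body, tab, tab_r0, tab_dr, sig * sig,
                          r_cut * r_cut, r_lo, r_hi, n_bins, lnw, z_last,
                          production_steps, n_blocks, 1.2)
    total = hist.sum(axis=0)
    flat = float(total.min() / max(total.mean(), 1.0))
    with np.errstate(divide="ignore"):
        block_pmf = -(lnw[None, :] + np.log(np.maximum(hist, 0.5)))
    block_pmf -= block_pmf[:, -1:]
    pmf = -(lnw + np.log(np.maximum(total, 0.5)))
    pmf -= pmf[-1]
    se = block_pmf.std(axis=0, ddof=1) / math.sqrt(hist.shape[0])
    centers = r_lo + (np.arange(n_bins) + 0.5) * (r_hi - r_lo) / n_bins
    return centers, pmf, se, flat


def orientation_averaged_pmf(model: BeadModel, kappa: float, bjerrum: float,
                             r: float, seed: int,
                             n_samples: int = 200_000) -> float:
    """Brute-force oracle: -ln < exp(-beta V) > over independent random
    orientations of both molecules at fixed COM separation r."""
    rng = np.random.default_rng(seed)
    sig = model.bead_diameter
    r_cut = r + 4.0 * model.enclosing_radius
    tab, tab_r0, tab_dr = _energy_table(model, kappa, bjerrum, r_cut)
    quats = rng.normal(size=(2, n_samples, 4))
    quats /= np.linalg.norm(quats, axis=-1, keepdims=True)
    return float(_pmf_oracle_kernel(
        np.ascontiguousarray(model.bead_centers), tab, tab_r0, tab_dr,
        sig * sig, r_cut * r_cut, r,
        np.ascontiguousarray(quats[0]), np.ascontiguousarray(quats[1])))


@njit(cache=True)
def _pmf_oracle_kernel(body, tab, tab_r0, tab_dr, sig2, r_cut2, r, qa, qb):
    n = qa.shape[0]
    n_b = body.shape[0]
    b1 = np.empty((n_b, 3))
    b2 = np.empty((n_b, 3))
    acc = 0.0
    for k in range(n):
        _rotate_body(qa[k], body, 0.0, 0.0, 0.0, b1)
        _rotate_body(qb[k], body, 0.0, 0.0, r, b2)
        e = _pair_config_energy(b1, b2, tab, tab_r0, tab_dr, sig2, r_cut2)
        if e < 300.0:
            acc += math.exp(-e)
    return -math.log(acc / n)
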