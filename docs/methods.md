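# Methods

This note documents the models, parameter choices, numerical methods and
known limitations of `colloidab`. Units are nm, k_BT and nm⁻³ unless stated
otherwise.

## Solution model and pair potential

An antibody solution is treated as a one-component colloid fluid in a
continuum solvent with implicit monovalent microions. The effective pair
potential is a hard core of diameter σ_hs plus a DLVO screened-Coulomb
(Yukawa) repulsion and a steep power-law attraction:

    βV(r) = Z_eff² L_B e^{κσ_hs} e^{−κr} / [(1+κσ_hs/2)² r]
            − ε_a (σ_hs/r)^α ,    r ≥ σ_hs.

The screened-Coulomb prefactor is the standard expression for a charge
Z_eff distributed on the surface of a sphere of radius σ_hs/2 in
Debye–Hückel theory. Hard-core overlap is represented by a finite sentinel
energy (1e4 k_BT) chosen so that exp(−V) underflows to exactly 0.0, keeping
array arithmetic total while making overlapping configurations strictly
forbidden in every Boltzmann factor.

The screening parameter is concentration dependent:

    κ² = 4π L_B (|Z_eff| ρ + 2ρ_s + 2ρ_b) / (1 − φ).

Each protein contributes |Z_eff| monovalent counterions; added salt and
dissociated buffer contribute both ion signs (2ρ); 1/(1−φ) confines the
microions to the free volume outside the proteins. Finite microion size,
charge regulation and explicit Donnan equilibration are not modelled — the
free-volume form is the deliberate stand-in for the ultrafiltration-induced
ion redistribution in concentrated stocks.

Key defaults and their origin:

| parameter | default | unit | rationale |
|---|---|---|---|
| σ_hs | 10 | nm | 2R_g of an IgG-class antibody |
| Z_eff | 20 | e | structure-factor-level effective charge of the studied mAb |
| ε_a | 3.5 | k_BT | contact depth reproducing high-salt compressibility data |
| α | 90 | – | steep attraction; 1/e range ≈ σ/α ≈ 1.1% of σ |
| M_w | 148 000 | g/mol | IgG molecular weight |
| T, ε_r, η | 298.15 K, 78.4, 0.8904 mPa·s | | water at 25 °C |
| buffer / added salt | 7 / 50 | mM | the two studied ionic strengths |

### Second virial coefficient

B2 = 2π∫₀^∞ (1−e^{−βV}) r² dr with the hard-core part analytic
(B2_hs = 2πσ³/3) and the tail by adaptive quadrature (absolute tolerance
1e-8·B2_hs) with break points at σ+σ/α, σ+5σ/α, σ+25σ/α bracketing the
narrow well. A dense-trapezoid oracle in the test suite confirms 1e-4
relative agreement. The Baxter stickiness follows from
B2* = 1 − 1/(4τ_b); B2* ≥ 1 maps to τ_b = ∞ (no net stickiness).

**Sensitivity note.** The α = 90 attraction is extremely short ranged
(1/e range ≈ 1.1% of σ, falling below 0.1 k_BT beyond ≈ 4%). The B2*
chain at 57 mM evaluates here to 1.26 (3 mg/mL), 0.97 (169 mg/mL) and
0.92 (200 mg/mL). Values near 0.87/0.32/0.22 quoted elsewhere for the same
nominal parameter set are only reachable if the attractive well is ~4×
wider (α ≈ 25, i.e. a true 4% range) or ~1.8 k_BT deeper at the same
width; the concentration *trend* is identical in all cases because it is
carried entirely by the screening of the repulsion. The package reports
the faithful α = 90 computation and exposes α so either convention can be
evaluated.

## Ornstein–Zernike solver

Standard one-component OZ machinery: uniform r-grid (default n = 4096,
r_max = 40σ), radial Fourier transforms by type-I discrete sine transform,
Picard iteration with fixed mixing (default 0.5, automatically damped if an
iterate makes 1−ρĉ(q) non-positive), convergence at max|Δc| < 1e-9. The
grid spacing is adjusted so the hard-core boundary falls halfway between
grid points, which makes S(0) second-order accurate in dr (doubling n
changes S(0) by < 0.05%).

Closures: PY g = e^{−βV}(1+γ); HNC g = e^{−βV}e^γ; Rogers–Young
g = e^{−βV}[1 + (e^{f γ}−1)/f] with f(r) = 1−e^{−ξr}, which reduces to PY
as ξ→0 and to HNC as ξ→∞. The RY mixing parameter is bracketed on
ξσ ∈ [0.05, 15] and bisected until the virial route d(βP_v)/dρ (central
finite difference of the virial pressure, with the hard-core delta entering
through the contact value g(σ⁺) obtained by quadratic extrapolation)
matches the compressibility route 1/S(0). At very low density the two
routes coincide for every ξ and the bracket degenerates; the solver then
returns the closest-to-consistent solution, which is also the correct
limit. S(0) is always reported through the compressibility integral
1 + 4πρ∫(g−1)r²dr; no analytic tail correction is applied because every
supported condition has κ r_max ≫ 1.

Validation: hard-sphere S(0) agrees with the Carnahan–Starling closed form
(1−φ)⁴/[(1+2φ)²+φ³(φ−4)] within 2% up to φ = 0.3 (RY), the dilute limit
reproduces g = e^{−βV}, and RY/HNC S(q) agree with a single-bead Monte
Carlo simulation of the same potential at φ = 0.02 within 3 standard
errors.

## 9-bead Y model and Monte Carlo

Geometry: planar construction with a central equilateral tangent triangle
(circumradius σ/√3, leg vertex on −y), a leg of two appended tangent beads
along −y, and two arms of two tangent beads along the 60° and 120°
directions — arm axes at 60° to each other and 150° to the leg. The
construction is pinned by two invariants asserted at build time: radius of
gyration 1.72975 σ_bead and tangent-circle diameter 6.1547 σ_bead. The
bead diameter matching a measured R_g = 5.0 nm is 2.89 nm. Each bead
carries Z_eff/9 and the bead-level potential has the same functional form
as the molecular one (bead-scale σ, depth ε_a,bead = 0.5 k_BT, α = 90);
uniform charge and attraction per bead are deliberate simplifications
appropriate for a mAb with a homogeneous surface-charge distribution.

Sampling: single-molecule Metropolis moves (translation or quaternion
rotation with equal probability, N attempts per sweep), rigid molecules,
cubic periodic box with minimum image per bead pair, box edge from
V = N_p M_w/(c N_A 10⁻²⁷) Å³. Bead-pair energies come from a 32768-point
linear interpolation table on [σ_bead, r_cut] (r_cut ≤ L/2, chosen where
the Yukawa tail is ≲ 1e-4 k_BT; no shifting — Metropolis only needs energy
differences, and a full energy recomputation every 10³ sweeps asserts
≤ 1e-8 relative bookkeeping drift). A molecule-level prescreen skips pairs
whose centers are beyond r_cut + 2×(enclosing radius). Step sizes are
tuned toward ~40% acceptance during burn-in, then frozen; a fixed seed
gives bit-reproducible trajectories (single-threaded kernels, numba).
Initial configurations are grown by random insertion with rejection.

Structure factors are accumulated on the lattice wavevectors q = 2π n/L,
averaged over all integer vectors within each |n|² shell (not isotropic
shells), with block averaging over frames for standard errors. S_cm uses
molecular centers; S_eff uses every bead, normalised by N n_b² P_Y(q) so
uncorrelated molecules give 1. P_Y(q) is the exact Debye sum; the
decoupling approximation uses β(q) = ⟨|F|⟩²/⟨|F|²⟩ computed by a
1024-point Fibonacci-sphere orientation average.

Two-body PMF: one molecule rotates in place, the other rotates and
translates along z within [r_lo, 4 d_Y]. A Wang–Landau bias on the
center-distance bin (ln f from 0.5, halved on 80% flatness, down to 2e-4)
is followed by a fixed-weight production stage whose per-block histograms
give the statistical errors; PMF = −(ln w + ln h), anchored to zero at the
largest distance. Note the PMF of even the hard-core-only model is
positive at short distance (orientational exclusion), so the profile is a
free energy, not a pair energy. Validation against a brute-force
orientation average of −ln⟨e^{−βV}⟩ agrees within 0.03 k_BT at desk scale;
the acceptance tolerance is 0.1 k_BT. The oracle must be evaluated at the
bin centers — the profile is steep near contact and a half-bin offset is
visible.

Desk-scale defaults used in the shipped tests: 64–108 molecules,
6×10³–2.4×10⁴ sweeps, 30 nm bead-level cutoff at 7 mM. These are the
package's working sizes for laptop-class runs; production studies would
scale N_p and sweeps up by an order of magnitude through the same API.

## Hydrodynamics

DLS measures D_c = D_0 H(0)/S(0). H(0) is computed in the
pairwise-additive far-field approximation: the angle-averaged
Rotne–Prager pair mobility contributes a/r per neighbour (its r⁻³
source-dipole terms vanish in the trace) and the divergent backflow is
renormalised Batchelor-style, leaving

    H(0) = 1 + 4πρ (σ_hs/2) ∫₀^∞ r (g(r)−1) dr.

For hard spheres this yields the dilute slope −6φ, within 5% of
Batchelor's exact −6.55φ at φ = 0.02; the approximation is only trusted
for φ ≤ 0.05 and a warning is attached beyond that. The phenomenological
alternative H_hs(0) = (1+1.45φ)·S_hs^CS(0) (virial coefficient k_D = 1.45)
has the exact −6.55 slope and is used for hard-sphere baselines. The
apparent-radius ratio is R_h,app/R_h,0 = S(0)/H(0) and the experimental
inversion H_exp(0) = S_exp(0)/(R_h,app/R_h,0).

## Rheology

Quemada: η_r = (1−φ/φ_max)⁻², φ_max = 0.58. The sticky-sphere correction
kernel is η_r = η_r^hs·[1 + 1.9 φ²/(τ_b (1−φ/φ_max))]; the coefficient is
exposed in `STICKY_COEFF`. The kernel was chosen to satisfy the hard
limits that define the contract — it vanishes as τ_b→∞ and as φ→0, and is
strictly decreasing in τ_b — rather than any particular closed form from
the sticky-sphere literature, and only those limits are tested. Cluster
mapping: φ_cluster = φ⟨s⟩_n^{3/d_F−1} with d_F default 2.2; inversion of a
measured η_r solves the Quemada curve in closed form. Cluster apparent
S(0) = ⟨s⟩_w·S_eff(0) of an effective suspension of spheres with radius
R_1⟨s⟩_n^{1/d_F}, additive charge Z_1⟨s⟩_n (which overestimates charge
effects for large clusters — charges inside a fractal cluster are partly
screened internally) and density ρ/⟨s⟩_n; the screening κ is kept at its
monomer value since the counterion content is unchanged by clustering.
Cluster polydispersity defaults to ⟨s⟩_w/⟨s⟩_n = 2 (exponential-like size
distribution), exposed in `ClusterParams`.

## Data reduction

* Cumulant fits: g2(t) = B + β e^{−2Γt + μ₂t²}, trust-region least squares
  on a log-spaced lag grid, Γ initialised from the half-decay lag; order 1
  pins μ₂ = 0. A 50-replicate simulation at 1% noise shows < 1% bias in Γ.
* Apparent M_w: excess Rayleigh ratio from sample/toluene/solvent
  intensities with K = 4π²n_sol²(dn/dc)²/(N_A λ⁴); the toluene Rayleigh
  ratio is an instrument constant that must be supplied (default 1.35e-5
  cm⁻¹); all synthetic-data tests are constructed so it cancels.
* SAXS: S(q) = [I(q)/c]/[I₀(q)/c₀] with the 1 mg/mL convention for the
  form curve; non-positive form points are NaN-masked.
* Electrophoresis: Z_eff = μ_e·6πηR_h·(1+κa_ζ)/(e·f_SF(κa_ζ)), where f_SF
  is the Swan–Furst closed-form Henry function (2/3 → 1 convention; the
  package's `henry_function` exposes the classic 1 → 3/2 convention,
  f_SF = (2/3)·f_Henry). The (1+κa_ζ) factor is the Debye–Hückel relation
  between the surface potential and the charge; a_ζ = R_hs + 0.18 nm adds
  the counterion radius (Stern layer). With R_h = 5.4 nm this maps the
  measured mobilities 0.6427e-4 / 0.3539e-4 cm²/(V s) at 7 / 57 mM to
  Z ≈ 12.6 / 13.5.
* χ²: per-point mean square difference on the measured q-grid (simulated
  table interpolated), optional inverse-variance weights. The identifiability
  experiment in the acceptance suite reproduces the expected structure: at
  low c and low ionic strength the grid is sharp in Z_eff and flat in ε_a.

## Synthetic data

Every generator is the measurable forward image of exactly one reduction
operation, and generator∘reduction is asserted to be the identity at zero
noise. Noise defaults to 2% (multiplicative Gaussian on intensities,
additive on g2) emulating a well-behaved bench instrument; all randomness
flows from one `numpy` Generator seeded per call. The generators do **not**
emulate multiple scattering, beam smearing, detector artifacts, solvent
mismatch or aggregation kinetics — passing round-trip tests therefore
demonstrates the internal consistency of the analysis chain, not robustness
to real-instrument systematics.

## Known limitations

* The pairwise-additive H(0) ignores many-body hydrodynamics and is
  unreliable above φ ≈ 0.05; no arrest-line prediction is attempted.
* The OZ solver is single-component with PY/HNC/RY only; φ is capped at
  0.55.
* The 9-bead model has uniform bead charge/attraction and no internal
  flexibility; anisotropic charge patches are out of scope.
* The sticky-viscosity kernel coefficient (1.9) is a documented default,
  not a fitted constant; only its limiting behaviour is contractual.
* The B2* sensitivity to the attraction-range convention documented above
  means absolute B2* values should be quoted together with (ε_a, α).
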