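# Methods

`excitonuv` models the near-UV spectroscopy of aromatic side chains
(tyrosine, phenylalanine) and backbone amides in peptides with a vibronic
Frenkel-exciton Hamiltonian, and computes three observables: circular
dichroism (CD) via rotational strengths, linear absorption, and
quasi-absorptive two-dimensional electronic spectra at waiting time
t2 = 0. This note records the model, its assumptions, the numerical
conventions, and what the synthetic test systems do and do not probe.

## Vibronic structure

Each electronic transition couples to a small set of displaced harmonic
intramolecular modes. For mode i with frequency omega_i and
reorganization energy lambda_i (both cm^-1), the Huang-Rhys factor is
S_i = lambda_i / omega_i, and the 0->n Franck-Condon (FC) amplitude at
zero initial temperature is sqrt(e^-S S^n / n!). A multimode vibronic
level carries the product of per-mode amplitudes and an energy offset
sum_i n_i omega_i above the 0-0 line; electric and magnetic transition
dipoles and monopole charges are scaled by the FC amplitude. Manifolds
are truncated at a configurable energy cutoff (default 3200 cm^-1 above
the origin, which for the tyrosine L_b pair of modes at 800 ("u",
lambda ~990) and 1250 cm^-1 ("v") retains nine levels and >= 95% of the
FC weight). Energies are strictly additive (harmonic): anharmonic shifts
of combination bands, which can displace e.g. the u1+v1 line by a few
hundred cm^-1 in condensed-phase assignments, are neglected; so are
Duschinsky rotation and hot bands.

The v-mode reorganization energy of tyrosine is not an established
number; the parameter files ship S_v = 0.3 with an explicit provenance
flag, and users can override it. Phenylalanine L_b uses two modes,
570/300 and 980/660 cm^-1 (frequency/lambda), totalling 960 cm^-1.

## Geometry

Cyclic dipeptides cyclo(Pro-Tyr) and cyclo(Tyr-Tyr) are built from fixed
internal coordinates: a diketopiperazine six-ring closed by deterministic
least squares (fixed initial guess) in a boat pucker that displaces the
two carbonyl carbons 0.55 A to the same side of the N-CA-N-CA base
plane, L-configured side chains, and user-specified chi1 (N-CA-CB-CG).
The chi2 default is 120 deg: with this idealized C-boat ring, chi2 = 120
reproduces the characteristic inter-Tyr L_b transition-dipole-angle
pattern of the conformer family (near-parallel, ~7 deg, for
cYY_60_60; 50-80 deg for cYY_300_60 and cYY_300_300), which a 90 deg
default does not. The builder is a model geometry, not an energy
minimum; angle-level agreement (tens of degrees) is the design target,
not bit-exact coordinates.

Aromatic transition frames: origin at the ring centroid, x towards CZ
(the OH-bearing para carbon in Tyr) projected into the best-fit ring
plane, z the ring normal with sign fixed by the atom circulation
(CD1 before CD2), y completing a right-handed set. The L_b electric TDM
defaults to in-plane perpendicular to x, L_a parallel to x; these
orientations are data in the parameter files, not code.

## Couplings and units

Inter-site couplings use transition monopoles when both transitions
carry them, V = K sum q_i q_j / r_ij with K = 116,140 cm^-1 A
(= e^2/(4 pi eps0 A) in wavenumbers), else the point-dipole formula with
prefactor 5034 cm^-1 A^3 D^-2 (= K x 0.2081943^2, 1 D = 0.2081943 e A).
Off-diagonal vibronic elements are V_electronic x fc_a x fc_b; vibronic
levels of one site are mutually uncoupled (displaced-oscillator model).
Coupling classes (Tyr-Tyr, Phe-Phe, Tyr-Phe, aromatic-backbone) can be
zeroed to realise the Forster-limit strategy in which weakly coupled
sites are treated as independent emitters. Eigenvector signs are fixed
(largest coefficient positive) so downstream spectra are reproducible.

## Circular dichroism

Rotational strength of exciton k (1e-40 cgs):

    R_k = Im(mu_k . m_k)
        - (pi nu_k / 2) 1e-4 sum_ij c_ki c_kj (R_i - R_j).(mu_i x mu_j)

with mu in Debye, intrinsic magnetic moments m in Bohr magnetons
(1 D uB = 92.740e-40 cgs), positions in A, nu in cm^-1. The
double-difference origin term is exactly translation-invariant; a
positive R_k means electric and magnetic moments subtend < 90 deg. For a
coupled electric-only pair the two exciton lines form a couplet,
R+ ~ -R-; the sum rule holds to O(2V/nu) because each line carries its
own frequency factor. Line spectra are convolved with a Gaussian on the
wavelength axis (default FWHM 4.0 nm, grid 250-320 nm, 0.1 nm step);
intensities are in arbitrary units proportional to Delta-epsilon (no
absolute calibration is attempted).

## Lineshapes

Site baths are a Drude-Lorentz density J(w) = 2 lambda w L / (w^2 + L^2)
(defaults lambda = 300, L = 85 cm^-1, T = 300 K) plus the discrete
modes, with the standard convention that a mode's total reorganization
energy is lambda_i and S_i = lambda_i / omega_i. The lineshape function
uses the analytic overdamped form with Matsubara summation (terminated
at < 1e-8 relative change) plus, per discrete mode,
S[coth(w/2kT)(1 - cos wt) + i(sin wt - wt)]. Sign convention: Im g has
long-time slope -lambda_total t, so a site's "vertical" energy is its
0-0 energy plus the discrete-mode reorganization; the code performs that
bookkeeping so parameter files can state 0-0 lines. At T -> 0 a single
mode yields a Poisson progression to 1e-3, which is unit-tested.

## Third-order response at t2 = 0

Pathways (GSB, SE, ESA; rephasing and non-rephasing) are dressed with
second-cumulant lineshape factors derived by contour-pair accumulation:
every pair of excited-state segments on the ket/bra branches contributes
a four-term combination of cross-lineshapes g_ab, where
g_ab(t) = sum_n |c_n^a|^2 |c_n^b|^2 g_n(t) for uncorrelated site baths
(for a two-exciton state f the weights are the site indicators). The
resulting t2 = 0 factors are listed in `excitonuv/response.py`; two
internal consistency checks pin them down: the static limit of the
rephasing factor is the photon echo, and all cross pathways of uncoupled
chromophores cancel exactly, making the response additive over connected
components of the coupling graph (the implementation computes each
component separately, which also realises the Forster mode without any
special casing). Two-exciton states are site-pair products with additive
energies and no double excitation of one site; transport between
excitons is neglected throughout, so within the cumulant treatment the
lineshapes are exact.

Numerical conventions: time grids default to 2048 points x 2 fs
(Nyquist window ~8300 cm^-1); phases are carried in a rotating frame at
the mean one-exciton energy; a cosine tail over the last 10% of each
time axis plus half-weighted t = 0 endpoints control truncation ripple;
half-Fourier transforms over t1 and t3 use zero-padding x2. The
quasi-absorptive map is the real part of the rephasing + non-rephasing
sum, with the rephasing omega_1 axis sign-flipped so peaks appear at
positive frequencies. Maps are divided by the number of Tyr sites.
The narrowband strategy restricts the FC-expanded basis to a window
around one vibronic line (e.g. the L_b 0-0 at 34,965 cm^-1) and then
carries only the solvent bath, emulating spectrally tuned pulses; the
full-window (Forster) strategy instead keeps one electronic state per
site and carries the vibronic progression in the spectral density.
Excited-state absorption for isolated single-site components does not
arise (no doubly excitable site states are parameterized in the near-UV
window). The 9.8%/0.30% polarization-combination contrasts quoted in the
README use 512 x 512 grids at 2 fs; ratios change by < 0.1% (relative)
against 2048-point grids.

Orientational averaging uses the isotropic fourth-rank formula
<(e1.d1)(e2.d2)(e3.d3)(e4.d4)> = [L_A(4A-B-C) + L_B(4B-A-C) +
L_C(4C-A-B)]/30 with A,B,C the molecular and L_A,L_B,L_C the lab cosine
pair products; polarization combinations (xxxx - 3xxyy, xyxy - xyyx) are
applied pathway-wise, which is equivalent to (and cheaper than)
combining finished maps.

## Static disorder and fluctuation emulation

Site energies are drawn per realization from a Gaussian centred on the
nominal energy; a site's whole vibronic manifold shifts rigidly. The
width parameter "sigma = 100 cm^-1" is interpreted as a standard
deviation (it carries cm^-1 units); a `variance_literal` switch allows
the literal reading. An exciton is classed by the root-sum-square site
coefficient: strong mixing for max coefficient in [0.707, 0.90], weak in
(0.90, 0.999), localized >= 0.999; a realization counts as
strong-mixing if any of its excitons does. For the 2 x 2 case this gives
the closed form P(strong) = 2 Phi(1.580 V / (sigma sqrt(2))) - 1, used
as the Monte-Carlo oracle in the tests (V = 7, sigma = 100 gives 6.2%).

Molecular-dynamics-driven electrostatic fluctuations are emulated, not
computed: a seeded Gaussian-mixture generator produces per-snapshot site
shifts with a configurable rare-outlier channel (multi-eV shifts), and a
state filter removes basis states beyond a threshold deviation and/or
whole residue classes — reproducing the shape of such pipelines without
any quantum-chemistry or MD dependency. Snapshot selection ranks CD
spectra by RMSD to a reference and keeps the k best (stable tie-break by
index). Everything is reproducible from the seed.

## What the synthetic systems do and do not show

The generated fixtures (idealized dipeptide conformers, a toy
4-Tyr/4-Phe chain with randomly oriented rings, two-point monopole sets
that reproduce a dipole) exercise the full code path — geometry in,
spectra out — with realistic energy scales, couplings of a few cm^-1 and
disorder of ~100 cm^-1. They do not contain real protein electrostatics,
force-field geometry, ab initio transition densities, or experimental
reference spectra; passing tests therefore validate the spectroscopic
machinery and its invariants (unit FC weight, origin/rotation invariance
and mirror antisymmetry of CD, exact single-chromophore cancellation of
the crossed polarization combination, dipole-strength conservation,
additivity over uncoupled sites, Monte-Carlo vs analytic mixing
statistics), not agreement with any particular measured spectrum.

## Known limitations

- t2 > 0 dynamics, exciton transport and finite pulse envelopes are out
  of scope (the narrowband window is the surrogate for pulse shaping).
- The vibronic dimer is treated perturbatively in V through the exciton
  transformation of the lineshapes; neither full vibronic-dimer
  Hamiltonians nor inter-exciton spectral densities are implemented.
- The degenerate-dimer crossed-polarization contrast at fixed dipole
  angle is nearly independent of the coupling strength in this
  treatment; published tabulations that differ between couplings at the
  same angle encode geometry beyond the two inputs and are matched only
  at loose tolerance.
- Absolute CD intensities are uncalibrated; comparisons are shape-level.
- The dipeptide builder trades force-field realism for determinism.
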