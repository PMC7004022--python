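# Methods

This note documents the models, conventions and numerical choices behind
`aquakrig`, and what the synthetic labelling oracle does and does not
emulate.

## The surrogate labelling oracle

Production force fields of this family are trained on per-atom labels from
an electronic-structure calculation followed by a topological atomic-basin
partition. `aquakrig` replaces that step with an analytic stand-in so that
the full pipeline is runnable and testable on one CPU.

**Molecular PES.** A Morse/harmonic surface in the internal coordinates
`(r1, r2, theta)`:

    E = M(r1) + M(r2) + (k_bend/2)(theta - theta0)^2
        + k_rr dr1 dr2 + k_rth (dr1 + dr2)(theta - theta0),
    M(r) = D (1 - exp(-a (r - r0)))^2,

minimised (value 0, gradient 0) at the gas-phase monomer geometry
r0 = 0.9619 A, theta0 = 105.05 deg. Defaults (chosen once for realistic
water vibrations, then left alone):

| parameter | value | unit | rationale |
|---|---|---|---|
| D (Morse depth) | 500 | kJ/mol | ~O-H bond dissociation energy |
| a (Morse width) | 2.2 | 1/A | stretch frequency ~3700-3800 cm^-1 |
| k_bend | 420 | kJ/mol/rad^2 | bend frequency ~1600 cm^-1 |
| k_rr | -40 | kJ/mol/A^2 | small stretch-stretch coupling; puts the asymmetric stretch above the symmetric one |
| k_rth | 100 | kJ/mol/(A rad) | small stretch-bend coupling |

The finite-difference normal-mode analysis of this surface gives
1647 / 3742 / 3838 cm^-1 (bend < symmetric < asymmetric), the physically
correct ordering for water.

**Atomic partition.** O receives the bend term, half of each Morse term and
half of the couplings; each H receives half of its own Morse term and a
quarter of the couplings. The shares are smooth, sum *exactly* to the
molecular energy, and are H-exchange symmetric. Any smooth partition with
these properties exercises the learning machinery equally well; no claim is
made that this is the partition an atomic-basin integration would produce.

**Atomic multipoles.** Local-frame moments (ranks 0-2) are smooth low-order
polynomials of the internal coordinates with H charges near +0.55 e and
O near -1.1 e. Components odd in the out-of-plane axis vanish by the
monomer's planar mirror symmetry; components built from `(dr1 - dr2)` are
odd under H exchange, matching the sign flip of the in-plane y axis of the
O frame. The noiseless O charge is strictly monotone along a single-bond
stretch. Independent zero-mean Gaussian noise (sigma = 2.95e-4 e per atom)
is added to the three charges, so the net molecular charge equals the sum of
three draws exactly; 2.95e-4 e makes ~5% of configurations trip the
0.001 e net-charge filter. Dipole/quadrupole components receive 2e-4 e A^l
noise. Energies carry no noise, so energy-model errors are pure
interpolation error.

**Integration errors.** L(Omega) is drawn per atom from a lognormal with
median 1e-5 Ha and log-width 0.783, giving ~2% of atoms above the
5e-5 Ha threshold and ~0.2% above 1e-4 Ha — a heavy-tailed, strictly
positive error figure for exercising the quality filter at both standard
thresholds.

**What the surrogate does not emulate.** Electronic structure (no charge
transfer between molecules, no intermolecular effect on monomer labels), the
geometry of atomic basins, correlated label noise, and any coupling between
L(Omega) and geometry. Consequently, passing tests demonstrate that the
machinery (sampling, filtering, regression, electrostatics, dynamics) is
correct and well-conditioned at realistic magnitudes — not that the
resulting water model is chemically accurate.

## Ensemble generation

Normal modes come from a central-difference Cartesian Hessian (step 1e-4 A),
mass-weighted with O = 15.999 u, H = 1.008 u, with the six rigid-body
directions projected out. Each mode coordinate is drawn uniformly over the
largest interval that alone respects the 20% distortion constraint (found by
bisection), and joint draws are rejection-sampled against the full
constraint — uniform-in-constraint coverage of the allowed box, since no
sampling temperature is prescribed. `max_distortion = 0` is a degenerate
but valid request (copies of the seed); negative values are errors.

## Kriging

The kernel is `exp(-sum_h theta_h |df_h|^p_h)` over the three internal
coordinates (angle in radians). The concentrated log-likelihood profiles
out the trend mean and process variance analytically:

    mu = (1' R^-1 y)/(1' R^-1 1),  sigma^2 = (y-mu)' R^-1 (y-mu)/N,
    CLL = -(N/2) ln sigma^2 - (1/2) ln det R,

computed via Cholesky. Constant targets give sigma^2 = 0; the CLL is then
capped at +1e10 (a perfect trend-only fit) rather than returning infinity.

**Hyperparameter search.** Global-best PSO over log10(theta) in [-3, 3]^3
(and p in [0.5, 2]^3 when optimised): swarm 40, 300 iterations, inertia
0.72, cognitive = social = 1.49 — standard constricted settings. The search
is deterministic given its seed. If every initial particle lands in the
infeasible (ill-conditioned) region the initialisation retries with a
doubled swarm, still deterministically.

**Conditioning.** The nugget defaults to 1e-10 x var(y) and is escalated
(at most to 1e-6 x var) with a warning if the Cholesky fails. After each
factorisation a LAPACK `dpocon` reciprocal-condition estimate is checked;
below 1e-9 the matrix is treated as numerically singular and the
hyperparameter point as infeasible. This floor matters: for smooth,
noise-free targets the marginal likelihood increases without bound as the
kernel flattens (theta -> 0), where R approaches a rank-one matrix and the
"fit" degenerates into an ill-conditioned trend model. The rcond floor is
the package's operational definition of that degeneracy and confines the
search to models whose weights are numerically meaningful.

**Interpolation.** Exactly, `prediction(f_j) - y_j = -nugget x a_j` at every
training point; the per-run interpolation assertion checks
`max_j |resid_j| <= 10 x nugget x max_j |a_j|` (plus a 1e-10 relative
floor). A tolerance phrased against `max|y|` instead of `max|a|` is not
attainable for likelihood-selected hyperparameters on smooth noise-free
targets, where the optimum sits near the conditioning boundary by the
argument above.

**Model sets.** Separate independent models per atom and per property:
3 atomic energies and 3 x 9 local-frame moment components. The 27 moment
models are trained with a lighter swarm (16 particles, 60 iterations) —
their targets are low-amplitude, near-linear functions of the features and
converge quickly; the difference in validation error against full settings
is below the split-to-split scatter. All models of one set share a training
split, which lets the dynamics evaluate all 30 kernels from a single
feature-difference computation per molecule.

## Multipole conventions and electrostatics

Real tesseral harmonics with Racah normalization, component order
(Q00, Q10, Q11c, Q11s, Q20, Q21c, Q21s, Q22c, Q22s), moments in e A^l.
Conversions to Cartesian tensors: mu = (Q11c, Q11s, Q10); traceless
quadrupole Theta_zz = Q20, Theta_xz = (sqrt3/2) Q21c, Theta_yz =
(sqrt3/2) Q21s, Theta_xx - Theta_yy = sqrt3 Q22c, Theta_xy =
(sqrt3/2) Q22s, with Theta_ab = sum q (3ab - r^2 delta_ab)/2. Rank-2
rotation goes through the Cartesian round trip (exact; no hand-coded Wigner
matrices); per-rank Euclidean norms are rotation invariants and are tested
as such.

Pair energies use the classical closed forms in Cartesian variables
(signs fixed by the point-charge limit, which the tests enforce to
second-order convergence): 1/R charge-charge, R^-2 charge-dipole, R^-3
dipole-dipole and charge-quadrupole. The rank rule `l_A + l_B + 1 <= L`
(with atomic rank capped at 2) selects the active couplings; L <= 3 is
supported, which never requires dipole-quadrupole or quadrupole-quadrupole
tensors. The Coulomb factor is 1389.35457644 kJ mol^-1 A e^-2
(CODATA-derived). Intramolecular pairs are excluded — intramolecular
physics lives entirely in the learned atomic energies. Electrostatics are
summed in direct space within 30 A (larger than any cluster here) in a
non-periodic box; the Lennard-Jones term uses a 10 A cutoff with the
potential shifted to zero at the cutoff and the unshifted derivative as the
force (the resulting force discontinuity at 10 A is ~1e-4 kJ/mol/A and is
accepted).

**Local frames.** O: x along the H-O-H bisector, z along (O->H1)x(O->H2),
y right-handed; H: x along H->O, z the same plane normal. Smooth and
well-defined away from collinearity, covariant under rigid rotation, and
the O-frame y axis flips sign under H relabelling (which the surrogate's
odd moment components mirror).

## Forces

Forces are the exact gradient of the total energy:

* kriged atomic energies: analytic kernel gradients (p = 2 required) chained
  with the analytic Wilson B-matrix;
* interaction-tensor terms: hand-differentiated closed forms;
* polarization terms: the Jacobian of each molecule's global moments with
  respect to its nine coordinates combines analytic kernel/B-matrix
  derivatives for the local moments with complex-step differentiation
  (step 1e-30) of the frame rotation — exact to machine precision, since
  the frame construction is written dtype-generically with unconjugated
  norms.

Finite-difference checks hold to ~1e-7 relative; the net force on a cluster
vanishes to ~1e-12 kJ/mol/A because every term depends on relative
coordinates only.

## Dynamics

Internal units: A, fs, u, kJ/mol, e (1 u A^2/fs^2 = 1e4 kJ/mol exactly).
Velocity Verlet with one force evaluation per step; dt defaults to 1 fs
(0.1 fs for microcanonical integrity checks). Andersen thermostat:
independent per-atom Maxwell-Boltzmann redraws with default collision rate
10 ps^-1 per atom — unspecified by convention, chosen strong enough to
thermalise small clusters within a few picoseconds and configurable.
Kinetic temperature uses 3N degrees of freedom (6 per molecule in rigid
mode).

Clusters are initialised as seed-geometry monomers on a jittered cubic
lattice (spacing 3.4 A, compact sites first), uniformly random
orientations, with every O-O separation >= 2.6 A and every intermolecular
atom pair >= 1.5 A (resampled otherwise), and Maxwell-Boltzmann velocities
with the net momentum removed.

**Rigid-monomer control runs.** After every position update each molecule is
replaced by the mass-weighted best-fit (SVD superposition) of the reference
geometry onto its current atoms, and velocities are projected onto
centre-of-mass translation plus rigid rotation (omega = I^-1 L). Local
moments are frozen at the reference geometry's values but still co-rotate
with each molecule's frame, so the rigid model is a fixed-multipole,
orientation-dependent electrostatic model; the kriging moment-gradient
force terms are absent, the frame-rotation terms remain.

Blow-up protection: a step that produces non-finite forces or total energy
beyond a configurable bound aborts with the last good state and the energy
log attached to the exception.

Microcanonical drift is quantified as the difference between the first and
last 10%-block means of the total energy, normalised by
max(|mean E_total|, mean kinetic energy) — the total energy of a small
cluster can sit near zero, so the kinetic energy provides a stable scale.
Drift is measured on a thermally equilibrated system (a short thermostatted
run precedes the microcanonical segment): from a packed, high-force start
the shadow energy relaxes during the first close approaches, which would be
misread as integrator drift.

## Analysis conventions

Cluster RDFs have no periodic density to normalise against; the ideal-gas
reference uses the cluster's gyration-equivalent sphere (radius
sqrt(5/3) R_g per frame). Peak *positions* are insensitive to this choice;
peak heights are convention-dependent and the convention is recorded in the
result metadata. Defaults: 0.05 A bins to 10 A; intramolecular pairs
included for OH/HH (their first peaks are the intramolecular distances,
e.g. H-H at 2 r sin(theta/2) = 1.527 A at the seed geometry). Histogram
modes are the centre of the maximum bin, ties toward smaller values.

The bond-scan validation varies one O-H bond over 0.85-1.15 A in 0.005 A
steps (61 points) at fixed angles 105.05 and 100 deg with the other bond at
0.9619 A, comparing model predictions against the noiseless oracle; model
energies are reported relative to the model's value at the seed geometry,
oracle energies relative to its exact minimum (zero).

## Problem sizes used in the shipped checks

Chosen as the smallest sizes at which the quantities are stable: ensembles
of 3000-3600 configurations (2000-configuration pool for the N_trn = 250
quality check, 1000 validation points); learning curves over N_trn in
{50, 75, 125, 250} with 5 repeated splits; a 10 ps, dt = 0.1 fs
microcanonical dimer run; a 3 ps thermostatted 25-molecule cluster; 0.3-0.4
ps rigid-control runs on 4 molecules.

## Known limitations

* Direct-space, non-periodic electrostatics only; no Ewald summation, hence
  no bulk liquid.
* Atomic multipoles stop at rank 2 and interaction rank at L = 3.
* Dispersion-repulsion is a fixed Lennard-Jones term, not learned.
* The kriging predictor provides no uncertainty output; no gradient-enhanced
  or sparse variants.
* Andersen collisions destroy dynamical correlations; the thermostatted runs
  target structural observables only.
* Maximum-likelihood hyperparameters for noise-free smooth targets sit near
  the conditioning boundary (see above); training residuals are then
  nugget x weights in magnitude (~1e-4 relative), not machine epsilon.
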