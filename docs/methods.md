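# Methods

This note documents the models implemented in `implisolv`, their
assumptions, the parameter choices, and the numerical decisions made where
the design was genuinely open.

## Units and data model

GROMOS conventions throughout: nm, ps, kJ·mol⁻¹, u, K; k_B = 0.00831451
kJ·mol⁻¹·K⁻¹. Atom indices are 0-based internally; residue numbers are
preserved verbatim from the source structure (1-based for PDB), which
avoids renumbering mistakes when matching experimental tables. United-atom
CHn groups carry aggregate masses (CH1 = 13.019 u, CH2 = 14.027 u,
CH3 = 15.035 u); their hydrogens exist only as virtual/pseudo sites built
at observable-calculation time, never as dynamic particles.

## SASA implicit solvation

The accessible area of each atom is the Hasel-style pairwise product
approximation (see README for the formulas); the energy is Σ σ_i A_i and
forces are its exact gradient. Implementation notes:

* **Neighbour order.** p_ij distinguishes only first and second covalent
  neighbours; the order is computed from the bond graph by breadth-first
  search, and all pairs three or more bonds apart (or non-bonded) use
  p_ij = 1.
* **Bracket clamping.** At unphysically short distances the product
  factors [1 − p_i p_ij b_ij/S_i] can leave [0, 1], which would flip the
  sign of an area. Each factor is clamped to [0, 1] with zero derivative
  where clamped; clamping events are reported on the result object
  (`clamped_pairs`) as a model-deviation flag. Away from the clamped
  regime the forces are the exact analytic gradient (verified against
  central finite differences at 10⁻⁴ relative tolerance on randomised
  clusters).
* **Per-pair antisymmetric forces.** The gradient is accumulated per
  atom pair with equal and opposite contributions, so zero net force and
  torque hold to round-off by construction.
* **Undefined entries.** Types with no radius (OW, CH4, DUM) take part in
  neither area nor occlusion and are listed in `excluded`. Types with a
  radius but no σ (OE, CH0, CH2r in the per-type set) still occlude their
  neighbours but raise if their own energy term is requested, unless an
  override σ is supplied — the conservative reading of a blank parameter.
  In the three-class set the class-less σ = 0 types (HC, H, S) inherit
  σ = 0 so hydrogen- or sulphur-containing solutes remain usable.
* **Hydrogens occlude.** Explicit hydrogens have defined radii (0.110 nm)
  and σ = 0: they shade their neighbours' surfaces but contribute no
  energy. This is configurable (`hydrogens_occlude`).
* **Pair search.** A k-d tree with the global cutoff
  max(R_i + R_j) + 2R_solv; the brute-force O(N²) product evaluation is
  retained in the test suite as the independent oracle.
* **Default parameter set** is the per-type column; the three-class
  simplified set is selected with `set_id="three-class"`.

## Stochastic dynamics

* **Discretisation.** Exponential Langevin leap-frog:
  v′ = e^(−γΔt) v + (f/m)Δt + ξ with Var(ξ) = (k_B T_ref/m)(1 − e^(−2γΔt)),
  then x′ = x + v′Δt. The Ornstein–Uhlenbeck part is exact, so the
  velocity marginal is correct at any γΔt (γ_solv Δt ≈ 0.18 here), and at
  γ = 0 the scheme is bitwise plain leap-frog. Configurational averages
  carry an O(γΔt·(ωΔt)²)-type discretisation bias for stiff modes —
  measured at ~8 % in position variance for a test oscillator at
  γ = 91 ps⁻¹, ωΔt ≈ 0.018, and < 1.5 % at γ = 10 ps⁻¹ — while kinetic
  temperatures remain correct within sampling error. This trade-off
  favours robust thermalisation of exposed atoms over configurational
  accuracy of the stiffest (constrained anyway) modes.
* **Exposure-dependent friction.** γ_i = γ_solv·max(0, 1 − N_i/6) with
  γ_solv = 91 ps⁻¹ and N_i the number of non-hydrogen atoms within
  0.3 nm, refreshed every 1 ps. Covalently bonded heavy atoms are
  *included* in the count: they sit within 0.3 nm by construction, and
  excluding them would leave every surface atom at ω ≈ 1. The strictness
  of the 0.3 nm cut is `r < radius`. Buried atoms (N ≥ 6) receive exactly
  zero friction and zero stochastic force.
* **Thermostat layering.** Berendsen weak coupling
  λ = √(1 + (Δt/τ_T)(T_ref/T − 1)), τ_T = 0.1 ps, is applied once per step
  — by default to the whole solute with the instantaneous temperature of
  all atoms (n_dof = 3N − N_constraints). The alternative of scaling only
  γ = 0 atoms is available (`thermostat_group="zero-gamma"`); the global
  choice is the simpler one and both routes are exercised in tests.
* **SHAKE.** Applied after the position update; corrections act along the
  pre-update bond directions with inverse-mass weighting, iterated until
  every constraint satisfies |r − d|/d ≤ 10⁻⁴ (internally converged one
  decade tighter). Velocities are recomputed from the constrained
  position difference. Stochastic and systematic forces are not projected
  onto the constraint manifold (first-order treatment, standard
  SHAKE-in-SD practice).
* **Heat-up protocol.** Five staged runs at 60/120/180/240/308 K, 20 ps
  each, the first four with harmonic position restraints of 25 000, 2500,
  250 and 25 kJ·mol⁻¹·nm⁻², the last unrestrained. Initial velocities are
  Maxwell-distributed at the first stage temperature. Tests run the same
  protocol at 1 ps per stage on a small chain, which reaches the target
  temperature within 10 %; full-length stages equilibrate correspondingly
  closer.
* **Bookkeeping.** Centre-of-mass translation is removed every 2 ps,
  frames stored every 5 ps (both configurable); trajectories are bitwise
  reproducible given `rng_seed`. A single Generator stream seeded per run
  is used rather than per-atom counter-based streams: the engine is
  serial, and the reproducibility contract is per-seed determinism.
* **Toy force field.** Harmonic bonds/angles, cosine torsions, LJ +
  Coulomb with plain cutoff and 1-2/1-3 exclusions. It exists to exercise
  the engine on synthetic molecules and is not a calibrated protein force
  field; its dihedral gradient uses the exact Blondel–Karplus form and is
  finite-difference verified.

## NMR observables

* **Virtual sites.** CH: H on the negative resultant of the three heavy
  neighbour unit vectors at 0.1 nm. Prochiral CH₂: H2/H3 mirror-symmetric
  about the heavy-neighbour plane (H2 on the positive side of u₁×u₂ with
  neighbours ordered by atom index — a deterministic stereo convention).
  CH₃: a single pseudo-site at the methyl carbon, named with a trailing
  `*`; the pseudo-atom distance-bound corrections compensate. Peptide N
  without explicit H: planar H on the negative bisector.
* **Pseudo-atom corrections.** The packaged defaults are +0.10 nm per
  methyl or CH₂ wildcard side and +0.20 nm when a wildcard spans two
  methyls; they live in editable package data
  (`data/pseudoatom_corrections.tsv`) because they are empirical bound
  relaxations, and results are sensitive to them.
* **NOE.** Distances are ⟨r⁻³⟩⁻¹/³ over frames; multi-proton wildcard
  specs contribute (Σ r⁻³)⁻¹/³ per frame (standard multiplet treatment,
  flagged per record). violation = max(0, d − (bound + correction));
  histogram bins [0.05–0.1, 0.1–0.15, 0.15–0.2, 0.2–0.25, 0.25–0.3,
  > 0.3] nm, half-open on the left edge. Unresolvable restraints go to a
  rejects list, never silently dropped.
* **³J couplings.** θ is measured directly on the (virtual) H–N–Cα–Hα or
  Hα–Cα–Cβ–Hβ dihedral rather than derived from φ with an offset —
  avoiding offset-convention drift. Experimental values flagged with
  `cap_flag` are capped at the backbone Karplus maximum (9.7 Hz); the cap
  is a table column, not hard-coded residue names. Deviation bins
  [1–2, 2–3, 3–4, 4–5, > 5] Hz.
* **Ambiguous assignments.** Stereo-specifically unassigned pairs
  (`pair:<id>` status) are assigned to the calculated pair minimising the
  summed absolute deviation; ties keep the input order. The chosen
  pairing can never exceed either fixed pairing (property-tested).
* **S².** The ensemble-averaging expression with ⟨μ_α μ_β/r³⟩ terms,
  multiplied by (r_eff)⁶; with constrained bonds r is constant and r_eff
  equals the bond length (default: the mean observed length). Averages
  are taken per non-overlapping window of the stated length (default
  1 ns; the final partial window is discarded — the overlap policy being
  unspecified, non-overlapping is the variance-safe choice) and then
  averaged over windows. Frames are superimposed first (backbone atoms
  of the fit selection) to remove overall rotation. Deviation bins
  [0.05–0.1, 0.1–0.2, 0.2–0.3, 0.3–0.4, 0.4–0.5, > 0.5].

## Structure analysis

* **Superposition.** Kabsch SVD fit, proper rotations only (determinant
  +1 enforced; mirrored inputs fit with positive RMSD rather than
  reflecting). Collinear selections raise.
* **Radius of gyration.** The standard mass-weighted form
  √(Σ m_i (r_i − r_cm)²/M). A raw (un-normalised) summed variant exists
  behind `normalized=False` for comparison; the normalised form is the
  one that reproduces published protein values (≈1.4 nm for lysozyme).
* **Hydrogen bonds.** Geometric criterion, strict inequalities: H–acceptor
  distance < 0.25 nm and donor–H–acceptor angle > 135°. Donors are N/O
  with an explicit or virtual H (methyl pseudo-sites never donate);
  acceptors are the N/O type codes. The hydrogen-bonding extent metric is
  the occupancy-weighted bond count relative to a reference structure
  count.
* **Autocorrelation.** C_Q(t) = ⟨Q(τ)·Q(τ+t)⟩_τ/⟨Q·Q⟩_τ with the
  unbiased (n − t) pair normalisation, evaluated by zero-padded FFT; the
  O(n²) direct sum is kept as the test oracle and agrees to < 10⁻¹⁰.
  Spectral densities use only the leading 2 % of C(t) (configurable) via
  a cosine transform. Torsion series are embedded as unit vectors
  (cos χ, sin χ): the dot product is then periodicity-safe and C(0) = 1
  automatically; raw angles are attached to the series for inspection.

## Synthetic data

The generators exist so every pipeline runs with no downloads; all are
bitwise-deterministic under a seed.

* **Toy chain.** Backbone N–CA–C(=O) plus a side chain per residue, built
  from idealised internal coordinates (N–CA 0.147, CA–C 0.153, C–N 0.133,
  C=O 0.123, CA–CB 0.153 nm) with extended-region backbone torsions
  jittered ±10° by the seed; bond lengths equal the constraint targets
  exactly by construction. Side chains alternate CH₃ (pseudo-site paths)
  and CH₂–CH₃ (prochiral virtual-pair paths). The chain emulates the
  *shape* of united-atom protein input — it has no real protein's fold,
  so passing tests demonstrate correctness of the machinery, not
  force-field realism.
* **Cone trajectory.** A two-atom bond vector uniform on a spherical cap;
  uniform-in-cone orientation gives the closed form
  S = cos β(1 + cos β)/2, the independent oracle for S² (0.1406 at 60°).
* **NOE fixture.** Restraint bounds are back-computed from the generating
  structure so that chosen records violate their corrected bound by
  exactly the planted amounts; the expected histogram is returned with
  the set.
* **Experimental tables.** ³J and S² values are the back-calculated truth
  plus Gaussian noise; a fraction of CH₂ pairs is flagged unassigned with
  randomised order (exercising assignment recovery), and backbone values
  exceeding the Karplus maximum are capped and flagged. With zero noise
  the scoring pipelines must return zero deviations — the main
  end-to-end consistency check.

## Problem sizes and limitations

Property suites run at: 100 random 3–20-atom clusters for the SASA
force/finite-difference check; 10⁵ steps for equipartition and zero-
friction energy conservation; 64 independent oscillators × 5·10⁴ steps
(≈10⁷ dof-samples) for the Boltzmann-variance check; 2·10⁵ orientations
for the S² limits. These sizes give sampling errors comfortably inside
the asserted 2–3 % bands.

Known limitations: the validation chain against the lysozyme crystal
structure and its experimental tables requires third-party data the
package cannot ship (see README); reading a plain PDB cannot recover
united-atom type codes or the bond graph, so united-atom analyses use the
package's text topology format alongside the PDB; NH₂/NH₃ virtual
hydrogens are not constructed (explicit hydrogens are used where such
donors matter); and no claim is made that the toy force field reproduces
protein energetics.
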