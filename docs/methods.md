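# Methods

This note records the models, conventions and numerical choices behind
`ioneda`, and what the synthetic test conditions do and do not show.

## Scope and framing

The package analyzes vertical ion–water interaction energies for
X⁻(H₂O)ₙ clusters consisting of an ion plus its first two hydration
shells, treated as a *dimer*: the ion is one monomer and the entire
water cluster the other. No charge embedding is used and monomer
geometries are never relaxed, so every energy is an interaction energy
at fixed geometry, not a binding or solvation energy. Snapshots are
labeled *bulk* or *interfacial* by the position of the ion's center of
mass relative to the Gibbs dividing surface of the slab they came from.

## Slab analysis

* The mass density profile along the slab normal is binned per frame and
  frame-averaged; mass is conserved exactly by construction (histogram of
  atom masses divided by bin volume).
* Each slab face is fitted with ρ(z) = (ρ_b/2)[1 − tanh((z − z_GDS)/d)]
  (the lower face mirrored first). ρ_b is initialized from the central
  plateau and refined in the fit; the GDS is the ρ_b/2 crossing. The
  tanh form is a standard, bin-noise-robust choice. A profile that never
  decays below half its maximum raises a "no interface" error.
* Classification: depth = distance below the *nearer* GDS face;
  interfacial iff depth ≤ 3 Å (boundary inclusive), bulk if deeper, and
  an ion above both faces is flagged "ejected" rather than classified.
* Cluster carving includes every water whose oxygen lies within `r_cut`
  of any ion atom (minimum image), as whole molecules, unwrapped so the
  cluster is contiguous. `r_cut` defaults to 6.0 Å — near the second
  minimum of halide–water g(r) — and is configurable per ion; the value
  used is recorded in the snapshot metadata by the caller.

## Electronic structure

No external quantum-chemistry engine is used. The package carries:

* **Integrals** — McMurchie–Davidson Hermite-expansion integrals over
  Cartesian Gaussians through d functions (overlap, kinetic, per-center
  nuclear attraction, dipole, two-electron repulsion with Schwarz
  screening), numba-jitted. The Boys function uses a downward-stable
  series for T < 35 and the erf asymptote above.
* **Basis sets** — generated, not tabulated. For every occupied subshell
  (n, l) of an element, a Slater exponent ζ comes from Slater's
  screening rules and the nodeless Slater radial function is expanded in
  three Gaussians by least squares (the classic STO-3G construction; the
  ζ = 1 fit reproduces the canonical 1s expansion to five digits).
  Levels: `min` (one contraction per subshell), `dz` (outermost valence
  primitive released), `tz` (valence fully uncontracted);
  `diffuse=True` adds even-tempered diffuse s and p (α_min/3) on non-H
  atoms. **Anion work uses `min`+diffuse by default**: the
  polarization/CT analysis rests on the diffuse tail of the anion
  density, which a minimal expansion lacks entirely. These bases are
  internally consistent rather than literature-identical; all shipped
  checks are symmetry-forced numbers, closures, conservation laws or
  qualitative contrasts, which do not depend on basis identity.
* **SCF** — closed-shell restricted HF, core guess, DIIS (8-vector)
  with optional level shifting, symmetric orthogonalization dropping
  overlap eigenvalues below 1e-9. Default convergence 1e-10 hartree /
  1e-7 on the orbital gradient. Ghost centers carry basis functions but
  no charge or electrons; every monomer entering the decomposition is
  converged in the dimer-centered basis (counterpoise-consistent).
  An arbitrary extra one-electron potential (frozen-partner embedding)
  and a λW population-constraint term are supported; reported energies
  always exclude the constraint term.

## The decomposition

With A = ion, B = water cluster, all in the dimer basis:

* **E_elst**: Coulomb interaction of the unperturbed monomer charge
  distributions (nuclei and SCF densities). Exact for the given
  densities; checked against point-charge and charge–dipole asymptotics.
* **E_exch**: Heitler–London exchange — the energy of the normalized
  antisymmetrized product of the two monomer determinants (Löwdin rules
  for nonorthogonal orbitals) minus monomer energies and E_elst. This is
  the full-overlap first-order exchange, not the S² truncation; with an
  in-house engine the exact expression is simpler and better behaved,
  and an independent AO-contraction route reproduces it in the tests.
* **E_ind (directional)**: coupled-perturbed HF — the second-order
  response of one monomer to the frozen electrostatic potential of the
  other (nuclei + converged density), obtained from an explicit
  occupied–virtual orbital-Hessian solve. Each direction is non-positive.
  The independent oracle is the λ → 0 quadratic response of embedded
  finite-field SCF runs (symmetric second difference, two-stage
  Richardson), which agrees to better than 1e-6 hartree. *Full*
  variational relaxation in the frozen field is not used: without the
  partner's Pauli wall it collapses into the partner's cores (tens of
  hartree on Cl⁻/H₂O) and is not a usable definition.
* **E_exch-ind (directional)**: the directional derivative of the
  Heitler–London exchange along the response rotation (symmetric
  difference with step 0.1 in the rotation amplitude). This captures the
  linear, second-order-consistent exchange quench of induction; the
  finite-rotation difference is deliberately avoided because response
  amplitudes into ghost functions are large.
* **δHF**: remainder against the counterpoise supermolecular HF
  interaction energy, ΔE_int^HF = E_AB − E_A − E_B. The total induction
  reported is (both directional inductions) + (both exchange-induction
  terms) + δHF, which makes E_elst + E_exch + E_ind = ΔE_int^HF an exact
  identity — the module's master self-test — while the split among its
  pieces carries the stated definitions.
* **E_disp**: damped pairwise interfragment dispersion,
  −f₆(bR)C₆/R⁶ − f₈(bR)C₈/R⁸ with Tang–Toennies damping and a range
  parameter set by the pair's van der Waals contact distance
  (b = 5.6/(R_i + R_j)). C₆/C₈ depend only on the element. The shipped
  coefficients are literature-magnitude free-atom values — placeholders
  for a fitted set, replaceable via a plain-text parameter file — and
  the EDA records which set produced E_disp. Many-body dispersion,
  coefficient screening and three-body terms are out of scope.

## Polarization vs charge transfer

The CT-free reference is a charge-constrained restricted HF state of the
supersystem: N_ion = Tr(D W) is driven to the isolated ion's integer
electron count by a safeguarded secant loop on the Lagrange multiplier λ
in F + λW (population tolerance 1e-4 e, warm-started inner SCFs,
bracketing expansion with λ-scan diagnostics on failure). E_CT is the
energy lowering on lifting the constraint (≤ 0 variationally);
E_pol = E_ind − E_CT.

The weight matrix W = ∫ w_ion(r) φ_μ φ_ν is built on a quadrature grid
and held fixed during the SCF:

* **Becke**: iterated smoothing polynomial (k = 3) on cell coordinates
  with heteroatomic boundary shifts from Slater's atomic radii
  (H 0.25, C 0.70, N 0.65, O 0.60, S 1.00, Cl 1.00, Br 1.15, I 1.40 Å;
  shift parameter clamped to |a| ≤ 1/2). Size adjustments are always on
  for constraints — without them the O–H boundary sits at the bond
  midpoint and hydrogen is grossly over-assigned, which the tests
  demonstrate explicitly.
* **FBH**: w_A = ρ_A⁰/Σ_B ρ_B⁰ from isolated-fragment SCF densities at
  the supersystem geometry. The water-side promolecule defaults to the
  whole (H₂O)ₙ cluster's own density, consistent with the dimer framing;
  a per-water superposition mode is available. Points where the
  promolecule falls below 1e-12 a.u. are assigned to the nearest
  fragment (they carry negligible density).

FBH is the default reporting scheme. On the iodide test cluster the
geometric Becke cells under-count the anion's diffuse tail and give CT
magnitudes an order larger than FBH, reproducing the qualitative scheme
contrast this separation is known for.

## Quadrature grids

Atom-centered product grids: Mura–Knowles log3 radial mapping (α = 5
bohr, 7 for Br/I) × Gauss–Legendre(cos θ) × uniform(φ) angular rule
(exact through spherical-harmonic degree 2n_θ − 1), combined with
size-adjusted Becke cell weights. Levels: coarse 45×(14×28), standard
75×(20×40), fine 105×(28×56) per atom. A normalized Gaussian integrates
to 1 within 1e-8 already at coarse; electron counts converge to ~1e-4 at
standard. The exact engine-specific pruned-grid construction used in
production codes is not reproduced; accuracy is certified by electron-
count convergence instead. Constraint matrices use the coarse grid
(population tolerance is 1e-4 e; the grid is orders tighter).

## Synthetic data

Generators are pure functions of their spec, seed included.

* **Slabs**: rigid waters (r_OH = 0.9572 Å, ∠HOH = 104.52°) placed by
  rejection sampling (O–O < 2.4 Å rejected) at 0.997 g/cm³ in a central
  slab, vacuum elsewhere, ion at a requested depth below the upper
  surface; frames differ by per-molecule rigid jitter (σ = 0.08 Å) and
  orientation wobble. These slabs have sharp, capillary-wave-free
  interfaces (fitted tanh widths ≪ 1 Å) and no force-field relaxation —
  sufficient for exercising profile/GDS/classification machinery, not a
  model of real liquid structure.
* **Clusters**: first-shell waters donate one O–H to the ion with
  X⁻···H drawn from a truncated Gaussian (σ = jitter) inside the stated
  range and tilt within the angular spread; second-shell waters H-bond
  to first-shell oxygens at 2.8 Å with full 3D jitter. Default desk
  scale is n ≤ 6 waters; the data model supports the ~28–44-water
  two-shell clusters of production work, but the shipped ensembles stay
  small so the whole quantum pipeline runs in minutes.

Passing tests on these synthetic conditions certify the machinery
(closures, conservation, sign laws, scheme contrasts, classification
logic), not quantitative agreement with condensed-phase ensembles, which
would require the large carved clusters and polarized triple-ζ bases of
production studies.

## Statistics and reporting

Sample statistics use the n−1 denominator. Comparison tables report the
interface − bulk mean difference and its size in bulk-SD units, flagging
differences of at least one bulk SD (the significance convention used
for the CT comparison). Box-whisker exports encode box = mean ± 1 SD
with the center mark at the mean and whiskers at min/max — not quartiles
— and always write a numeric sidecar CSV so the convention is checkable
without rendering. Tables print to 0.1 kcal/mol; CSVs keep full
precision.

## Known limitations

* Closed-shell RHF only; no DFT monomers, no Kohn–Sham variant of the
  decomposition, no ω-tuned functionals.
* Dispersion coefficients are placeholders (model form is the commitment).
* Generated bases are not literature basis sets; absolute energetics are
  internally consistent but not comparable to published per-ion numbers.
* Heavy elements are all-electron (no ECPs); iodine uses Slater-rule
  exponents that are serviceable but crude in the deep core.
* One population constraint at a time; no per-water CT resolution; no
  instantaneous-interface (Willard–Chandler) analysis.
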