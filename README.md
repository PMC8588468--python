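# ioneda

Energy decomposition analysis of ion–water interactions in bulk and
interfacial environments.

Soft (chaotropic) anions such as I⁻, ClO₄⁻ and SCN⁻ accumulate at the
air/water interface, and a long-standing question is whether polarization
or charge transfer (CT) drives that surface preference. `ioneda` provides
the full analysis chain for attacking this question with cluster models
carved from slab simulations:

1. **Slab analysis** — water mass-density profiles, a tanh-fitted Gibbs
   dividing surface (GDS) per slab face, classification of ion snapshots
   as *interfacial* (ion center of mass no more than 3 Å below the nearer
   GDS) or *bulk*, two-shell cluster carving and radial distribution
   functions.
2. **Interaction-energy decomposition** — for the X⁻/(H₂O)ₙ dimer (the
   whole water cluster is one monomer, no charge embedding), the vertical
   interaction energy is decomposed as

   E_int = E_elst + E_exch + E_ind + E_disp

   with counterpoise-consistent Hartree–Fock monomers in the
   dimer-centered basis: first-order electrostatics from frozen monomer
   densities, first-order exchange from the antisymmetrized product of
   the monomer determinants, coupled (response) induction per direction
   plus exchange-induction and the δHF correction

   δE_HF = ΔE_int^HF − (E_elst + E_exch + E_ind,resp + E_exch-ind,resp),

   so that E_elst + E_exch + E_ind reproduces the counterpoise
   supermolecular HF interaction energy exactly. Dispersion is a damped
   pairwise interfragment −f₆C₆/R⁶ − f₈C₈/R⁸ model whose coefficients
   depend only on atomic number.
3. **Polarization/CT separation** — a charge-constrained SCF defines a
   CT-free reference: the ion fragment is constrained to its integer
   electron count N_A = ∫ w_A(r) ρ(r) dr while the monomers polarize each
   other. Lifting the constraint lowers the energy by E_CT ≤ 0, and
   E_pol = E_ind − E_CT. The weight w_A is either a Becke multicenter
   partition with atomic size adjustments (Slater radii) or
   fragment-based Hirshfeld (FBH) weights w_A = ρ_A⁰ / Σ_B ρ_B⁰ built
   from isolated-fragment densities; FBH is the default.
4. **Ensemble statistics** — per-component, per-environment mean, sample
   SD, extrema; bulk-vs-interface comparison tables flagging differences
   that exceed one bulk SD; box-whisker export (box = mean ± SD, whiskers
   = min/max) with a numeric sidecar.
5. **Synthetic data** — seeded generators for periodic water slabs at
   0.997 g/cm³ with an ion at controllable depth, and for hydrogen-bonded
   X⁻(H₂O)ₙ cluster ensembles with controlled X⁻···H distances and
   snapshot jitter, so every stage can be exercised without an MD engine.

The quantum layer is self-contained: Cartesian-Gaussian integrals
(McMurchie–Davidson, numba-accelerated through d functions), restricted
HF with DIIS, ghost centers for counterpoise, coupled-perturbed HF, and
basis sets generated on the fly as STO-3G-style expansions of
Slater-rule orbitals with optional split-valence and diffuse
augmentation (`BasisSpec("min"|"dz"|"tz", diffuse=True|False)`).

## Worked example

```bash
python examples/binary_eda.py
```

decomposes the quasi-linear Cl⁻···H–O binary complex at 3.2 Å and prints

```
Cl-(H2O) vertical interaction energy decomposition (kcal/mol)
  E_elst      =    -17.886   (frozen-density Coulomb)
  E_exch      =     11.170   (Pauli repulsion)
  E_ind       =     -4.320   (response induction + delta-HF)
  E_disp      =     -0.770   (damped pairwise C6/C8)
  E_int       =    -11.806
  E_elst+exch =     -6.716   (grouped short-range electrostatics)
  E_CT        =     -0.837   (FBH-constrained charge transfer)
  E_pol       =     -3.483   (CT-free polarization)
closure vs supermolecular HF: +1.78e-15 kcal/mol
```

The hydrogen bond is electrostatically dominated; exchange repulsion
cancels most of it at contact, induction and dispersion stabilize, and
the FBH-defined CT is a small fraction of the induction energy — the
pattern this kind of analysis probes when comparing bulk against
interfacial snapshot ensembles. Other examples cover the slab/GDS
pipeline (`slab_interface.py`), the Becke-vs-FBH CT contrast on
I⁻(H₂O)₄ (`ct_split_schemes.py`), ensemble statistics and the
box-whisker export (`ensemble_stats.py`), and the symmetry-forced
perchlorate dipole (`perchlorate_dipole.py`).

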