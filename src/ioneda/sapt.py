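"""Hartree-Fock-based interaction-energy decomposition for an
ion/(H2O)n dimer.

The cluster of waters is treated as a single monomer; both monomers are
converged in the dimer-centered basis (partner atoms as ghosts), so all
terms are counterpoise-consistent.  Components:

electrostatics
    Coulomb interaction of the unperturbed monomer charge densities
    (nuclei and electrons), exact for the given densities.
exchange
    first-order Pauli repulsion from the antisymmetrized product of the
    two monomer determinants (Lowdin nonorthogonal determinant rules,
    all orders in the intermolecular overlap).
induction
    per-direction variational relaxation of one monomer in the partner's
    frozen electrostatic field (an embedded SCF), plus the corresponding
    exchange-induction quench (the change in first-order exchange upon
    using the relaxed orbitals), plus the delta-HF remainder against the
    counterpoise supermolecular HF interaction energy.  With this
    definition electrostatics + exchange + induction reproduces the
    supermolecular HF interaction energy identically.
dispersion
    supplied externally (pairwise damped C6/C8 model).

Interaction energies are vertical: monomer geometries are used as-is.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .geometry import Atom, Fragment, center_of_nuclear_charge
from .integrals import AOIntegrals, ao_integrals
from .basis import BasisSpec
from .periodic import AU_TO_DEBYE, BOHR_PER_ANGSTROM, HARTREE_TO_KCAL
from .scf import SCFSolution, solve_scf


class UnconvergedInputError(ValueError):
    pass


def _check_converged(*solutions: SCFSolution):
    for s in solutions:
        if not s.converged:
            raise UnconvergedInputError("input SCF solution is not converged")


def cross_nuclear_repulsion(atoms: Sequence[Atom], idx_a, idx_b) -> float:
    e = 0.0
    for i in idx_a:
        for j in idx_b:
            r = np.linalg.norm(atoms[i].position - atoms[j].position)
            e += atoms[i].z * atoms[j].z / (r * BOHR_PER_ANGSTROM)
    return e


def elst1(sol_a: SCFSolution, sol_b: SCFSolution, ints: AOIntegrals,
          idx_a: Sequence[int], idx_b: Sequence[int]) -> float:
    """First-order electrostatics (hartree): frozen monomer densities."""
    _check_converged(sol_a, sol_b)
    va = ints.nuclear(idx_a)
    vb = ints.nuclear(idx_b)
    e = cross_nuclear_repulsion(ints.atoms, idx_a, idx_b)
    e += np.einsum("ij,ij->", sol_a.density, vb)
    e += np.einsum("ij,ij->", sol_b.density, va)
    e += np.einsum("ij,ij->", sol_a.density, ints.coulomb(sol_b.density))
    return float(e)


def _intra_energy(density: np.ndarray, ints: AOIntegrals,
                  idx: Sequence[int]) -> float:
    """HF energy functional of one monomer evaluated at a given density."""
    h = ints.kinetic + ints.nuclear(idx)
    e = np.einsum("ij,ij->", density, h)
    e += 0.5 * np.einsum("ij,ij->", density, ints.coulomb(density))
    e -= 0.25 * np.einsum("ij,ij->", density, ints.exchange(density))
    return float(e + ints.nuclear_repulsion(idx))


def heitler_london_energy(cocc_a: np.ndarray, cocc_b: np.ndarray,
                          ints: AOIntegrals, idx_a, idx_b) -> float:
    """Energy of the normalized antisymmetrized product of the two
    closed-shell determinants (Lowdin rules for nonorthogonal orbitals)."""
    C = np.hstack([cocc_a, cocc_b])
    S = ints.overlap
    smo = C.T @ S @ C
    M = C @ np.linalg.solve(smo, C.T)   # per-spin transition density
    D = 2.0 * M
    idx_all = list(idx_a) + list(idx_b)
    h = ints.kinetic + ints.nuclear(idx_all)
    e = np.einsum("ij,ij->", D, h)
    e += 0.5 * np.einsum("ij,ij->", D, ints.coulomb(D))
    e -= 0.25 * np.einsum("ij,ij->", D, ints.exchange(D))
    return float(e + ints.nuclear_repulsion(idx_all))


def exch1(sol_a: SCFSolution, sol_b: SCFSolution, ints: AOIntegrals,
          idx_a, idx_b) -> float:
    """First-order exchange (hartree): Heitler-London energy minus
    monomer energies and electrostatics."""
    _check_converged(sol_a, sol_b)
    return _exch_from_orbitals(sol_a.occ_coeff, sol_b.occ_coeff,
                               ints, idx_a, idx_b)


def _exch_from_orbitals(ca, cb, ints, idx_a, idx_b) -> float:
    da = 2.0 * ca @ ca.T
    db = 2.0 * cb @ cb.T
    ehl = heitler_london_energy(ca, cb, ints, idx_a, idx_b)
    e_elst = (cross_nuclear_repulsion(ints.atoms, idx_a, idx_b)
              + np.einsum("ij,ij->", da, ints.nuclear(idx_b))
              + np.einsum("ij,ij->", db, ints.nuclear(idx_a))
              + np.einsum("ij,ij->", da, ints.coulomb(db)))
    return float(ehl - _intra_energy(da, ints, idx_a)
                 - _intra_energy(db, ints, idx_b) - e_elst)


def embedding_potential(sol_partner: SCFSolution, ints: AOIntegrals,
                        idx_partner) -> np.ndarray:
    """Frozen electrostatic potential of a monomer as an AO matrix."""
    return ints.nuclear(idx_partner) + ints.coulomb(sol_partner.density)


def cphf_response(sol: SCFSolution, ints: AOIntegrals,
                  perturbation: np.ndarray) -> tuple[float, np.ndarray]:
    """Coupled-perturbed HF response of one monomer to a one-electron
    perturbation.

    Solves the coupled (orbital-relaxed) equations in the occupied-virtual
    rotation space and returns (second-order energy, X) with X the
    first-order occupied->virtual rotation amplitudes, shape
    (n_occ, n_virt).  The second-order energy is non-positive for a
    stable reference.
    """
    C = sol.mo_coeff
    nocc = sol.n_occ
    Co = C[:, :nocc]
    Cv = C[:, nocc:]
    eo = sol.mo_energy[:nocc]
    ev = sol.mo_energy[nocc:]
    nvirt = Cv.shape[1]
    if nvirt == 0:
        return 0.0, np.zeros((nocc, 0))
    v_ov = Co.T @ perturbation @ Cv
    eri = ints.eri
    # MO integrals (chemists' notation)
    half = np.einsum("mnls,mi,na->ials", eri, Co, Cv, optimize=True)
    ovov = np.einsum("ials,lj,sb->iajb", half, Co, Cv, optimize=True)
    half2 = np.einsum("mnls,mi,nj->ijls", eri, Co, Co, optimize=True)
    oovv = np.einsum("ijls,la,sb->ijab", half2, Cv, Cv, optimize=True)
    n = nocc * nvirt
    H = (4.0 * ovov
         - ovov.transpose(0, 3, 2, 1)
         - oovv.transpose(0, 2, 1, 3)).reshape(n, n)
    H += np.diag(np.add.outer(-eo, ev).ravel())
    # closed-shell coupling gradient is 4*v_ov and the orbital Hessian is
    # 2*H, so the stationary rotation solves H x = -2 v
    x = np.linalg.solve(H, -2.0 * v_ov.ravel())
    e2 = 2.0 * float(v_ov.ravel() @ x)
    return e2, x.reshape(nocc, nvirt)


def induction_resp(sol_a: SCFSolution, sol_b: SCFSolution, ints: AOIntegrals,
                   idx_a, idx_b) -> tuple[float, float, np.ndarray]:
    """Directional coupled induction A <- B and its exchange quench
    (hartree).

    The induction energy is the second-order coupled-perturbed (response)
    relaxation of monomer A in the frozen electrostatic field of B
    (nuclei + converged electron density); it is non-positive.  The
    exchange-induction counterpart is the change in the first-order
    (Heitler-London) exchange when A's occupied space is rotated by the
    first-order response amplitudes.  Returns
    (E_ind, E_exch_ind, relaxed occupied coefficients).
    """
    _check_converged(sol_a, sol_b)
    v_emb = embedding_potential(sol_b, ints, idx_b)
    e_ind, x = cphf_response(sol_a, ints, v_emb)
    nocc = sol_a.n_occ
    dc = sol_a.mo_coeff[:, nocc:] @ x.T
    c_relaxed = sol_a.occ_coeff + dc
    # exchange-induction: directional derivative of the first-order
    # exchange along the response rotation (the linear-in-response part;
    # symmetric difference removes the quadratic overshoot)
    h = 0.1
    e_xp = _exch_from_orbitals(sol_a.occ_coeff + h * dc, sol_b.occ_coeff,
                               ints, idx_a, idx_b)
    e_xm = _exch_from_orbitals(sol_a.occ_coeff - h * dc, sol_b.occ_coeff,
                               ints, idx_a, idx_b)
    return float(e_ind), float((e_xp - e_xm) / (2.0 * h)), c_relaxed


def supramolecular_hf(sol_dimer: SCFSolution, sol_a: SCFSolution,
                      sol_b: SCFSolution) -> float:
    """Counterpoise-corrected supermolecular HF interaction energy
    (hartree): E_AB - E_A(DCBS) - E_B(DCBS)."""
    _check_converged(sol_dimer, sol_a, sol_b)
    return float(sol_dimer.energy - sol_a.energy - sol_b.energy)


def delta_hf(e_int_hf: float, e_elst: float, e_exch: float,
             e_ind_ab: float, e_ind_ba: float,
             e_exchind_ab: float, e_exchind_ba: float) -> float:
    """Higher-order induction remainder against the supermolecular HF."""
    return float(e_int_hf - (e_elst + e_exch + e_ind_ab + e_ind_ba
                             + e_exchind_ab + e_exchind_ba))


@dataclass
class EDAResult:
    """Interaction-energy decomposition, kcal/mol.

    ``e_ind`` is the total induction (both directions + exchange-induction
    + delta-HF); closure e_elst + e_exch + e_ind = e_int_hf holds to
    numerical precision, as does e_int = e_elst + e_exch + e_ind + e_disp
    and, when a CT split is attached, e_ind = e_pol + e_ct.
    """

    e_elst: float
    e_exch: float
    e_ind_ab: float
    e_ind_ba: float
    e_exchind_ab: float
    e_exchind_ba: float
    delta_hf: float
    e_ind: float
    e_disp: float
    e_int_hf: float
    e_int: float
    e_ct: float | None = None
    e_pol: float | None = None
    metadata: dict = field(default_factory=dict)

    @property
    def e_elst_exch(self) -> float:
        """Grouped elst+exch: short-range-corrected electrostatics."""
        return self.e_elst + self.e_exch


def assemble_eda(components: dict, dispersion: float,
                 ct_split: tuple[float, float] | None = None,
                 metadata: dict | None = None) -> EDAResult:
    """Combine hartree-scale components into an EDAResult in kcal/mol.

    ``components`` must carry keys elst, exch, ind_ab, ind_ba,
    exchind_ab, exchind_ba, e_int_hf (hartree); ``dispersion`` is in
    kcal/mol already (the dispersion model is parameterized in those
    units); ``ct_split`` is (E_CT, E_pol) in kcal/mol.
    """
    required = ("elst", "exch", "ind_ab", "ind_ba", "exchind_ab",
                "exchind_ba", "e_int_hf")
    missing = [k for k in required if k not in components]
    if missing:
        raise KeyError(f"missing EDA components: {missing}")
    h2k = HARTREE_TO_KCAL
    elst = components["elst"] * h2k
    exch = components["exch"] * h2k
    ind_ab = components["ind_ab"] * h2k
    ind_ba = components["ind_ba"] * h2k
    xind_ab = components["exchind_ab"] * h2k
    xind_ba = components["exchind_ba"] * h2k
    e_int_hf = components["e_int_hf"] * h2k
    dhf = e_int_hf - (elst + exch + ind_ab + ind_ba + xind_ab + xind_ba)
    e_ind = ind_ab + ind_ba + xind_ab + xind_ba + dhf
    e_int = elst + exch + e_ind + dispersion
    e_ct = e_pol = None
    if ct_split is not None:
        e_ct, e_pol = ct_split
    return EDAResult(
        e_elst=elst, e_exch=exch, e_ind_ab=ind_ab, e_ind_ba=ind_ba,
        e_exchind_ab=xind_ab, e_exchind_ba=xind_ba, delta_hf=dhf,
        e_ind=e_ind, e_disp=dispersion, e_int_hf=e_int_hf, e_int=e_int,
        e_ct=e_ct, e_pol=e_pol, metadata=metadata or {})


def compute_dipole(atoms: Sequence[Atom], density: np.ndarray,
                   ints: AOIntegrals) -> tuple[float, np.ndarray]:
    """Molecular dipole about the center of nuclear charge.

    Returns (magnitude in debye, vector in debye).  Using the nuclear
    charge centroid as origin makes the dipole of a charged species
    independent of rigid translations.
    """
    real = ints.real_indices
    real_atoms = [ints.atoms[i] for i in real]
    origin = center_of_nuclear_charge(real_atoms)
    mu_nuc = np.zeros(3)
    for a in real_atoms:
        mu_nuc += a.z * (a.position - origin) * BOHR_PER_ANGSTROM
    dip_ints = ints.dipole(origin)
    mu_el = -np.einsum("dij,ij->d", dip_ints, density)
    mu = (mu_nuc + mu_el) * AU_TO_DEBYE
    return float(np.linalg.norm(mu)), mu
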