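"""Restricted Hartree-Fock with DIIS, ghost centers, external potentials
and a single-fragment population constraint.

All species handled by the pipeline are closed-shell.  The solver accepts
an arbitrary extra one-electron potential (used for frozen-partner
embedding in the induction analysis) and an optional ``lambda * W`` term
(used by the charge-constrained SCF); the reported total energy always
excludes the constraint term itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.linalg import eigh

from .basis import BasisSpec
from .geometry import Atom
from .integrals import AOIntegrals, ao_integrals


class SCFConvergenceError(RuntimeError):
    def __init__(self, msg, n_iter=None, energies=None):
        super().__init__(msg)
        self.n_iter = n_iter
        self.energies = energies


@dataclass
class SCFSolution:
    """Converged single-determinant state.

    ``density`` is the total one-particle density (trace against the
    overlap equals the electron count); ``mo_coeff`` columns are orbitals
    over the AO basis, ``n_occ`` of them doubly occupied.
    """

    energy: float               # hartree, includes extra_potential coupling
    e_nuc: float
    mo_coeff: np.ndarray
    mo_energy: np.ndarray
    density: np.ndarray         # total (2 * occ) AO density
    n_occ: int
    nbf: int
    converged: bool
    n_iter: int
    n_electrons: int
    metadata: dict = field(default_factory=dict)

    @property
    def occ_coeff(self) -> np.ndarray:
        return self.mo_coeff[:, :self.n_occ]


def _diis_extrapolate(fock_list, err_list):
    n = len(fock_list)
    B = -np.ones((n + 1, n + 1))
    B[-1, -1] = 0.0
    for i in range(n):
        for j in range(n):
            B[i, j] = np.vdot(err_list[i], err_list[j])
    rhs = np.zeros(n + 1)
    rhs[-1] = -1.0
    try:
        c = np.linalg.solve(B, rhs)[:n]
    except np.linalg.LinAlgError:
        return fock_list[-1]
    return sum(ci * fi for ci, fi in zip(c, fock_list))


def solve_scf(atoms: Sequence[Atom] | None = None,
              charge: int = 0,
              spin: int = 0,
              basis: BasisSpec | None = None,
              ghost_indices: Sequence[int] = (),
              integrals: AOIntegrals | None = None,
              extra_potential: np.ndarray | None = None,
              constraint: tuple[np.ndarray, float] | None = None,
              init_density: np.ndarray | None = None,
              conv_tol: float = 1e-10,
              conv_tol_grad: float = 1e-7,
              max_cycle: int = 200,
              level_shift: float = 0.0) -> SCFSolution:
    """Converge a closed-shell RHF state.

    Parameters largely mirror the fields of the run configuration.  Pass
    ``integrals`` to reuse a cached AO bundle (same geometry/basis/ghosts);
    otherwise ``atoms`` + ``basis`` are required.  ``constraint`` is
    ``(W, lam)``: the Fock matrix is augmented by ``lam * W`` but the
    reported energy excludes that term.
    """
    if integrals is None:
        if atoms is None or basis is None:
            raise ValueError("need either an integral bundle or atoms+basis")
        integrals = ao_integrals(atoms, basis, ghost_indices)
    if spin != 0:
        raise NotImplementedError("only closed-shell systems are supported")
    ints = integrals
    zsum = sum(ints.atoms[i].z for i in ints.real_indices)
    nelec = zsum - charge
    if nelec <= 0 or nelec % 2:
        raise ValueError(f"{nelec} electrons: need a positive even count")
    nocc = nelec // 2

    S = ints.overlap
    hcore = ints.kinetic + ints.nuclear()
    if extra_potential is not None:
        hcore = hcore + extra_potential
    enuc = ints.nuclear_repulsion()
    eri = ints.eri

    # symmetric orthogonalization with removal of near-dependencies
    sval, svec = np.linalg.eigh(S)
    keep = sval > 1e-9
    X = svec[:, keep] / np.sqrt(sval[keep])

    def fock_of(D):
        J = np.einsum("ijkl,kl->ij", eri, D, optimize=True)
        K = np.einsum("ikjl,kl->ij", eri, D, optimize=True)
        return hcore + J - 0.5 * K

    def energy_of(D, F):
        return 0.5 * np.einsum("ij,ij->", D, hcore + F) + enuc

    if init_density is not None:
        D = init_density
    else:
        # core guess
        e, c = eigh(X.T @ hcore @ X)
        C = X @ c
        D = 2.0 * C[:, :nocc] @ C[:, :nocc].T

    W = lam = None
    if constraint is not None:
        W, lam = constraint

    fock_hist, err_hist, e_hist = [], [], []
    e_old = None
    shift = level_shift
    converged = False
    C = None
    mo_e = None
    for it in range(1, max_cycle + 1):
        F = fock_of(D)
        if W is not None:
            F_eff = F + lam * W
        else:
            F_eff = F
        err = F_eff @ D @ S - S @ D @ F_eff
        gnorm = np.max(np.abs(err))
        e_tot = energy_of(D, F)
        e_hist.append(e_tot)

        if e_old is not None and abs(e_tot - e_old) < conv_tol and gnorm < conv_tol_grad:
            converged = True
        e_old = e_tot

        fock_hist.append(F_eff)
        err_hist.append(X.T @ err @ X)
        if len(fock_hist) > 8:
            fock_hist.pop(0)
            err_hist.pop(0)
        F_use = _diis_extrapolate(fock_hist, err_hist) if len(fock_hist) > 1 else F_eff

        if shift > 0.0 and not converged:
            # shift virtual space to stabilize early iterations
            F_use = F_use + shift * (S - S @ D @ S / 2.0)
        Fp = X.T @ F_use @ X
        mo_e, c = eigh(Fp)
        C = X @ c
        D_new = 2.0 * C[:, :nocc] @ C[:, :nocc].T
        if converged:
            D = D_new
            break
        if shift > 0.0 and gnorm < 1e-3:
            shift = 0.0
        D = D_new
    else:
        it = max_cycle

    # final self-consistent quantities from the last orbitals
    F = fock_of(D)
    e_tot = energy_of(D, F)
    if not converged:
        raise SCFConvergenceError(
            f"SCF failed to converge in {max_cycle} cycles "
            f"(last dE={e_hist[-1] - e_hist[-2] if len(e_hist) > 1 else np.nan:.3e})",
            n_iter=max_cycle, energies=e_hist)

    return SCFSolution(
        energy=float(e_tot), e_nuc=float(enuc), mo_coeff=C, mo_energy=mo_e,
        density=D, n_occ=nocc, nbf=ints.nbf, converged=True, n_iter=it,
        n_electrons=nelec,
        metadata={"basis": ints.spec.name, "charge": charge,
                  "ghosts": tuple(ints.ghost_indices),
                  "constrained": constraint is not None})
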