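"""AO integral bundle over a (possibly ghost-augmented) molecule.

Ghost centers carry basis functions but no nuclear charge and no
electrons, which is how counterpoise / dimer-centered-basis monomer
calculations are realized.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from . import _md_kernels as mdk
from .basis import AOBasis, BasisSpec, build_ao_basis
from .geometry import Atom
from .periodic import BOHR_PER_ANGSTROM


@dataclass
class AOIntegrals:
    """One- and two-electron AO integrals for a fixed geometry and basis.

    ``real_atoms`` excludes ghosts; ``nuclear(subset)`` gives the
    attraction matrix for any subset of the real nuclei, enabling monomer
    electrostatic potentials in the dimer-centered basis.
    """

    atoms: list[Atom]
    ghost_indices: tuple[int, ...]
    spec: BasisSpec
    ao: AOBasis

    def __post_init__(self):
        self._S = None
        self._T = None
        self._eri = None
        self._vnuc = {}

    @property
    def nbf(self) -> int:
        return self.ao.nbf

    @property
    def real_indices(self) -> list[int]:
        return [i for i in range(len(self.atoms)) if i not in self.ghost_indices]

    def _st(self):
        if self._S is None and getattr(self, "_parent", None) is not None:
            self._S, self._T = self._parent._st()
        if self._S is None:
            self._S, self._T = mdk.overlap_kinetic(
                self.ao.centers, self.ao.lvec, self.ao.nprim,
                self.ao.exps, self.ao.coefs)
        return self._S, self._T

    @property
    def overlap(self) -> np.ndarray:
        return self._st()[0]

    @property
    def kinetic(self) -> np.ndarray:
        return self._st()[1]

    def nuclear(self, atom_indices: Sequence[int] | None = None) -> np.ndarray:
        """Nuclear-attraction matrix for the given real atoms (default: all)."""
        if atom_indices is None:
            atom_indices = self.real_indices
        key = tuple(sorted(atom_indices))
        if key not in self._vnuc:
            for i in key:
                if i in self.ghost_indices:
                    raise ValueError(f"atom {i} is a ghost center")
            ctr = np.array([self.atoms[i].position * BOHR_PER_ANGSTROM
                            for i in key]).reshape(-1, 3)
            chg = np.array([float(self.atoms[i].z) for i in key])
            self._vnuc[key] = mdk.nuclear_attraction(
                self.ao.centers, self.ao.lvec, self.ao.nprim,
                self.ao.exps, self.ao.coefs, ctr, chg)
        return self._vnuc[key]

    @property
    def eri(self) -> np.ndarray:
        if self._eri is None and getattr(self, "_parent", None) is not None:
            self._eri = self._parent.eri
        if self._eri is None:
            self._eri = mdk.eri_tensor(
                self.ao.centers, self.ao.lvec, self.ao.nprim,
                self.ao.exps, self.ao.coefs)
        return self._eri

    def dipole(self, origin_angstrom: np.ndarray) -> np.ndarray:
        """Electronic dipole integrals about the given origin, (3, nbf, nbf)."""
        origin = np.asarray(origin_angstrom, float) * BOHR_PER_ANGSTROM
        return mdk.dipole_integrals(
            self.ao.centers, self.ao.lvec, self.ao.nprim,
            self.ao.exps, self.ao.coefs, origin)

    def nuclear_repulsion(self, atom_indices: Sequence[int] | None = None) -> float:
        if atom_indices is None:
            atom_indices = self.real_indices
        idx = list(atom_indices)
        e = 0.0
        for a in range(len(idx)):
            for b in range(a):
                ia, ib = idx[a], idx[b]
                r = np.linalg.norm(self.atoms[ia].position -
                                   self.atoms[ib].position) * BOHR_PER_ANGSTROM
                e += self.atoms[ia].z * self.atoms[ib].z / r
        return e

    def with_ghosts(self, ghost_indices: Sequence[int]) -> "AOIntegrals":
        """A view over the same AO basis with a different ghost set.

        Cached overlap/kinetic/ERI arrays are shared (they do not depend on
        which centers are ghosts); only nuclear terms differ.
        """
        view = AOIntegrals(self.atoms, tuple(ghost_indices), self.spec, self.ao)
        view._S, view._T, view._eri = self._S, self._T, self._eri
        view._vnuc = self._vnuc  # keyed by atom subset; safe to share
        view._parent = self
        return view

    def coulomb(self, density: np.ndarray) -> np.ndarray:
        """J[D]_{mu nu} = sum_{ls} (mu nu|l s) D_{l s} for a total density."""
        return np.einsum("ijkl,kl->ij", self.eri, density, optimize=True)

    def exchange(self, density: np.ndarray) -> np.ndarray:
        """K[D]_{mu nu} = sum_{ls} (mu l|k nu)... standard RHF exchange build."""
        return np.einsum("ikjl,kl->ij", self.eri, density, optimize=True)


def ao_integrals(atoms: Sequence[Atom], spec: BasisSpec,
                 ghost_indices: Sequence[int] = ()) -> AOIntegrals:
    """Build the integral bundle for a molecule (lazy, cached per instance)."""
    ao = build_ao_basis(atoms, spec)
    return AOIntegrals(list(atoms), tuple(ghost_indices), spec, ao)
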