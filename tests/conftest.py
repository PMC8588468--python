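import numpy as np
import pytest

import ioneda as io
from ioneda.basis import BasisSpec
from ioneda.integrals import ao_integrals
from ioneda.scf import solve_scf


@pytest.fixture(scope="session")
def min_basis():
    return BasisSpec("min")


@pytest.fixture(scope="session")
def diffuse_basis():
    return BasisSpec("min", diffuse=True)


@pytest.fixture(scope="session")
def water_atoms():
    """Isolated rigid water monomer."""
    snap = io.generate_binary_complex("Cl-", 100.0)
    return [snap.atoms[i] for i in snap.waters[0].indices]


@pytest.fixture(scope="session")
def clw_snapshot():
    """Cl-...H2O binary complex at H-bond contact (quasi-linear)."""
    return io.generate_binary_complex("Cl-", 3.2)


@pytest.fixture(scope="session")
def clw_monomers(clw_snapshot, min_basis):
    """Dimer-centered-basis SCF solutions for the contact complex.

    Returns (ints, dimer, ion, water, idx_ion, idx_water); shared across
    the SAPT-layer tests to keep the suite fast.
    """
    snap = clw_snapshot
    ion = snap.ion
    wc = snap.water_cluster_fragment()
    ia, ib = list(ion.indices), list(wc.indices)
    ints = ao_integrals(snap.atoms, min_basis)
    sol_d = solve_scf(integrals=ints, charge=-1)
    sol_a = solve_scf(integrals=ints.with_ghosts(ib), charge=-1)
    sol_b = solve_scf(integrals=ints.with_ghosts(ia), charge=0)
    return ints, sol_d, sol_a, sol_b, ia, ib
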