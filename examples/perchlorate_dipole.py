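"""Dipole moment of tetrahedral perchlorate about the center of nuclear
charge.

For a charged species the dipole depends on the origin; the center of
nuclear charge makes it translation-invariant, and Td symmetry then
forces it to vanish exactly.  A chlorite-like bent ClO2- geometry is
included for contrast (nonzero dipole).
"""

import numpy as np

from ioneda.basis import BasisSpec
from ioneda.geometry import atom
from ioneda.integrals import ao_integrals
from ioneda.sapt import compute_dipole
from ioneda.scf import solve_scf

basis = BasisSpec("min")

d = 1.45 / np.sqrt(3.0)
clo4 = [atom("Cl", [0, 0, 0])] + [
    atom("O", [sx * d, sy * d, sz * d])
    for sx, sy, sz in [(1, 1, 1), (1, -1, -1), (-1, 1, -1), (-1, -1, 1)]]
ints = ao_integrals(clo4, basis)
sol = solve_scf(integrals=ints, charge=-1)
mag, _ = compute_dipole(clo4, sol.density, ints)
print(f"ClO4- (Td, r = 1.45 A): |mu| = {mag:.2f} D  "
      "(symmetry-forced zero)")

ang = np.radians(111.0)
clo2 = [atom("Cl", [0, 0, 0]),
        atom("O", [1.57 * np.sin(ang / 2), 0, 1.57 * np.cos(ang / 2)]),
        atom("O", [-1.57 * np.sin(ang / 2), 0, 1.57 * np.cos(ang / 2)])]
ints2 = ao_integrals(clo2, basis)
sol2 = solve_scf(integrals=ints2, charge=-1)
mag2, vec2 = compute_dipole(clo2, sol2.density, ints2)
print(f"ClO2- (bent):           |mu| = {mag2:.2f} D along "
      f"[{vec2[0]:+.2f} {vec2[1]:+.2f} {vec2[2]:+.2f}]")
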