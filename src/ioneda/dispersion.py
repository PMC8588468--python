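"""Damped pairwise interfragment dispersion, -f6 C6/R^6 - f8 C8/R^8.

Atom-atom C6/C8 coefficients depend only on the atomic number; damping is
Tang-Toennies with a range parameter set by the pair's van der Waals
radii.  The shipped coefficient table carries literature-magnitude
free-atom values and is meant to be replaced by a fitted set (the model
form, not the numbers, is what downstream code relies on); the EDA
records which parameter set produced E_disp.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .geometry import Atom, Fragment
from .periodic import BOHR_PER_ANGSTROM, HARTREE_TO_KCAL, VDW_RADII

# free-atom-scale C6 (hartree bohr^6); C8 ~ 35 * C6 * r_vdw-ish scaling
DEFAULT_C6 = {
    "H": 6.5, "C": 46.6, "N": 24.2, "O": 15.6, "F": 9.5,
    "S": 134.0, "Cl": 94.6, "Br": 162.0, "I": 385.0,
}
DEFAULT_C8 = {
    "H": 124.0, "C": 1103.0, "N": 535.0, "O": 316.0, "F": 166.0,
    "S": 4114.0, "Cl": 2618.0, "Br": 5174.0, "I": 14522.0,
}


@dataclass(frozen=True)
class DispersionParams:
    """Per-element C6/C8 (a.u.) and damping radii (angstrom)."""

    c6: dict = field(default_factory=lambda: dict(DEFAULT_C6))
    c8: dict = field(default_factory=lambda: dict(DEFAULT_C8))
    radii: dict = field(default_factory=lambda: dict(VDW_RADII))
    damping: str = "tang-toennies"
    name: str = "builtin-free-atom"

    def __post_init__(self):
        for table in (self.c6, self.c8):
            for el, v in table.items():
                if v < 0:
                    raise ValueError(f"negative dispersion coefficient for {el}")

    @classmethod
    def from_file(cls, path) -> "DispersionParams":
        """Plain columnar text: ``element  C6  C8  radius`` per line."""
        c6, c8, radii = {}, {}, {}
        with open(path) as fh:
            for line in fh:
                line = line.split("#")[0].strip()
                if not line:
                    continue
                el, a, b, r = line.split()
                c6[el] = float(a)
                c8[el] = float(b)
                radii[el] = float(r)
        return cls(c6, c8, radii, name=str(path))


def tang_toennies(n: int, x: float) -> float:
    """Incomplete-gamma damping f_n(x) = 1 - e^-x sum_{k<=n} x^k/k!."""
    s = 0.0
    term = 1.0
    for k in range(n + 1):
        if k > 0:
            term *= x / k
        s += term
    return 1.0 - math.exp(-x) * s


def pairwise_dispersion(atoms: Sequence[Atom],
                        fragments: Sequence[Fragment],
                        params: DispersionParams | None = None) -> float:
    """Interfragment dispersion energy in kcal/mol (<= 0).

    Sums damped -C6/R^6 - C8/R^8 over atom pairs belonging to different
    fragments; intrafragment pairs are excluded.
    """
    if params is None:
        params = DispersionParams()
    frag_of = {}
    for k, fr in enumerate(fragments):
        for i in fr.indices:
            frag_of[i] = k
    for a in atoms:
        if a.symbol not in params.c6 or a.symbol not in params.c8 \
                or a.symbol not in params.radii:
            raise KeyError(f"no dispersion parameters for element {a.symbol}")
    e = 0.0
    idx = sorted(frag_of)
    for ii in range(len(idx)):
        for jj in range(ii):
            i, j = idx[ii], idx[jj]
            if frag_of[i] == frag_of[j]:
                continue
            ai, aj = atoms[i], atoms[j]
            r = np.linalg.norm(ai.position - aj.position) * BOHR_PER_ANGSTROM
            c6 = math.sqrt(params.c6[ai.symbol] * params.c6[aj.symbol])
            c8 = math.sqrt(params.c8[ai.symbol] * params.c8[aj.symbol])
            # damping range from the pair's vdW contact distance
            b = 2.8 / ((params.radii[ai.symbol] + params.radii[aj.symbol])
                       * BOHR_PER_ANGSTROM) * 2.0
            x = b * r
            e -= tang_toennies(6, x) * c6 / r ** 6
            e -= tang_toennies(8, x) * c8 / r ** 8
    return float(e * HARTREE_TO_KCAL)
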