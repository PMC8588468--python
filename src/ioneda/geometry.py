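"""Molecular geometries, fragment bookkeeping and XYZ file I/O.

An ion-water system is described as a list of :class:`Atom` plus a set of
:class:`Fragment` index groups (the ion, and one fragment per water or a
single fragment for the whole water cluster).  Slab trajectories are lists
of :class:`TrajectoryFrame`; carved snapshots are :class:`ClusterSnapshot`.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

from .periodic import MASS, SYMBOLS, mass_of, z_of


class ParseError(ValueError):
    """Raised for malformed structure files; carries the offending line."""


class CompositionError(ValueError):
    """Raised when atoms cannot be partitioned into ion + rigid waters."""


@dataclass(frozen=True)
class Atom:
    symbol: str
    z: int
    position: np.ndarray  # angstrom, shape (3,)

    def __post_init__(self):
        if self.z < 1:
            raise ValueError(f"atomic number must be >= 1, got {self.z}")
        if SYMBOLS[self.z] != self.symbol:
            raise ValueError(f"symbol {self.symbol!r} inconsistent with Z={self.z}")
        object.__setattr__(self, "position", np.asarray(self.position, dtype=float))


def atom(symbol: str, xyz: Sequence[float]) -> Atom:
    """Convenience constructor resolving Z from the element symbol."""
    return Atom(symbol, z_of(symbol), np.asarray(xyz, dtype=float))


@dataclass(frozen=True)
class Fragment:
    """A named group of atom indices with integer formal charge.

    The reference electron count ``n_electrons`` is the number of electrons
    the isolated fragment carries: sum(Z) - formal charge.
    """

    label: str  # "ion" | "water" | "water_cluster"
    indices: tuple[int, ...]
    charge: int

    def n_electrons(self, atoms: Sequence[Atom]) -> int:
        return int(sum(atoms[i].z for i in self.indices) - self.charge)


@dataclass
class TrajectoryFrame:
    atoms: list[Atom]
    box: np.ndarray | None  # angstrom, shape (3,) or None for isolated systems
    time_ps: float = 0.0
    frame_id: int = 0

    def __post_init__(self):
        if self.box is not None:
            self.box = np.asarray(self.box, dtype=float)
            if np.any(self.box <= 0):
                raise ValueError("box lengths must be positive")

    def coords(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms])

    def masses(self) -> np.ndarray:
        return np.array([mass_of(a.symbol) for a in self.atoms])


@dataclass
class ClusterSnapshot:
    """An ion with its carved water shells.

    environment is "bulk", "interface" or "unassigned".
    """

    atoms: list[Atom]
    ion: Fragment
    waters: list[Fragment]
    environment: str = "unassigned"
    source_frame: int = -1

    def __post_init__(self):
        for w in self.waters:
            syms = sorted(self.atoms[i].symbol for i in w.indices)
            if syms != ["H", "H", "O"]:
                raise ValueError(f"water fragment {w.indices} is not H2O: {syms}")

    @property
    def n_waters(self) -> int:
        return len(self.waters)

    def water_cluster_fragment(self) -> Fragment:
        """All waters merged into a single monomer for the dimer framing."""
        idx = tuple(i for w in self.waters for i in w.indices)
        return Fragment("water_cluster", idx, 0)


def center_of_nuclear_charge(atoms: Sequence[Atom]) -> np.ndarray:
    """Nuclear-charge-weighted centroid, sum(Z_i r_i)/sum(Z_i), in angstrom."""
    if len(atoms) == 0:
        raise ValueError("need at least one atom")
    zs = np.array([a.z for a in atoms], dtype=float)
    pos = np.array([a.position for a in atoms])
    return (zs[:, None] * pos).sum(axis=0) / zs.sum()


def center_of_mass(atoms: Sequence[Atom]) -> np.ndarray:
    ms = np.array([mass_of(a.symbol) for a in atoms])
    pos = np.array([a.position for a in atoms])
    return (ms[:, None] * pos).sum(axis=0) / ms.sum()


# ---------------------------------------------------------------------------
# XYZ / extended-XYZ I/O
# ---------------------------------------------------------------------------

_BOX_RE = re.compile(r'box="([^"]+)"|Lattice="([^"]+)"', re.IGNORECASE)
_KV_RE = re.compile(r'(\w+)=("[^"]*"|\S+)')


def _parse_comment(comment: str) -> tuple[np.ndarray | None, float | None]:
    """Extract box lengths and time from an extended-XYZ comment line.

    Recognizes ``box="Lx Ly Lz"`` and the orthorhombic case of
    ``Lattice="ax 0 0 0 by 0 0 0 cz"``; ``time=...`` in ps.
    """
    box = None
    time = None
    m = _BOX_RE.search(comment)
    if m:
        vals = [float(x) for x in (m.group(1) or m.group(2)).split()]
        if len(vals) == 3:
            box = np.array(vals)
        elif len(vals) == 9:
            box = np.array([vals[0], vals[4], vals[8]])
    for key, val in _KV_RE.findall(comment):
        if key.lower() == "time":
            time = float(val.strip('"'))
    return box, time


def read_xyz(path) -> list[TrajectoryFrame]:
    """Read a (multi-frame, extended-)XYZ file.

    Returns frames in file order with ids 0, 1, ...; positions in angstrom.
    The comment line may carry ``box="Lx Ly Lz"`` (or an orthorhombic
    Lattice) and ``time=<ps>``; frames without a box are isolated clusters.
    """
    with open(path) as fh:
        lines = fh.readlines()
    frames: list[TrajectoryFrame] = []
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            natoms = int(lines[i].split()[0])
        except (ValueError, IndexError):
            raise ParseError(f"{path}: line {i + 1}: expected atom count, got "
                             f"{lines[i].strip()!r}")
        if i + 1 + natoms >= len(lines) + 1 and natoms > 0:
            pass
        comment = lines[i + 1] if i + 1 < len(lines) else ""
        box, time = _parse_comment(comment)
        atoms = []
        for j in range(natoms):
            k = i + 2 + j
            if k >= len(lines) or not lines[k].strip():
                raise ParseError(f"{path}: line {k + 1}: frame declares {natoms} "
                                 f"atoms but the file ends early")
            parts = lines[k].split()
            if len(parts) < 4:
                raise ParseError(f"{path}: line {k + 1}: expected 'El x y z'")
            sym = parts[0]
            try:
                xyz = [float(p) for p in parts[1:4]]
                atoms.append(atom(sym, xyz))
            except (ValueError, KeyError):
                raise ParseError(f"{path}: line {k + 1}: malformed atom record "
                                 f"{lines[k].strip()!r}")
        frames.append(TrajectoryFrame(atoms, box,
                                      time_ps=time if time is not None else float(len(frames)),
                                      frame_id=len(frames)))
        i += 2 + natoms
    if not frames:
        raise ParseError(f"{path}: no frames found")
    return frames


def write_xyz(path, frames: Iterable[TrajectoryFrame | ClusterSnapshot],
              comment: str = "") -> None:
    """Write frames (or snapshots) as multi-frame extended XYZ."""
    with open(path, "w") as fh:
        for fr in frames:
            atoms = fr.atoms
            parts = [comment] if comment else []
            if isinstance(fr, TrajectoryFrame):
                if fr.box is not None:
                    parts.append('box="%.10g %.10g %.10g"' % tuple(fr.box))
                parts.append(f'time={fr.time_ps:.6g}')
            fh.write(f"{len(atoms)}\n{' '.join(parts)}\n")
            for a in atoms:
                fh.write(f"{a.symbol:<3s} {a.position[0]:18.10f} "
                         f"{a.position[1]:18.10f} {a.position[2]:18.10f}\n")


def write_fragment_map(path, atoms: Sequence[Atom], ion: Fragment,
                       waters: Sequence[Fragment]) -> None:
    """Plain-text sidecar: one row per atom, ``index  element  fragment``."""
    labels = {}
    for i in ion.indices:
        labels[i] = "ion"
    for k, w in enumerate(waters):
        for i in w.indices:
            labels[i] = f"water{k}"
    with open(path, "w") as fh:
        fh.write("# index element fragment\n")
        for i, a in enumerate(atoms):
            fh.write(f"{i:6d} {a.symbol:<3s} {labels.get(i, 'unassigned')}\n")


# ---------------------------------------------------------------------------
# Fragment detection
# ---------------------------------------------------------------------------

# element composition of supported monovalent anions
ION_COMPOSITIONS = {
    "Cl-": {"Cl": 1}, "Br-": {"Br": 1}, "I-": {"I": 1}, "F-": {"F": 1},
    "CN-": {"C": 1, "N": 1}, "OCN-": {"O": 1, "C": 1, "N": 1},
    "SCN-": {"S": 1, "C": 1, "N": 1},
    "NO2-": {"N": 1, "O": 2}, "NO3-": {"N": 1, "O": 3},
    "ClO-": {"Cl": 1, "O": 1}, "ClO2-": {"Cl": 1, "O": 2},
    "ClO3-": {"Cl": 1, "O": 3}, "ClO4-": {"Cl": 1, "O": 4},
}

OH_CUTOFF = 1.2  # angstrom; separates covalent O-H (~0.96) from H-bonds (>1.5)


def detect_fragments(atoms: Sequence[Atom], ion_species: str,
                     oh_cutoff: float = OH_CUTOFF,
                     ) -> tuple[Fragment, list[Fragment]]:
    """Partition atoms into one ion fragment and rigid H2O fragments.

    Each water is an O with its two nearest H within ``oh_cutoff``; the
    remaining atoms must match the ion's element composition.  Ion oxygens
    (e.g. in ClO4-) are distinguished from water oxygens by having fewer
    than two H neighbours within the cutoff.
    """
    if ion_species not in ION_COMPOSITIONS:
        raise KeyError(f"unknown ion species {ion_species!r}; known: "
                       f"{sorted(ION_COMPOSITIONS)}")
    comp = dict(ION_COMPOSITIONS[ion_species])
    pos = np.array([a.position for a in atoms])
    o_idx = [i for i, a in enumerate(atoms) if a.symbol == "O"]
    h_idx = [i for i, a in enumerate(atoms) if a.symbol == "H"]

    # match each O to H atoms within the covalent cutoff
    used_h: set[int] = set()
    waters: list[tuple[int, int, int]] = []
    bare_o: list[int] = []
    for o in o_idx:
        if h_idx:
            d = np.linalg.norm(pos[h_idx] - pos[o], axis=1)
            near = [h for h, dist in zip(h_idx, d)
                    if dist <= oh_cutoff and h not in used_h]
            near.sort(key=lambda h: np.linalg.norm(pos[h] - pos[o]))
        else:
            near = []
        if len(near) >= 2:
            waters.append((o, near[0], near[1]))
            used_h.update(near[:2])
        else:
            bare_o.append(o)

    leftover = [i for i, a in enumerate(atoms)
                if a.symbol not in ("O", "H")] + bare_o
    leftover += [h for h in h_idx if h not in used_h]

    # bare O atoms may belong to the ion (oxyanions); stray H may not
    got = {}
    for i in leftover:
        got[atoms[i].symbol] = got.get(atoms[i].symbol, 0) + 1
    if got != comp:
        # maybe too many waters were formed and the ion needs an O back:
        # not attempted; report the mismatch
        raise CompositionError(
            f"atoms left after water detection {got} do not match the "
            f"composition of {ion_species} {comp}")

    ion = Fragment("ion", tuple(sorted(leftover)), -1)
    water_frags = [Fragment("water", tuple(sorted(w)), 0)
                   for w in sorted(waters)]
    return ion, water_frags
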