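"""Seeded generators for every input the pipeline consumes.

Two families of structures are produced, emulating the statistical shape
of slab molecular dynamics without requiring an MD engine:

* periodic water-slab trajectories at a target bulk density with an ion
  placed at a controllable depth below the upper liquid/vacuum interface;
* X-(H2O)n cluster ensembles with quasi-linear ion-water hydrogen bonds
  and snapshot-to-snapshot geometric jitter.

Waters are rigid at the experimental monomer geometry (r_OH = 0.9572 A,
HOH angle 104.52 deg); placement is geometric with rejection sampling,
not force-field relaxed.  Every generator is a pure function of its spec,
including the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .geometry import (Atom, ClusterSnapshot, Fragment, TrajectoryFrame, atom,
                       detect_fragments)
from .periodic import mass_of

R_OH = 0.9572          # angstrom
HOH_DEG = 104.52
WATER_MASS = 2 * mass_of("H") + mass_of("O")
AVOGADRO = 6.02214076e23

# monatomic vs linear/planar model geometries for supported ions (angstrom)
ION_GEOMETRIES = {
    "Cl-": [("Cl", (0.0, 0.0, 0.0))],
    "Br-": [("Br", (0.0, 0.0, 0.0))],
    "I-": [("I", (0.0, 0.0, 0.0))],
    "F-": [("F", (0.0, 0.0, 0.0))],
    "CN-": [("C", (0.0, 0.0, 0.0)), ("N", (0.0, 0.0, 1.18))],
    "SCN-": [("S", (0.0, 0.0, -1.63)), ("C", (0.0, 0.0, 0.0)),
             ("N", (0.0, 0.0, 1.18))],
    "OCN-": [("O", (0.0, 0.0, -1.17)), ("C", (0.0, 0.0, 0.0)),
             ("N", (0.0, 0.0, 1.21))],
}


def water_template() -> np.ndarray:
    """Rigid water coordinates (O, H, H), O at origin, in angstrom."""
    half = math.radians(HOH_DEG / 2.0)
    return np.array([
        [0.0, 0.0, 0.0],
        [R_OH * math.sin(half), 0.0, R_OH * math.cos(half)],
        [-R_OH * math.sin(half), 0.0, R_OH * math.cos(half)],
    ])


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix (quaternion method)."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


def _place_water(o_pos: np.ndarray, rot: np.ndarray) -> list[Atom]:
    tpl = water_template() @ rot.T
    return [atom("O", o_pos + tpl[0]), atom("H", o_pos + tpl[1]),
            atom("H", o_pos + tpl[2])]


@dataclass(frozen=True)
class SlabSpec:
    """Water slab with an ion at a controlled depth.

    ``depth`` is the ion's distance below the upper slab surface in
    angstrom; ``density`` is the target bulk mass density in g/cm^3.
    """

    box: tuple[float, float, float] = (31.3, 31.3, 156.7)
    slab_thickness: float = 30.0
    density: float = 0.997
    ion: str = "Cl-"
    depth: float = 10.0
    n_frames: int = 5
    frame_spacing_ps: float = 10.0
    jitter: float = 0.08       # angstrom, rigid-body per frame
    seed: int = 0

    def __post_init__(self):
        if self.slab_thickness >= self.box[2]:
            raise ValueError("slab thickness must be below the box z-length")
        if self.density <= 0:
            raise ValueError("density must be positive")


@dataclass(frozen=True)
class ClusterSpec:
    """Hydrogen-bonded X-(H2O)n snapshot ensemble."""

    ion: str = "Cl-"
    n_first_shell: int = 4
    n_second_shell: int = 0
    hbond_range: tuple[float, float] = (2.1, 2.4)   # X...H, angstrom
    angular_spread_deg: float = 15.0
    jitter: float = 0.1        # angstrom
    n_snapshots: int = 51
    seed: int = 0

    def __post_init__(self):
        if self.n_first_shell < 0 or self.n_second_shell < 0:
            raise ValueError("shell counts must be non-negative")
        lo, hi = self.hbond_range
        if not (0 < lo <= hi):
            raise ValueError("H-bond distance range must be positive/ordered")


def ion_atoms(species: str, center: np.ndarray | None = None) -> list[Atom]:
    if species not in ION_GEOMETRIES:
        raise KeyError(f"no model geometry for ion {species!r}")
    c = np.zeros(3) if center is None else np.asarray(center, float)
    return [atom(sym, c + np.asarray(xyz)) for sym, xyz in
            ION_GEOMETRIES[species]]


def generate_slab(spec: SlabSpec) -> list[TrajectoryFrame]:
    """Periodic slab frames: rigid waters at the target density in the
    central slab region, vacuum elsewhere, the ion at the requested depth.

    Water oxygens are rejection-sampled with a 2.4 A O-O exclusion; the
    base configuration is fixed by the seed and each frame differs by
    resampled rigid-body jitter, emulating thermal decorrelation.
    """
    rng = np.random.default_rng(spec.seed)
    lx, ly, lz = spec.box
    z_lo = 0.5 * (lz - spec.slab_thickness)
    z_hi = 0.5 * (lz + spec.slab_thickness)
    vol_cm3 = lx * ly * spec.slab_thickness * 1e-24
    n_w = int(round(spec.density * vol_cm3 * AVOGADRO / WATER_MASS))

    o_pos = np.empty((n_w, 3))
    placed = 0
    attempts = 0
    ion_center = np.array([lx / 2, ly / 2, z_hi - spec.depth])
    while placed < n_w:
        attempts += 1
        if attempts > 500 * n_w:
            raise RuntimeError(
                f"could not reach density {spec.density} g/cm^3: placed "
                f"{placed}/{n_w} waters")
        cand = rng.uniform([0, 0, z_lo], [lx, ly, z_hi])
        d = o_pos[:placed] - cand
        d[:, 0] -= lx * np.round(d[:, 0] / lx)
        d[:, 1] -= ly * np.round(d[:, 1] / ly)
        if placed and (np.einsum("ij,ij->i", d, d) < 2.4 ** 2).any():
            continue
        if np.linalg.norm(cand - ion_center) < 3.0:
            continue
        o_pos[placed] = cand
        placed += 1
    base_rots = [_random_rotation(rng) for _ in range(n_w)]

    frames = []
    for f in range(spec.n_frames):
        atoms = ion_atoms(spec.ion, ion_center)
        for k in range(n_w):
            shift = rng.normal(scale=spec.jitter, size=3) if spec.jitter else 0.0
            wob = _random_rotation(rng) if spec.jitter else np.eye(3)
            # small orientational wobble: blend toward identity
            rot = base_rots[k] if spec.jitter == 0 else base_rots[k] @ wob
            atoms += _place_water(o_pos[k] + shift, rot)
        frames.append(TrajectoryFrame(atoms, np.array(spec.box),
                                      time_ps=f * spec.frame_spacing_ps,
                                      frame_id=f))
    return frames


def generate_binary_complex(ion: str, r: float, theta_deg: float = 0.0,
                            ) -> ClusterSnapshot:
    """Single-water fixture: water O at distance ``r`` from the ion site
    along +z, one O-H directed at the ion with H-bond bend ``theta_deg``.

    theta = 0 gives the quasi-linear X...H-O motif; the construction is
    deterministic and exact.
    """
    ion_list = ion_atoms(ion)
    anchor = np.zeros(3)
    if r <= 1.5:
        raise ValueError("r must exceed contact distance")
    o_pos = anchor + np.array([0.0, 0.0, r])
    th = math.radians(theta_deg)
    # H on the ion side of O, tilted by theta in the xz-plane
    h1 = o_pos + R_OH * np.array([math.sin(th), 0.0, -math.cos(th)])
    # second H completes the HOH angle in-plane, on the side that makes
    # theta -> -theta an exact mirror pair
    ang = math.radians(HOH_DEG) * (1.0 if theta_deg >= 0 else -1.0)
    h2 = o_pos + R_OH * np.array([math.sin(th - ang), 0.0, -math.cos(th - ang)])
    atoms = ion_list + [atom("O", o_pos), atom("H", h1), atom("H", h2)]
    ion_frag, waters = detect_fragments(atoms, ion)
    return ClusterSnapshot(atoms, ion_frag, waters)


def _fibonacci_directions(n: int) -> np.ndarray:
    k = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * k / n)
    theta = np.pi * (1 + 5 ** 0.5) * k
    return np.stack([np.sin(phi) * np.cos(theta),
                     np.sin(phi) * np.sin(theta), np.cos(phi)], axis=1)


def generate_cluster_ensemble(spec: ClusterSpec) -> list[ClusterSnapshot]:
    """Seeded ensemble of H-bonded ion-water clusters.

    First-shell waters donate one H toward the ion with the X...H distance
    drawn from ``hbond_range`` and the O-H...X axis tilted within the
    angular spread; second-shell waters H-bond to first-shell oxygens.
    Rigid-body Gaussian jitter is applied per snapshot.
    """
    rng = np.random.default_rng(spec.seed)
    snapshots = []
    base_dirs = _fibonacci_directions(max(spec.n_first_shell, 1))
    lo, hi = spec.hbond_range
    center = 0.5 * (lo + hi)

    def sample_r():
        # truncated Gaussian: radial spread tracks the jitter parameter
        # while X...H stays strictly inside the stated range
        if spec.jitter == 0 or hi == lo:
            return center
        for _ in range(200):
            r = rng.normal(center, spec.jitter)
            if lo <= r <= hi:
                return r
        return center

    for isnap in range(spec.n_snapshots):
        for attempt in range(60):
            atoms = ion_atoms(spec.ion)
            anchor = np.zeros(3)
            first_o = []
            ok = True
            for k in range(spec.n_first_shell):
                d = base_dirs[k] + rng.normal(scale=0.08, size=3)
                d /= np.linalg.norm(d)
                r_xh = sample_r()
                h_pos = anchor + r_xh * d
                # O sits one O-H bond beyond H, tilted off-axis
                tilt = math.radians(rng.uniform(0, spec.angular_spread_deg))
                azim = rng.uniform(0, 2 * math.pi)
                perp = np.cross(d, [0.0, 0.0, 1.0])
                if np.linalg.norm(perp) < 1e-8:
                    perp = np.cross(d, [0.0, 1.0, 0.0])
                perp /= np.linalg.norm(perp)
                perp2 = np.cross(d, perp)
                off = (math.cos(azim) * perp + math.sin(azim) * perp2)
                oh_dir = math.cos(tilt) * d + math.sin(tilt) * off
                o_pos = h_pos + R_OH * oh_dir
                # complete the water: second H from the template HOH angle
                ang = math.radians(HOH_DEG)
                u = -oh_dir
                h2_dir = (math.cos(ang) * u
                          + math.sin(ang) * _any_perp(u, rng))
                h2 = o_pos + R_OH * h2_dir
                w_atoms = [atom("O", o_pos), atom("H", h_pos), atom("H", h2)]
                if _clashes(atoms, w_atoms):
                    ok = False
                    break
                atoms += w_atoms
                first_o.append(o_pos)
            if ok:
                for k in range(spec.n_second_shell):
                    parent = first_o[k % len(first_o)]
                    away = parent - anchor
                    away /= np.linalg.norm(away)
                    d2 = away + rng.normal(scale=0.25, size=3)
                    d2 /= np.linalg.norm(d2)
                    o2 = parent + 2.8 * d2 + rng.normal(scale=spec.jitter, size=3)
                    rot = _random_rotation(rng)
                    w_atoms = _place_water(o2, rot)
                    if _clashes(atoms, w_atoms):
                        ok = False
                        break
                    atoms += w_atoms
            if not ok:
                continue
            ion_frag, waters = detect_fragments(atoms, spec.ion)
            snapshots.append(ClusterSnapshot(atoms, ion_frag, waters,
                                             source_frame=isnap))
            break
        else:
            raise RuntimeError("steric placement failed after 60 attempts")
    return snapshots


def _any_perp(u: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    v = np.cross(u, [0.0, 0.0, 1.0])
    if np.linalg.norm(v) < 1e-8:
        v = np.cross(u, [0.0, 1.0, 0.0])
    v /= np.linalg.norm(v)
    w = np.cross(u, v)
    a = rng.uniform(0, 2 * math.pi)
    return math.cos(a) * v + math.sin(a) * w


def _clashes(existing: Sequence[Atom], new: Sequence[Atom],
             cutoff: float = 1.9) -> bool:
    for b in new:
        for a in existing:
            if np.linalg.norm(a.position - b.position) < cutoff:
                return True
    return False
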