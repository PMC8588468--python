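"""Interface location and snapshot classification for water-slab
trajectories.

The liquid/vacuum interface is defined by the Gibbs dividing surface
(GDS): the z position where a hyperbolic-tangent fit of the water mass
density profile crosses half the bulk density.  Ion snapshots whose
center of mass lies no more than a cutoff (default 3 A) below the nearer
GDS are classified as interfacial; deeper ions are bulk.  Two-shell
clusters are carved by including every water whose oxygen lies within a
configurable cutoff of any ion atom, whole molecules, minimum-image
unwrapped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import curve_fit

from .geometry import (Atom, ClusterSnapshot, Fragment, TrajectoryFrame,
                       center_of_mass, detect_fragments)
from .periodic import mass_of

INTERFACE_CUTOFF = 3.0   # angstrom below the GDS
TWO_SHELL_CUTOFF = 6.0   # angstrom, ion heavy atom -> water O (configurable)

BULK = "bulk"
INTERFACE = "interface"
EJECTED = "ejected"


class NoInterfaceError(ValueError):
    pass


@dataclass
class DensityProfile:
    axis: str
    bin_centers: np.ndarray    # angstrom
    density: np.ndarray        # g/cm^3
    n_frames: int
    box: np.ndarray

    def __post_init__(self):
        if np.any(self.density < 0):
            raise ValueError("density must be non-negative")


@dataclass
class GDSResult:
    z_lower: float             # angstrom
    z_upper: float
    bulk_density: float        # g/cm^3
    width_lower: float         # tanh width d, angstrom
    width_upper: float
    residual: float

    def __post_init__(self):
        if self.bulk_density <= 0:
            raise ValueError("bulk density must be positive")
        if self.z_lower >= self.z_upper:
            raise ValueError("lower GDS must lie below upper GDS")


@dataclass
class RDF:
    r: np.ndarray
    g: np.ndarray
    center_selection: str
    target_selection: str
    n_frames: int

    def __post_init__(self):
        if np.any(self.g < -1e-12):
            raise ValueError("g(r) must be non-negative")


_AMU_PER_CM3_TO_G = 1.0 / 6.02214076e23
_A3_TO_CM3 = 1e-24


def mass_density_profile(frames: Sequence[TrajectoryFrame], axis: str = "z",
                         bin_width: float = 1.0) -> DensityProfile:
    """Frame-averaged mass density along one box axis, g/cm^3."""
    if not frames:
        raise ValueError("no frames given")
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    ax = {"x": 0, "y": 1, "z": 2}[axis]
    box = frames[0].box
    if box is None:
        raise ValueError("frames must carry a periodic box")
    for fr in frames:
        if fr.box is None or not np.allclose(fr.box, box):
            raise ValueError("all frames must share the same box")
    length = box[ax]
    nbins = max(int(round(length / bin_width)), 1)
    edges = np.linspace(0.0, length, nbins + 1)
    cross_area = box.prod() / length
    hist = np.zeros(nbins)
    for fr in frames:
        coords = fr.coords()[:, ax] % length
        masses = fr.masses()
        idx = np.minimum((coords / (length / nbins)).astype(int), nbins - 1)
        np.add.at(hist, idx, masses)
    hist /= len(frames)
    bin_vol_cm3 = cross_area * (length / nbins) * _A3_TO_CM3
    density = hist * _AMU_PER_CM3_TO_G / bin_vol_cm3
    centers = 0.5 * (edges[:-1] + edges[1:])
    return DensityProfile(axis, centers, density, len(frames), box)


def _tanh_face(z, z_gds, d, rho_b):
    return 0.5 * rho_b * (1.0 - np.tanh((z - z_gds) / d))


def locate_gds(profile: DensityProfile) -> GDSResult:
    """Fit each slab face with a tanh profile and return the half-density
    crossings.  Raises NoInterfaceError for a fully periodic liquid."""
    z = profile.bin_centers
    rho = profile.density
    occupied = rho > 0.05 * rho.max()
    if occupied.all() or rho.max() <= 0:
        raise NoInterfaceError("density profile shows no decay to vacuum")
    # bulk density from the central plateau of the occupied region
    zc = z[occupied]
    z_mid = 0.5 * (zc.min() + zc.max())
    half_span = 0.25 * (zc.max() - zc.min())
    plateau = occupied & (np.abs(z - z_mid) < half_span)
    rho_b = float(rho[plateau].mean())
    if rho_b <= 0:
        raise NoInterfaceError("no liquid plateau found")

    results = {}
    resid = 0.0
    for face, sel in (("upper", z >= z_mid), ("lower", z <= z_mid)):
        zz = z[sel]
        rr = rho[sel]
        if face == "lower":
            # mirror so the density decays with increasing coordinate
            zz = (2 * z_mid - zz)[::-1]
            rr = rr[::-1]
        # initial guess: crossing of rho_b/2
        below = np.where(rr < 0.5 * rho_b)[0]
        z0 = zz[below[0]] if len(below) else zz[-1]
        try:
            popt, _ = curve_fit(_tanh_face, zz, rr, p0=[z0, 1.5, rho_b],
                                maxfev=10000)
        except RuntimeError as exc:
            raise NoInterfaceError(f"tanh fit failed on {face} face: {exc}")
        z_gds, d, rb = popt
        if face == "lower":
            z_gds = 2 * z_mid - z_gds
        results[face] = (float(z_gds), abs(float(d)), float(rb))
        resid += float(((rr - _tanh_face(zz, *popt)) ** 2).sum())
    (zu, du, _), (zl, dl, _) = results["upper"], results["lower"]
    return GDSResult(z_lower=zl, z_upper=zu, bulk_density=rho_b,
                     width_lower=dl, width_upper=du, residual=resid)


def classify_environment(ion_z: float, gds: GDSResult,
                         cutoff: float = INTERFACE_CUTOFF) -> str:
    """"interface" if the depth below the nearer GDS is <= cutoff
    (inclusive), "bulk" if deeper, "ejected" if outside the liquid."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    depth = min(gds.z_upper - ion_z, ion_z - gds.z_lower)
    if depth < 0:
        return EJECTED
    return INTERFACE if depth <= cutoff else BULK


def minimum_image(vec: np.ndarray, box: np.ndarray | None) -> np.ndarray:
    if box is None:
        return vec
    return vec - box * np.round(vec / box)


def carve_two_shell_cluster(frame: TrajectoryFrame, ion: Fragment,
                            r_cut: float = TWO_SHELL_CUTOFF,
                            ion_species: str | None = None,
                            ) -> ClusterSnapshot:
    """Extract the ion plus all waters whose O lies within ``r_cut`` of
    any ion atom (minimum image), unwrapped to a contiguous cluster."""
    if r_cut <= 0:
        raise ValueError("r_cut must be positive")
    atoms = frame.atoms
    box = frame.box
    ion_pos = np.array([atoms[i].position for i in ion.indices])
    ion_set = set(ion.indices)

    # group non-ion atoms into waters: O followed by its two H
    others = [i for i in range(len(atoms)) if i not in ion_set]
    o_list = [i for i in others if atoms[i].symbol == "O"]
    h_list = [i for i in others if atoms[i].symbol == "H"]
    h_pos = np.array([atoms[i].position for i in h_list]) if h_list else \
        np.empty((0, 3))

    new_atoms = [atoms[i] for i in ion.indices]
    waters: list[Fragment] = []
    for o in o_list:
        disp = minimum_image(atoms[o].position - ion_pos, box)
        d = np.linalg.norm(disp, axis=1)
        if d.min() > r_cut:
            continue
        k = int(np.argmin(d))
        o_unwrapped = ion_pos[k] + disp[k]
        shift = o_unwrapped - atoms[o].position
        dh = np.linalg.norm(minimum_image(h_pos - atoms[o].position, box),
                            axis=1)
        hh = [h_list[j] for j in np.argsort(dh)[:2]]
        start = len(new_atoms)
        new_atoms.append(Atom(atoms[o].symbol, atoms[o].z, o_unwrapped))
        for h in hh:
            rel = minimum_image(atoms[h].position - atoms[o].position, box)
            new_atoms.append(Atom(atoms[h].symbol, atoms[h].z,
                                  o_unwrapped + rel))
        waters.append(Fragment("water", (start, start + 1, start + 2), 0))
    if not waters:
        raise ValueError(f"no waters within r_cut={r_cut} of the ion")
    ion_frag = Fragment("ion", tuple(range(len(ion.indices))), ion.charge)
    return ClusterSnapshot(new_atoms, ion_frag, waters,
                           source_frame=frame.frame_id)


def compute_rdf(frames: Sequence[TrajectoryFrame],
                center_sel: Callable[[Atom], bool] | str,
                target_sel: Callable[[Atom], bool] | str,
                dr: float = 0.1, r_max: float | None = None) -> RDF:
    """Radial distribution function between two atom selections.

    Selections are predicates on Atom or element symbols.  Normalization
    is by ideal-gas shell counts at the target species' mean density.
    """
    if not frames:
        raise ValueError("no frames given")
    if dr <= 0:
        raise ValueError("dr must be positive")
    box = frames[0].box
    if box is None:
        raise ValueError("RDF requires a periodic box")
    if r_max is None:
        r_max = float(box.min()) / 2.0
    if r_max > box.min() / 2.0 + 1e-9:
        raise ValueError("r_max must not exceed half the smallest box length")

    def as_pred(sel):
        if callable(sel):
            return sel, getattr(sel, "__name__", "custom")
        return (lambda a, s=sel: a.symbol == s), str(sel)

    cpred, cname = as_pred(center_sel)
    tpred, tname = as_pred(target_sel)
    nbins = int(np.ceil(r_max / dr))
    counts = np.zeros(nbins)
    n_center = n_target = 0
    for fr in frames:
        cidx = [i for i, a in enumerate(fr.atoms) if cpred(a)]
        tidx = [i for i, a in enumerate(fr.atoms) if tpred(a)]
        if not cidx or not tidx:
            raise ValueError("empty selection for RDF")
        n_center += len(cidx)
        n_target += len(tidx)
        cpos = fr.coords()[cidx]
        tpos = fr.coords()[tidx]
        for k, c in enumerate(cpos):
            disp = minimum_image(tpos - c, box)
            d = np.linalg.norm(disp, axis=1)
            same = [j for j, t in enumerate(tidx) if t == cidx[k]]
            if same:
                d = np.delete(d, same)
            sel = d < r_max
            idx = (d[sel] / dr).astype(int)
            np.add.at(counts, idx, 1.0)
    n_frames = len(frames)
    mean_center = n_center / n_frames
    mean_target = n_target / n_frames
    vol = float(np.prod(box))
    edges = np.arange(nbins + 1) * dr
    shell_vol = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    ideal = mean_target / vol * shell_vol * mean_center * n_frames
    g = np.where(ideal > 0, counts / ideal, 0.0)
    r = 0.5 * (edges[:-1] + edges[1:])
    return RDF(r, g, cname, tname, n_frames)


def build_ensemble(frames: Sequence[TrajectoryFrame], ion_species: str,
                   n_snapshots: int = 51, spacing_ps: float = 10.0,
                   gds: GDSResult | None = None,
                   cutoff: float = INTERFACE_CUTOFF,
                   r_cut: float = TWO_SHELL_CUTOFF,
                   ) -> tuple[list[ClusterSnapshot], list[ClusterSnapshot]]:
    """Sample frames at fixed temporal spacing, classify and carve.

    Returns (bulk, interface) snapshot lists, each at most ``n_snapshots``
    long; warns if the trajectory cannot fill an environment.
    """
    if gds is None:
        gds = locate_gds(mass_density_profile(frames))
    bulk: list[ClusterSnapshot] = []
    interface: list[ClusterSnapshot] = []
    next_time = frames[0].time_ps
    for fr in frames:
        if fr.time_ps + 1e-9 < next_time:
            continue
        next_time = fr.time_ps + spacing_ps
        ion_frag, _ = detect_fragments(fr.atoms, ion_species)
        ion_atoms_ = [fr.atoms[i] for i in ion_frag.indices]
        ion_z = center_of_mass(ion_atoms_)[2]
        env = classify_environment(ion_z, gds, cutoff)
        if env == EJECTED:
            continue
        target = bulk if env == BULK else interface
        if len(target) >= n_snapshots:
            if len(bulk) >= n_snapshots and len(interface) >= n_snapshots:
                break
            continue
        snap = carve_two_shell_cluster(fr, ion_frag, r_cut)
        snap.environment = env
        target.append(snap)
    for name, lst in ((BULK, bulk), (INTERFACE, interface)):
        if len(lst) < n_snapshots:
            warnings.warn(f"only {len(lst)}/{n_snapshots} {name} snapshots "
                          "available in the trajectory")
    return bulk, interface
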