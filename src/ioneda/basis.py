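"""Gaussian basis sets generated from Slater-type orbitals.

No basis-set library is bundled.  For each occupied subshell (n, l) of an
element, a Slater exponent zeta is obtained from Slater's screening rules
and the radial Slater function is expanded in ``n_gauss`` primitive
Gaussians by least squares (the classic STO-nG construction, computed at
import time and cached).  Three contraction levels are offered:

``min``
    one contracted function per occupied subshell (STO-3G-like),
``dz``
    split valence: the outermost primitive of each valence subshell is
    released as its own function,
``tz``
    valence subshells fully uncontracted (three independent primitives).

``diffuse=True`` adds one even-tempered diffuse s (and p where the valence
holds p) function on non-hydrogen atoms, which matters for anions.

All quantities are in atomic units (exponents bohr^-2); Cartesian Gaussians
are used throughout (6 components for d shells).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Sequence

import numpy as np
from scipy.optimize import minimize

from .periodic import BOHR_PER_ANGSTROM, z_of

# aufbau order, sufficient through Z=54
_AUFBAU = [(1, 0), (2, 0), (2, 1), (3, 0), (3, 1), (4, 0), (3, 2),
           (4, 1), (5, 0), (4, 2), (5, 1)]
_N_STAR = {1: 1.0, 2: 2.0, 3: 3.0, 4: 3.7, 5: 4.0, 6: 4.2}


def electron_configuration(z: int) -> list[tuple[int, int, int]]:
    """Ground-state (n, l, occupancy) by the aufbau rule."""
    conf = []
    left = z
    for n, l in _AUFBAU:
        if left <= 0:
            break
        occ = min(left, 2 * (2 * l + 1))
        conf.append((n, l, occ))
        left -= occ
    return conf


def slater_zeta(z: int, n: int, l: int) -> float:
    """Effective Slater exponent zeta = (Z - s)/n* for subshell (n, l)."""
    conf = electron_configuration(z)
    # screening groups: (1s)(2s2p)(3s3p)(3d)(4s4p)(4d)(5s5p)...
    def group(nn, ll):
        return (nn, "d" if ll >= 2 else "sp")
    me = group(n, l)
    s = 0.0
    for nn, ll, occ in conf:
        g = group(nn, ll)
        if g == me:
            same = occ - 1 if (nn, ll) == (n, l) else occ
            if me == (1, "sp"):
                s += 0.30 * same
            else:
                s += 0.35 * same
        elif me[1] == "d":
            if (nn < n) or (nn == n and ll < 2):
                s += 1.00 * occ
        else:  # sp group
            if nn == n - 1:
                s += 0.85 * occ
            elif nn < n - 1:
                s += 1.00 * occ
    zeff = max(z - s, 0.5)
    return zeff / _N_STAR[n]


@lru_cache(maxsize=None)
def sto_ng_fit(n: int, l: int, n_gauss: int = 3) -> tuple[tuple[float, ...],
                                                          tuple[float, ...]]:
    """Least-squares expansion of the nodeless Slater radial function.

    Fits R_nl(r; zeta=1) ~ r^(n-1) e^(-r) with ``n_gauss`` normalized
    Gaussians of angular momentum l on a radial grid, minimizing the
    L2 error of r*R(r).  Returns (exponents, coefficients) for zeta = 1;
    scale exponents by zeta^2 for other zeta values.
    """
    r = np.linspace(1e-4, 25.0, 1200)
    norm = math.sqrt((2.0) ** (2 * n + 1) / math.factorial(2 * n))
    sto = norm * r ** (n - 1) * np.exp(-r)

    def gauss_mat(alphas):
        cols = []
        for a in alphas:
            gn = math.sqrt(2.0 * (2.0 * a) ** (l + 1.5) / math.gamma(l + 1.5))
            cols.append(gn * r ** l * np.exp(-a * r * r))
        return np.array(cols).T

    w = r  # weight by r: fit r*R in plain L2
    target = sto * w

    def objective(log_a):
        A = gauss_mat(np.exp(log_a)) * w[:, None]
        c, res, *_ = np.linalg.lstsq(A, target, rcond=None)
        return float(((A @ c - target) ** 2).sum())

    # even-tempered start centred near the STO decay scale
    start = np.log(np.array([0.08 * 4.0 ** k for k in range(n_gauss)]) /
                   max(n - 0.5, 0.7) ** 1.5)
    best = minimize(objective, start, method="Nelder-Mead",
                    options={"xatol": 1e-8, "fatol": 1e-12, "maxiter": 4000})
    alphas = np.exp(best.x)
    A = gauss_mat(alphas) * w[:, None]
    coeffs, *_ = np.linalg.lstsq(A, target, rcond=None)
    order = np.argsort(alphas)[::-1]
    return tuple(float(a) for a in alphas[order]), tuple(float(c) for c in coeffs[order])


@dataclass(frozen=True)
class Shell:
    l: int
    exponents: tuple[float, ...]   # bohr^-2
    coefficients: tuple[float, ...]  # for normalized primitives


@dataclass(frozen=True)
class BasisSpec:
    """Basis request: contraction level plus optional diffuse augmentation."""

    level: str = "min"          # "min" | "dz" | "tz"
    diffuse: bool = False
    n_gauss: int = 3

    def shells_for(self, symbol: str) -> list[Shell]:
        return element_shells(symbol, self.level, self.diffuse, self.n_gauss)

    @property
    def name(self) -> str:
        return f"sto{self.n_gauss}g-{self.level}" + ("+" if self.diffuse else "")


@lru_cache(maxsize=None)
def element_shells(symbol: str, level: str = "min", diffuse: bool = False,
                   n_gauss: int = 3) -> list[Shell]:
    if level not in ("min", "dz", "tz"):
        raise ValueError(f"unknown basis level {level!r}")
    z = z_of(symbol)
    conf = electron_configuration(z)
    n_val = max(n for n, l, _ in conf)
    shells: list[Shell] = []
    min_exp: dict[int, float] = {}
    for n, l, _occ in conf:
        zeta = slater_zeta(z, n, l)
        a0, c0 = sto_ng_fit(n, l, n_gauss)
        alphas = tuple(a * zeta * zeta for a in a0)
        min_exp[l] = min(min_exp.get(l, np.inf), alphas[-1])
        valence = (n == n_val) or (n == n_val - 1 and l == 2)
        if level == "min" or not (n >= n_val and l <= 1):
            # core subshells (and everything at level "min"): one contraction
            shells.append(Shell(l, alphas, c0))
        elif level == "dz":
            shells.append(Shell(l, alphas[:-1], c0[:-1]))
            shells.append(Shell(l, (alphas[-1],), (1.0,)))
        else:  # tz: fully uncontract the valence subshell
            for a in alphas:
                shells.append(Shell(l, (a,), (1.0,)))
    if diffuse and symbol != "H":
        for l in sorted(min_exp):
            if l > 1:
                continue
            shells.append(Shell(l, (min_exp[l] / 3.0,), (1.0,)))
    return shells


# Cartesian component exponent triples per angular momentum
CART_COMPONENTS = {
    0: [(0, 0, 0)],
    1: [(1, 0, 0), (0, 1, 0), (0, 0, 1)],
    2: [(2, 0, 0), (0, 2, 0), (0, 0, 2), (1, 1, 0), (1, 0, 1), (0, 1, 1)],
}


def _double_factorial(k: int) -> float:
    out = 1.0
    while k > 1:
        out *= k
        k -= 2
    return out


def _primitive_norm(alpha: float, lx: int, ly: int, lz: int) -> float:
    l = lx + ly + lz
    num = (2.0 * alpha / math.pi) ** 0.75 * (4.0 * alpha) ** (l / 2.0)
    den = math.sqrt(_double_factorial(2 * lx - 1) *
                    _double_factorial(2 * ly - 1) *
                    _double_factorial(2 * lz - 1))
    return num / den


@dataclass
class AOBasis:
    """Flattened Cartesian AO basis over all (real and ghost) centers.

    Arrays are shaped for the numba integral kernels; coefficients include
    primitive norms and an overall contraction normalization so every AO
    has unit self-overlap.
    """

    centers: np.ndarray      # (nbf, 3) bohr
    lvec: np.ndarray         # (nbf, 3) int
    nprim: np.ndarray        # (nbf,) int
    exps: np.ndarray         # (nbf, maxprim)
    coefs: np.ndarray        # (nbf, maxprim) normalized
    atom_of: np.ndarray      # (nbf,) parent center index

    @property
    def nbf(self) -> int:
        return len(self.nprim)


def build_ao_basis(atoms: Sequence, spec: BasisSpec) -> AOBasis:
    """Expand a molecule (list of Atom) into Cartesian contracted AOs."""
    raw = []  # (center, lx, ly, lz, exps, coefs, iatom)
    for ia, a in enumerate(atoms):
        for sh in spec.shells_for(a.symbol):
            for (lx, ly, lz) in CART_COMPONENTS[sh.l]:
                raw.append((a.position * BOHR_PER_ANGSTROM, lx, ly, lz,
                            sh.exponents, sh.coefficients, ia))
    nbf = len(raw)
    maxprim = max(len(r[4]) for r in raw)
    centers = np.zeros((nbf, 3))
    lvec = np.zeros((nbf, 3), dtype=np.int64)
    nprim = np.zeros(nbf, dtype=np.int64)
    exps = np.zeros((nbf, maxprim))
    coefs = np.zeros((nbf, maxprim))
    atom_of = np.zeros(nbf, dtype=np.int64)
    for i, (c, lx, ly, lz, al, cl, ia) in enumerate(raw):
        centers[i] = c
        lvec[i] = (lx, ly, lz)
        np_i = len(al)
        nprim[i] = np_i
        exps[i, :np_i] = al
        coefs[i, :np_i] = [cc * _primitive_norm(aa, lx, ly, lz)
                           for aa, cc in zip(al, cl)]
        atom_of[i] = ia
        # contraction normalization from the analytic same-center overlap
        p = np.add.outer(exps[i, :np_i], exps[i, :np_i])
        pref = (_double_factorial(2 * lx - 1) * _double_factorial(2 * ly - 1)
                * _double_factorial(2 * lz - 1))
        s = 0.0
        for m in range(np_i):
            for n in range(np_i):
                pp = p[m, n]
                s += (coefs[i, m] * coefs[i, n] * pref /
                      (2.0 * pp) ** (lx + ly + lz) * (math.pi / pp) ** 1.5)
        coefs[i, :np_i] /= math.sqrt(s)
    return AOBasis(centers, lvec, nprim, exps, coefs, atom_of)
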