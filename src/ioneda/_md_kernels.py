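"""Numba kernels for Gaussian integrals (McMurchie-Davidson scheme).

Supports Cartesian angular momenta through d.  The Hermite expansion
coefficients E_t^{ij} are built by recursion; Coulomb-type integrals use
the Hermite integrals R_tuv with the Boys function.
"""

import math

import numpy as np
from numba import njit

LMAX = 2          # through d functions
TMAX = 2 * LMAX + 1  # Hermite orders per dimension per pair


@njit(cache=True)
def boys(mmax, T, out):
    """Boys function F_m(T) for m = 0..mmax into ``out``."""
    if T < 1e-13:
        for m in range(mmax + 1):
            out[m] = 1.0 / (2.0 * m + 1.0)
        return
    if T < 35.0:
        # series for F_mmax, then stable downward recursion
        em = math.exp(-T)
        num = 1.0
        den = 2.0 * mmax + 1.0
        term = num / den
        s = term
        k = 1
        while True:
            term *= 2.0 * T / (2.0 * mmax + 2.0 * k + 1.0)
            s += term
            if term < 1e-17 * s or k > 200:
                break
            k += 1
        out[mmax] = em * s
        for m in range(mmax - 1, -1, -1):
            out[m] = (2.0 * T * out[m + 1] + em) / (2.0 * m + 1.0)
    else:
        em = math.exp(-T)
        out[0] = 0.5 * math.sqrt(math.pi / T) * math.erf(math.sqrt(T))
        for m in range(mmax):
            out[m + 1] = ((2.0 * m + 1.0) * out[m] - em) / (2.0 * T)


@njit(cache=True)
def e_coeffs(l1, l2, PA, PB, p, out):
    """Hermite expansion coefficients E_t^{l1 l2} (without the K factor)."""
    E = np.zeros((l1 + 1, l2 + 1, l1 + l2 + 2))
    E[0, 0, 0] = 1.0
    inv2p = 0.5 / p
    for i in range(1, l1 + 1):
        for t in range(i + 1):
            v = PA * E[i - 1, 0, t] + (t + 1) * E[i - 1, 0, t + 1]
            if t > 0:
                v += inv2p * E[i - 1, 0, t - 1]
            E[i, 0, t] = v
    for j in range(1, l2 + 1):
        for i in range(l1 + 1):
            for t in range(i + j + 1):
                v = PB * E[i, j - 1, t] + (t + 1) * E[i, j - 1, t + 1]
                if t > 0:
                    v += inv2p * E[i, j - 1, t - 1]
                E[i, j, t] = v
    for t in range(l1 + l2 + 1):
        out[t] = E[l1, l2, t]


@njit(cache=True)
def r_tensor(tmax, umax, vmax, p, X, Y, Z, R):
    """Hermite Coulomb integrals R^0_{tuv} into R[t, u, v]."""
    L = tmax + umax + vmax
    T = p * (X * X + Y * Y + Z * Z)
    F = np.empty(L + 1)
    boys(L, T, F)
    Rn = np.zeros((L + 1, tmax + 1, umax + 1, vmax + 1))
    f = 1.0
    for n in range(L + 1):
        Rn[n, 0, 0, 0] = f * F[n]
        f *= -2.0 * p
    for n in range(L - 1, -1, -1):
        for t in range(tmax + 1):
            for u in range(umax + 1):
                for v in range(vmax + 1):
                    if t + u + v == 0 or t + u + v > L - n:
                        continue
                    if t > 0:
                        val = X * Rn[n + 1, t - 1, u, v]
                        if t > 1:
                            val += (t - 1) * Rn[n + 1, t - 2, u, v]
                    elif u > 0:
                        val = Y * Rn[n + 1, t, u - 1, v]
                        if u > 1:
                            val += (u - 1) * Rn[n + 1, t, u - 2, v]
                    else:
                        val = Z * Rn[n + 1, t, u, v - 1]
                        if v > 1:
                            val += (v - 1) * Rn[n + 1, t, u, v - 2]
                    Rn[n, t, u, v] = val
    for t in range(tmax + 1):
        for u in range(umax + 1):
            for v in range(vmax + 1):
                R[t, u, v] = Rn[0, t, u, v]


@njit(cache=True)
def _overlap_1d(l1, l2, PA, PB, p):
    tmp = np.zeros(l1 + l2 + 1)
    e_coeffs(l1, l2, PA, PB, p, tmp)
    return tmp[0] * math.sqrt(math.pi / p)


@njit(cache=True)
def overlap_kinetic(centers, lvec, nprim, exps, coefs):
    """Contracted overlap and kinetic-energy matrices."""
    nbf = len(nprim)
    S = np.zeros((nbf, nbf))
    Tm = np.zeros((nbf, nbf))
    for i in range(nbf):
        for j in range(i + 1):
            s = 0.0
            t = 0.0
            for mp in range(nprim[i]):
                a = exps[i, mp]
                ca = coefs[i, mp]
                for nq in range(nprim[j]):
                    b = exps[j, nq]
                    cb = coefs[j, nq]
                    p = a + b
                    mu = a * b / p
                    ab2 = 0.0
                    P = np.empty(3)
                    for d in range(3):
                        diff = centers[i, d] - centers[j, d]
                        ab2 += diff * diff
                        P[d] = (a * centers[i, d] + b * centers[j, d]) / p
                    K = math.exp(-mu * ab2)
                    sd = np.empty(3)
                    td = np.empty(3)
                    for d in range(3):
                        l1 = lvec[i, d]
                        l2 = lvec[j, d]
                        PA = P[d] - centers[i, d]
                        PB = P[d] - centers[j, d]
                        s0 = _overlap_1d(l1, l2, PA, PB, p)
                        sd[d] = s0
                        # kinetic 1D via overlaps with shifted l2
                        s_p2 = _overlap_1d(l1, l2 + 2, PA, PB, p)
                        kin = -2.0 * b * b * s_p2 + b * (2 * l2 + 1) * s0
                        if l2 >= 2:
                            s_m2 = _overlap_1d(l1, l2 - 2, PA, PB, p)
                            kin -= 0.5 * l2 * (l2 - 1) * s_m2
                        td[d] = kin
                    cc = ca * cb * K
                    s += cc * sd[0] * sd[1] * sd[2]
                    t += cc * (td[0] * sd[1] * sd[2] + sd[0] * td[1] * sd[2]
                               + sd[0] * sd[1] * td[2])
            S[i, j] = S[j, i] = s
            Tm[i, j] = Tm[j, i] = t
    return S, Tm


@njit(cache=True)
def nuclear_attraction(centers, lvec, nprim, exps, coefs,
                       nuc_centers, nuc_charges):
    """Nuclear-attraction matrix for the given point charges (negative)."""
    nbf = len(nprim)
    V = np.zeros((nbf, nbf))
    Ex = np.zeros(TMAX)
    Ey = np.zeros(TMAX)
    Ez = np.zeros(TMAX)
    for i in range(nbf):
        for j in range(i + 1):
            acc = 0.0
            for mp in range(nprim[i]):
                a = exps[i, mp]
                ca = coefs[i, mp]
                for nq in range(nprim[j]):
                    b = exps[j, nq]
                    cb = coefs[j, nq]
                    p = a + b
                    mu = a * b / p
                    ab2 = 0.0
                    P = np.empty(3)
                    for d in range(3):
                        diff = centers[i, d] - centers[j, d]
                        ab2 += diff * diff
                        P[d] = (a * centers[i, d] + b * centers[j, d]) / p
                    K = math.exp(-mu * ab2)
                    if K < 1e-16:
                        continue
                    lx1, ly1, lz1 = lvec[i, 0], lvec[i, 1], lvec[i, 2]
                    lx2, ly2, lz2 = lvec[j, 0], lvec[j, 1], lvec[j, 2]
                    e_coeffs(lx1, lx2, P[0] - centers[i, 0], P[0] - centers[j, 0], p, Ex)
                    e_coeffs(ly1, ly2, P[1] - centers[i, 1], P[1] - centers[j, 1], p, Ey)
                    e_coeffs(lz1, lz2, P[2] - centers[i, 2], P[2] - centers[j, 2], p, Ez)
                    tx = lx1 + lx2
                    tu = ly1 + ly2
                    tv = lz1 + lz2
                    R = np.zeros((tx + 1, tu + 1, tv + 1))
                    for c in range(len(nuc_charges)):
                        r_tensor(tx, tu, tv, p,
                                 P[0] - nuc_centers[c, 0],
                                 P[1] - nuc_centers[c, 1],
                                 P[2] - nuc_centers[c, 2], R)
                        val = 0.0
                        for t in range(tx + 1):
                            for u in range(tu + 1):
                                for v in range(tv + 1):
                                    val += Ex[t] * Ey[u] * Ez[v] * R[t, u, v]
                        acc += -nuc_charges[c] * ca * cb * K * (2.0 * math.pi / p) * val
            V[i, j] = V[j, i] = acc
    return V


@njit(cache=True)
def dipole_integrals(centers, lvec, nprim, exps, coefs, origin):
    """Electronic dipole integrals <mu| r - origin |nu> (3, nbf, nbf)."""
    nbf = len(nprim)
    D = np.zeros((3, nbf, nbf))
    for i in range(nbf):
        for j in range(i + 1):
            acc = np.zeros(3)
            for mp in range(nprim[i]):
                a = exps[i, mp]
                ca = coefs[i, mp]
                for nq in range(nprim[j]):
                    b = exps[j, nq]
                    cb = coefs[j, nq]
                    p = a + b
                    mu = a * b / p
                    ab2 = 0.0
                    P = np.empty(3)
                    for d in range(3):
                        diff = centers[i, d] - centers[j, d]
                        ab2 += diff * diff
                        P[d] = (a * centers[i, d] + b * centers[j, d]) / p
                    K = math.exp(-mu * ab2)
                    sd = np.empty(3)
                    md = np.empty(3)
                    for d in range(3):
                        l1 = lvec[i, d]
                        l2 = lvec[j, d]
                        PA = P[d] - centers[i, d]
                        PB = P[d] - centers[j, d]
                        tmp = np.zeros(l1 + l2 + 2)
                        e_coeffs(l1, l2, PA, PB, p, tmp)
                        sp = math.sqrt(math.pi / p)
                        sd[d] = tmp[0] * sp
                        e1 = tmp[1] if l1 + l2 >= 1 else 0.0
                        md[d] = (e1 + (P[d] - origin[d]) * tmp[0]) * sp
                    cc = ca * cb * K
                    acc[0] += cc * md[0] * sd[1] * sd[2]
                    acc[1] += cc * sd[0] * md[1] * sd[2]
                    acc[2] += cc * sd[0] * sd[1] * md[2]
            for d in range(3):
                D[d, i, j] = D[d, j, i] = acc[d]
    return D


@njit(cache=True)
def _pair_data(centers, lvec, nprim, exps, coefs):
    """Precompute Hermite data for all AO pairs (i >= j).

    Returns flat arrays over primitive pairs plus per-AO-pair offsets.
    """
    nbf = len(nprim)
    npair = nbf * (nbf + 1) // 2
    counts = np.zeros(npair, dtype=np.int64)
    k = 0
    for i in range(nbf):
        for j in range(i + 1):
            counts[k] = nprim[i] * nprim[j]
            k += 1
    offs = np.zeros(npair + 1, dtype=np.int64)
    for k in range(npair):
        offs[k + 1] = offs[k] + counts[k]
    ntot = offs[npair]
    pp = np.empty(ntot)
    pK = np.empty(ntot)          # contraction coeffs * exp factor
    pP = np.empty((ntot, 3))
    pE = np.zeros((ntot, 3, TMAX))
    ptmax = np.zeros((npair, 3), dtype=np.int64)
    pair_ij = np.empty((npair, 2), dtype=np.int64)
    k = 0
    for i in range(nbf):
        for j in range(i + 1):
            ptmax[k, 0] = lvec[i, 0] + lvec[j, 0]
            ptmax[k, 1] = lvec[i, 1] + lvec[j, 1]
            ptmax[k, 2] = lvec[i, 2] + lvec[j, 2]
            pair_ij[k, 0] = i
            pair_ij[k, 1] = j
            idx = offs[k]
            for mp in range(nprim[i]):
                a = exps[i, mp]
                for nq in range(nprim[j]):
                    b = exps[j, nq]
                    p = a + b
                    mu = a * b / p
                    ab2 = 0.0
                    for d in range(3):
                        diff = centers[i, d] - centers[j, d]
                        ab2 += diff * diff
                    pp[idx] = p
                    pK[idx] = coefs[i, mp] * coefs[j, nq] * math.exp(-mu * ab2)
                    for d in range(3):
                        pP[idx, d] = (a * centers[i, d] + b * centers[j, d]) / p
                        tmp = np.zeros(TMAX)
                        e_coeffs(lvec[i, d], lvec[j, d],
                                 pP[idx, d] - centers[i, d],
                                 pP[idx, d] - centers[j, d], p, tmp)
                        for t in range(TMAX):
                            pE[idx, d, t] = tmp[t]
                    idx += 1
            k += 1
    return offs, pp, pK, pP, pE, ptmax, pair_ij


@njit(cache=True)
def _eri_pair_pair(o1, n1, o2, n2, pp, pK, pP, pE, t1, t2):
    """Contracted (ij|kl) from precomputed bra/ket primitive-pair data."""
    val = 0.0
    R = np.zeros((t1[0] + t2[0] + 1, t1[1] + t2[1] + 1, t1[2] + t2[2] + 1))
    for b1 in range(o1, o1 + n1):
        K1 = pK[b1]
        if abs(K1) < 1e-14:
            continue
        p = pp[b1]
        for b2 in range(o2, o2 + n2):
            K2 = pK[b2]
            if abs(K1 * K2) < 1e-14:
                continue
            q = pp[b2]
            alpha = p * q / (p + q)
            r_tensor(t1[0] + t2[0], t1[1] + t2[1], t1[2] + t2[2], alpha,
                     pP[b1, 0] - pP[b2, 0], pP[b1, 1] - pP[b2, 1],
                     pP[b1, 2] - pP[b2, 2], R)
            acc = 0.0
            for ta in range(t1[0] + 1):
                Ea = pE[b1, 0, ta]
                if Ea == 0.0:
                    continue
                for ua in range(t1[1] + 1):
                    Eua = Ea * pE[b1, 1, ua]
                    if Eua == 0.0:
                        continue
                    for va in range(t1[2] + 1):
                        Eva = Eua * pE[b1, 2, va]
                        if Eva == 0.0:
                            continue
                        for tb in range(t2[0] + 1):
                            Eb = pE[b2, 0, tb]
                            if Eb == 0.0:
                                continue
                            sgn_t = -1.0 if tb % 2 else 1.0
                            for ub in range(t2[1] + 1):
                                Eub = Eb * pE[b2, 1, ub]
                                if Eub == 0.0:
                                    continue
                                sgn_u = -sgn_t if ub % 2 else sgn_t
                                for vb in range(t2[2] + 1):
                                    Evb = Eub * pE[b2, 2, vb]
                                    if Evb == 0.0:
                                        continue
                                    sgn = -sgn_u if vb % 2 else sgn_u
                                    acc += Eva * Evb * sgn * R[ta + tb, ua + ub, va + vb]
            pref = 2.0 * math.pi ** 2.5 / (p * q * math.sqrt(p + q))
            val += K1 * K2 * pref * acc
    return val


@njit(cache=True)
def eri_tensor(centers, lvec, nprim, exps, coefs, screen_tol=1e-12):
    """Full two-electron repulsion tensor (chemists' notation)."""
    nbf = len(nprim)
    offs, pp, pK, pP, pE, ptmax, pair_ij = _pair_data(
        centers, lvec, nprim, exps, coefs)
    npair = len(ptmax)
    # Schwarz diagonal
    qdiag = np.empty(npair)
    for k in range(npair):
        v = _eri_pair_pair(offs[k], offs[k + 1] - offs[k],
                           offs[k], offs[k + 1] - offs[k],
                           pp, pK, pP, pE, ptmax[k], ptmax[k])
        qdiag[k] = math.sqrt(abs(v))
    eri = np.zeros((nbf, nbf, nbf, nbf))
    for k1 in range(npair):
        i = pair_ij[k1, 0]
        j = pair_ij[k1, 1]
        for k2 in range(k1 + 1):
            if qdiag[k1] * qdiag[k2] < screen_tol:
                continue
            kk = pair_ij[k2, 0]
            ll = pair_ij[k2, 1]
            v = _eri_pair_pair(offs[k1], offs[k1 + 1] - offs[k1],
                               offs[k2], offs[k2 + 1] - offs[k2],
                               pp, pK, pP, pE, ptmax[k1], ptmax[k2])
            eri[i, j, kk, ll] = v
            eri[j, i, kk, ll] = v
            eri[i, j, ll, kk] = v
            eri[j, i, ll, kk] = v
            eri[kk, ll, i, j] = v
            eri[ll, kk, i, j] = v
            eri[kk, ll, j, i] = v
            eri[ll, kk, j, i] = v
    return eri
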