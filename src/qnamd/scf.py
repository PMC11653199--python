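"""Minimal restricted Hartree–Fock backend over Cartesian Gaussians.

McMurchie–Davidson evaluation of overlap, kinetic, nuclear-attraction,
dipole and electron-repulsion integrals for s/p shells, plus a DIIS-
converged closed-shell RHF.  This provides the mean-field reference and
active-space integrals consumed by the variational-quantum layer; it is
deliberately small (first-row elements, no point-group symmetry, no
analytic gradients) since all derivative quantities in this package are
obtained by finite differences of the Hamiltonian.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammainc, gammaln

from .basis import BASIS_SETS
from .geometry import Geometry

_CART = {0: [(0, 0, 0)], 1: [(1, 0, 0), (0, 1, 0), (0, 0, 1)]}

_DFACT = {-1: 1.0, 0: 1.0, 1: 1.0, 2: 3.0}  # (2l-1)!! for small l


@dataclass
class Shell:
    l: int
    center: np.ndarray  # (3,), bohr
    exps: np.ndarray
    coeffs: np.ndarray  # primitive-normalized * contraction, renormalized

    @property
    def n_funcs(self) -> int:
        return len(_CART[self.l])


class BasisSet:
    """A list of shells with AO bookkeeping for one geometry."""

    def __init__(self, geometry: Geometry, name: str = "6-31g"):
        data = BASIS_SETS[name.lower()]
        self.name = name.lower()
        self.geometry = geometry
        self.shells: list[Shell] = []
        for sym, center in zip(geometry.symbols, geometry.coords):
            for l, exps, coeffs in data[sym]:
                e = np.asarray(exps, float)
                c = np.asarray(coeffs, float)
                # primitive normalization (same for every component at l<=1)
                norm = (2 * e / np.pi) ** 0.75 * (4 * e) ** (l / 2.0) / np.sqrt(_DFACT[l])
                cc = c * norm
                # contracted renormalization via the self-overlap of one component
                i = l  # (l,0,0) component: x-moment i=l
                ee = e[:, None] + e[None, :]
                s = (
                    (cc[:, None] * cc[None, :])
                    * (np.pi / ee) ** 1.5
                    * _DFACT[2 * l - 1 if l else -1]
                    / (2 * ee) ** l
                ).sum()
                self.shells.append(Shell(l, np.asarray(center, float), e, cc / np.sqrt(s)))
        self.offsets = np.cumsum([0] + [sh.n_funcs for sh in self.shells])
        self.n_ao = int(self.offsets[-1])


# ----------------------------------------------------------- Boys function

def boys(nmax: int, x: np.ndarray) -> np.ndarray:
    """F_n(x) for n = 0..nmax; stable downward recursion. Shape (nmax+1, *x)."""
    x = np.asarray(x, float)
    out = np.empty((nmax + 1,) + x.shape)
    a = nmax + 0.5
    small = x < 1e-13
    xs = np.where(small, 1.0, x)
    top = np.exp(gammaln(a)) * gammainc(a, xs) / (2.0 * xs**a)
    out[nmax] = np.where(small, 1.0 / (2 * nmax + 1) - x / (2 * nmax + 3), top)
    ex = np.exp(-x)
    for n in range(nmax, 0, -1):
        out[n - 1] = (2.0 * x * out[n] + ex) / (2 * n - 1)
    return out


# ------------------------------------------------- Hermite expansion coeffs

def hermite_e(imax: int, jmax: int, tmax: int, qx: np.ndarray, a: np.ndarray, b: np.ndarray):
    """E_t^{ij} arrays, shape (tmax+1, imax+1, jmax+1, m) over primitive pairs."""
    p = a + b
    mu = a * b / p
    m = np.broadcast(qx, p).shape
    E = np.zeros((tmax + 2, imax + 1, jmax + 1) + m)
    E[0, 0, 0] = np.exp(-mu * qx * qx)
    xpa = -b * qx / p  # P - A
    xpb = a * qx / p  # P - B
    for i in range(imax + 1):
        for j in range(jmax + 1):
            if i == 0 and j == 0:
                continue
            for t in range(tmax + 1):
                if i > 0:
                    E[t, i, j] = (
                        (E[t - 1, i - 1, j] / (2 * p) if t > 0 else 0.0)
                        + xpa * E[t, i - 1, j]
                        + (t + 1) * E[t + 1, i - 1, j]
                    )
                else:
                    E[t, i, j] = (
                        (E[t - 1, i, j - 1] / (2 * p) if t > 0 else 0.0)
                        + xpb * E[t, i, j - 1]
                        + (t + 1) * E[t + 1, i, j - 1]
                    )
    return E[: tmax + 1]


def hermite_coulomb(L: int, p: np.ndarray, PC: np.ndarray):
    """R_{tuv} tensors for all t+u+v <= L, shape (L+1, L+1, L+1, *m).

    Iterative build over the auxiliary Boys order, vectorized over the
    trailing (primitive-combination) axes.
    """
    r2 = (PC**2).sum(axis=-1)
    F = boys(L, np.broadcast_to(p * r2, np.broadcast(p, r2).shape))
    mshape = F.shape[1:]
    if L == 0:
        return F.reshape((1, 1, 1) + mshape)
    X, Y, Z = (np.broadcast_to(PC[..., d], mshape) for d in range(3))
    pfac = np.broadcast_to(-2.0 * p, mshape)
    prev = {(0, 0, 0): pfac ** L * F[L]}
    for n in range(L - 1, -1, -1):
        cur = {(0, 0, 0): pfac ** n * F[n]}
        lmax = L - n
        for t in range(lmax + 1):
            for u in range(lmax + 1 - t):
                for v in range(lmax + 1 - t - u):
                    if t == u == v == 0:
                        continue
                    if t > 0:
                        val = X * prev[(t - 1, u, v)]
                        if t > 1:
                            val = val + (t - 1) * prev[(t - 2, u, v)]
                    elif u > 0:
                        val = Y * prev[(t, u - 1, v)]
                        if u > 1:
                            val = val + (u - 1) * prev[(t, u - 2, v)]
                    else:
                        val = Z * prev[(t, u, v - 1)]
                        if v > 1:
                            val = val + (v - 1) * prev[(t, u, v - 2)]
                    cur[(t, u, v)] = val
        prev = cur
    out = np.zeros((L + 1, L + 1, L + 1) + mshape)
    for (t, u, v), val in prev.items():
        out[t, u, v] = val
    return out


class _PairData:
    """Per-shell-pair primitive data and Hermite coefficients."""

    def __init__(self, sa: Shell, sb: Shell, extra: int = 0):
        a = sa.exps[:, None].repeat(len(sb.exps), 1).ravel()
        b = sb.exps[None, :].repeat(len(sa.exps), 0).ravel()
        self.a, self.b = a, b
        self.p = a + b
        self.cc = (sa.coeffs[:, None] * sb.coeffs[None, :]).ravel()
        self.P = (a[:, None] * sa.center + b[:, None] * sb.center) / self.p[:, None]
        self.AB = sa.center - sb.center
        tmax = sa.l + sb.l + extra
        self.E = [
            hermite_e(sa.l + extra, sb.l + extra, tmax, self.AB[d], a, b) for d in range(3)
        ]
        self.la, self.lb = sa.l, sb.l


# -------------------------------------------------------- one-electron ints

def _pairs(basis_a: BasisSet, basis_b: BasisSet | None):
    same = basis_b is None
    bb = basis_a if same else basis_b
    for ia, sa in enumerate(basis_a.shells):
        jstart = ia if same else 0
        for jb in range(jstart, len(bb.shells)):
            yield ia, jb, sa, bb.shells[jb]


def overlap(basis_a: BasisSet, basis_b: BasisSet | None = None) -> np.ndarray:
    """AO overlap matrix; cross-geometry when two basis sets are given."""
    same = basis_b is None
    bb = basis_a if same else basis_b
    S = np.zeros((basis_a.n_ao, bb.n_ao))
    for ia, jb, sa, sb in _pairs(basis_a, basis_b):
        pd = _PairData(sa, sb)
        pref = pd.cc * (np.pi / pd.p) ** 1.5
        oa, ob = basis_a.offsets[ia], bb.offsets[jb]
        for fa, ca in enumerate(_CART[sa.l]):
            for fb, cb in enumerate(_CART[sb.l]):
                val = pref.copy()
                for d in range(3):
                    val = val * pd.E[d][0, ca[d], cb[d]]
                S[oa + fa, ob + fb] = val.sum()
                if same:
                    S[ob + fb, oa + fa] = S[oa + fa, ob + fb]
    return S


def kinetic(basis: BasisSet) -> np.ndarray:
    T = np.zeros((basis.n_ao, basis.n_ao))
    for ia, jb, sa, sb in _pairs(basis, None):
        pd = _PairData(sa, sb, extra=2)
        pref = pd.cc * (np.pi / pd.p) ** 1.5
        oa, ob = basis.offsets[ia], basis.offsets[jb]
        b = pd.b
        for fa, ca in enumerate(_CART[sa.l]):
            for fb, cb in enumerate(_CART[sb.l]):
                s = [pd.E[d][0] for d in range(3)]

                def k1(d, i, j):
                    val = b * (2 * j + 1) * s[d][i, j] - 2.0 * b**2 * s[d][i, j + 2]
                    if j >= 2:
                        val = val - 0.5 * j * (j - 1) * s[d][i, j - 2]
                    return val

                tot = 0.0
                for d in range(3):
                    term = k1(d, ca[d], cb[d])
                    for e in range(3):
                        if e != d:
                            term = term * s[e][ca[e], cb[e]]
                    tot = tot + term
                T[oa + fa, ob + fb] = T[ob + fb, oa + fa] = (pref * tot).sum()
    return T


def nuclear_attraction(basis: BasisSet, geometry: Geometry) -> np.ndarray:
    V = np.zeros((basis.n_ao, basis.n_ao))
    charges = geometry.atomic_numbers.astype(float)
    centers = geometry.coords
    for ia, jb, sa, sb in _pairs(basis, None):
        pd = _PairData(sa, sb)
        oa, ob = basis.offsets[ia], basis.offsets[jb]
        lab = sa.l + sb.l
        # R tensors for all nuclei at once: PC shape (m, ncharges, 3)
        PC = pd.P[:, None, :] - centers[None, :, :]
        R = hermite_coulomb(lab, pd.p[:, None], PC)
        pref = pd.cc * 2.0 * np.pi / pd.p
        for fa, ca in enumerate(_CART[sa.l]):
            for fb, cb in enumerate(_CART[sb.l]):
                acc = 0.0
                for t in range(ca[0] + cb[0] + 1):
                    for u in range(ca[1] + cb[1] + 1):
                        for v in range(ca[2] + cb[2] + 1):
                            coef = (
                                pd.E[0][t, ca[0], cb[0]]
                                * pd.E[1][u, ca[1], cb[1]]
                                * pd.E[2][v, ca[2], cb[2]]
                            )
                            acc = acc + coef[:, None] * R[t, u, v]
                val = -(pref[:, None] * charges[None, :] * acc).sum()
                V[oa + fa, ob + fb] = V[ob + fb, oa + fa] = val
    return V


def dipole_integrals(basis: BasisSet, origin=(0.0, 0.0, 0.0)) -> np.ndarray:
    """<a| r - origin |b> for the three Cartesian components, shape (3, n, n)."""
    origin = np.asarray(origin, float)
    D = np.zeros((3, basis.n_ao, basis.n_ao))
    for ia, jb, sa, sb in _pairs(basis, None):
        pd = _PairData(sa, sb, extra=1)  # moment needs Hermite order t = 1
        pref = pd.cc * (np.pi / pd.p) ** 1.5
        oa, ob = basis.offsets[ia], basis.offsets[jb]
        for fa, ca in enumerate(_CART[sa.l]):
            for fb, cb in enumerate(_CART[sb.l]):
                s0 = [pd.E[d][0, ca[d], cb[d]] for d in range(3)]
                for d in range(3):
                    mom = pd.E[d][1, ca[d], cb[d]] + (pd.P[:, d] - origin[d]) * s0[d]
                    val = pref * mom
                    for e in range(3):
                        if e != d:
                            val = val * s0[e]
                    D[d, oa + fa, ob + fb] = D[d, ob + fb, oa + fa] = val.sum()
    return D


# ------------------------------------------------------------ two-electron

def electron_repulsion(basis: BasisSet, screen_tol: float = 1e-12) -> np.ndarray:
    """Full (ij|kl) AO tensor in chemist notation, Schwarz-screened."""
    n = basis.n_ao
    eri = np.zeros((n, n, n, n))
    shells = basis.shells
    npairs = []
    for i in range(len(shells)):
        for j in range(i + 1):
            npairs.append((i, j))
    pair_data = {(i, j): _PairData(shells[i], shells[j]) for i, j in npairs}

    # Schwarz bounds sqrt(max |(ab|ab)|) per shell pair
    qmax = {}
    for i, j in npairs:
        pb = pair_data[(i, j)]
        block = _quartet_block(shells, i, j, i, j, pb, pb)
        qmax[(i, j)] = np.sqrt(np.max(np.abs(block)))

    for ip, (i, j) in enumerate(npairs):
        pb = pair_data[(i, j)]
        for kq in range(ip + 1):
            k, l = npairs[kq]
            if qmax[(i, j)] * qmax[(k, l)] < screen_tol:
                continue
            block = _quartet_block(shells, i, j, k, l, pb, pair_data[(k, l)])
            _scatter_eri(eri, basis, i, j, k, l, block)
    return eri


def _quartet_block(shells, i, j, k, l, pb, pk):
    labx = shells[i].l + shells[j].l
    lcdx = shells[k].l + shells[l].l
    alpha = pb.p[:, None] * pk.p[None, :] / (pb.p[:, None] + pk.p[None, :])
    PQ = pb.P[:, None, :] - pk.P[None, :, :]
    R = hermite_coulomb(labx + lcdx, alpha, PQ)
    pref = (
        2.0
        * np.pi**2.5
        / (pb.p[:, None] * pk.p[None, :] * np.sqrt(pb.p[:, None] + pk.p[None, :]))
        * pb.cc[:, None]
        * pk.cc[None, :]
    )
    ca_list, cb_list = _CART[shells[i].l], _CART[shells[j].l]
    cc_list, cd_list = _CART[shells[k].l], _CART[shells[l].l]
    out = np.zeros((len(ca_list), len(cb_list), len(cc_list), len(cd_list)))
    for fc, cc in enumerate(cc_list):
        for fd, cd in enumerate(cd_list):
            Tc, Uc, Vc = (cc[d] + cd[d] for d in range(3))
            K3 = np.einsum(
                "tn,un,vn->tuvn",
                pk.E[0][: Tc + 1, cc[0], cd[0]],
                pk.E[1][: Uc + 1, cc[1], cd[1]],
                pk.E[2][: Vc + 1, cc[2], cd[2]],
            )
            sign = (-1.0) ** (
                np.arange(Tc + 1)[:, None, None]
                + np.arange(Uc + 1)[None, :, None]
                + np.arange(Vc + 1)[None, None, :]
            )
            K3 = K3 * sign[..., None]
            # half-contraction G[t,u,v] over the ket Hermite indices
            G = {}
            for t in range(labx + 1):
                for u in range(labx + 1 - t):
                    for v in range(labx + 1 - t - u):
                        G[(t, u, v)] = np.einsum(
                            "TUVn,TUVmn->mn",
                            K3,
                            R[t : t + Tc + 1, u : u + Uc + 1, v : v + Vc + 1],
                            optimize=False,
                        )
            for fa, ca in enumerate(ca_list):
                for fb, cb in enumerate(cb_list):
                    acc = 0.0
                    for t in range(ca[0] + cb[0] + 1):
                        bt = pb.E[0][t, ca[0], cb[0]]
                        for u in range(ca[1] + cb[1] + 1):
                            btu = bt * pb.E[1][u, ca[1], cb[1]]
                            for v in range(ca[2] + cb[2] + 1):
                                bra = btu * pb.E[2][v, ca[2], cb[2]]
                                acc = acc + bra[:, None] * G[(t, u, v)]
                    out[fa, fb, fc, fd] = (pref * acc).sum()
    return out


def _scatter_eri(eri, basis, i, j, k, l, block):
    oi, oj, ok, ol = (basis.offsets[x] for x in (i, j, k, l))
    ni, nj, nk, nl = block.shape
    for a in range(ni):
        for b in range(nj):
            for c in range(nk):
                for d in range(nl):
                    v = block[a, b, c, d]
                    A, B, C, D = oi + a, oj + b, ok + c, ol + d
                    eri[A, B, C, D] = eri[B, A, C, D] = v
                    eri[A, B, D, C] = eri[B, A, D, C] = v
                    eri[C, D, A, B] = eri[D, C, A, B] = v
                    eri[C, D, B, A] = eri[D, C, B, A] = v


# ------------------------------------------------------------------- RHF

@dataclass
class SCFResult:
    energy: float  # total RHF energy (hartree)
    mo_coeff: np.ndarray  # (n_ao, n_mo)
    mo_energy: np.ndarray
    S: np.ndarray
    hcore: np.ndarray
    eri: np.ndarray
    n_occ: int
    converged: bool
    basis: BasisSet


def rhf(geometry: Geometry, basis_name: str = "6-31g", max_cycles: int = 100,
        conv_tol: float = 1e-10, diis_size: int = 8) -> SCFResult:
    """Closed-shell restricted Hartree–Fock with DIIS acceleration."""
    basis = BasisSet(geometry, basis_name)
    S = overlap(basis)
    hcore = kinetic(basis) + nuclear_attraction(basis, geometry)
    eri = electron_repulsion(basis)
    n_elec = int(geometry.atomic_numbers.sum())
    if n_elec % 2:
        raise ValueError("rhf requires an even electron count")
    n_occ = n_elec // 2
    e_nn = geometry.nuclear_repulsion()

    sval, svec = np.linalg.eigh(S)
    X = svec @ np.diag(sval**-0.5) @ svec.T

    def fock(D):
        J = np.einsum("ijkl,kl->ij", eri, D)
        K = np.einsum("ikjl,kl->ij", eri, D)
        return hcore + J - 0.5 * K

    F = hcore
    D = None
    energy = 0.0
    errs, focks = [], []
    converged = False
    for cycle in range(max_cycles):
        Fp = X.T @ F @ X
        eps, Cp = np.linalg.eigh(Fp)
        C = X @ Cp
        D = 2.0 * C[:, :n_occ] @ C[:, :n_occ].T
        F = fock(D)
        e_new = 0.5 * np.sum(D * (hcore + F)) + e_nn
        err = F @ D @ S - S @ D @ F
        errs.append(err)
        focks.append(F)
        if len(errs) > diis_size:
            errs.pop(0)
            focks.pop(0)
        if cycle > 0 and abs(e_new - energy) < conv_tol and np.max(np.abs(err)) < 1e-7:
            energy = e_new
            converged = True
            break
        energy = e_new
        if len(errs) >= 2:
            m = len(errs)
            B = -np.ones((m + 1, m + 1))
            B[m, m] = 0.0
            for a in range(m):
                for b in range(m):
                    B[a, b] = np.sum(errs[a] * errs[b])
            rhs = np.zeros(m + 1)
            rhs[m] = -1.0
            try:
                w = np.linalg.solve(B, rhs)[:m]
                F = sum(wi * Fi for wi, Fi in zip(w, focks))
            except np.linalg.LinAlgError:
                pass
    Fp = X.T @ F @ X
    eps, Cp = np.linalg.eigh(Fp)
    C = X @ Cp
    return SCFResult(energy, C, eps, S, hcore, eri, n_occ, converged, basis)
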