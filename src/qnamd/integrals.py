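"""Active-space electronic integrals, FCIDUMP I/O and second quantization.

Spin-orbital ordering is interleaved: spatial orbital ``p`` yields the alpha
spin-orbital ``2p`` and the beta spin-orbital ``2p+1``.  The two-electron
tensor is stored in physicist notation, ``g[p,q,r,s] = <pq|rs>``, so the
electronic Hamiltonian reads

    H = sum_rs h_rs a†_r a_s
      + 1/2 sum_pqrs g_pqrs a†_p a†_q a_s a_r
      + core_energy

with ``core_energy`` housing the nuclear repulsion plus any frozen-core
mean-field contribution.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

from .fermion import FermionOperator


@dataclass(frozen=True)
class ActiveSpaceSpec:
    """Selection of a (n_electrons, n_orbitals) active space."""

    n_active_electrons: int
    n_active_orbitals: int
    orbital_indices: tuple[int, ...] | None = None  # spatial MO indices, 0-based

    def __post_init__(self):
        if not 0 < self.n_active_electrons <= 2 * self.n_active_orbitals:
            raise ValueError("0 < n_electrons <= 2 n_orbitals required")
        if self.orbital_indices is not None:
            idx = tuple(self.orbital_indices)
            if list(idx) != sorted(set(idx)):
                raise ValueError("orbital_indices must be strictly increasing")
            if len(idx) != self.n_active_orbitals:
                raise ValueError("orbital_indices length mismatch")
            object.__setattr__(self, "orbital_indices", idx)

    @property
    def n_qubits(self) -> int:
        return 2 * self.n_active_orbitals


@dataclass
class SpatialIntegrals:
    """Restricted (spin-free) integrals over spatial orbitals.

    ``g`` is in chemist notation ``(ij|kl)`` as carried by FCIDUMP files.
    """

    h: np.ndarray  # (n, n)
    g: np.ndarray  # (n, n, n, n), chemist (ij|kl)
    core_energy: float = 0.0
    n_electrons: int | None = None
    ms2: int = 0

    @property
    def n_orbitals(self) -> int:
        return self.h.shape[0]

    def to_spin_orbital(self) -> "SpinOrbitalIntegrals":
        n = self.n_orbitals
        ns = 2 * n
        h_so = np.zeros((ns, ns))
        for sigma in (0, 1):
            h_so[sigma::2, sigma::2] = self.h
        # physicist <pq|rs> from chemist (pr|qs), with spin deltas p~r, q~s
        g_phys_spatial = self.g.transpose(0, 2, 1, 3)  # <pq|rs> = (pr|qs)
        g_so = np.zeros((ns, ns, ns, ns))
        for s1 in (0, 1):
            for s2 in (0, 1):
                g_so[s1::2, s2::2, s1::2, s2::2] = g_phys_spatial
        return SpinOrbitalIntegrals(h_so, g_so, self.core_energy)


@dataclass
class SpinOrbitalIntegrals:
    """One- and two-electron integrals over spin-orbitals (physicist g)."""

    h: np.ndarray
    g: np.ndarray
    core_energy: float = 0.0

    def __post_init__(self):
        if self.h.shape[0] % 2:
            raise ValueError("spin-orbital count must be even")
        if not np.allclose(self.h, self.h.T.conj(), atol=1e-10):
            raise ValueError("one-electron matrix must be Hermitian")

    @property
    def n_spin_orbitals(self) -> int:
        return self.h.shape[0]


# ---------------------------------------------------------------- FCIDUMP

def write_fcidump(path, integrals: SpatialIntegrals, threshold: float = 1e-14) -> None:
    """Write spatial integrals in the Molpro FCIDUMP dialect (1-based)."""
    n = integrals.n_orbitals
    nelec = integrals.n_electrons or 0
    with open(path, "w") as fh:
        orbsym = ",".join(["1"] * n)
        fh.write(
            f"&FCI NORB={n},NELEC={nelec},MS2={integrals.ms2},\n"
            f"  ORBSYM={orbsym},\n  ISYM=1,\n&END\n"
        )
        g = integrals.g
        for i in range(n):
            for j in range(i + 1):
                for k in range(i + 1):
                    lmax = j if k == i else k
                    for l in range(lmax + 1):
                        v = g[i, j, k, l]
                        if abs(v) > threshold:
                            fh.write(f"{v:23.16e} {i+1:4d} {j+1:4d} {k+1:4d} {l+1:4d}\n")
        for i in range(n):
            for j in range(i + 1):
                v = integrals.h[i, j]
                if abs(v) > threshold:
                    fh.write(f"{v:23.16e} {i+1:4d} {j+1:4d}    0    0\n")
        fh.write(f"{integrals.core_energy:23.16e}    0    0    0    0\n")


def read_fcidump(path) -> SpatialIntegrals:
    """Read a Molpro-dialect FCIDUMP file into spatial integrals.

    The 8-fold permutational symmetry of the real chemist-notation integrals
    is restored from the unique entries stored in the file.
    """
    with open(path) as fh:
        text = fh.read()
    m = re.search(r"&FCI(.*?)&END", text, re.S | re.I)
    if m is None:
        # Some dialects terminate the namelist with a bare "/"
        m = re.search(r"&FCI(.*?)(?:^\s*/\s*$)", text, re.S | re.I | re.M)
    if m is None:
        raise ValueError("malformed FCIDUMP header: no &FCI ... &END namelist")
    header = m.group(1)

    def _get(key, default=None):
        mm = re.search(rf"{key}\s*=\s*(-?\d+)", header, re.I)
        return int(mm.group(1)) if mm else default

    norb = _get("NORB")
    if norb is None:
        raise ValueError("malformed FCIDUMP header: NORB missing")
    nelec = _get("NELEC", 0)
    ms2 = _get("MS2", 0)

    h = np.zeros((norb, norb))
    g = np.zeros((norb, norb, norb, norb))
    core = 0.0
    body = text[m.end():]
    for line in body.strip().splitlines():
        parts = line.split()
        if len(parts) != 5:
            continue
        v = float(parts[0].replace("D", "e").replace("d", "e"))
        i, j, k, l = (int(x) for x in parts[1:])
        for idx in (i, j, k, l):
            if idx < 0 or idx > norb:
                raise ValueError(f"orbital index {idx} outside NORB={norb}")
        if i == j == k == l == 0:
            core = v
        elif k == l == 0:
            h[i - 1, j - 1] = h[j - 1, i - 1] = v
        else:
            i, j, k, l = i - 1, j - 1, k - 1, l - 1
            for a, b, c, d in (
                (i, j, k, l), (j, i, k, l), (i, j, l, k), (j, i, l, k),
                (k, l, i, j), (l, k, i, j), (k, l, j, i), (l, k, j, i),
            ):
                g[a, b, c, d] = v
    return SpatialIntegrals(h, g, core, n_electrons=nelec or None, ms2=ms2)


# ---------------------------------------------------- second quantization

def second_quantized_hamiltonian(integrals: SpinOrbitalIntegrals) -> FermionOperator:
    """Normal-ordered term list of the active-space electronic Hamiltonian."""
    h, g = integrals.h, integrals.g
    n = integrals.n_spin_orbitals
    terms = {(): complex(integrals.core_energy)}
    for r in range(n):
        for s in range(n):
            if abs(h[r, s]) > 0:
                terms[((r, True), (s, False))] = complex(h[r, s])
    for p in range(n):
        for q in range(n):
            for r in range(n):
                for s in range(n):
                    v = g[p, q, r, s]
                    if abs(v) > 0:
                        term = ((p, True), (q, True), (s, False), (r, False))
                        terms[term] = terms.get(term, 0.0) + 0.5 * v
    op = FermionOperator(terms)
    return op


def one_body_operator(matrix: np.ndarray, constant: float = 0.0) -> FermionOperator:
    """sum_pq M_pq a†_p a_q + constant, over spin-orbitals."""
    n = matrix.shape[0]
    terms = {(): complex(constant)} if constant else {}
    for p in range(n):
        for q in range(n):
            if abs(matrix[p, q]) > 0:
                terms[((p, True), (q, False))] = complex(matrix[p, q])
    return FermionOperator(terms)


def _pair_index(i: int, j: int) -> int:
    a, b = (i, j) if i >= j else (j, i)
    return a * (a + 1) // 2 + b


def pack_g8(g: np.ndarray) -> np.ndarray:
    """Unique elements of a real chemist-notation tensor (8-fold symmetry)."""
    n = g.shape[0]
    npair = n * (n + 1) // 2
    out = np.zeros(npair * (npair + 1) // 2)
    for i in range(n):
        for j in range(i + 1):
            for k in range(i + 1):
                lmax = j if k == i else k
                for l in range(lmax + 1):
                    out[_pair_index(_pair_index(i, j), _pair_index(k, l))] = g[i, j, k, l]
    return out


def unpack_g8(packed: np.ndarray, n: int) -> np.ndarray:
    g = np.zeros((n, n, n, n))
    for i in range(n):
        for j in range(n):
            for k in range(n):
                for l in range(n):
                    g[i, j, k, l] = packed[
                        _pair_index(_pair_index(i, j), _pair_index(k, l))
                    ]
    return g


def spatial_one_body_to_spin(matrix: np.ndarray) -> np.ndarray:
    """Expand a spatial one-electron matrix to interleaved spin-orbitals."""
    n = matrix.shape[0]
    out = np.zeros((2 * n, 2 * n))
    for sigma in (0, 1):
        out[sigma::2, sigma::2] = matrix
    return out
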