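"""Pauli-string algebra for qubit Hamiltonians and observables.

A Pauli word is stored as a tuple of ``(qubit, letter)`` pairs sorted by
qubit index, with identity factors omitted; the empty tuple is the identity.
A :class:`QubitOperator` maps distinct words to complex weights, i.e. it
represents ``sum_alpha w_alpha P_alpha``.

Basis-state convention: bit ``q`` of an integer basis index is the
occupation of qubit ``q`` (little-endian), so statevectors have length
``2**n_qubits`` and qubit 0 toggles the least significant bit.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import scipy.sparse as sp

_LETTERS = ("X", "Y", "Z")

# single-qubit products: (a, b) -> (phase, c) with  a.b = phase * c
_PRODUCT = {
    ("X", "X"): (1.0, None),
    ("Y", "Y"): (1.0, None),
    ("Z", "Z"): (1.0, None),
    ("X", "Y"): (1j, "Z"),
    ("Y", "X"): (-1j, "Z"),
    ("Y", "Z"): (1j, "X"),
    ("Z", "Y"): (-1j, "X"),
    ("Z", "X"): (1j, "Y"),
    ("X", "Z"): (-1j, "Y"),
}

Word = tuple[tuple[int, str], ...]


def _validate_word(word: Word) -> Word:
    word = tuple(sorted((int(q), p) for q, p in word))
    for q, p in word:
        if q < 0:
            raise ValueError("qubit indices must be >= 0")
        if p not in _LETTERS:
            raise ValueError(f"unknown Pauli letter {p!r}")
    if len({q for q, _ in word}) != len(word):
        raise ValueError("duplicate qubit in Pauli word")
    return word


def multiply_words(a: Word, b: Word) -> tuple[complex, Word]:
    """Product of two Pauli words: returns (phase, word)."""
    da, db = dict(a), dict(b)
    phase = 1.0 + 0.0j
    out = {}
    for q in set(da) | set(db):
        pa, pb = da.get(q), db.get(q)
        if pa is None:
            out[q] = pb
        elif pb is None:
            out[q] = pa
        else:
            ph, pc = _PRODUCT[(pa, pb)]
            phase *= ph
            if pc is not None:
                out[q] = pc
    return phase, tuple(sorted(out.items()))


def words_commute(a: Word, b: Word) -> bool:
    """Full (not merely qubit-wise) commutation of two Pauli words."""
    n_anti = sum(
        1 for q, p in a if q in dict(b) and dict(b)[q] != p
    )
    return n_anti % 2 == 0


def words_qubitwise_compatible(a: Word, b: Word) -> bool:
    """True if on every qubit the factors are equal or one is identity."""
    db = dict(b)
    return all(db.get(q, p) == p for q, p in a)


class QubitOperator:
    """Weighted sum of Pauli words acting on ``n_qubits`` qubits."""

    def __init__(self, terms: Mapping[Word, complex] | None = None, n_qubits: int | None = None):
        self.terms: dict[Word, complex] = {}
        if terms:
            for word, coeff in terms.items():
                word = _validate_word(word)
                self.terms[word] = self.terms.get(word, 0.0) + complex(coeff)
        inferred = 1 + max((q for w in self.terms for q, _ in w), default=-1)
        self.n_qubits = n_qubits if n_qubits is not None else max(inferred, 1)
        if inferred > self.n_qubits:
            raise ValueError("qubit index exceeds n_qubits")

    # ------------------------------------------------------------- algebra
    @classmethod
    def identity(cls, n_qubits: int, coeff: complex = 1.0) -> "QubitOperator":
        return cls({(): coeff}, n_qubits)

    def copy(self) -> "QubitOperator":
        return QubitOperator(dict(self.terms), self.n_qubits)

    def __add__(self, other):
        if np.isscalar(other):
            other = QubitOperator.identity(self.n_qubits, other)
        terms = dict(self.terms)
        for w, c in other.terms.items():
            terms[w] = terms.get(w, 0.0) + c
        return QubitOperator(terms, max(self.n_qubits, other.n_qubits))

    __radd__ = __add__

    def __sub__(self, other):
        return self + (other * -1.0)

    def __mul__(self, other):
        if np.isscalar(other):
            return QubitOperator({w: c * other for w, c in self.terms.items()}, self.n_qubits)
        terms: dict[Word, complex] = {}
        for wa, ca in self.terms.items():
            for wb, cb in other.terms.items():
                phase, w = multiply_words(wa, wb)
                terms[w] = terms.get(w, 0.0) + phase * ca * cb
        return QubitOperator(terms, max(self.n_qubits, other.n_qubits))

    __rmul__ = lambda self, other: self * other

    def dagger(self) -> "QubitOperator":
        return QubitOperator({w: np.conj(c) for w, c in self.terms.items()}, self.n_qubits)

    def prune(self, threshold: float = 1e-12) -> "QubitOperator":
        """Drop terms with |coefficient| below ``threshold``."""
        return QubitOperator(
            {w: c for w, c in self.terms.items() if abs(c) > threshold}, self.n_qubits
        )

    @property
    def constant(self) -> complex:
        return self.terms.get((), 0.0)

    def is_hermitian(self, tol: float = 1e-10) -> bool:
        return all(abs(c.imag) <= tol for c in self.terms.values())

    def __len__(self):
        return len(self.terms)

    def __repr__(self):
        return f"QubitOperator({len(self.terms)} terms, {self.n_qubits} qubits)"

    # ------------------------------------------------ matrices and vectors
    def _word_action(self, word: Word):
        """Signed-permutation action of a word on all 2^n basis states.

        Returns (target_indices, phases): ``P |b> = phases[b] |target[b]>``.
        """
        n = self.n_qubits
        b = np.arange(2**n, dtype=np.int64)
        xmask = 0
        phases = np.ones(2**n, dtype=complex)
        for q, p in word:
            bit = (b >> q) & 1
            if p == "X":
                xmask |= 1 << q
            elif p == "Y":
                xmask |= 1 << q
                phases = phases * np.where(bit, -1j, 1j)
            else:  # Z
                phases = phases * np.where(bit, -1.0, 1.0)
        return b ^ xmask, phases

    def apply(self, psi: np.ndarray) -> np.ndarray:
        """Operator acting on a statevector."""
        out = np.zeros_like(psi, dtype=complex)
        for word, coeff in self.terms.items():
            target, phases = self._word_action(word)
            out[target] += coeff * phases * psi
        return out

    def to_sparse(self) -> sp.csr_matrix:
        cached = getattr(self, "_sparse_cache", None)
        if cached is not None:
            return cached
        dim = 2**self.n_qubits
        mat = sp.csr_matrix((dim, dim), dtype=complex)
        for word, coeff in self.terms.items():
            target, phases = self._word_action(word)
            mat = mat + sp.csr_matrix(
                (coeff * phases, (target, np.arange(dim))), shape=(dim, dim)
            )
        self._sparse_cache = mat
        return mat

    def to_dense(self) -> np.ndarray:
        return self.to_sparse().toarray()

    # ------------------------------------------------------- serialization
    def to_text(self) -> str:
        """Line-oriented text form ``coeff  word`` (e.g. ``0.5 X0 Y3``)."""
        lines = []
        for word in sorted(self.terms):
            c = self.terms[word]
            coeff = f"{c.real:.16e}" if abs(c.imag) < 1e-300 else f"({c.real:.16e}{c.imag:+.16e}j)"
            label = " ".join(f"{p}{q}" for q, p in word) or "I"
            lines.append(f"{coeff} {label}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str, n_qubits: int | None = None) -> "QubitOperator":
        terms: dict[Word, complex] = {}
        for line in text.strip().splitlines():
            parts = line.split()
            coeff = complex(parts[0])
            word = tuple(
                (int(tok[1:]), tok[0]) for tok in parts[1:] if tok != "I"
            )
            terms[_validate_word(word)] = terms.get(word, 0.0) + coeff
        return cls(terms, n_qubits)


# ------------------------------------------------------ measurement grouping

def count_native_pauli_bases(op: QubitOperator, include_constant: bool = True) -> int:
    """Number of native Pauli measurement bases: one per Pauli string.

    Measuring a Hamiltonian term by term requires one measurement setting
    per distinct Pauli word, so the native count is simply the number of
    strings N_P in the operator (the identity term counts as a string by
    convention; pass ``include_constant=False`` to drop it).  See
    :func:`count_qubitwise_bases` and :func:`group_commuting_cliques` for
    the two grouping-based reductions.
    """
    n = len(op.terms)
    if not include_constant and () in op.terms:
        n -= 1
    return n


def count_qubitwise_bases(op: QubitOperator) -> int:
    """Measurement settings after merging Pauli words qubit-wise.

    Two words can share one setting iff on every qubit their factors are
    equal or one of them is the identity (the identity slots act as
    wildcards that the merge fills in).  Words are processed in sorted
    order and greedily merged into the first compatible setting, which
    makes the count deterministic.  The constant term needs no measurement
    and is excluded.
    """
    bases: list[dict[int, str]] = []
    for word in sorted(op.terms):
        if not word:
            continue
        d = dict(word)
        for basis in bases:
            if all(basis.get(q, p) == p for q, p in d.items()):
                basis.update(d)
                break
        else:
            bases.append(d)
    return len(bases)


def group_commuting_cliques(op: QubitOperator) -> list[list[Word]]:
    """Partition the non-constant words into mutually commuting cliques.

    Greedy largest-first colouring of the anticommutation graph (full
    commutation, not merely qubit-wise), with lexicographic tie-breaking for
    determinism.  Colour classes are cliques of the commutation graph.
    """
    words = sorted(w for w in op.terms if w)
    syms = []
    for w in words:
        x = z = 0
        for q, p in w:
            if p in ("X", "Y"):
                x |= 1 << q
            if p in ("Y", "Z"):
                z |= 1 << q
        syms.append((x, z))

    def anticommute(i, j):
        xi, zi = syms[i]
        xj, zj = syms[j]
        return (bin(xi & zj).count("1") + bin(zi & xj).count("1")) % 2 == 1

    n = len(words)
    adj = [set() for _ in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            if anticommute(i, j):
                adj[i].add(j)
                adj[j].add(i)

    order = sorted(range(n), key=lambda i: (-len(adj[i]), words[i]))
    colour = {}
    for i in order:
        used = {colour[j] for j in adj[i] if j in colour}
        c = 0
        while c in used:
            c += 1
        colour[i] = c
    cliques: dict[int, list[Word]] = {}
    for i, c in colour.items():
        cliques.setdefault(c, []).append(words[i])
    return [sorted(cliques[c]) for c in sorted(cliques)]
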