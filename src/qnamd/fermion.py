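"""Second-quantized fermionic operators and the Jordan–Wigner mapping.

A term is a tuple of elementary operators ``(mode, dagger)`` applied left to
right as written, e.g. ``((2, True), (0, False))`` is ``a†_2 a_0``.  Modes
index spin-orbitals; the interleaved convention (alpha on even, beta on odd
modes) is used throughout the package.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np

from .pauli import QubitOperator

Term = tuple[tuple[int, bool], ...]


class FermionOperator:
    """Weighted sum of products of fermionic creation/annihilation operators."""

    def __init__(self, terms: Mapping[Term, complex] | None = None):
        self.terms: dict[Term, complex] = {}
        if terms:
            for t, c in terms.items():
                t = tuple((int(m), bool(d)) for m, d in t)
                self.terms[t] = self.terms.get(t, 0.0) + complex(c)

    @classmethod
    def from_term(cls, term: Term, coeff: complex = 1.0) -> "FermionOperator":
        return cls({tuple(term): coeff})

    def __add__(self, other):
        if np.isscalar(other):
            other = FermionOperator({(): complex(other)})
        terms = dict(self.terms)
        for t, c in other.terms.items():
            terms[t] = terms.get(t, 0.0) + c
        return FermionOperator(terms)

    __radd__ = __add__

    def __mul__(self, other):
        if np.isscalar(other):
            return FermionOperator({t: c * other for t, c in self.terms.items()})
        terms: dict[Term, complex] = {}
        for ta, ca in self.terms.items():
            for tb, cb in other.terms.items():
                t = ta + tb
                terms[t] = terms.get(t, 0.0) + ca * cb
        return FermionOperator(terms)

    __rmul__ = lambda self, other: self * other

    def __sub__(self, other):
        return self + (-1.0) * other

    def dagger(self) -> "FermionOperator":
        terms: dict[Term, complex] = {}
        for t, c in self.terms.items():
            td = tuple((m, not d) for m, d in reversed(t))
            terms[td] = terms.get(td, 0.0) + np.conj(c)
        return FermionOperator(terms)

    @property
    def n_modes(self) -> int:
        return 1 + max((m for t in self.terms for m, _ in t), default=-1)

    def __len__(self):
        return len(self.terms)

    def __repr__(self):
        return f"FermionOperator({len(self.terms)} terms)"


def _ladder_jw(mode: int, dagger: bool, n_qubits: int) -> QubitOperator:
    """a†_p -> 1/2 (X_p - i Y_p) Z_{p-1} ... Z_0  (adjoint for a_p)."""
    zstring = tuple((q, "Z") for q in range(mode))
    sign = -1j if dagger else 1j
    return QubitOperator(
        {
            zstring + ((mode, "X"),): 0.5,
            zstring + ((mode, "Y"),): 0.5 * sign,
        },
        n_qubits,
    )


def jordan_wigner(op: FermionOperator, n_qubits: int | None = None) -> QubitOperator:
    """Jordan–Wigner transform of a fermionic operator to a qubit operator."""
    n = n_qubits if n_qubits is not None else max(op.n_modes, 1)
    result = QubitOperator({}, n)
    for term, coeff in op.terms.items():
        if any(m >= n for m, _ in term):
            raise ValueError("mode index exceeds qubit count")
        part = QubitOperator.identity(n, coeff)
        for mode, dagger in term:
            part = part * _ladder_jw(mode, dagger, n)
        result = result + part
    return result.prune(0.0)
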