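"""k-UpCCGSD ansatz and exact statevector simulation.

The ansatz applies, per layer, all generalized spin-adapted single
excitations over spatial-orbital pairs p<q and all paired double
excitations moving an alpha-beta pair p -> q, each as the exponential of an
anti-Hermitian Jordan–Wigner-mapped generator:

    U(theta) = prod_l prod_mu exp(theta_{l,mu} G_mu) ,

acting on the Hartree–Fock reference determinant.  The Pauli terms inside
one generator mutually commute, so each exponential factorizes exactly into
one rotation per Pauli term; the term order is fixed lexicographically,
which pins the ansatz (a different order would define a slightly different
but equally valid ansatz).

All generators conserve particle number and S_z by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .fermion import FermionOperator, jordan_wigner
from .pauli import QubitOperator


def _excitation(*modes_dagger) -> FermionOperator:
    return FermionOperator.from_term(tuple(modes_dagger))


def single_generator(p: int, q: int) -> FermionOperator:
    """Spin-adapted generalized single p->q (spatial), anti-Hermitian."""
    g = FermionOperator()
    for sigma in (0, 1):
        up, uq = 2 * p + sigma, 2 * q + sigma
        g = g + _excitation((uq, True), (up, False)) - _excitation((up, True), (uq, False))
    return g


def paired_double_generator(p: int, q: int) -> FermionOperator:
    """Paired double moving the alpha-beta pair p -> q, anti-Hermitian."""
    pa, pb, qa, qb = 2 * p, 2 * p + 1, 2 * q, 2 * q + 1
    ex = _excitation((qa, True), (qb, True), (pb, False), (pa, False))
    return ex - ex.dagger()


@dataclass
class Ansatz:
    """Compiled product-of-exponentials circuit acting on a reference."""

    n_qubits: int
    n_electrons: int
    reference_occ: tuple[int, ...]  # occupied spin-orbital (mode) indices
    generators: list[QubitOperator]
    parameter_labels: list[str]
    _compiled: list = field(default=None, repr=False)

    @property
    def n_parameters(self) -> int:
        return len(self.generators)

    @property
    def reference_index(self) -> int:
        return sum(1 << m for m in self.reference_occ)

    def reference_state(self) -> np.ndarray:
        psi = np.zeros(2**self.n_qubits, dtype=complex)
        psi[self.reference_index] = 1.0
        return psi

    def _compile(self):
        if self._compiled is None:
            compiled = []
            for g in self.generators:
                rots = []
                for word in sorted(g.terms):
                    c = g.terms[word]
                    if abs(c.real) > 1e-14:
                        raise ValueError("generator must be anti-Hermitian (i * real Paulis)")
                    target, phases = g._word_action(word)
                    rots.append((target, phases, c.imag))
                compiled.append(rots)
            self._compiled = compiled
        return self._compiled

    def apply_unitary(self, theta: np.ndarray, psi: np.ndarray, dagger: bool = False) -> np.ndarray:
        """U(theta) |psi> (or U† when dagger), applied in place-free fashion."""
        theta = np.asarray(theta, float)
        if len(theta) != self.n_parameters:
            raise ValueError("parameter vector length mismatch")
        compiled = self._compile()
        order = range(len(compiled) - 1, -1, -1) if dagger else range(len(compiled))
        sign = -1.0 if dagger else 1.0
        for i in order:
            t = sign * theta[i]
            rots = reversed(compiled[i]) if dagger else compiled[i]
            for target, phases, c in rots:
                # exp(i * t * c * P) with P a self-inverse signed permutation
                ppsi = np.empty_like(psi)
                ppsi[target] = phases * psi
                psi = np.cos(t * c) * psi + 1j * np.sin(t * c) * ppsi
        return psi

    def apply_generator(self, index: int, psi: np.ndarray) -> np.ndarray:
        out = np.zeros_like(psi)
        for target, phases, c in self._compile()[index]:
            ppsi = np.empty_like(psi)
            ppsi[target] = phases * psi
            out += 1j * c * ppsi
        return out


def build_kupccgsd(n_qubits: int, n_electrons: int, k: int = 1) -> Ansatz:
    """k layers of generalized singles + paired doubles on n_qubits/2 orbitals."""
    if n_electrons % 2:
        raise ValueError("paired ansatz requires an even electron count")
    if k < 1:
        raise ValueError("k must be >= 1")
    n_spatial = n_qubits // 2
    if 2 * n_spatial != n_qubits:
        raise ValueError("n_qubits must be even (interleaved spin-orbitals)")
    generators, labels = [], []
    for layer in range(k):
        for p in range(n_spatial):
            for q in range(p + 1, n_spatial):
                generators.append(jordan_wigner(single_generator(p, q), n_qubits))
                labels.append(f"L{layer}_s_{p}_{q}")
        for p in range(n_spatial):
            for q in range(p + 1, n_spatial):
                generators.append(jordan_wigner(paired_double_generator(p, q), n_qubits))
                labels.append(f"L{layer}_d_{p}_{q}")
    reference = tuple(range(n_electrons))
    return Ansatz(n_qubits, n_electrons, reference, generators, labels)


def prepare_state(ansatz: Ansatz, theta: np.ndarray) -> np.ndarray:
    """U(theta) acting on the Hartree–Fock reference determinant."""
    return ansatz.apply_unitary(theta, ansatz.reference_state())
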