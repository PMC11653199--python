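"""Gradients, nonadiabatic couplings, transition dipoles and CI expansions.

All derivative properties come from expectation values of the
finite-difference Hamiltonian derivative operators (Hellmann–Feynman only;
Pulay basis-set forces are neglected, an approximation validated by
comparing against finite differences of the energy):

    grad_m(I, xi)  = <Psi_m| dH/dR_{I,xi} |Psi_m>
    nac_ml(I, xi)  = <Psi_m| dH/dR_{I,xi} |Psi_l> / (E_l - E_m)

One set of derivative operators serves every state, so the cost of
gradients and couplings grows only weakly with the number of states.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import Geometry
from .integrals import ActiveSpaceSpec
from .pauli import QubitOperator
from .provider import ElectronicStructureProvider, hamiltonian_derivative
from .vqe import ElectronicStateSet, VariationalState

DEGENERACY_FLOOR = 1e-6  # hartree
NAC_CAP = 1e6  # 1/bohr, applied when a pair is flagged near-degenerate


def hamiltonian_derivatives(provider: ElectronicStructureProvider, geometry: Geometry,
                            active_space: ActiveSpaceSpec,
                            shift_angstrom: float = 0.001) -> list[list[QubitOperator]]:
    """dH/dR operators for every atom and Cartesian axis, [atom][axis]."""
    return [
        [hamiltonian_derivative(provider, geometry, active_space, atom, axis, shift_angstrom)
         for axis in range(3)]
        for atom in range(geometry.n_atoms)
    ]


def _matrix_element(bra: VariationalState, op: QubitOperator, ket: VariationalState) -> float:
    return float(np.vdot(bra.statevector, op.to_sparse() @ ket.statevector).real)


def state_gradients(state_set: ElectronicStateSet,
                    deriv_ops: list[list[QubitOperator]]) -> list[np.ndarray]:
    """Energy gradients (hartree/bohr), one (N_atoms, 3) array per state.

    The derivative operators carry the scalar-term (nuclear repulsion and
    frozen core) derivative in their identity component, so the returned
    gradients are total-energy gradients.
    """
    grads = []
    for state in state_set.states:
        g = np.array([
            [_matrix_element(state, deriv_ops[a][x], state) for x in range(3)]
            for a in range(len(deriv_ops))
        ])
        grads.append(g)
    return grads


@dataclass
class NACVector:
    """First-order nonadiabatic coupling vector between states (m, l)."""

    vector: np.ndarray  # (N_atoms, 3), 1/bohr
    m: int
    l: int
    gap: float  # E_l - E_m, hartree
    near_degenerate: bool = False


def nac_vector(state_set: ElectronicStateSet, m: int, l: int,
               deriv_ops: list[list[QubitOperator]],
               degeneracy_floor: float = DEGENERACY_FLOOR) -> NACVector:
    """d_ml = <Psi_m|dH/dR|Psi_l> / (E_l - E_m); antisymmetric under m<->l."""
    if m == l:
        raise ValueError("nonadiabatic coupling requires two distinct states")
    sm, sl = state_set.states[m], state_set.states[l]
    gap = sl.energy - sm.energy
    near = abs(gap) < degeneracy_floor
    denom = gap if not near else np.sign(gap or 1.0) * degeneracy_floor
    vec = np.array([
        [_matrix_element(sm, deriv_ops[a][x], sl) for x in range(3)]
        for a in range(len(deriv_ops))
    ]) / denom
    if near:
        norm = np.linalg.norm(vec)
        if norm > NAC_CAP:
            vec *= NAC_CAP / norm
    return NACVector(vec, m, l, gap, near)


def transition_dipole_and_f(state_set: ElectronicStateSet, m: int, l: int,
                            dipole_ops: list[QubitOperator]):
    """Transition dipole (a.u., length gauge) and oscillator strength.

    f = (2/3) |dE| |mu_ml|^2 in atomic units.  The constant (nuclear plus
    frozen-core) part of the dipole operator does not contribute between
    orthogonal states.
    """
    if m == l:
        raise ValueError("transition moment requires two distinct states")
    sm, sl = state_set.states[m], state_set.states[l]
    mu = np.array([_matrix_element(sm, op, sl) for op in dipole_ops])
    # remove the constant part times the (tiny) residual overlap
    ov = float(np.vdot(sm.statevector, sl.statevector).real)
    mu -= ov * np.array([op.constant.real for op in dipole_ops])
    de = abs(sl.energy - sm.energy)
    f = (2.0 / 3.0) * de * float(mu @ mu)
    return mu, f


# --------------------------------------------------------- CI expansions

@dataclass
class CIExpansion:
    """Determinant expansion of a variational state for overlap evaluation.

    Determinants are stored spin-blocked as (alpha, beta) tuples of
    occupied *spatial* orbital indices; the stored coefficients include the
    sign of reordering the interleaved spin-orbital creation string into
    alpha-block-then-beta-block order, so that the expansion can be
    contracted directly with spin-factorized determinant overlaps.
    """

    determinants: list[tuple[tuple[int, ...], tuple[int, ...]]]
    coefficients: np.ndarray
    mo_matrix: np.ndarray | None = None
    norm_retained: float = 1.0
    warning: str | None = None

    def __len__(self):
        return len(self.determinants)


def _decode_modes(index: int, n_qubits: int):
    return [m for m in range(n_qubits) if (index >> m) & 1]


def _spin_block_sign(modes: list[int]) -> int:
    """Parity of moving beta modes past alpha modes (interleaved -> blocked)."""
    sign = 1
    alphas = [m for m in modes if m % 2 == 0]
    for b in (m for m in modes if m % 2 == 1):
        crossings = sum(1 for a in alphas if a > b)
        if crossings % 2:
            sign = -sign
    return sign


def extract_ci_expansion(state: VariationalState, threshold: float = 1e-6,
                         mo_matrix: np.ndarray | None = None,
                         norm_budget: float = 0.999) -> CIExpansion:
    """Configuration-interaction-type expansion read off the statevector.

    Amplitudes are taken in the Jordan–Wigner computational basis; bit q of
    a basis index is the occupation of spin-orbital q (alpha even, beta
    odd).  Coefficients with |c| >= threshold are kept and the retained
    squared norm is reported; a global phase is removed so coefficients are
    real for the real-amplitude ansatz used here.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    psi = state.statevector
    n_qubits = state.ansatz.n_qubits
    pivot = int(np.argmax(np.abs(psi)))
    phase = psi[pivot] / abs(psi[pivot])
    psi = psi / phase
    dets, coeffs = [], []
    norm = 0.0
    for idx in np.nonzero(np.abs(psi) >= threshold)[0]:
        modes = _decode_modes(int(idx), n_qubits)
        c = psi[idx]
        if abs(c.imag) > 1e-8:
            raise ValueError("statevector is not real up to a global phase")
        sign = _spin_block_sign(modes)
        alpha = tuple(m // 2 for m in modes if m % 2 == 0)
        beta = tuple(m // 2 for m in modes if m % 2 == 1)
        dets.append((alpha, beta))
        coeffs.append(sign * c.real)
        norm += abs(c) ** 2
    warning = None
    if norm < norm_budget:
        warning = f"retained norm {norm:.6f} below budget {norm_budget}"
    return CIExpansion(dets, np.array(coeffs), mo_matrix, norm, warning)
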