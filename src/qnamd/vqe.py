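"""VQE ground states and penalty-based (VQD) excited states.

The ground state minimizes E(theta) = <Psi(theta)|H|Psi(theta)> over the
ansatz parameters (the variational bound guarantees E >= E_exact).  Excited
state n minimizes the deflation cost

    L(theta) = <Psi|H|Psi> + sum_j lambda_j |<Psi(theta)|Psi_j>|^2

over the previously converged states j < n; the default penalty weight is
the magnitude of the VQE ground-state energy, which is sufficient for bound
(negative-energy) excited states.  Optimization is BFGS with analytic
parameter gradients obtained by the adjoint (reverse-sweep) method on the
statevector.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.optimize
import scipy.sparse.linalg

from .ansatz import Ansatz, build_kupccgsd
from .fermion import FermionOperator, jordan_wigner
from .pauli import QubitOperator

DEFAULT_GTOL = 1e-6
DEFAULT_MAXITER = 500


def expectation(psi: np.ndarray, op: QubitOperator) -> float:
    """<psi|op|psi> for a Hermitian operator; the value is real by construction."""
    if not op.is_hermitian():
        raise ValueError("expectation requires a Hermitian operator")
    val = np.vdot(psi, op.apply(psi))
    return float(val.real)


def transition_element(bra: np.ndarray, op: QubitOperator, ket: np.ndarray) -> complex:
    return complex(np.vdot(bra, op.apply(ket)))


@dataclass
class VariationalState:
    """A converged (or flagged) variational eigenstate approximation."""

    theta: np.ndarray
    statevector: np.ndarray
    energy: float
    n_iterations: int
    converged: bool
    ansatz: Ansatz
    max_lower_overlap_sq: float = 0.0  # for VQD states: final overlap with lower states


@dataclass
class ElectronicStateSet:
    """Ordered ground + excited states at one geometry."""

    states: list[VariationalState]
    lambda_used: list[float]
    overlaps_sq: np.ndarray  # pairwise |<m|l>|^2, same geometry
    flagged: bool = False

    @property
    def energies(self) -> np.ndarray:
        return np.array([s.energy for s in self.states])

    def __len__(self):
        return len(self.states)


class _Objective:
    """Cost and adjoint gradient of <psi|A_eff|psi> for a product ansatz."""

    def __init__(self, ansatz: Ansatz, hmat, penalties=()):
        self.ansatz = ansatz
        self.hmat = hmat  # sparse matrix of H
        self.penalties = penalties  # list of (lambda, statevector)
        self.n_calls = 0

    def _apply_a(self, psi):
        out = self.hmat @ psi
        for lam, phi in self.penalties:
            out = out + lam * np.vdot(phi, psi) * phi
        return out

    def value_and_grad(self, theta):
        self.n_calls += 1
        ansatz = self.ansatz
        psi = ansatz.apply_unitary(theta, ansatz.reference_state())
        apsi = self._apply_a(psi)
        value = float(np.vdot(psi, apsi).real)
        grad = np.zeros(len(theta))
        lam = apsi
        cur = psi
        compiled = ansatz._compile()
        for i in range(len(compiled) - 1, -1, -1):
            # cur = psi_i = U_i ... U_1 |ref>, lam = U_{i+1..N}† A psi
            gpsi = ansatz.apply_generator(i, cur)
            grad[i] = 2.0 * float(np.vdot(lam, gpsi).real)
            if i > 0:
                cur = self._undo(i, theta[i], cur)
                lam = self._undo(i, theta[i], lam)
        return value, grad

    def _undo(self, i, t, psi):
        for target, phases, c in reversed(self.ansatz._compile()[i]):
            ppsi = np.empty_like(psi)
            ppsi[target] = phases * psi
            psi = np.cos(t * c) * psi - 1j * np.sin(t * c) * ppsi
        return psi


def _minimize(objective: _Objective, theta0, gtol, maxiter, free_mask=None):
    theta0 = np.asarray(theta0, float)
    if free_mask is None:
        fun = objective.value_and_grad
        x0 = theta0
    else:
        free = np.asarray(free_mask, bool)

        def fun(x):
            full = theta0.copy()
            full[free] = x
            val, grad = objective.value_and_grad(full)
            return val, grad[free]

        x0 = theta0[free]
    res = scipy.optimize.minimize(
        fun, x0, jac=True, method="BFGS",
        options={"gtol": gtol, "maxiter": maxiter},
    )
    converged = bool(res.success) or np.linalg.norm(res.jac, np.inf) < 10 * gtol
    if free_mask is None:
        theta = res.x
    else:
        theta = theta0.copy()
        theta[np.asarray(free_mask, bool)] = res.x
    return theta, float(res.fun), int(res.nit), converged


def vqe(H: QubitOperator, ansatz: Ansatz, theta0=None, gtol: float = DEFAULT_GTOL,
        maxiter: int = DEFAULT_MAXITER, free_mask=None) -> VariationalState:
    """Ground-state VQE: BFGS minimization of <H> from theta0 (zeros by default)."""
    if not H.is_hermitian():
        raise ValueError("Hamiltonian must be Hermitian")
    theta0 = np.zeros(ansatz.n_parameters) if theta0 is None else np.asarray(theta0, float)
    obj = _Objective(ansatz, H.to_sparse())
    theta, energy, nit, converged = _minimize(obj, theta0, gtol, maxiter, free_mask)
    psi = ansatz.apply_unitary(theta, ansatz.reference_state())
    return VariationalState(theta, psi, energy, nit, converged, ansatz)


def vqd(H: QubitOperator, ansatz: Ansatz, lower_states: list[VariationalState],
        lam: float | list[float], theta0=None, gtol: float = DEFAULT_GTOL,
        maxiter: int = DEFAULT_MAXITER,
        overlap_tol: float = 1e-3, require_converged: bool = True,
        free_mask=None) -> VariationalState:
    """Penalty-based excited-state search orthogonal to ``lower_states``.

    The overlap penalty is evaluated directly on statevectors, which equals
    the projector-expectation form |<Psi(theta)|Psi_j>|^2 exactly.
    """
    lams = [lam] * len(lower_states) if np.isscalar(lam) else list(lam)
    if any(l <= 0 for l in lams):
        raise ValueError("penalty weights must be positive")
    if require_converged and not all(s.converged for s in lower_states):
        raise ValueError("lower states must be converged before deflation")
    theta0 = np.zeros(ansatz.n_parameters) if theta0 is None else np.asarray(theta0, float)
    penalties = [(l, s.statevector) for l, s in zip(lams, lower_states)]
    obj = _Objective(ansatz, H.to_sparse(), penalties)
    theta, _, nit, converged = _minimize(obj, theta0, gtol, maxiter, free_mask)
    psi = ansatz.apply_unitary(theta, ansatz.reference_state())
    energy = float(np.vdot(psi, H.to_sparse() @ psi).real)
    max_ov = max((abs(np.vdot(s.statevector, psi)) ** 2 for s in lower_states), default=0.0)
    if max_ov > overlap_tol:
        converged = False  # collapsed onto a lower state
    return VariationalState(theta, psi, energy, nit, converged, ansatz, max_ov)


@dataclass
class AnsatzPolicy:
    """Per-state ansatz depth policy.

    ``uniform``: every state uses the same k-layer ansatz.
    ``grow``: state n uses k_base + n layers with the lower layers' angles
    initialized from the previous state and optionally frozen — one reading
    of protocols that report more angles than optimized parameters for
    higher states.
    """

    mode: str = "uniform"
    k: int = 1
    freeze_lower_layers: bool = False

    def ansatz_for_state(self, state_index: int, n_qubits: int, n_electrons: int) -> Ansatz:
        k = self.k if self.mode == "uniform" else self.k + state_index
        return build_kupccgsd(n_qubits, n_electrons, k)

    def free_mask_for_state(self, state_index: int, ansatz: Ansatz):
        """Boolean mask of optimized angles (None = all free)."""
        if self.mode != "grow" or not self.freeze_lower_layers or state_index == 0:
            return None
        k = self.k + state_index
        layer = ansatz.n_parameters // k
        mask = np.zeros(ansatz.n_parameters, dtype=bool)
        mask[-layer:] = True
        return mask


def solve_state_set(H: QubitOperator, n_states: int, n_electrons: int,
                    policy: AnsatzPolicy | None = None,
                    warm_start: list[np.ndarray] | None = None,
                    lam: float | None = None,
                    gtol: float = DEFAULT_GTOL, maxiter: int = DEFAULT_MAXITER,
                    cold_start_scale: float = 0.1,
                    cold_start_seed: int = 7) -> ElectronicStateSet:
    """Sequential VQE + VQD solve of the lowest ``n_states`` states.

    ``warm_start`` passes per-state initial angles (typically the previous
    time step's converged angles); states are sorted by energy with a
    stable sort so that degenerate states keep their discovery order.

    Cold-started excited states begin from a small deterministic
    perturbation of theta = 0: the unperturbed reference is a local minimum
    of the deflated cost whenever the ground state is dominated by the
    reference determinant, and a symmetry-breaking kick is required to
    escape it.
    """
    if n_states < 1:
        raise ValueError("need at least one state")
    policy = policy or AnsatzPolicy()
    states: list[VariationalState] = []
    lambdas: list[float] = []
    for n in range(n_states):
        ansatz = policy.ansatz_for_state(n, H.n_qubits, n_electrons)
        free_mask = policy.free_mask_for_state(n, ansatz)
        theta0 = None
        if warm_start is not None and n < len(warm_start) and warm_start[n] is not None:
            theta0 = np.zeros(ansatz.n_parameters)
            m = min(len(theta0), len(warm_start[n]))
            theta0[:m] = warm_start[n][:m]
        elif n > 0:
            rng = np.random.default_rng(cold_start_seed + n)
            theta0 = cold_start_scale * rng.standard_normal(ansatz.n_parameters)
            if free_mask is not None:
                # frozen lower layers carry the previous state's angles
                prev = states[-1].theta
                theta0[: len(prev)] = prev
                theta0[~free_mask & (np.arange(len(theta0)) >= len(prev))] = 0.0
        if n == 0:
            states.append(vqe(H, ansatz, theta0, gtol, maxiter, free_mask))
        else:
            lam_n = lam if lam is not None else abs(states[0].energy)
            lambdas.append(lam_n)
            states.append(vqd(H, ansatz, states, lam_n, theta0, gtol, maxiter,
                              require_converged=False, free_mask=free_mask))
    order = np.argsort([s.energy for s in states], kind="stable")
    states = [states[i] for i in order]
    m = len(states)
    ov = np.zeros((m, m))
    for a in range(m):
        for b in range(m):
            ov[a, b] = abs(np.vdot(states[a].statevector, states[b].statevector)) ** 2
    flagged = not all(s.converged for s in states)
    return ElectronicStateSet(states, lambdas, ov, flagged)


# ------------------------------------------------------- exact oracle

def number_operator(n_qubits: int) -> QubitOperator:
    return jordan_wigner(
        FermionOperator({((m, True), (m, False)): 1.0 for m in range(n_qubits)}), n_qubits
    )


def sz_operator(n_qubits: int) -> QubitOperator:
    terms = {}
    for m in range(n_qubits):
        terms[((m, True), (m, False))] = 0.5 if m % 2 == 0 else -0.5
    return jordan_wigner(FermionOperator(terms), n_qubits)


def s_squared_operator(n_qubits: int) -> QubitOperator:
    """Total-spin S^2 = S- S+ + Sz (Sz + 1) over interleaved spin-orbitals."""
    n_spatial = n_qubits // 2
    splus = FermionOperator(
        {((2 * p, True), (2 * p + 1, False)): 1.0 for p in range(n_spatial)}
    )
    szf = FermionOperator(
        {((m, True), (m, False)): (0.5 if m % 2 == 0 else -0.5) for m in range(n_qubits)}
    )
    s2 = splus.dagger() * splus + szf * szf + szf
    return jordan_wigner(s2, n_qubits)


def sector_indices(n_qubits: int, n_electrons: int, sz: float | None = 0.0) -> np.ndarray:
    """Computational-basis indices with given particle number and S_z."""
    b = np.arange(2**n_qubits)
    occ = ((b[:, None] >> np.arange(n_qubits)[None, :]) & 1).astype(int)
    mask = occ.sum(axis=1) == n_electrons
    if sz is not None:
        szv = 0.5 * (occ[:, 0::2].sum(axis=1) - occ[:, 1::2].sum(axis=1))
        mask &= np.isclose(szv, sz)
    return np.nonzero(mask)[0]


def exact_spectrum(H: QubitOperator, n: int, n_electrons: int | None = None,
                   sz: float | None = 0.0, s2_target: float | None = None,
                   return_vectors: bool = False):
    """Lowest eigenvalues of the dense sector-restricted Hamiltonian matrix.

    With ``s2_target`` set (e.g. 0.0 for singlets), eigenvectors whose
    <S^2> differs from the target by more than 1e-6 are filtered out.
    Serves as the independent oracle for the variational solvers.
    """
    if H.n_qubits > 12:
        raise ValueError("dense oracle capped at 12 qubits")
    mat = H.to_dense()
    if n_electrons is not None:
        idx = sector_indices(H.n_qubits, n_electrons, sz)
        mat = mat[np.ix_(idx, idx)]
    else:
        idx = np.arange(mat.shape[0])
    vals, vecs = np.linalg.eigh(mat)
    if s2_target is not None:
        s2 = s_squared_operator(H.n_qubits).to_dense()[np.ix_(idx, idx)]
        keep = [
            i for i in range(len(vals))
            if abs(np.vdot(vecs[:, i], s2 @ vecs[:, i]).real - s2_target) < 1e-6
        ]
        vals, vecs = vals[keep], vecs[:, keep]
    vals, vecs = vals[:n], vecs[:, :n]
    if return_vectors:
        full = np.zeros((2**H.n_qubits, vecs.shape[1]), dtype=complex)
        full[idx] = vecs
        return vals, full
    return vals
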