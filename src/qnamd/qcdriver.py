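"""Electronic driver running VQE/VQD on a provider's qubit Hamiltonians.

This is the on-the-fly electronic-structure engine of the trajectory loop:
at each geometry it builds the active-space qubit Hamiltonian, solves the
requested number of states (warm-started from the previous step so the
deflation tracks the same states), evaluates Hellmann–Feynman gradients
from finite-difference Hamiltonian derivatives, and forms cross-timestep
overlaps from CI-type expansions of the statevectors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dynamics import ElectronicDriver
from .geometry import Geometry
from .integrals import ActiveSpaceSpec
from .overlap import ci_overlap_matrix
from .properties import extract_ci_expansion, hamiltonian_derivatives, state_gradients
from .provider import ElectronicStructureProvider, build_qubit_hamiltonian, dipole_operator
from .vqe import AnsatzPolicy, ElectronicStateSet, solve_state_set


@dataclass
class SolveResult:
    state_set: ElectronicStateSet
    geometry: Geometry
    expansions: list | None = None

    @property
    def energies(self):
        return self.state_set.energies

    @property
    def overlaps_sq(self):
        return self.state_set.overlaps_sq


class VQEDriver(ElectronicDriver):
    """VQE/VQD electronic structure for surface hopping."""

    def __init__(self, provider: ElectronicStructureProvider, active_space: ActiveSpaceSpec,
                 n_states: int, policy: AnsatzPolicy | None = None, lam: float | None = None,
                 gradient_shift_angstrom: float = 0.001, ci_threshold: float = 1e-6,
                 gtol: float = 1e-6, maxiter: int = 500, prune: float = 1e-12):
        self.provider = provider
        self.active_space = active_space
        self.n_states = n_states
        self.policy = policy or AnsatzPolicy()
        self.lam = lam
        self.shift = gradient_shift_angstrom
        self.ci_threshold = ci_threshold
        self.gtol = gtol
        self.maxiter = maxiter
        self.prune = prune

    def hamiltonian(self, geometry: Geometry):
        if hasattr(self.provider, "set_reference"):
            self.provider.set_reference(geometry)
        return build_qubit_hamiltonian(self.provider, geometry, self.active_space,
                                       prune=self.prune)

    def solve(self, geometry: Geometry, warm_start=None) -> SolveResult:
        H = self.hamiltonian(geometry)
        warm = None
        if warm_start is not None:
            warm = [s.theta for s in warm_start.state_set.states]
        state_set = solve_state_set(
            H, self.n_states, self.active_space.n_active_electrons,
            policy=self.policy, warm_start=warm, lam=self.lam,
            gtol=self.gtol, maxiter=self.maxiter,
        )
        return SolveResult(state_set, geometry)

    def gradients(self, geometry: Geometry, result: SolveResult) -> np.ndarray:
        ops = hamiltonian_derivatives(self.provider, geometry, self.active_space, self.shift)
        return np.array(state_gradients(result.state_set, ops))

    def _expansions(self, result: SolveResult):
        if result.expansions is None:
            result.expansions = [
                extract_ci_expansion(s, self.ci_threshold) for s in result.state_set.states
            ]
        return result.expansions

    def overlap(self, geom_bra, result_bra, geom_ket, result_ket) -> np.ndarray:
        mo_cross = self.provider.cross_overlap(geom_bra, geom_ket, self.active_space)
        S = ci_overlap_matrix(self._expansions(result_bra), self._expansions(result_ket),
                              mo_cross)
        return S.S

    def apply_phase_fix(self, result: SolveResult, signs: np.ndarray) -> None:
        for s, sign in zip(result.state_set.states, signs):
            if sign < 0:
                s.statevector = -s.statevector
        if result.expansions is not None:
            for e, sign in zip(result.expansions, signs):
                if sign < 0:
                    e.coefficients = -e.coefficients

    def dipole_operators(self, geometry: Geometry):
        return dipole_operator(self.provider, geometry, self.active_space)
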