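"""Gradients, nonadiabatic couplings, transition dipoles, CI expansions."""

import numpy as np
import pytest

import qnamd as q
from qnamd.properties import (
    extract_ci_expansion,
    hamiltonian_derivatives,
    nac_vector,
    state_gradients,
    transition_dipole_and_f,
)
from qnamd.vqe import AnsatzPolicy, solve_state_set
from oracles import hamiltonian_matrix_from_integrals


@pytest.fixture(scope="module")
def model_states(crossing_model=None):
    model = q.AvoidedCrossing(gap=0.02, coupling_width=0.5, slope=0.01)
    provider = q.TwoLevelFermionicProvider(model)
    aspace = q.ActiveSpaceSpec(2, 2)
    geom = q.scalar_geometry(0.35)
    H = q.build_qubit_hamiltonian(provider, geom, aspace)
    st = solve_state_set(H, 2, 2, policy=AnsatzPolicy(k=1), lam=1.0)
    ops = hamiltonian_derivatives(provider, geom, aspace)
    return model, provider, aspace, geom, st, ops


class TestGradients:
    def test_geometry_independent_hamiltonian_gives_zero_gradient(self, h2_hamiltonian):
        """A provider whose integrals ignore geometry produces zero force."""
        provider = q.FcidumpProvider(
            q.SpatialIntegrals(np.diag([-1.0, -0.5]), np.zeros((2, 2, 2, 2)), 0.3,
                               n_electrons=2)
        )
        aspace = q.ActiveSpaceSpec(2, 2)
        geom = q.Geometry(("H", "H"), np.array([[0, 0, 0], [0, 0, 1.4]]))
        ops = hamiltonian_derivatives(provider, geom, aspace)
        st = solve_state_set(q.build_qubit_hamiltonian(provider, geom, aspace), 1, 2)
        grads = state_gradients(st, ops)
        np.testing.assert_allclose(grads[0], 0.0, atol=1e-10)

    def test_hellmann_feynman_matches_fd_of_energy(self, h2_provider, h2_aspace,
                                                   h2_geometry):
        """At the FCI-exact ansatz the Hellmann–Feynman gradient equals the
        central difference of the energy to 5e-5 hartree/bohr."""
        H = q.build_qubit_hamiltonian(h2_provider, h2_geometry, h2_aspace)
        st = solve_state_set(H, 1, 2)
        ops = hamiltonian_derivatives(h2_provider, h2_geometry, h2_aspace)
        grads = state_gradients(st, ops)

        def energy(geom):
            Hg = q.build_qubit_hamiltonian(h2_provider, geom, h2_aspace)
            return q.exact_spectrum(Hg, 1, n_electrons=2, sz=0.0)[0]

        delta = 1e-3
        for atom, axis in [(0, 2), (1, 2)]:
            ep = energy(h2_geometry.displaced(atom, axis, +delta))
            em = energy(h2_geometry.displaced(atom, axis, -delta))
            fd = (ep - em) / (2 * delta)
            assert grads[0][atom, axis] == pytest.approx(fd, abs=5e-5)

    def test_translational_invariance(self, h2_provider, h2_aspace, h2_geometry):
        """Total force sums to ~0 (no net translation) on the diatomic."""
        H = q.build_qubit_hamiltonian(h2_provider, h2_geometry, h2_aspace)
        st = solve_state_set(H, 1, 2)
        ops = hamiltonian_derivatives(h2_provider, h2_geometry, h2_aspace)
        grads = state_gradients(st, ops)
        np.testing.assert_allclose(grads[0].sum(axis=0), 0.0, atol=2e-5)


class TestHamiltonianDerivative:
    class _QuadraticProvider(q.ElectronicStructureProvider):
        """h(x) = h0 + x^2 v along atom-0 x; analytic derivative 2 x v."""

        def __init__(self):
            self.h0 = np.diag([-1.0, -0.5])
            self.v = np.array([[0.3, 0.1], [0.1, -0.2]])

        def spatial_integrals(self, geometry, active_space):
            x = geometry.coords[0, 0]
            return q.SpatialIntegrals(self.h0 + x**2 * self.v,
                                      np.zeros((2, 2, 2, 2)), 0.0, n_electrons=2)

        def cross_overlap(self, a, b, s):
            return np.eye(2)

    def test_quadratic_model_derivative_exact_and_shift_robust(self):
        provider = self._QuadraticProvider()
        aspace = q.ActiveSpaceSpec(2, 2)
        x0 = 0.7
        geom = q.scalar_geometry(x0)
        from qnamd.fermion import jordan_wigner
        from qnamd.integrals import second_quantized_hamiltonian, SpatialIntegrals

        exact = jordan_wigner(second_quantized_hamiltonian(
            SpatialIntegrals(2 * x0 * provider.v, np.zeros((2, 2, 2, 2)), 0.0,
                             n_electrons=2).to_spin_orbital()), 4)
        for shift in (0.001, 0.01):
            fd = q.hamiltonian_derivative(provider, geom, aspace, 0, 0,
                                          shift_angstrom=shift)
            diff = fd - exact
            assert max(abs(c) for c in diff.terms.values()) < 1e-9

    def test_other_axes_have_zero_derivative(self):
        provider = self._QuadraticProvider()
        fd = q.hamiltonian_derivative(provider, q.scalar_geometry(0.4),
                                      q.ActiveSpaceSpec(2, 2), 0, 1)
        assert len(fd.prune(1e-10)) == 0

    def test_backend_failure_reported_with_geometry(self):
        class Failing(self._QuadraticProvider):
            def spatial_integrals(self, geometry, active_space):
                raise RuntimeError("SCF exploded")

        with pytest.raises(RuntimeError, match="atom 0 axis 0"):
            q.hamiltonian_derivative(Failing(), q.scalar_geometry(0.0),
                                     q.ActiveSpaceSpec(2, 2), 0, 0)


class TestNAC:
    def test_same_state_rejected(self, model_states):
        *_, st, ops = model_states
        with pytest.raises(ValueError):
            nac_vector(st, 1, 1, ops)

    def test_antisymmetric_under_state_swap(self, model_states):
        *_, st, ops = model_states
        d01 = nac_vector(st, 0, 1, ops)
        d10 = nac_vector(st, 1, 0, ops)
        np.testing.assert_allclose(d01.vector, -d10.vector, atol=1e-8)

    def test_matches_analytic_model_across_crossing(self):
        """d_01 from VQE states and dH/dR equals the closed-form mixing-angle
        derivative of the avoided-crossing model."""
        model = q.AvoidedCrossing(gap=0.02, coupling_width=0.5, slope=0.01)
        provider = q.TwoLevelFermionicProvider(model)
        aspace = q.ActiveSpaceSpec(2, 2)
        for r in (-0.6, -0.1, 0.0, 0.2, 0.8):
            geom = q.scalar_geometry(r)
            H = q.build_qubit_hamiltonian(provider, geom, aspace)
            st = solve_state_set(H, 2, 2, policy=AnsatzPolicy(k=1), lam=1.0)
            ops = hamiltonian_derivatives(provider, geom, aspace)
            d = nac_vector(st, 0, 1, ops)
            assert abs(d.vector[0, 0]) == pytest.approx(abs(model.nac(r)), abs=2e-4)


class TestTransitionDipole:
    def test_zero_dipole_zero_f(self, model_states):
        _, provider, aspace, geom, st, _ = model_states
        zero_ops = [q.QubitOperator.identity(4, 0.0) for _ in range(3)]
        mu, f = transition_dipole_and_f(st, 0, 1, zero_ops)
        assert f == 0.0

    def test_constant_shift_does_not_contribute(self, model_states):
        _, provider, aspace, geom, st, _ = model_states
        ops = q.dipole_operator(provider, geom, aspace)
        shifted = [op + 5.0 for op in ops]
        mu1, f1 = transition_dipole_and_f(st, 0, 1, ops)
        mu2, f2 = transition_dipole_and_f(st, 0, 1, shifted)
        np.testing.assert_allclose(mu1, mu2, atol=1e-8)

    def test_matches_dense_eigenvector_matrix_element(self, model_states):
        _, provider, aspace, geom, st, _ = model_states
        ops = q.dipole_operator(provider, geom, aspace)
        mu, f = transition_dipole_and_f(st, 0, 1, ops)
        H = q.build_qubit_hamiltonian(provider, geom, aspace)
        vals, vecs = q.exact_spectrum(H, 2, n_electrons=2, sz=0.0, s2_target=0.0,
                                      return_vectors=True)
        ref = abs(np.vdot(vecs[:, 0], ops[0].to_dense() @ vecs[:, 1]))
        assert abs(mu[0]) == pytest.approx(ref, abs=1e-6)
        assert f >= 0.0


class TestCIExpansion:
    def test_reference_state_single_determinant(self):
        ansatz = q.build_kupccgsd(4, 2)
        gs = q.vqe(q.QubitOperator({(): 0.0, ((0, "Z"),): 0.5, ((1, "Z"),): 0.5,
                                    ((2, "Z"),): -0.5, ((3, "Z"),): -0.5}, 4), ansatz)
        exp = extract_ci_expansion(gs, threshold=1e-6)
        assert len(exp) == 1
        assert exp.determinants[0] == ((0,), (0,))
        assert abs(exp.coefficients[0]) == pytest.approx(1.0, abs=1e-10)

    def test_uniform_two_determinant_state(self, h2_hamiltonian):
        """Rotate the paired double to exactly 50/50: two coefficients 1/sqrt(2)."""
        ansatz = q.build_kupccgsd(4, 2)
        theta = np.zeros(2)
        theta[1] = np.pi / 4  # the pair amplitude rotates by theta: 50/50 here
        psi = q.prepare_state(ansatz, theta)
        state = q.VariationalState(theta, psi, 0.0, 0, True, ansatz)
        exp = extract_ci_expansion(state, threshold=1e-6)
        assert len(exp) == 2
        np.testing.assert_allclose(np.abs(exp.coefficients), 1 / np.sqrt(2), atol=1e-10)

    def test_energy_reconstructed_from_expansion(self, h2_provider, h2_geometry,
                                                 h2_aspace, h2_hamiltonian):
        """The truncated expansion reproduces <H> through the CI-matrix
        quadratic form built from brute-force fermionic matrices."""
        st = solve_state_set(h2_hamiltonian, 1, 2)
        exp = extract_ci_expansion(st.states[0], threshold=1e-8)
        so = h2_provider.integrals(h2_geometry, h2_aspace)
        Hmat = hamiltonian_matrix_from_integrals(so.h, so.g, so.core_energy, 4)
        # rebuild the statevector from (alpha, beta) determinants
        vec = np.zeros(16)
        from qnamd.properties import _spin_block_sign

        for c, (alpha, beta) in zip(exp.coefficients, exp.determinants):
            modes = sorted([2 * a for a in alpha] + [2 * b + 1 for b in beta])
            idx = sum(1 << m for m in modes)
            vec[idx] = c * _spin_block_sign(modes)
        e = vec @ Hmat.real @ vec
        assert e == pytest.approx(st.states[0].energy, abs=1e-8)
        assert exp.norm_retained == pytest.approx(1.0, abs=1e-8)

    def test_low_norm_budget_warns(self, h2_hamiltonian):
        st = solve_state_set(h2_hamiltonian, 1, 2)
        exp = extract_ci_expansion(st.states[0], threshold=0.5, norm_budget=0.999)
        assert exp.warning is not None

    def test_invalid_threshold_rejected(self, h2_hamiltonian):
        st = solve_state_set(h2_hamiltonian, 1, 2)
        with pytest.raises(ValueError):
            extract_ci_expansion(st.states[0], threshold=2.0)
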