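"""k-UpCCGSD ansatz, VQE, VQD and the dense oracle."""

import numpy as np
import pytest
import scipy.linalg
from hypothesis import given, settings, strategies as st

import qnamd as q
from qnamd.ansatz import build_kupccgsd, prepare_state
from qnamd.vqe import (
    AnsatzPolicy,
    exact_spectrum,
    expectation,
    number_operator,
    s_squared_operator,
    solve_state_set,
    sz_operator,
    vqd,
    vqe,
)


class TestAnsatzConstruction:
    def test_parameter_count_three_orbitals(self):
        """3 spatial orbitals, one layer: 3 singles + 3 paired doubles."""
        ansatz = build_kupccgsd(6, 4, k=1)
        assert ansatz.n_parameters == 6

    def test_two_layers_double_parameters_and_pad_reduces(self):
        a1 = build_kupccgsd(6, 4, k=1)
        a2 = build_kupccgsd(6, 4, k=2)
        assert a2.n_parameters == 12
        rng = np.random.default_rng(0)
        theta = rng.normal(0, 0.2, 6)
        psi1 = prepare_state(a1, theta)
        psi2 = prepare_state(a2, np.concatenate([theta, np.zeros(6)]))
        assert abs(np.vdot(psi1, psi2)) == pytest.approx(1.0, abs=1e-12)

    def test_zero_angles_give_reference_determinant(self):
        ansatz = build_kupccgsd(6, 4)
        psi = prepare_state(ansatz, np.zeros(6))
        np.testing.assert_allclose(psi, ansatz.reference_state(), atol=1e-14)

    def test_odd_electron_count_rejected(self):
        with pytest.raises(ValueError):
            build_kupccgsd(6, 3)

    def test_wrong_parameter_length_rejected(self):
        ansatz = build_kupccgsd(4, 2)
        with pytest.raises(ValueError):
            prepare_state(ansatz, np.zeros(5))


class TestStatePreparation:
    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_symmetries_conserved_at_any_angles(self, seed):
        """<N> and <Sz> equal the reference values for every theta."""
        rng = np.random.default_rng(seed)
        ansatz = build_kupccgsd(6, 4, k=1)
        psi = prepare_state(ansatz, rng.normal(0, 1.0, 6))
        assert np.linalg.norm(psi) == pytest.approx(1.0, abs=1e-12)
        assert expectation(psi, number_operator(6)) == pytest.approx(4.0, abs=1e-12)
        assert expectation(psi, sz_operator(6)) == pytest.approx(0.0, abs=1e-12)

    def test_singlet_character_preserved(self, rng):
        ansatz = build_kupccgsd(6, 4, k=2)
        psi = prepare_state(ansatz, rng.normal(0, 0.7, 12))
        assert expectation(psi, s_squared_operator(6)) == pytest.approx(0.0, abs=1e-10)

    def test_single_generator_rotation_matches_expm(self, rng):
        """One paired-double generator at theta: compare against the dense
        matrix exponential of the generator (scipy oracle)."""
        ansatz = build_kupccgsd(4, 2, k=1)
        idx = 1  # the paired double
        theta = np.zeros(2)
        theta[idx] = np.pi / 2
        gmat = ansatz.generators[idx].to_dense()
        ref = scipy.linalg.expm((np.pi / 2) * gmat) @ ansatz.reference_state()
        only_double = np.zeros(2)
        only_double[idx] = np.pi / 2
        # apply only that generator: zero the other angle
        psi = prepare_state(ansatz, only_double)
        np.testing.assert_allclose(psi, ref, atol=1e-12)

    def test_two_pi_periodicity_up_to_global_phase(self):
        ansatz = build_kupccgsd(4, 2, k=1)
        t1 = np.array([0.3, 0.0])
        t2 = np.array([0.3 + 2 * np.pi, 0.0])
        p1, p2 = prepare_state(ansatz, t1), prepare_state(ansatz, t2)
        assert abs(np.vdot(p1, p2)) == pytest.approx(1.0, abs=1e-12)


class TestExpectation:
    def test_identity_gives_one(self, rng):
        psi = rng.normal(size=4) + 1j * rng.normal(size=4)
        psi /= np.linalg.norm(psi)
        assert expectation(psi, q.QubitOperator.identity(2)) == pytest.approx(1.0)

    def test_z_on_zero_state(self):
        psi = np.zeros(2, complex)
        psi[0] = 1.0
        assert expectation(psi, q.QubitOperator({((0, "Z"),): 1.0})) == pytest.approx(1.0)

    def test_matches_dense_quadratic_form(self, rng):
        terms = {}
        for _ in range(10):
            word = tuple(sorted((int(qb), rng.choice(list("XYZ")))
                                for qb in rng.choice(4, rng.integers(1, 4), replace=False)))
            terms[word] = rng.normal()
        op = q.QubitOperator(terms, 4)
        psi = rng.normal(size=16) + 1j * rng.normal(size=16)
        psi /= np.linalg.norm(psi)
        ref = np.vdot(psi, op.to_dense() @ psi).real
        assert expectation(psi, op) == pytest.approx(ref, abs=1e-10)

    def test_non_hermitian_rejected(self, rng):
        psi = np.array([1.0, 0.0], complex)
        with pytest.raises(ValueError):
            expectation(psi, q.QubitOperator({((0, "X"),): 1j}))


class TestVQE:
    def test_diagonal_hamiltonian_converges_at_reference(self):
        """HF determinant already optimal for a diagonal H."""
        H = q.QubitOperator({(): -1.0, ((0, "Z"),): 0.5, ((1, "Z"),): 0.5,
                             ((2, "Z"),): -0.5, ((3, "Z"),): -0.5}, 4)
        gs = vqe(H, build_kupccgsd(4, 2))
        assert gs.converged
        assert gs.energy == pytest.approx(-3.0, abs=1e-8)
        assert np.linalg.norm(gs.theta) < 1e-6

    def test_h2_energy_matches_oracle(self, h2_hamiltonian, h2_singlets):
        gs = vqe(h2_hamiltonian, build_kupccgsd(4, 2))
        assert gs.energy == pytest.approx(h2_singlets[0], abs=1e-7)

    def test_variational_bound(self, h2_hamiltonian, h2_singlets, rng):
        """Rayleigh bound: any converged VQE energy >= exact ground energy."""
        for _ in range(3):
            gs = vqe(h2_hamiltonian, build_kupccgsd(4, 2),
                     theta0=rng.normal(0, 0.5, 2))
            assert gs.energy >= h2_singlets[0] - 1e-10

    def test_warm_start_cheaper_than_cold(self, h2_provider, h2_aspace):
        """Restarting from a neighbouring geometry's angles needs no more
        iterations than a cold start."""
        g1 = q.Geometry(("H", "H"), np.array([[0, 0, 0], [0, 0, 1.4]]))
        g2 = q.Geometry(("H", "H"), np.array([[0, 0, 0], [0, 0, 1.45]]))
        H2op = q.build_qubit_hamiltonian(h2_provider, g2, h2_aspace)
        cold = vqe(H2op, build_kupccgsd(4, 2))
        warm_theta = vqe(q.build_qubit_hamiltonian(h2_provider, g1, h2_aspace),
                         build_kupccgsd(4, 2)).theta
        warm = vqe(H2op, build_kupccgsd(4, 2), theta0=warm_theta)
        assert warm.n_iterations <= cold.n_iterations
        assert warm.energy == pytest.approx(cold.energy, abs=1e-8)


class TestVQD:
    def test_degenerate_ground_level_returns_partner(self):
        """H with a doubly degenerate ground level: deflating one member
        yields an orthogonal state at the same energy."""
        H = q.QubitOperator({(): 0.0, ((0, "Z"), (1, "Z")): -1.0}, 4)
        # restrict to the 2-electron ansatz manifold; |0011> and flipped-pair
        ansatz = build_kupccgsd(4, 2, k=2)
        gs = vqe(H, ansatz)
        ex = vqd(H, ansatz, [gs], lam=2.0, theta0=np.full(4, 0.2))
        assert ex.energy == pytest.approx(gs.energy, abs=1e-6)
        assert ex.max_lower_overlap_sq < 1e-8

    def test_three_states_match_oracle(self, h2_hamiltonian, h2_singlets):
        st_set = solve_state_set(h2_hamiltonian, 3, 2, policy=AnsatzPolicy(k=2), lam=3.0)
        np.testing.assert_allclose(st_set.energies, h2_singlets, atol=1e-6)
        off = st_set.overlaps_sq - np.diag(np.diag(st_set.overlaps_sq))
        assert np.max(np.abs(off)) < 1e-5

    def test_weak_penalty_sinks_below_true_excited_energy(self):
        """lambda below the gap: the penalized minimum undershoots E_1."""
        H = q.QubitOperator({(): 0.0, ((0, "Z"), (1, "Z")): -0.5,
                             ((0, "Z"),): -0.25, ((1, "Z"),): -0.25}, 4)
        ansatz = build_kupccgsd(4, 2, k=2)
        gs = vqe(H, ansatz)
        e_exact = exact_spectrum(H, 2, n_electrons=2, sz=0.0)
        gap = e_exact[1] - e_exact[0]
        weak = vqd(H, ansatz, [gs], lam=0.2 * gap, theta0=np.full(4, 0.3),
                   overlap_tol=1.1)
        assert weak.energy < e_exact[1] - 1e-6

    def test_nonpositive_lambda_rejected(self, h2_hamiltonian):
        ansatz = build_kupccgsd(4, 2)
        gs = vqe(h2_hamiltonian, ansatz)
        with pytest.raises(ValueError):
            vqd(h2_hamiltonian, ansatz, [gs], lam=0.0)


class TestAnsatzPolicy:
    def test_grow_policy_layer_counts(self):
        pol = AnsatzPolicy(mode="grow", k=1, freeze_lower_layers=True)
        a0 = pol.ansatz_for_state(0, 6, 4)
        a2 = pol.ansatz_for_state(2, 6, 4)
        assert a0.n_parameters == 6 and a2.n_parameters == 18
        assert pol.free_mask_for_state(0, a0) is None
        mask = pol.free_mask_for_state(2, a2)
        assert mask.sum() == 6 and mask[-6:].all()

    def test_grow_with_frozen_layers_stays_variational(self, h2_hamiltonian,
                                                       h2_singlets):
        pol = AnsatzPolicy(mode="grow", k=1, freeze_lower_layers=True)
        st = solve_state_set(h2_hamiltonian, 2, 2, policy=pol, lam=3.0)
        # ground state exact; excited state bounded below by the oracle and
        # orthogonal to the ground state
        assert st.energies[0] == pytest.approx(h2_singlets[0], abs=1e-7)
        assert st.energies[1] >= h2_singlets[1] - 1e-8
        assert st.overlaps_sq[0, 1] < 1e-4


class TestExactSpectrum:
    def test_single_z(self):
        vals = exact_spectrum(q.QubitOperator({((0, "Z"),): 1.0}), 2)
        np.testing.assert_allclose(vals, [-1.0, 1.0])

    def test_constant_operator(self):
        vals = exact_spectrum(q.QubitOperator.identity(2, 0.7), 4)
        np.testing.assert_allclose(vals, 0.7)

    def test_sector_restriction_counts(self):
        """2 electrons, Sz = 0 on 4 spin-orbitals: 4 determinants."""
        from qnamd.vqe import sector_indices

        assert len(sector_indices(4, 2, 0.0)) == 4

    def test_dimension_cap(self):
        with pytest.raises(ValueError):
            exact_spectrum(q.QubitOperator.identity(13), 1)

    def test_solve_single_state_reduces_to_vqe(self, h2_hamiltonian, h2_singlets):
        st_set = solve_state_set(h2_hamiltonian, 1, 2)
        assert len(st_set) == 1
        assert st_set.energies[0] == pytest.approx(h2_singlets[0], abs=1e-7)
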