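"""Velocity Verlet, local diabatization, hopping, decoherence, trajectories."""

import numpy as np
import pytest

import qnamd as q
from qnamd.constants import AUT_PER_FS
from qnamd.dynamics import (
    SHConfig,
    TrajectoryState,
    apply_decoherence,
    attempt_hop,
    hopping_probabilities,
    propagate_electronic_ld,
    velocity_verlet_step,
)
from oracles import tdse_adiabatic_populations


def _free_particle(geom):
    return np.zeros((geom.n_atoms, 3))


class TestVelocityVerlet:
    def test_zero_force_uniform_motion(self):
        geom = q.Geometry(("H",), np.zeros((1, 3)), np.array([1000.0]))
        v = np.array([[0.01, 0.0, 0.0]])
        g, v2, _ = velocity_verlet_step(geom, v, np.zeros((1, 3)), _free_particle, 10.0)
        np.testing.assert_allclose(g.coords, [[0.1, 0.0, 0.0]], atol=1e-14)
        np.testing.assert_allclose(v2, v, atol=1e-14)

    def test_harmonic_energy_and_period(self):
        """1-D harmonic oscillator: period within 0.1% of 2 pi / omega and
        bounded energy error of O(dt^2)."""
        m, k = 1836.0, 0.3
        omega = np.sqrt(k / m)
        period = 2 * np.pi / omega
        dt = period / 400.0
        geom = q.Geometry(("H",), np.array([[0.3, 0.0, 0.0]]), np.array([m]))
        v = np.zeros((1, 3))
        force = lambda g: -k * g.coords
        f = force(geom)
        e0 = 0.5 * k * 0.3**2
        xs = []
        for _ in range(800):
            geom, v, f = velocity_verlet_step(geom, v, f, force, dt)
            xs.append(geom.coords[0, 0])
            e = 0.5 * m * (v**2).sum() + 0.5 * k * (geom.coords**2).sum()
            assert abs(e - e0) < 1e-3 * e0
        xs = np.array(xs)
        # period from the 1st and 3rd zero crossings (T/4 and 5T/4),
        # linearly interpolated for sub-step accuracy
        sign_changes = np.nonzero(np.sign(xs[:-1]) != np.sign(xs[1:]))[0]
        t_cross = []
        for i in sign_changes[:3]:
            frac = xs[i] / (xs[i] - xs[i + 1])
            t_cross.append((i + 1 + frac) * dt)
        measured = t_cross[2] - t_cross[0]
        assert measured == pytest.approx(period, rel=1e-3)

    def test_time_reversal_recovers_initial_state(self):
        m, k = 1836.0, 0.3
        geom0 = q.Geometry(("H",), np.array([[0.25, 0.0, 0.0]]), np.array([m]))
        v = np.array([[0.002, 0.0, 0.0]])
        force = lambda g: -k * g.coords
        f = force(geom0)
        geom, vv, ff = geom0, v, f
        for _ in range(50):
            geom, vv, ff = velocity_verlet_step(geom, vv, ff, force, 5.0)
        vv = -vv
        for _ in range(50):
            geom, vv, ff = velocity_verlet_step(geom, vv, ff, force, 5.0)
        np.testing.assert_allclose(geom.coords, geom0.coords, atol=1e-10)
        np.testing.assert_allclose(-vv, v, atol=1e-12)


class TestLocalDiabatization:
    def test_identity_overlap_pure_phases(self):
        a = np.array([0.6, 0.8], complex)
        e = np.array([-0.1, 0.2])
        a2, P, T, signs = propagate_electronic_ld(a, e, e, np.eye(2), 10.0, 20)
        np.testing.assert_allclose(np.abs(a2), np.abs(a), atol=1e-12)
        np.testing.assert_allclose(a2, a * np.exp(-1j * e * 10.0), atol=1e-10)
        np.testing.assert_allclose(T, np.eye(2), atol=1e-14)

    def test_norm_conserved_over_many_random_steps(self, rng):
        a = np.array([1.0, 0.0, 0.0], complex)
        for _ in range(1000):
            e1 = np.sort(rng.normal(size=3))
            e2 = np.sort(rng.normal(size=3))
            S = np.eye(3) + 0.05 * rng.normal(size=(3, 3))
            a, P, *_ = propagate_electronic_ld(a, e1, e2, S, 5.0, 5)
            np.testing.assert_allclose(np.abs(P.conj().T @ P), np.eye(3), atol=1e-8)
        assert np.linalg.norm(a) == pytest.approx(1.0, abs=1e-8)

    def test_matches_nac_tdse_oracle_across_crossing(self, crossing_model):
        """LD propagation along a prescribed path through the avoided
        crossing agrees with direct TDSE integration using analytic NACs."""
        model = crossing_model
        v = 0.01  # bohr per a.u. time
        r0 = -6.0
        t_total = 2 * abs(r0) / v
        a0 = np.array([0.0, 1.0], complex)
        _, pops_ref = tdse_adiabatic_populations(model, lambda t: r0 + v * t,
                                                 lambda t: v, a0, t_total)
        for n_steps, tol in ((1500, 1e-4),):
            dt = t_total / n_steps
            a = a0.copy()
            vecs_prev = model.adiabatic_states(r0)
            for i in range(n_steps):
                r_new = r0 + v * (i + 1) * dt
                vecs_new = model.adiabatic_states(r_new)
                S = vecs_prev.T @ vecs_new
                e1 = model.adiabatic_energies(r0 + v * i * dt)
                e2 = model.adiabatic_energies(r_new)
                a, P, T, signs = propagate_electronic_ld(a, e1, e2, S, dt, 4)
                vecs_prev = vecs_new * signs[None, :]
            np.testing.assert_allclose(np.abs(a) ** 2, pops_ref[-1], atol=tol)

    def test_convergence_order_in_dt(self, crossing_model):
        """Population error vs the TDSE oracle shrinks at least
        quadratically with the step size."""
        model = crossing_model
        v, r0 = 0.01, -4.0
        t_total = 2 * abs(r0) / v
        a0 = np.array([0.0, 1.0], complex)
        _, pops_ref = tdse_adiabatic_populations(model, lambda t: r0 + v * t,
                                                 lambda t: v, a0, t_total)

        def run(n_steps):
            dt = t_total / n_steps
            a = a0.copy()
            vecs_prev = model.adiabatic_states(r0)
            for i in range(n_steps):
                r_new = r0 + v * (i + 1) * dt
                vecs_new = model.adiabatic_states(r_new)
                S = vecs_prev.T @ vecs_new
                e1 = model.adiabatic_energies(r0 + v * i * dt)
                e2 = model.adiabatic_energies(r_new)
                a, *_, signs = propagate_electronic_ld(a, e1, e2, S, dt, 2)
                vecs_prev = vecs_new * signs[None, :]
            return abs(np.abs(a[0]) ** 2 - pops_ref[-1][0])

        errs = [run(n) for n in (100, 200, 400)]
        orders = [np.log2(errs[i] / errs[i + 1]) for i in range(2)]
        assert min(orders) >= 1.7


class TestHoppingProbabilities:
    def test_diagonal_propagator_no_hops(self):
        a = np.array([0.8, 0.6], complex)
        P = np.diag(np.exp(1j * np.array([0.3, -0.2])))
        probs = hopping_probabilities(a, P @ a, P, 0)
        np.testing.assert_allclose(probs, 0.0, atol=1e-14)

    def test_unchanged_population_no_hops(self):
        a1 = np.array([0.6, 0.8], complex)
        a2 = np.array([0.6 * np.exp(0.4j), 0.8], complex)
        P = np.eye(2, dtype=complex)
        probs = hopping_probabilities(a1, a2, P, 0)
        assert probs.sum() == 0.0

    def test_probabilities_bounded_and_nonnegative(self, rng):
        for _ in range(50):
            U = np.linalg.qr(rng.normal(size=(3, 3))
                             + 1j * rng.normal(size=(3, 3)))[0]
            a1 = rng.normal(size=3) + 1j * rng.normal(size=3)
            a1 /= np.linalg.norm(a1)
            probs = hopping_probabilities(a1, U @ a1, U, 1)
            assert np.all(probs >= 0.0)
            assert probs.sum() <= 1.0 + 1e-12

    def test_ensemble_hop_rate_matches_population_flux(self, rng):
        """Over many fewest-switches draws, the realized hop fraction
        equals the net active-state population loss (internal consistency
        of the flux apportioning)."""
        theta = 0.15
        U = np.array([[np.cos(theta), -np.sin(theta)],
                      [np.sin(theta), np.cos(theta)]], dtype=complex)
        a1 = np.array([1.0, 0.0], complex)
        a2 = U @ a1
        probs = hopping_probabilities(a1, a2, U, 0)
        expected = (abs(a1[0]) ** 2 - abs(a2[0]) ** 2) / abs(a1[0]) ** 2
        assert probs.sum() == pytest.approx(expected, abs=1e-12)
        n = 20_000
        hops = sum(rng.random() < probs.sum() for _ in range(n))
        assert hops / n == pytest.approx(expected, abs=4 * np.sqrt(expected / n))


class TestAttemptHop:
    def _state(self, v, active=1):
        geom = q.Geometry(("H",), np.zeros((1, 3)), np.array([2000.0]))
        return TrajectoryState(0.0, geom, np.array([[v, 0.0, 0.0]]), active,
                               np.array([0.6, 0.8], complex),
                               np.array([-0.1, 0.1]))

    def test_random_number_above_cumulative_no_hop(self):
        state = self._state(0.01)

        class FixedRng:
            def random(self):
                return 0.99

        new, event = attempt_hop(state, np.array([0.5, 0.0]), FixedRng())
        assert event is None and new.active_state == 1

    def test_successful_hop_conserves_total_energy(self):
        state = self._state(0.01, active=1)

        class FixedRng:
            def random(self):
                return 0.0

        new, event = attempt_hop(state, np.array([0.4, 0.0]), FixedRng())
        assert event.successful and new.active_state == 0
        e_before = state.kinetic_energy + state.energies[1]
        e_after = new.kinetic_energy + new.energies[0]
        assert e_after == pytest.approx(e_before, abs=1e-12)

    def test_downhill_hop_with_tiny_velocity_speeds_up(self):
        state = self._state(1e-5, active=1)

        class FixedRng:
            def random(self):
                return 0.0

        new, event = attempt_hop(state, np.array([1.0, 0.0]), FixedRng())
        assert event.successful
        assert np.linalg.norm(new.velocities) > np.linalg.norm(state.velocities)
        assert new.kinetic_energy + new.energies[0] == pytest.approx(
            state.kinetic_energy + state.energies[1], abs=1e-12)

    def test_frustrated_hop_leaves_state_unchanged(self):
        state = self._state(1e-5, active=0)  # uphill by 0.2 Eh, KE ~ 1e-7

        class FixedRng:
            def random(self):
                return 0.0

        new, event = attempt_hop(state, np.array([0.0, 1.0]), FixedRng())
        assert event is not None and not event.successful
        assert new.active_state == 0
        np.testing.assert_array_equal(new.velocities, state.velocities)


class TestDecoherence:
    def test_all_population_on_active_unchanged(self):
        a = np.array([0.0, 1.0], complex)
        out = apply_decoherence(a, 1, np.array([-0.1, 0.1]), 0.01, 20.0, 0.1)
        np.testing.assert_allclose(out, a, atol=1e-14)

    def test_degenerate_pair_no_decay(self):
        a = np.array([0.6, 0.8], complex)
        out = apply_decoherence(a, 1, np.array([0.1, 0.1]), 0.01, 20.0, 0.1)
        np.testing.assert_allclose(np.abs(out), np.abs(a), atol=1e-14)

    def test_matches_closed_form(self):
        a = np.array([0.6, 0.8], complex)
        de, ekin, dt, c = 0.05, 0.02, 20.0, 0.1
        out = apply_decoherence(a, 1, np.array([0.0, de]), ekin, dt, c)
        tau = (1.0 / de) * (1.0 + c / ekin)
        expected_inactive = 0.6 * np.exp(-dt / tau)
        assert abs(out[0]) == pytest.approx(expected_inactive, abs=1e-12)
        assert np.linalg.norm(out) == pytest.approx(1.0, abs=1e-12)

    def test_zero_kinetic_energy_suppresses_decay(self):
        a = np.array([0.6, 0.8], complex)
        out = apply_decoherence(a, 1, np.array([0.0, 0.1]), 0.0, 20.0, 0.1)
        np.testing.assert_allclose(out, a, atol=1e-14)

    def test_invalid_c_rejected(self):
        with pytest.raises(ValueError):
            apply_decoherence(np.array([1.0, 0.0], complex), 0,
                              np.array([0.0, 0.1]), 0.01, 1.0, 0.0)


class TestRunTrajectory:
    def test_single_state_harmonic_conserves_energy(self):
        """Pure adiabatic dynamics on a bound model surface: no hops and
        drift below 1e-4 hartree over 100 steps."""

        model = q.AvoidedCrossing(gap=0.4, coupling_width=5.0, slope=0.002)
        driver = q.AnalyticDriver(model)
        driver.n_states = 2
        ic = q.InitialCondition(q.scalar_geometry(-1.0), np.array([[2e-4, 0, 0]]),
                                state=0)
        cfg = SHConfig(n_states=2, dt_nuclear_fs=0.25, dt_electronic_fs=0.05,
                       max_time_fs=25.0, seed=0)
        traj = q.run_trajectory(ic, driver, cfg)
        assert len(traj.hops) == 0
        assert traj.energy_drift_ev * q.constants.HARTREE_PER_EV < 1e-4

    def test_zero_coupling_zero_hops(self):
        """Away from any crossing the off-diagonal overlap vanishes and the
        fewest-switches rule never fires."""
        model = q.AvoidedCrossing(gap=1e-8, coupling_width=1e-3, slope=0.01)
        driver = q.AnalyticDriver(model)
        # move away from the crossing: the states never mix along the path
        ic = q.InitialCondition(q.scalar_geometry(-3.0), np.array([[-5e-3, 0, 0]]),
                                state=1)
        cfg = SHConfig(n_states=2, dt_nuclear_fs=0.25, dt_electronic_fs=0.05,
                       max_time_fs=15.0, seed=1)
        traj = q.run_trajectory(ic, driver, cfg)
        assert len(traj.hops) == 0
        np.testing.assert_allclose(np.array(traj.populations)[:, 1], 1.0, atol=1e-10)

    def test_trivial_crossing_transfers_population_with_hop(self):
        """Passing an (essentially) uncoupled crossing, local diabatization
        keeps the wavepacket diabatic: the trajectory hops between the
        adiabatic labels with near-unit probability."""
        model = q.AvoidedCrossing(gap=1e-8, coupling_width=1e-3, slope=0.01)
        driver = q.AnalyticDriver(model)
        ic = q.InitialCondition(q.scalar_geometry(-3.0), np.array([[5e-3, 0, 0]]),
                                state=1)
        cfg = SHConfig(n_states=2, dt_nuclear_fs=0.25, dt_electronic_fs=0.05,
                       max_time_fs=20.0, seed=1)
        traj = q.run_trajectory(ic, driver, cfg)
        assert len([h for h in traj.hops if h.successful]) == 1
        assert traj.active_states[-1] == 0

    def test_electronic_norm_conserved_along_trajectory(self, crossing_model):
        driver = q.AnalyticDriver(crossing_model)
        ic = q.InitialCondition(q.scalar_geometry(-5.0), np.array([[7.5e-3, 0, 0]]),
                                state=1)
        cfg = SHConfig(n_states=2, dt_nuclear_fs=0.25, dt_electronic_fs=0.01,
                       max_time_fs=40.0, seed=5)
        traj = q.run_trajectory(ic, driver, cfg)
        sums = np.array([p.sum() for p in traj.populations])
        np.testing.assert_allclose(sums, 1.0, atol=1e-8)

    def test_dt_mismatch_rejected(self):
        with pytest.raises(ValueError):
            SHConfig(n_states=2, dt_nuclear_fs=0.5, dt_electronic_fs=0.03).n_substeps
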