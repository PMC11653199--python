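"""Fewest-switches surface hopping with local-diabatization propagation.

Nuclei move classically on the active adiabatic surface (velocity Verlet);
the electronic coefficients are propagated in a locally diabatic basis
constructed from the Löwdin-orthonormalized cross-timestep wavefunction
overlap matrix, which avoids explicit nonadiabatic couplings and is robust
at trivial crossings.  Hops follow the fewest-switches stochastic rule with
probabilities formed from the step propagator (the propagator-flux form of
the local-diabatization literature), velocities are rescaled along the
momentum direction on a successful hop, and the energy-based decoherence
correction damps inactive amplitudes.
"""

from __future__ import annotations

from abc import ABC, abstractmethod
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .constants import AUT_PER_FS, EV_PER_HARTREE, FS_PER_AUT
from .geometry import Geometry
from .overlap import OverlapMatrix, TrivialCrossingError, lowdin_orthonormalize


# ------------------------------------------------------------- interfaces

class ElectronicDriver(ABC):
    """Supplies electronic structure along a trajectory."""

    n_states: int

    @abstractmethod
    def solve(self, geometry: Geometry, warm_start=None):
        """Electronic states at a geometry; returns a driver-specific result
        exposing ``energies`` (ascending, hartree)."""

    @abstractmethod
    def gradients(self, geometry: Geometry, result) -> np.ndarray:
        """Total-energy gradients, shape (n_states, n_atoms, 3), hartree/bohr."""

    @abstractmethod
    def overlap(self, geom_bra: Geometry, result_bra, geom_ket: Geometry, result_ket) -> np.ndarray:
        """Cross-timestep state overlap matrix S_ml = <m(bra)|l(ket)>."""

    def apply_phase_fix(self, result, signs: np.ndarray) -> None:
        """Flip stored state phases after the Löwdin sign convention."""


# ------------------------------------------------------------ data types

@dataclass
class SHConfig:
    """Run parameters for a surface-hopping trajectory (I/O units: fs, eV)."""

    n_states: int
    dt_nuclear_fs: float = 0.5
    dt_electronic_fs: float = 0.02
    decoherence_c: float = 0.1  # a.u., energy-based decoherence strength
    max_time_fs: float = 100.0
    ground_state_dwell_fs: float | None = None  # stop after this long in S0
    energy_drift_threshold_ev: float = 0.2
    seed: int = 0

    @property
    def n_substeps(self) -> int:
        n = int(round(self.dt_nuclear_fs / self.dt_electronic_fs))
        if abs(n * self.dt_electronic_fs - self.dt_nuclear_fs) > 1e-9:
            raise ValueError("electronic time step must divide the nuclear one")
        return n


@dataclass
class HopEvent:
    time_fs: float
    source: int
    target: int
    successful: bool
    geometry: Geometry
    kinetic_energy: float


@dataclass
class TrajectoryState:
    """Instantaneous state of one trajectory (positions in bohr, a.u.)."""

    time_fs: float
    geometry: Geometry
    velocities: np.ndarray  # (N, 3), bohr / a.u. time
    active_state: int
    coefficients: np.ndarray  # complex adiabatic amplitudes a_m
    energies: np.ndarray

    @property
    def kinetic_energy(self) -> float:
        return float(0.5 * (self.geometry.masses[:, None] * self.velocities**2).sum())

    @property
    def total_energy(self) -> float:
        return self.kinetic_energy + float(self.energies[self.active_state])


@dataclass
class Trajectory:
    """Full record of one surface-hopping run."""

    times_fs: list = field(default_factory=list)
    active_states: list = field(default_factory=list)
    energies: list = field(default_factory=list)  # per step, (n_states,)
    populations: list = field(default_factory=list)  # |a_m|^2 per step
    total_energies: list = field(default_factory=list)
    geometries: list = field(default_factory=list)
    velocities: list = field(default_factory=list)
    hops: list = field(default_factory=list)
    state_overlap_sq: list = field(default_factory=list)  # per step: |<m|l>|^2 matrix
    discarded: bool = False
    aborted: str | None = None

    def log(self, ts: TrajectoryState):
        self.times_fs.append(ts.time_fs)
        self.active_states.append(ts.active_state)
        self.energies.append(ts.energies.copy())
        self.populations.append(np.abs(ts.coefficients) ** 2)
        self.total_energies.append(ts.total_energy)
        self.geometries.append(ts.geometry)
        self.velocities.append(ts.velocities.copy())

    @property
    def energy_drift_ev(self) -> float:
        e = np.asarray(self.total_energies)
        return float(np.max(np.abs(e - e[0]))) * EV_PER_HARTREE if len(e) else 0.0

    def to_frame(self):
        import pandas as pd

        n_states = len(self.energies[0])
        data = {"time_fs": self.times_fs, "active": self.active_states,
                "e_total": self.total_energies}
        for m in range(n_states):
            data[f"e_{m}"] = [e[m] for e in self.energies]
            data[f"pop_{m}"] = [p[m] for p in self.populations]
        return pd.DataFrame(data)


# ------------------------------------------------------------ integrators

def velocity_verlet_step(geometry: Geometry, velocities: np.ndarray, forces: np.ndarray,
                         force_provider, dt: float):
    """One velocity-Verlet step; returns (geometry', velocities', forces').

    ``force_provider(geometry')`` must return the force on the new
    geometry; it is evaluated exactly once per step.
    """
    m = geometry.masses[:, None]
    new_coords = geometry.coords + velocities * dt + 0.5 * forces / m * dt**2
    new_geom = geometry.with_coords(new_coords)
    new_forces = force_provider(new_geom)
    new_vel = velocities + 0.5 * (forces + new_forces) / m * dt
    return new_geom, new_vel, new_forces


def propagate_electronic_ld(a_t: np.ndarray, e_t: np.ndarray, e_tdt: np.ndarray,
                            S: np.ndarray, dt_au: float, n_substeps: int):
    """Local-diabatization propagation of adiabatic coefficients over one step.

    Returns (a_tdt, propagator, T, signs): T is the Löwdin transform with
    columns sign-fixed so diag(T) >= 0 (``signs`` records the flips, which
    the caller must also apply to the stored t+dt states), and
    ``propagator`` maps a(t) -> a(t+dt); it is unitary by construction.
    """
    T = lowdin_orthonormalize(np.asarray(S, float))
    signs = np.where(np.diag(T) < 0, -1.0, 1.0)
    T = T * signs[None, :]
    H0 = np.diag(np.asarray(e_t, float))
    H1 = T @ np.diag(np.asarray(e_tdt, float)) @ T.T
    delta = dt_au / n_substeps
    U = np.eye(len(a_t), dtype=complex)
    for j in range(n_substeps):
        tau = (j + 0.5) / n_substeps
        Hmid = (1.0 - tau) * H0 + tau * H1
        U = _expm_hermitian(-1j * delta * Hmid) @ U
    propagator = T.T @ U  # a(t+dt) = T^T d(t+dt), d(t) = a(t)
    a_tdt = propagator @ np.asarray(a_t, complex)
    return a_tdt, propagator, T, signs


def _expm_hermitian(x: np.ndarray) -> np.ndarray:
    """exp of an anti-Hermitian matrix i*H via eigendecomposition."""
    H = (1j * x)  # Hermitian
    vals, vecs = np.linalg.eigh(H)
    return (vecs * np.exp(-1j * vals)) @ vecs.conj().T


# ----------------------------------------------------------- FSSH pieces

def hopping_probabilities(a_t: np.ndarray, a_tdt: np.ndarray, propagator: np.ndarray,
                          active: int) -> np.ndarray:
    """Fewest-switches hop probabilities from the propagator flux.

    The population lost by the active state over the step is apportioned to
    the target states by the real part of their propagator flux
    contribution; negative contributions are clamped to zero and the total
    never exceeds one.
    """
    n = len(a_t)
    probs = np.zeros(n)
    pk_t = abs(a_t[active]) ** 2
    if pk_t < 1e-14:
        return probs
    pk_dt = abs(a_tdt[active]) ** 2
    loss = (pk_t - pk_dt) / pk_t
    if loss <= 0.0:
        return probs
    denom = pk_t - (a_tdt[active] * np.conj(propagator[active, active]) * np.conj(a_t[active])).real
    if abs(denom) < 1e-15:
        return probs
    for l in range(n):
        if l == active:
            continue
        flux = (a_tdt[l] * np.conj(propagator[l, active]) * np.conj(a_t[active])).real
        probs[l] = max(0.0, loss * flux / denom)
    total = probs.sum()
    if total > 1.0:
        probs /= total
    return probs


def attempt_hop(state: TrajectoryState, probs: np.ndarray, rng: np.random.Generator):
    """Stochastic hop decision with momentum-direction velocity rescaling.

    On an energetically allowed hop the velocity vector is scaled so the
    total energy is conserved exactly; an insufficient kinetic energy gives
    a frustrated hop (active state and velocities unchanged).
    """
    r = rng.random()
    cum = 0.0
    target = None
    for l, p in enumerate(probs):
        cum += p
        if r < cum:
            target = l
            break
    if target is None:
        return state, None
    ekin = state.kinetic_energy
    gap = float(state.energies[state.active_state] - state.energies[target])
    new_ekin = ekin + gap
    if new_ekin <= 0.0:
        event = HopEvent(state.time_fs, state.active_state, target, False,
                         state.geometry, ekin)
        return state, event
    factor = np.sqrt(new_ekin / ekin) if ekin > 0 else 1.0
    new_state = TrajectoryState(state.time_fs, state.geometry,
                                state.velocities * factor, target,
                                state.coefficients, state.energies)
    event = HopEvent(state.time_fs, state.active_state, target, True,
                     state.geometry, ekin)
    return new_state, event


def apply_decoherence(a: np.ndarray, active: int, energies: np.ndarray,
                      kinetic_energy: float, dt_au: float, c_param: float = 0.1) -> np.ndarray:
    """Energy-based decoherence: a_l *= exp(-dt/tau_lm), active renormalized.

    tau_lm = (1/|E_l - E_m|) (1 + C/E_kin) in atomic units.  At vanishing
    kinetic energy tau diverges and the correction switches off smoothly.
    """
    if c_param <= 0:
        raise ValueError("decoherence parameter must be positive")
    a = np.asarray(a, complex).copy()
    if kinetic_energy <= 1e-12:
        return a
    for l in range(len(a)):
        if l == active:
            continue
        gap = abs(energies[l] - energies[active])
        if gap < 1e-12:
            continue
        tau = (1.0 / gap) * (1.0 + c_param / kinetic_energy)
        a[l] *= np.exp(-dt_au / tau)
    inactive = sum(abs(a[l]) ** 2 for l in range(len(a)) if l != active)
    if abs(a[active]) > 1e-14:
        a[active] *= np.sqrt(max(1.0 - inactive, 0.0)) / abs(a[active])
    return a


# ------------------------------------------------------------- main loop

@dataclass
class InitialCondition:
    geometry: Geometry
    velocities: np.ndarray
    state: int
    excitation_energy_ev: float | None = None
    oscillator_strength: float | None = None


def run_trajectory(initial: InitialCondition, driver: ElectronicDriver,
                   config: SHConfig, trajectory_index: int = 0) -> Trajectory:
    """Propagate one FSSH trajectory; returns the full step record.

    Per nuclear step: solve electronic states (warm-started), evaluate
    gradients, step the nuclei, build the cross-step overlap, propagate the
    coefficients by local diabatization, attempt a hop, apply decoherence.
    The trajectory stops at ``max_time_fs``, after the configured dwell on
    the ground state, or when the total-energy drift exceeds the discard
    threshold.
    """
    rng = np.random.default_rng(config.seed + trajectory_index)
    dt_au = config.dt_nuclear_fs * AUT_PER_FS
    n_sub = config.n_substeps

    traj = Trajectory()
    result = driver.solve(initial.geometry)
    a = np.zeros(config.n_states, dtype=complex)
    a[initial.state] = 1.0
    state = TrajectoryState(0.0, initial.geometry, np.asarray(initial.velocities, float),
                            initial.state, a, np.asarray(result.energies, float))
    grads = driver.gradients(initial.geometry, result)
    traj.log(state)
    _log_diag(traj, result)

    ground_entry_time = None
    n_steps = int(round(config.max_time_fs / config.dt_nuclear_fs))
    for _ in range(n_steps):
        forces = -grads[state.active_state]

        def force_on_active(geom, _active=state.active_state):
            nonlocal result, grads
            try:
                new_result = driver.solve(geom, warm_start=result)
            except Exception:  # one retry from scratch
                new_result = driver.solve(geom)
            result, prev_result = new_result, result
            grads = driver.gradients(geom, result)
            force_on_active.prev_result = prev_result
            return -grads[_active]

        prev_geom, prev_state = state.geometry, state
        new_geom, new_vel, _ = velocity_verlet_step(
            state.geometry, state.velocities, forces, force_on_active, dt_au
        )
        prev_result = force_on_active.prev_result
        e_t = prev_state.energies
        e_tdt = np.asarray(result.energies, float)

        try:
            S = driver.overlap(prev_geom, prev_result, new_geom, result)
            a_new, propagator, T, signs = propagate_electronic_ld(
                prev_state.coefficients, e_t, e_tdt, S, dt_au, n_sub
            )
        except TrivialCrossingError as exc:
            traj.aborted = str(exc)
            break
        driver.apply_phase_fix(result, signs)

        state = TrajectoryState(prev_state.time_fs + config.dt_nuclear_fs, new_geom,
                                new_vel, prev_state.active_state, a_new, e_tdt)
        probs = hopping_probabilities(prev_state.coefficients, a_new, propagator,
                                      state.active_state)
        state, event = attempt_hop(state, probs, rng)
        if event is not None:
            traj.hops.append(event)
        a_dec = apply_decoherence(state.coefficients, state.active_state, e_tdt,
                                  state.kinetic_energy, dt_au, config.decoherence_c)
        state = TrajectoryState(state.time_fs, state.geometry, state.velocities,
                                state.active_state, a_dec, state.energies)
        traj.log(state)
        _log_diag(traj, result)

        if traj.energy_drift_ev > config.energy_drift_threshold_ev:
            traj.discarded = True
            break
        if config.ground_state_dwell_fs is not None:
            if state.active_state == 0:
                if ground_entry_time is None:
                    ground_entry_time = state.time_fs
                elif state.time_fs - ground_entry_time >= config.ground_state_dwell_fs:
                    break
            else:
                ground_entry_time = None
    return traj


def _log_diag(traj: Trajectory, result) -> None:
    ov = getattr(result, "overlaps_sq", None)
    if ov is not None:
        traj.state_overlap_sq.append(np.asarray(ov).copy())
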