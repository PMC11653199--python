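"""Ensemble analysis: populations, kinetic fits, hopping geometries, yields.

State populations are trajectory fractions (the fraction of the ensemble
whose active surface is m at time t); trajectories stopped early after
reaching the ground state are held on their final state for the remainder
of the grid, mirroring the early-termination protocol of the dynamics.

Two kinetic models are provided: a delayed single-exponential decay

    P(t) = 1                      for t <= t0
    P(t) = exp(-(t - t0)/tau1)    for t >  t0     (lifetime tau1 + t0)

and the two-step irreversible chain S2 -> S1 -> S0,

    P_S2(t) = exp(-t/tau2)
    P_S1(t) = tau1 (exp(-t/tau1) - exp(-t/tau2)) / (tau1 - tau2)

with the equal-rate limit  P_S1 = (t/tau) exp(-t/tau)  handled explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.optimize

from .dynamics import Trajectory
from .geometry import Geometry


# ------------------------------------------------------------ populations

@dataclass
class PopulationSeries:
    times_fs: np.ndarray
    fractions: np.ndarray  # (n_states, n_times)
    n_trajectories: int


def populations(trajectories: list[Trajectory], grid_fs: np.ndarray,
                n_states: int | None = None, hold_final: bool = True) -> PopulationSeries:
    """Active-state indicator averaged over trajectories on a time grid."""
    if not trajectories:
        raise ValueError("need at least one trajectory")
    grid_fs = np.asarray(grid_fs, float)
    if grid_fs.size == 0:
        raise ValueError("empty time grid")
    if n_states is None:
        n_states = 1 + max(max(t.active_states) for t in trajectories)
    counts = np.zeros((n_states, len(grid_fs)))
    denom = np.zeros(len(grid_fs))
    for traj in trajectories:
        times = np.asarray(traj.times_fs)
        active = np.asarray(traj.active_states)
        for i, t in enumerate(grid_fs):
            if t <= times[-1]:
                idx = np.searchsorted(times, t, side="right") - 1
                counts[active[max(idx, 0)], i] += 1
                denom[i] += 1
            elif hold_final:
                counts[active[-1], i] += 1
                denom[i] += 1
    denom[denom == 0] = 1.0
    return PopulationSeries(grid_fs, counts / denom, len(trajectories))


# ------------------------------------------------------------ kinetic fits

@dataclass
class KineticFit:
    model: str  # "delayed-exponential" | "sequential-two-step"
    parameters: dict
    covariance: np.ndarray | None
    residual_norm: float
    flagged: bool = False
    message: str = ""

    @property
    def lifetime_fs(self) -> float:
        p = self.parameters
        if self.model == "delayed-exponential":
            return p["tau1_fs"] + p["t0_fs"]
        return p["tau1_fs"] + p["tau2_fs"]

    def summary(self) -> str:
        pars = ", ".join(f"{k} = {v:.3f}" for k, v in self.parameters.items())
        note = f"  [{self.message}]" if self.message else ""
        return (f"{self.model}: {pars}; lifetime = {self.lifetime_fs:.3f} fs; "
                f"residual = {self.residual_norm:.3e}{note}")


def delayed_exponential(t, t0, tau1):
    return np.where(t <= t0, 1.0, np.exp(-(np.maximum(t - t0, 0.0)) / tau1))


def fit_delayed_exponential(series: PopulationSeries, state: int = 1,
                            t0_fixed: float | None = None) -> KineticFit:
    """Least-squares fit of the delayed exponential to one state's decay."""
    t = series.times_fs
    y = series.fractions[state]
    if y[-1] > 0.95 * y[0]:
        return KineticFit("delayed-exponential", {"t0_fs": np.nan, "tau1_fs": np.nan},
                          None, float(np.nan), flagged=True,
                          message="series does not decay; lifetime unidentifiable")
    if t0_fixed is not None:
        def model(tt, tau1):
            return delayed_exponential(tt, t0_fixed, tau1)
        p0 = [max(t[-1] / 2.0, 1.0)]
        popt, pcov = scipy.optimize.curve_fit(model, t, y, p0=p0, maxfev=10000)
        pars = {"t0_fs": t0_fixed, "tau1_fs": float(popt[0])}
        resid = np.linalg.norm(model(t, *popt) - y)
    else:
        p0 = [t[-1] / 10.0, max(t[-1] / 2.0, 1.0)]
        popt, pcov = scipy.optimize.curve_fit(
            lambda tt, t0, tau1: delayed_exponential(tt, t0, tau1), t, y, p0=p0,
            bounds=([0.0, 1e-6], [t[-1], np.inf]), maxfev=10000,
        )
        pars = {"t0_fs": float(popt[0]), "tau1_fs": float(popt[1])}
        resid = np.linalg.norm(delayed_exponential(t, *popt) - y)
    return KineticFit("delayed-exponential", pars, pcov, float(resid))


def sequential_populations(t, tau2, tau1):
    """Closed form of the irreversible chain S2 -> S1 -> S0 (P_S2, P_S1)."""
    t = np.asarray(t, float)
    p2 = np.exp(-t / tau2)
    if abs(tau1 - tau2) < 1e-9 * max(tau1, tau2):
        p1 = (t / tau1) * np.exp(-t / tau1)
    else:
        p1 = tau1 / (tau1 - tau2) * (np.exp(-t / tau1) - np.exp(-t / tau2))
    return p2, p1


def fit_sequential_kinetics(series: PopulationSeries, upper_state: int = 2,
                            lower_state: int = 1) -> KineticFit:
    """Simultaneous least-squares fit of P_S2 and P_S1 to the two-step model."""
    t = series.times_fs
    y2 = series.fractions[upper_state]
    y1 = series.fractions[lower_state]
    if y2[-1] > 0.95 * y2[0]:
        return KineticFit("sequential-two-step", {"tau2_fs": np.nan, "tau1_fs": np.nan},
                          None, float(np.nan), flagged=True,
                          message="upper state does not decay")

    def resid(p):
        p2, p1 = sequential_populations(t, p[0], p[1])
        return np.concatenate([p2 - y2, p1 - y1])

    guess = [max(t[-1] / 10.0, 1.0), max(t[-1] / 4.0, 2.0)]
    sol = scipy.optimize.least_squares(resid, guess, bounds=([1e-6, 1e-6], [np.inf, np.inf]))
    J = sol.jac
    try:
        cov = np.linalg.inv(J.T @ J) * (sol.fun @ sol.fun) / max(len(sol.fun) - 2, 1)
    except np.linalg.LinAlgError:
        cov = None
    pars = {"tau2_fs": float(sol.x[0]), "tau1_fs": float(sol.x[1])}
    return KineticFit("sequential-two-step", pars, cov, float(np.linalg.norm(sol.fun)))


# ----------------------------------------------------- internal coordinates

def internal_coordinate(geometry: Geometry, spec: tuple[int, ...],
                        fold_dihedral: bool = False) -> float:
    """Bond length (angstrom), angle or proper dihedral (degrees).

    The dihedral follows the IUPAC right-hand sign convention in
    (-180, 180]; ``fold_dihedral`` maps it to [0, 180] for cis/trans
    statistics that ignore the sense of rotation.
    """
    from .constants import ANGSTROM_PER_BOHR

    x = geometry.coords
    if len(spec) == 2:
        return float(np.linalg.norm(x[spec[0]] - x[spec[1]])) * ANGSTROM_PER_BOHR
    if len(spec) == 3:
        a, b, c = (x[i] for i in spec)
        u, v = a - b, c - b
        cosang = u @ v / (np.linalg.norm(u) * np.linalg.norm(v))
        return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))
    if len(spec) == 4:
        a, b, c, d = (x[i] for i in spec)
        b1, b2, b3 = b - a, c - b, d - c
        n1, n2 = np.cross(b1, b2), np.cross(b2, b3)
        if np.linalg.norm(n1) < 1e-10 or np.linalg.norm(n2) < 1e-10:
            raise ValueError("dihedral undefined: collinear atoms")
        m1 = np.cross(n1, b2 / np.linalg.norm(b2))
        ang = np.degrees(np.arctan2(m1 @ n2, n1 @ n2))
        if ang <= -180.0:
            ang += 360.0
        return float(abs(ang)) if fold_dihedral else float(ang)
    raise ValueError("spec must contain 2, 3 or 4 atom indices")


# --------------------------------------------------------- hop statistics

def hopping_statistics(trajectories: list[Trajectory],
                       coordinate_specs: dict[str, tuple[int, ...]],
                       state_pair: tuple[int, int] | None = None,
                       successful_only: bool = True):
    """Per-hop internal coordinates with means and standard deviations.

    Returns (table, stats): ``table`` is a DataFrame with one row per hop,
    ``stats`` maps coordinate name -> (mean, std).  Dihedrals are folded to
    [0, 180] degrees.
    """
    import pandas as pd

    rows = []
    for i, traj in enumerate(trajectories):
        for hop in traj.hops:
            if successful_only and not hop.successful:
                continue
            if state_pair is not None and {hop.source, hop.target} != set(state_pair):
                continue
            row = {"trajectory": i, "time_fs": hop.time_fs,
                   "source": hop.source, "target": hop.target}
            for name, spec in coordinate_specs.items():
                row[name] = internal_coordinate(hop.geometry, spec,
                                                fold_dihedral=len(spec) == 4)
            rows.append(row)
    table = pd.DataFrame(rows)
    stats = {}
    for name in coordinate_specs:
        if len(table):
            stats[name] = (float(table[name].mean()), float(table[name].std(ddof=0)))
        else:
            stats[name] = (np.nan, np.nan)
    return table, stats


def quantum_yield(trajectories: list[Trajectory], dihedral_spec: tuple[int, int, int, int],
                  cis_cutoff: float = 50.0, trans_cutoff: float = 125.0):
    """Photoisomerization quantum yield from final folded dihedrals.

    Trajectories ending on the ground state are classified by their final
    dihedral: <= cis_cutoff -> unreacted, >= trans_cutoff -> isomerized,
    in between -> unassigned.  Phi = isomerized / assigned with the
    binomial standard deviation sqrt(Phi (1 - Phi) / n_assigned).
    """
    if not 0.0 < cis_cutoff < trans_cutoff < 180.0:
        raise ValueError("cutoffs must satisfy 0 < cis < trans < 180")
    n_cis = n_trans = n_unassigned = 0
    for traj in trajectories:
        if not traj.active_states or traj.active_states[-1] != 0:
            continue
        d = internal_coordinate(traj.geometries[-1], dihedral_spec, fold_dihedral=True)
        if d <= cis_cutoff:
            n_cis += 1
        elif d >= trans_cutoff:
            n_trans += 1
        else:
            n_unassigned += 1
    return yield_from_counts(n_cis, n_trans, n_unassigned)


def yield_from_counts(n_unreacted: int, n_isomerized: int, n_unassigned: int = 0):
    """Phi and its binomial standard deviation from assigned outcome counts."""
    n_assigned = n_unreacted + n_isomerized
    if n_assigned == 0:
        return {"phi": np.nan, "sigma": np.nan, "n_assigned": 0,
                "n_unassigned": n_unassigned, "flagged": True}
    phi = n_isomerized / n_assigned
    sigma = np.sqrt(phi * (1.0 - phi) / n_assigned)
    return {"phi": phi, "sigma": sigma, "n_assigned": n_assigned,
            "n_unassigned": n_unassigned, "flagged": False}
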