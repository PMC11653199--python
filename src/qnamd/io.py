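"""Plain-text serialization of run artifacts.

Everything a trajectory produces is logged in line-oriented text: angle
vectors, per-step trajectory tables (TSV), XYZ movies, gradient/coupling
blocks in the labelled-block layout common to trajectory codes, and
determinant/coefficient tables for the
CI-type expansions.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .constants import ANGSTROM_PER_BOHR
from .dynamics import Trajectory
from .properties import CIExpansion


def save_theta(path, theta: np.ndarray, labels=None) -> None:
    with open(path, "w") as fh:
        for i, t in enumerate(np.asarray(theta, float)):
            label = labels[i] if labels else f"theta_{i}"
            fh.write(f"{label}\t{t:.16e}\n")


def load_theta(path) -> np.ndarray:
    return np.array([float(line.split("\t")[1]) for line in
                     Path(path).read_text().strip().splitlines()])


def write_trajectory_log(path, trajectory: Trajectory) -> None:
    """Per-step TSV: time, active state, energies, populations, drift."""
    trajectory.to_frame().to_csv(path, sep="\t", index=False, float_format="%.10f")


def write_trajectory_xyz(path, trajectory: Trajectory, stride: int = 1) -> None:
    with open(path, "w") as fh:
        for i in range(0, len(trajectory.times_fs), stride):
            geom = trajectory.geometries[i]
            fh.write(f"{geom.n_atoms}\n"
                     f"t = {trajectory.times_fs[i]:.3f} fs, "
                     f"state = {trajectory.active_states[i]}\n")
            for s, xyz in zip(geom.symbols, geom.coords * ANGSTROM_PER_BOHR):
                fh.write(f"{s:<3s} {xyz[0]:15.8f} {xyz[1]:15.8f} {xyz[2]:15.8f}\n")


def write_property_block(path, arrays: dict[str, np.ndarray]) -> None:
    """Gradient/NAC blocks: one labelled (N, 3) block per entry."""
    with open(path, "w") as fh:
        for name, arr in arrays.items():
            arr = np.asarray(arr, float).reshape(-1, 3)
            fh.write(f"! {name} {arr.shape[0]} 3\n")
            for row in arr:
                fh.write(f"{row[0]:20.12e} {row[1]:20.12e} {row[2]:20.12e}\n")


def read_property_block(path) -> dict[str, np.ndarray]:
    out: dict[str, np.ndarray] = {}
    name, rows = None, []
    for line in Path(path).read_text().splitlines():
        if line.startswith("!"):
            if name is not None:
                out[name] = np.array(rows)
            parts = line[1:].split()
            name, rows = " ".join(parts[:-2]), []
        elif line.strip():
            rows.append([float(x) for x in line.split()])
    if name is not None:
        out[name] = np.array(rows)
    return out


def write_ci_expansion(path, expansion: CIExpansion) -> None:
    """Determinant table: occupation string (a/b/2/0 per orbital), coeff."""
    n_orb = 0
    for alpha, beta in expansion.determinants:
        n_orb = max([n_orb, *(o + 1 for o in alpha), *(o + 1 for o in beta)])
    with open(path, "w") as fh:
        fh.write(f"# {len(expansion)} determinants, norm retained "
                 f"{expansion.norm_retained:.8f}\n")
        for (alpha, beta), c in zip(expansion.determinants, expansion.coefficients):
            occ = []
            for p in range(n_orb):
                a, b = p in alpha, p in beta
                occ.append("2" if a and b else "a" if a else "b" if b else "0")
            fh.write(f"{''.join(occ)}\t{float(c):.16e}\t0.0\n")


def read_ci_expansion(path) -> CIExpansion:
    dets, coeffs = [], []
    for line in Path(path).read_text().splitlines():
        if line.startswith("#") or not line.strip():
            continue
        occ, re_c, _im = line.split("\t")
        alpha = tuple(i for i, ch in enumerate(occ) if ch in "2a")
        beta = tuple(i for i, ch in enumerate(occ) if ch in "2b")
        dets.append((alpha, beta))
        coeffs.append(float(re_c))
    coeffs = np.array(coeffs)
    return CIExpansion(dets, coeffs, norm_retained=float(coeffs @ coeffs))


def write_restart(path, state, thetas: list[np.ndarray] | None = None) -> None:
    """Checkpoint of a TrajectoryState (plus optional per-state angles)."""
    with open(path, "w") as fh:
        fh.write(f"# time_fs {state.time_fs:.10f}\n")
        fh.write(f"# active {state.active_state}\n")
        fh.write("# symbols " + " ".join(state.geometry.symbols) + "\n")
        np.savetxt(fh, state.geometry.coords, header="coords_bohr", comments="# ")
        np.savetxt(fh, state.velocities, header="velocities", comments="# ")
        np.savetxt(fh, np.column_stack([state.coefficients.real,
                                        state.coefficients.imag]),
                   header="coefficients", comments="# ")
        np.savetxt(fh, state.energies[None, :], header="energies", comments="# ")
        if thetas is not None:
            for i, th in enumerate(thetas):
                np.savetxt(fh, np.asarray(th, float)[None, :], header=f"theta_{i}",
                           comments="# ")


def read_restart(path):
    from .dynamics import TrajectoryState
    from .geometry import Geometry

    blocks: dict[str, list[str]] = {}
    meta: dict[str, str] = {}
    name = None
    for line in Path(path).read_text().splitlines():
        if line.startswith("# "):
            parts = line[2:].split()
            if parts[0] in ("time_fs", "active", "symbols"):
                meta[parts[0]] = " ".join(parts[1:])
                name = None
            else:
                name = parts[0]
                blocks[name] = []
        elif name is not None and line.strip():
            blocks[name].append(line)

    def arr(key):
        return np.loadtxt(blocks[key], ndmin=2)

    symbols = tuple(meta["symbols"].split())
    geom = Geometry(symbols, arr("coords_bohr"))
    coeff_ri = arr("coefficients")
    coeffs = coeff_ri[:, 0] + 1j * coeff_ri[:, 1]
    state = TrajectoryState(float(meta["time_fs"]), geom, arr("velocities"),
                            int(meta["active"]), coeffs, arr("energies").ravel())
    thetas = []
    i = 0
    while f"theta_{i}" in blocks:
        thetas.append(arr(f"theta_{i}").ravel())
        i += 1
    return state, (thetas or None)


def write_overlap_log(path, matrices: list[np.ndarray], times_fs=None) -> None:
    with open(path, "w") as fh:
        for i, S in enumerate(matrices):
            stamp = f"{times_fs[i]:.4f}" if times_fs is not None else str(i)
            fh.write(f"# step {stamp}\n")
            for row in np.asarray(S):
                fh.write("\t".join(f"{x:.12e}" for x in row) + "\n")
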