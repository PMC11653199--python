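"""Molecular geometries and XYZ input/output.

Coordinates are stored in bohr internally; XYZ files are read and written
in angstrom, following the universal convention of that format.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import ANGSTROM_PER_BOHR, BOHR_PER_ANGSTROM, ATOMIC_NUMBER, mass_au


@dataclass(frozen=True)
class Geometry:
    """A molecular geometry: element symbols, positions (bohr), masses (a.u.)."""

    symbols: tuple[str, ...]
    coords: np.ndarray  # (N, 3), bohr
    masses: np.ndarray = field(default=None)  # (N,), electron masses

    def __post_init__(self):
        coords = np.asarray(self.coords, dtype=float).reshape(len(self.symbols), 3)
        if not np.all(np.isfinite(coords)):
            raise ValueError("geometry coordinates must be finite")
        object.__setattr__(self, "coords", coords)
        masses = self.masses
        if masses is None:
            masses = np.array([mass_au(s) for s in self.symbols])
        masses = np.asarray(masses, dtype=float)
        if np.any(masses <= 0):
            raise ValueError("masses must be positive")
        object.__setattr__(self, "masses", masses)

    @property
    def n_atoms(self) -> int:
        return len(self.symbols)

    @property
    def atomic_numbers(self) -> np.ndarray:
        return np.array([ATOMIC_NUMBER[s] for s in self.symbols])

    def nuclear_repulsion(self) -> float:
        """E_NN(R) = sum_{I<J} Z_I Z_J / |R_I - R_J| in hartree."""
        z = self.atomic_numbers
        e = 0.0
        for i in range(self.n_atoms):
            for j in range(i + 1, self.n_atoms):
                e += z[i] * z[j] / np.linalg.norm(self.coords[i] - self.coords[j])
        return e

    def displaced(self, atom: int, axis: int, shift_bohr: float) -> "Geometry":
        coords = self.coords.copy()
        coords[atom, axis] += shift_bohr
        return Geometry(self.symbols, coords, self.masses)

    def with_coords(self, coords_bohr: np.ndarray) -> "Geometry":
        return Geometry(self.symbols, np.asarray(coords_bohr, float), self.masses)


def read_xyz(path) -> Geometry:
    with open(path) as fh:
        lines = fh.read().split("\n")
    n = int(lines[0].split()[0])
    symbols, coords = [], []
    for line in lines[2 : 2 + n]:
        parts = line.split()
        symbols.append(parts[0])
        coords.append([float(x) for x in parts[1:4]])
    return Geometry(tuple(symbols), np.array(coords) * BOHR_PER_ANGSTROM)


def write_xyz(path, geometry: Geometry, comment: str = "") -> None:
    with open(path, "w") as fh:
        fh.write(f"{geometry.n_atoms}\n{comment}\n")
        for s, xyz in zip(geometry.symbols, geometry.coords * ANGSTROM_PER_BOHR):
            fh.write(f"{s:<3s} {xyz[0]:18.12f} {xyz[1]:18.12f} {xyz[2]:18.12f}\n")
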