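"""Wigner initial conditions, normal modes and absorption spectra.

The ground-vibrational-state Wigner distribution of each harmonic normal
mode is a product of independent Gaussians with variances

    sigma_Q^2 = hbar / (2 omega),   sigma_P^2 = hbar omega / 2

in mass-weighted atomic units, so positions and momenta are sampled
independently per mode and transformed back to Cartesians.  Normal modes
come from a fully numerical (central finite difference) Hessian of the
ground-state energy; translations and rotations are projected out before
diagonalization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import EV_PER_HARTREE, WAVENUMBER_PER_HARTREE
from .dynamics import InitialCondition
from .geometry import Geometry


def numerical_hessian(energy, geometry: Geometry, displacement: float = 0.01) -> np.ndarray:
    """3N x 3N second-derivative matrix of ``energy(geometry)`` (hartree/bohr^2).

    Central finite differences with double-sided displacements (default
    0.01 bohr); the result is symmetrized as (H + H^T)/2.
    """
    if displacement <= 0:
        raise ValueError("displacement must be positive")
    n = 3 * geometry.n_atoms
    x0 = geometry.coords.ravel()

    def e_at(x):
        return float(energy(geometry.with_coords(x.reshape(-1, 3))))

    e0 = e_at(x0)
    h = np.zeros((n, n))
    e_plus = np.zeros(n)
    e_minus = np.zeros(n)
    for i in range(n):
        xp, xm = x0.copy(), x0.copy()
        xp[i] += displacement
        xm[i] -= displacement
        e_plus[i] = e_at(xp)
        e_minus[i] = e_at(xm)
        h[i, i] = (e_plus[i] - 2.0 * e0 + e_minus[i]) / displacement**2
    for i in range(n):
        for j in range(i + 1, n):
            xpp, xpm, xmp, xmm = (x0.copy() for _ in range(4))
            xpp[[i, j]] += displacement
            xmm[[i, j]] -= displacement
            xpm[i] += displacement
            xpm[j] -= displacement
            xmp[i] -= displacement
            xmp[j] += displacement
            val = (e_at(xpp) - e_at(xpm) - e_at(xmp) + e_at(xmm)) / (4.0 * displacement**2)
            h[i, j] = h[j, i] = val
    return 0.5 * (h + h.T)


@dataclass
class NormalModeSet:
    """Vibrational normal modes of a minimum-energy geometry."""

    frequencies_cm: np.ndarray  # (n_modes,), cm^-1 (positive)
    modes: np.ndarray  # (n_modes, 3N) mass-weighted, orthonormal
    geometry: Geometry
    n_imaginary: int = 0
    imaginary_frequencies_cm: np.ndarray | None = None

    @property
    def n_modes(self) -> int:
        return len(self.frequencies_cm)

    @property
    def frequencies_au(self) -> np.ndarray:
        return self.frequencies_cm / WAVENUMBER_PER_HARTREE


def normal_modes(hessian: np.ndarray, geometry: Geometry, linear: bool | None = None,
                 zero_tol_cm: float = 30.0) -> NormalModeSet:
    """Mass-weighted diagonalization with translation/rotation projection.

    Drops 6 external modes (5 for linear molecules); imaginary frequencies
    are reported, and more than the expected number of near-zero modes
    raises (the geometry is not a minimum of anything harmonic).
    """
    if not np.allclose(hessian, hessian.T, atol=1e-10):
        raise ValueError("hessian must be symmetric")
    masses = np.repeat(geometry.masses, 3)
    mw = hessian / np.sqrt(np.outer(masses, masses))

    # project out rigid translations and rotations
    n = geometry.n_atoms
    vecs = []
    sqm = np.sqrt(geometry.masses)
    for d in range(3):
        t = np.zeros((n, 3))
        t[:, d] = sqm
        vecs.append(t.ravel())
    com = (geometry.masses[:, None] * geometry.coords).sum(0) / geometry.masses.sum()
    rel = geometry.coords - com
    for d in range(3):
        axis = np.zeros(3)
        axis[d] = 1.0
        r = np.cross(rel, axis) * sqm[:, None]
        if np.linalg.norm(r) > 1e-8:
            vecs.append(r.ravel())
    basis = np.linalg.qr(np.array(vecs).T)[0]
    proj = np.eye(3 * n) - basis @ basis.T
    mw = proj @ mw @ proj

    vals, modes = np.linalg.eigh(mw)
    freqs = np.sign(vals) * np.sqrt(np.abs(vals))
    n_external = 5 if (linear or (linear is None and _is_linear(geometry))) else 6
    zero_tol = zero_tol_cm / WAVENUMBER_PER_HARTREE
    near_zero = np.abs(freqs) < zero_tol
    if near_zero.sum() > n_external:
        raise ValueError("more near-zero modes than rigid motions: not a minimum")
    keep = ~near_zero
    freqs, modes = freqs[keep], modes[:, keep]
    imag = freqs < 0
    return NormalModeSet(
        frequencies_cm=freqs[~imag] * WAVENUMBER_PER_HARTREE,
        modes=modes[:, ~imag].T,
        geometry=geometry,
        n_imaginary=int(imag.sum()),
        imaginary_frequencies_cm=(-freqs[imag] * WAVENUMBER_PER_HARTREE) if imag.any() else None,
    )


def _is_linear(geometry: Geometry, tol: float = 1e-6) -> bool:
    if geometry.n_atoms <= 2:
        return True
    rel = geometry.coords - geometry.coords[0]
    return np.linalg.matrix_rank(rel, tol=tol) < 2


def wigner_sample(modes: NormalModeSet, n_samples: int, seed: int = 0,
                  rng: np.random.Generator | None = None):
    """Draw (geometry, velocities) pairs from the harmonic ground-state
    Wigner distribution (one independent Gaussian pair per mode)."""
    if modes.n_imaginary:
        raise ValueError("imaginary frequencies present; exclude or reoptimize")
    rng = rng or np.random.default_rng(seed)
    omega = modes.frequencies_au
    sqm = np.sqrt(np.repeat(modes.geometry.masses, 3))
    out = []
    for _ in range(n_samples):
        q = rng.normal(0.0, np.sqrt(0.5 / omega))
        p = rng.normal(0.0, np.sqrt(0.5 * omega))
        dx = (modes.modes.T @ q) / sqm
        v = (modes.modes.T @ p) / sqm
        geom = modes.geometry.with_coords(modes.geometry.coords + dx.reshape(-1, 3))
        out.append((geom, v.reshape(-1, 3)))
    return out


# ------------------------------------------------------------- spectrum

@dataclass
class SpectrumResult:
    energies_ev: np.ndarray  # grid
    per_state: np.ndarray  # (n_excited, n_grid)
    total: np.ndarray
    excitations: list  # per sample: list of (state, dE_eV, f)
    n_failed: int = 0

    def band_maximum_ev(self, state: int | None = None) -> float:
        curve = self.total if state is None else self.per_state[state]
        return float(self.energies_ev[np.argmax(curve)])


def simulate_spectrum(ensemble, excitation_fn, n_states: int,
                      e_range_ev=(0.0, 15.0), n_grid: int = 600,
                      fwhm_ev: float = 0.1) -> SpectrumResult:
    """Gaussian-broadened absorption spectrum over a geometry ensemble.

    ``excitation_fn(geometry)`` must return a list of (dE_eV, f) for the
    excited states at that geometry; each line contributes a Gaussian of
    area f at dE.  Unconverged points may raise; they are skipped and
    counted.
    """
    grid = np.linspace(*e_range_ev, n_grid)
    sigma = fwhm_ev / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    per_state = np.zeros((n_states - 1, n_grid))
    excitations = []
    n_failed = 0
    for item in ensemble:
        geom = item[0] if isinstance(item, tuple) else item
        try:
            lines = excitation_fn(geom)
        except Exception:
            n_failed += 1
            continue
        sample = []
        for st, (de, f) in enumerate(lines):
            per_state[st] += f * np.exp(-0.5 * ((grid - de) / sigma) ** 2) / (
                sigma * np.sqrt(2 * np.pi)
            )
            sample.append((st + 1, de, f))
        excitations.append(sample)
    n_ok = max(len(excitations), 1)
    per_state /= n_ok
    return SpectrumResult(grid, per_state, per_state.sum(0), excitations, n_failed)


def select_initial_conditions(ensemble, excitations, window_ev, n_wanted: int | None = None,
                              p_norm: float | None = None, seed: int = 0):
    """Stochastic initial-state selection by oscillator strength.

    Within the excitation window, a (geometry, state) pair is accepted with
    probability f / p_norm; ``p_norm`` defaults to 1.01 * max f over the
    ensemble (it must exceed every f for the acceptance step to be valid).
    Raises when no excitation falls inside the window.
    """
    lo, hi = window_ev
    if not lo < hi:
        raise ValueError("window must satisfy lower < upper")
    rng = np.random.default_rng(seed)
    candidates = []
    for (geom, vel), lines in zip(ensemble, excitations):
        for st, de, f in lines:
            if lo <= de <= hi:
                candidates.append((geom, vel, st, de, f))
    if not candidates:
        all_de = sorted(de for lines in excitations for _, de, _ in lines)
        nearest = all_de[:3] + all_de[-3:] if all_de else []
        raise ValueError(f"no excitations inside window {window_ev}; nearest: {nearest}")
    fmax = max(c[4] for c in candidates)
    if fmax == 0.0:
        return []  # nothing bright enough to be excited
    if p_norm is None:
        p_norm = 1.01 * fmax
    if p_norm < fmax:
        raise ValueError("p_norm must exceed the largest oscillator strength")
    selected = []
    for geom, vel, st, de, f in candidates:
        if rng.random() < f / p_norm:
            selected.append(InitialCondition(geom, vel, st, de, f))
            if n_wanted is not None and len(selected) >= n_wanted:
                break
    return selected
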