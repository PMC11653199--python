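"""Self-contained model systems for exercising every pipeline stage.

* :class:`AvoidedCrossing` — a two-level diabatic model along one scalar
  coordinate with closed-form adiabatic surfaces, mixing angle and
  nonadiabatic coupling;
* :class:`AnalyticDriver` — the same model packaged as an electronic
  driver for the surface-hopping loop (exact eigenvectors, overlaps from
  eigenvector products);
* :class:`TwoLevelFermionicProvider` — a 2-electron-in-2-orbital integral
  set whose two closed-shell singlet eigenvalues follow the model curves,
  so the full variational-quantum stack can be validated against the
  closed form;
* :func:`synthesize_population_curves` — stochastic hop-time ensembles for
  the kinetic-fit machinery.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dynamics import ElectronicDriver
from .geometry import Geometry
from .integrals import ActiveSpaceSpec, SpatialIntegrals
from .provider import ElectronicStructureProvider


@dataclass
class AvoidedCrossing:
    """Linear diabats V11 = -V22 = slope*R coupled by a Gaussian V12.

    The minimum adiabatic gap (at R = 0) equals ``gap``; a large
    ``coupling_width`` gives an effectively constant coupling.  When the
    width exceeds the mixing length gap/(2 slope) the nonadiabatic
    coupling peaks at the crossing; narrower couplings split it into two
    lobes where the Gaussian shoulder meets the diabatic splitting.
    """

    gap: float = 0.02  # hartree; V12(0) = gap/2
    coupling_width: float = 1.0  # bohr
    slope: float = 0.01  # hartree/bohr

    def __post_init__(self):
        if self.gap <= 0 or self.coupling_width <= 0 or self.slope <= 0:
            raise ValueError("model parameters must be positive")

    def diabatic(self, r: float) -> np.ndarray:
        v12 = 0.5 * self.gap * np.exp(-0.5 * (r / self.coupling_width) ** 2)
        return np.array([[self.slope * r, v12], [v12, -self.slope * r]])

    def adiabatic_energies(self, r: float) -> np.ndarray:
        h = self.diabatic(r)
        w = np.sqrt(((h[0, 0] - h[1, 1]) / 2) ** 2 + h[0, 1] ** 2)
        mean = 0.5 * (h[0, 0] + h[1, 1])
        return np.array([mean - w, mean + w])

    def mixing_angle(self, r: float) -> float:
        h = self.diabatic(r)
        return 0.5 * np.arctan2(2.0 * h[0, 1], h[0, 0] - h[1, 1])

    def nac(self, r: float) -> float:
        """d_01(R) = d(mixing angle)/dR, exact."""
        v12 = 0.5 * self.gap * np.exp(-0.5 * (r / self.coupling_width) ** 2)
        dv12 = -r / self.coupling_width**2 * v12
        delta = 2.0 * self.slope * r
        ddelta = 2.0 * self.slope
        denom = delta**2 + 4.0 * v12**2
        return (dv12 * delta - v12 * ddelta) / denom if denom > 0 else 0.0

    def adiabatic_states(self, r: float) -> np.ndarray:
        """Columns are the lower/upper adiabatic states, continuous in R."""
        phi = self.mixing_angle(r)
        lower = np.array([-np.sin(phi), np.cos(phi)])
        upper = np.array([np.cos(phi), np.sin(phi)])
        return np.column_stack([lower, upper])


def make_avoided_crossing(gap: float, coupling_width: float, slope: float) -> AvoidedCrossing:
    return AvoidedCrossing(gap, coupling_width, slope)


def scalar_geometry(r: float, mass_au: float = 2000.0) -> Geometry:
    """One-particle geometry carrying the scalar model coordinate on x."""
    return Geometry(("H",), np.array([[r, 0.0, 0.0]]), np.array([mass_au]))


@dataclass
class _AnalyticResult:
    energies: np.ndarray
    vectors: np.ndarray  # (2, 2) adiabatic states in the diabatic basis


class AnalyticDriver(ElectronicDriver):
    """Two-state electronic driver with closed-form states and overlaps."""

    def __init__(self, model: AvoidedCrossing, mass_au: float = 2000.0):
        self.model = model
        self.mass_au = mass_au
        self.n_states = 2

    def solve(self, geometry: Geometry, warm_start=None) -> _AnalyticResult:
        r = float(geometry.coords[0, 0])
        return _AnalyticResult(self.model.adiabatic_energies(r),
                               self.model.adiabatic_states(r))

    def gradients(self, geometry: Geometry, result) -> np.ndarray:
        r = float(geometry.coords[0, 0])
        eps = 1e-6
        ep = self.model.adiabatic_energies(r + eps)
        em = self.model.adiabatic_energies(r - eps)
        g = np.zeros((2, geometry.n_atoms, 3))
        g[:, 0, 0] = (ep - em) / (2 * eps)
        return g

    def overlap(self, geom_bra, result_bra, geom_ket, result_ket) -> np.ndarray:
        return result_bra.vectors.T @ result_ket.vectors

    def apply_phase_fix(self, result, signs: np.ndarray) -> None:
        result.vectors = result.vectors * signs[None, :]


class TwoLevelFermionicProvider(ElectronicStructureProvider):
    """2-in-2 active-space integrals realizing the avoided-crossing model.

    The closed-shell determinant block {|p^2>, |q^2>} carries exactly the
    model's diabatic matrix; the open-shell singlet and triplet are pushed
    away by the Coulomb offset J = (pp|qq), so the two lowest singlet
    eigenvalues follow the model's adiabatic curves.
    """

    def __init__(self, model: AvoidedCrossing, coulomb_offset: float = 0.5):
        self.model = model
        self.j_offset = coulomb_offset
        self.active_space = ActiveSpaceSpec(2, 2)

    def spatial_integrals(self, geometry, active_space) -> SpatialIntegrals:
        r = float(geometry.coords[0, 0])
        hdia = self.model.diabatic(r)
        h = np.diag([0.5 * hdia[0, 0], 0.5 * hdia[1, 1]])
        g = np.zeros((2, 2, 2, 2))
        v12 = hdia[0, 1]
        # chemist notation: (pq|pq) couples the two closed-shell determinants
        g[0, 1, 0, 1] = g[1, 0, 0, 1] = g[0, 1, 1, 0] = g[1, 0, 1, 0] = v12
        g[0, 0, 1, 1] = g[1, 1, 0, 0] = self.j_offset
        return SpatialIntegrals(h, g, 0.0, n_electrons=2)

    def cross_overlap(self, geom_bra, geom_ket, active_space):
        return np.eye(2)

    def dipole_matrices(self, geometry, active_space):
        # a fixed off-diagonal moment; useful for transition-dipole checks
        d = np.zeros((3, 2, 2))
        d[0] = np.array([[0.0, 1.0], [1.0, 0.0]])
        return d, np.zeros(3)


# -------------------------------------------------------------- fixtures

@dataclass
class FixtureGrid:
    """Geometries along one coordinate with integrals and oracle energies."""

    coordinates: np.ndarray
    geometries: list[Geometry]
    integrals: list[SpatialIntegrals]
    oracle_energies: np.ndarray  # (n_points, n_states), lowest singlets


def h2_stretch_grid(n_points: int = 11, r_min: float = 1.0, r_max: float = 2.4,
                    basis: str = "sto-3g", n_states: int = 3) -> FixtureGrid:
    """H2 bond-stretch grid with FCI oracle energies from the built-in RHF."""
    from .fermion import jordan_wigner
    from .integrals import second_quantized_hamiltonian
    from .provider import HartreeFockProvider
    from .vqe import exact_spectrum

    aspace = ActiveSpaceSpec(2, 2)
    provider = HartreeFockProvider(basis)
    rs = np.linspace(r_min, r_max, n_points)
    geoms, ints, oracle = [], [], []
    for r in rs:
        g = Geometry(("H", "H"), np.array([[0.0, 0.0, 0.0], [0.0, 0.0, r]]))
        spatial = provider.spatial_integrals(g, aspace)
        H = jordan_wigner(second_quantized_hamiltonian(spatial.to_spin_orbital()), 4)
        vals = exact_spectrum(H, n_states, n_electrons=2, sz=0.0, s2_target=0.0)
        geoms.append(g)
        ints.append(spatial)
        oracle.append(vals)
    return FixtureGrid(rs, geoms, ints, np.array(oracle))


# ------------------------------------------------- synthetic populations

def synthesize_population_curves(model: str, params: dict, n_traj: int,
                                 grid_fs: np.ndarray, seed: int = 0):
    """Indicator-averaged population curves from sampled hop times.

    ``model`` is "delayed-exponential" (params t0_fs, tau1_fs; states
    S0/S1) or "sequential" (params tau2_fs, tau1_fs; states S0/S1/S2).
    ``n_traj = None`` returns the noiseless closed-form curves.
    """
    from .analysis import PopulationSeries, delayed_exponential, sequential_populations

    grid_fs = np.asarray(grid_fs, float)
    rng = np.random.default_rng(seed)
    if model == "delayed-exponential":
        t0, tau1 = params["t0_fs"], params["tau1_fs"]
        if n_traj is None:
            p1 = delayed_exponential(grid_fs, t0, tau1)
            return PopulationSeries(grid_fs, np.vstack([1.0 - p1, p1]), 0)
        hops = t0 + rng.exponential(tau1, size=n_traj)
        p1 = (grid_fs[None, :] < hops[:, None]).mean(axis=0)
        return PopulationSeries(grid_fs, np.vstack([1.0 - p1, p1]), n_traj)
    if model == "sequential":
        tau2, tau1 = params["tau2_fs"], params["tau1_fs"]
        if n_traj is None:
            p2, p1 = sequential_populations(grid_fs, tau2, tau1)
            return PopulationSeries(grid_fs, np.vstack([1.0 - p1 - p2, p1, p2]), 0)
        t_21 = rng.exponential(tau2, size=n_traj)
        t_10 = t_21 + rng.exponential(tau1, size=n_traj)
        p2 = (grid_fs[None, :] < t_21[:, None]).mean(axis=0)
        p1 = ((grid_fs[None, :] >= t_21[:, None])
              & (grid_fs[None, :] < t_10[:, None])).mean(axis=0)
        return PopulationSeries(grid_fs, np.vstack([1.0 - p1 - p2, p1, p2]), n_traj)
    raise ValueError(f"unknown kinetic model {model!r}")
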