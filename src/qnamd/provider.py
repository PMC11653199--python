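"""Electronic-structure providers and geometry-parametrized qubit Hamiltonians.

A provider supplies active-space integrals, molecular-orbital data,
cross-geometry orbital overlaps and dipole integrals for a geometry.  Three
implementations are shipped:

* :class:`HartreeFockProvider` — the built-in RHF backend with
  maximum-overlap orbital tracking across geometries;
* :class:`FcidumpProvider` — a single fixed integral set (geometry-blind),
  for desk fixtures;
* :class:`VibronicExpansionProvider` — active-space integrals expanded to
  first order in nuclear displacements around a reference point (with a
  harmonic scalar term), a vibronic-coupling-style molecular model that
  makes ab-initio-derived dynamics runnable without any SCF at run time.

All providers are deterministic: identical geometries give bit-identical
integrals.
"""

from __future__ import annotations

from abc import ABC, abstractmethod

import numpy as np

from .fermion import jordan_wigner
from .geometry import Geometry
from .integrals import (
    ActiveSpaceSpec,
    SpatialIntegrals,
    SpinOrbitalIntegrals,
    one_body_operator,
    second_quantized_hamiltonian,
    spatial_one_body_to_spin,
)
from .constants import BOHR_PER_ANGSTROM
from .pauli import QubitOperator


class ElectronicStructureProvider(ABC):
    """Contract for backends supplying geometry-dependent integrals."""

    @abstractmethod
    def spatial_integrals(self, geometry: Geometry, active_space: ActiveSpaceSpec) -> SpatialIntegrals:
        ...

    def integrals(self, geometry: Geometry, active_space: ActiveSpaceSpec) -> SpinOrbitalIntegrals:
        return self.spatial_integrals(geometry, active_space).to_spin_orbital()

    def mo_coefficients(self, geometry: Geometry) -> np.ndarray:
        raise NotImplementedError(f"{type(self).__name__} has no molecular orbitals")

    @abstractmethod
    def cross_overlap(self, geom_bra: Geometry, geom_ket: Geometry,
                      active_space: ActiveSpaceSpec) -> np.ndarray:
        """Active-orbital overlap matrix <phi_p(bra geom)|phi_q(ket geom)> (spatial)."""

    def dipole_matrices(self, geometry: Geometry, active_space: ActiveSpaceSpec):
        """(d, const): active-space spatial dipole matrices (3,n,n) and the
        nuclear + frozen-core constant (3,), in a.u. (length gauge)."""
        raise NotImplementedError(f"{type(self).__name__} supplies no dipole integrals")


# ------------------------------------------------------------ H builders

def build_qubit_hamiltonian(provider: ElectronicStructureProvider, geometry: Geometry,
                            active_space: ActiveSpaceSpec,
                            prune: float = 1e-12) -> QubitOperator:
    """Active-space qubit Hamiltonian H(R) via Jordan–Wigner.

    Providers may expose a ``qubit_hamiltonian`` fast path (e.g. the
    vibronic-expansion model combines precomputed JW parts linearly).
    """
    if hasattr(provider, "qubit_hamiltonian"):
        return provider.qubit_hamiltonian(geometry, active_space, prune)
    so = provider.integrals(geometry, active_space)
    op = jordan_wigner(second_quantized_hamiltonian(so), active_space.n_qubits)
    return op.prune(prune)


def hamiltonian_derivative(provider: ElectronicStructureProvider, geometry: Geometry,
                           active_space: ActiveSpaceSpec, atom: int, axis: int,
                           shift_angstrom: float = 0.001,
                           prune: float = 1e-14) -> QubitOperator:
    """Central-difference derivative dH/dR_{I,xi} as a qubit operator.

    The shift defaults to 0.001 angstrom.  Orbital consistency across the
    two displaced geometries is the provider's responsibility; the
    Hartree–Fock provider tracks active orbitals by maximum overlap with
    the undisplaced reference.
    """
    if shift_angstrom <= 0:
        raise ValueError("shift must be positive")
    delta = shift_angstrom * BOHR_PER_ANGSTROM
    if hasattr(provider, "derivative_operator"):
        # exact for models at most quadratic in R (equals the central
        # difference there, at zero cost)
        return provider.derivative_operator(geometry, active_space, atom, axis).prune(prune)
    if hasattr(provider, "set_reference"):
        provider.set_reference(geometry)
    try:
        h_plus = build_qubit_hamiltonian(provider, geometry.displaced(atom, axis, +delta),
                                         active_space, prune=0.0)
        h_minus = build_qubit_hamiltonian(provider, geometry.displaced(atom, axis, -delta),
                                          active_space, prune=0.0)
    except Exception as exc:
        raise RuntimeError(
            f"backend failed at geometry displaced along atom {atom} axis {axis}"
        ) from exc
    return ((h_plus - h_minus) * (0.5 / delta)).prune(prune)


def dipole_operator(provider: ElectronicStructureProvider, geometry: Geometry,
                    active_space: ActiveSpaceSpec) -> list[QubitOperator]:
    """Three dipole-component qubit operators (length gauge, a.u.).

    mu = sum_I Z_I R_I - sum_pq <p|r|q> a†_p a_q restricted to the active
    space; the nuclear and frozen-core parts enter as constants and cancel
    in transition moments.
    """
    d, const = provider.dipole_matrices(geometry, active_space)
    ops = []
    for k in range(3):
        mat = -spatial_one_body_to_spin(d[k])
        ops.append(jordan_wigner(one_body_operator(mat, const[k]), active_space.n_qubits))
    return ops


# ------------------------------------------------------------- providers

class FcidumpProvider(ElectronicStructureProvider):
    """Geometry-independent integrals from a single FCIDUMP payload."""

    def __init__(self, spatial: SpatialIntegrals):
        self._spatial = spatial

    @classmethod
    def from_file(cls, path) -> "FcidumpProvider":
        from .integrals import read_fcidump

        return cls(read_fcidump(path))

    def spatial_integrals(self, geometry, active_space):
        if active_space.n_active_orbitals != self._spatial.n_orbitals:
            raise ValueError("active space does not match the FCIDUMP orbital count")
        return self._spatial

    def cross_overlap(self, geom_bra, geom_ket, active_space):
        return np.eye(self._spatial.n_orbitals)


class HartreeFockProvider(ElectronicStructureProvider):
    """Active-space integrals on top of the built-in RHF backend.

    Orbital selection: the active spatial orbitals are ``orbital_indices``
    of the active-space spec when given, otherwise a window around the
    Fermi level.  When a reference geometry is set (`set_reference`),
    orbitals at other geometries are matched to the reference active
    orbitals by maximum overlap and sign-fixed, which keeps the active
    space and hence H(R) continuous under small displacements.
    """

    def __init__(self, basis: str = "6-31g", cache_size: int = 64):
        self.basis = basis
        self._cache: dict = {}
        self._cache_order: list = []
        self._ref = None  # (geometry, BasisSet, mo_coeff)
        self.cache_size = cache_size

    # -- SCF with caching -------------------------------------------------
    def _key(self, geometry: Geometry):
        return (geometry.symbols, np.round(geometry.coords, 10).tobytes())

    def scf(self, geometry: Geometry):
        from .scf import rhf

        key = self._key(geometry)
        if key not in self._cache:
            res = rhf(geometry, self.basis)
            if not res.converged:
                raise RuntimeError("SCF failed to converge")
            self._cache[key] = res
            self._cache_order.append(key)
            if len(self._cache_order) > self.cache_size:
                self._cache.pop(self._cache_order.pop(0))
        return self._cache[key]

    def set_reference(self, geometry: Geometry) -> None:
        from .scf import overlap

        res = self.scf(geometry)
        C = self._canonical_sign(res.mo_coeff)
        if self._ref is not None:
            ref_geom, ref_basis, ref_C = self._ref
            S_x = overlap(res.basis, ref_basis)
            C = self._align(C, S_x, ref_C)
        self._ref = (geometry, res.basis, C)

    @staticmethod
    def _canonical_sign(C: np.ndarray) -> np.ndarray:
        C = C.copy()
        for i in range(C.shape[1]):
            j = np.argmax(np.abs(C[:, i]))
            if C[j, i] < 0:
                C[:, i] = -C[:, i]
        return C

    @staticmethod
    def _align(C: np.ndarray, S_x: np.ndarray, C_ref: np.ndarray) -> np.ndarray:
        """Sign-fix columns of C so <C_i|S|C_ref_i> > 0 (order kept)."""
        C = C.copy()
        M = C.T @ S_x @ C_ref
        for i in range(C.shape[1]):
            if M[i, i] < 0:
                C[:, i] = -C[:, i]
        return C

    def _mo_set(self, geometry: Geometry):
        """Aligned MO matrix plus active/core spatial indices for a spec."""
        from .scf import overlap

        res = self.scf(geometry)
        C = self._canonical_sign(res.mo_coeff)
        if self._ref is not None:
            _, ref_basis, ref_C = self._ref
            S_x = overlap(res.basis, ref_basis)
            C = self._align(C, S_x, ref_C)
        return res, C

    def _select_active(self, res, C, active_space: ActiveSpaceSpec):
        n_core = (2 * res.n_occ - active_space.n_active_electrons) // 2
        if active_space.orbital_indices is not None:
            base_idx = list(active_space.orbital_indices)
        else:
            base_idx = list(range(n_core, n_core + active_space.n_active_orbitals))
        if self._ref is None:
            act = base_idx
        else:
            # track reference active orbitals by maximum overlap
            from .scf import overlap

            _, ref_basis, ref_C = self._ref
            S_x = overlap(res.basis, ref_basis)
            M = np.abs(C.T @ S_x @ ref_C[:, base_idx])  # (n_mo, n_act)
            act = []
            for a in range(len(base_idx)):
                order = np.argsort(-M[:, a])
                pick = next(i for i in order if i not in act)
                act.append(int(pick))
            act = sorted(act)
        core = [i for i in range(res.n_occ) if i not in act]
        n_occ_active = (active_space.n_active_electrons) // 2
        if len(core) != (res.n_occ - n_occ_active):
            raise RuntimeError("active-space selection inconsistent with electron count")
        return act, core

    def mo_coefficients(self, geometry: Geometry) -> np.ndarray:
        return self._mo_set(geometry)[1]

    def spatial_integrals(self, geometry: Geometry, active_space: ActiveSpaceSpec) -> SpatialIntegrals:
        res, C = self._mo_set(geometry)
        act, core = self._select_active(res, C, active_space)
        C_act, C_core = C[:, act], C[:, core]
        D_core = 2.0 * C_core @ C_core.T
        J = np.einsum("ijkl,kl->ij", res.eri, D_core)
        K = np.einsum("ikjl,kl->ij", res.eri, D_core)
        F = res.hcore + J - 0.5 * K
        h_act = C_act.T @ F @ C_act
        e_core = 0.5 * np.sum(D_core * (res.hcore + F)) + geometry.nuclear_repulsion()
        g = np.einsum("pqrs,pi->iqrs", res.eri, C_act)
        g = np.einsum("iqrs,qj->ijrs", g, C_act)
        g = np.einsum("ijrs,rk->ijks", g, C_act)
        g_act = np.einsum("ijks,sl->ijkl", g, C_act)
        return SpatialIntegrals(h_act, g_act, e_core,
                                n_electrons=active_space.n_active_electrons)

    def cross_overlap(self, geom_bra, geom_ket, active_space):
        from .scf import overlap

        res_b, C_b = self._mo_set(geom_bra)
        act_b, _ = self._select_active(res_b, C_b, active_space)
        res_k, C_k = self._mo_set(geom_ket)
        act_k, _ = self._select_active(res_k, C_k, active_space)
        S_x = overlap(res_b.basis, res_k.basis)
        return C_b[:, act_b].T @ S_x @ C_k[:, act_k]

    def dipole_matrices(self, geometry: Geometry, active_space: ActiveSpaceSpec):
        from .scf import dipole_integrals

        res, C = self._mo_set(geometry)
        act, core = self._select_active(res, C, active_space)
        D_ao = dipole_integrals(res.basis)
        C_act, C_core = C[:, act], C[:, core]
        d_act = np.einsum("kpq,pi,qj->kij", D_ao, C_act, C_act)
        D_core = 2.0 * C_core @ C_core.T
        z = geometry.atomic_numbers.astype(float)
        const = (z[:, None] * geometry.coords).sum(axis=0)
        const = const - np.einsum("kpq,qp->k", D_ao, D_core)
        return d_act, const


class VibronicExpansionProvider(ElectronicStructureProvider):
    """Active-space Hamiltonian expanded around a reference geometry.

    h(R), g(R) and the scalar term are linear in the Cartesian displacement
    x = R - R0 (flattened, bohr) and, optionally, polynomial (orders 2..5)
    in the mass-weighted normal-mode coordinates Q_m = L_m . M^(1/2) x:

        H(x) = H_eq + sum_i x_i dH_i + sum_k sum_m (Q_m^k / k!) d^kH_m .

    The diagonal mode polynomials are fitted to the ab initio integrals at
    +-1 and +-2 ground-state sigma of each mode, so the expansion is exact
    at the amplitudes that Wigner sampling visits; the odd orders carry the
    saturation of the out-of-plane sigma/pi coupling that a purely linear
    model exaggerates.  Orbitals are frozen at the reference, hence
    cross-geometry orbital overlaps are the identity.

    Without mode polynomials, the ground-state Hessian is added as a scalar
    harmonic term so all surfaces stay bound near the expansion point.

    This is a molecular model in the vibronic-coupling spirit, valid for
    moderate displacements; it deliberately trades global accuracy for an
    SCF-free, fully deterministic potential.
    """

    def __init__(self, reference: Geometry, active_space: ActiveSpaceSpec,
                 eq: SpatialIntegrals, dh: np.ndarray, dg: np.ndarray,
                 dcore: np.ndarray, hessian: np.ndarray | None = None,
                 dipole: tuple[np.ndarray, np.ndarray] | None = None,
                 mode_vectors: np.ndarray | None = None,
                 mode_response: dict[int, tuple] | None = None,
                 mode_sigma: np.ndarray | None = None):
        n = eq.n_orbitals
        self.reference = reference
        self.active_space = active_space
        self.eq = eq
        self.dh = dh.reshape(-1, n, n)  # (3N, n, n)
        self.dg = dg.reshape(-1, n, n, n, n)
        self.dcore = np.asarray(dcore, float).ravel()
        self.hessian = hessian
        self._dipole = dipole
        self.mode_vectors = mode_vectors  # (n_modes, 3N), mass-weighted
        # mode_response: order k -> (h (n_modes,n,n), g (n_modes,n,n,n,n),
        #                            core (n_modes,)) holding d^k H / dQ_m^k
        self.mode_response = {}
        if mode_response:
            for k, (hk, gk, ck) in sorted(mode_response.items()):
                self.mode_response[int(k)] = (
                    hk.reshape(-1, n, n), gk.reshape(-1, n, n, n, n),
                    np.asarray(ck, float).ravel(),
                )
        self.mode_sigma = (np.asarray(mode_sigma, float).ravel()
                           if mode_sigma is not None else None)
        # mode-coordinate saturation: identity inside +-cap*sigma, smooth
        # tanh beyond, so the fitted polynomials are never extrapolated
        self.saturation_cap = 2.2
        self.saturation_width = 0.4

    @property
    def _has_mode_poly(self) -> bool:
        return self.mode_vectors is not None and bool(self.mode_response)

    def _mode_jacobian(self) -> np.ndarray:
        """dQ_m/dx_i = L_{m,i} sqrt(M_i), shape (n_modes, 3N)."""
        sqm = np.sqrt(np.repeat(self.reference.masses, 3))
        return self.mode_vectors * sqm[None, :]

    def _q(self, x: np.ndarray) -> np.ndarray:
        return self._mode_jacobian() @ x

    def _q_saturated(self, x: np.ndarray):
        """Saturated mode coordinates and their derivative d q_eff / d Q.

        q_eff = Q inside |Q| <= cap*sigma and approaches cap*sigma +
        width*sigma*tanh(...) outside (C^1 continuous), which freezes the
        polynomial response beyond the fitted range instead of
        extrapolating it.
        """
        qv = self._q(x)
        if self.mode_sigma is None:
            return qv, np.ones_like(qv)
        cap = self.saturation_cap * self.mode_sigma
        width = self.saturation_width * self.mode_sigma
        out = qv.copy()
        dout = np.ones_like(qv)
        over = np.abs(qv) > cap
        if np.any(over):
            s = np.sign(qv[over])
            excess = (np.abs(qv[over]) - cap[over]) / width[over]
            out[over] = s * (cap[over] + width[over] * np.tanh(excess))
            safe = np.minimum(excess, 300.0)
            dout[over] = np.where(excess > 300.0, 0.0, 1.0 / np.cosh(safe) ** 2)
        return out, dout

    def _x(self, geometry: Geometry) -> np.ndarray:
        return (geometry.coords - self.reference.coords).ravel()

    # -- precomputed Jordan-Wigner parts: H(x) = JW_eq + sum_i x_i JW_i + ...
    def _jw_parts(self):
        if not hasattr(self, "_jw_cache"):
            from .integrals import second_quantized_hamiltonian as sq

            n_qubits = self.active_space.n_qubits

            def jw_of(h, g, core):
                return jordan_wigner(
                    sq(SpatialIntegrals(h, g, core).to_spin_orbital()), n_qubits)

            jw_eq = jw_of(self.eq.h, self.eq.g, self.eq.core_energy)
            jw_d = [jw_of(self.dh[i], self.dg[i], self.dcore[i])
                    for i in range(len(self.dcore))]
            jw_modes = {
                k: [jw_of(hk[m], gk[m], ck[m]) for m in range(len(ck))]
                for k, (hk, gk, ck) in self.mode_response.items()
            }
            self._jw_cache = (jw_eq, jw_d, jw_modes)
        return self._jw_cache

    def qubit_hamiltonian(self, geometry: Geometry, active_space: ActiveSpaceSpec,
                          prune: float = 1e-12) -> QubitOperator:
        jw_eq, jw_d, jw_modes = self._jw_parts()
        x = self._x(geometry)
        terms = dict(jw_eq.terms)

        def accumulate(coeff, op):
            if coeff == 0.0:
                return
            for w, c in op.terms.items():
                terms[w] = terms.get(w, 0.0) + coeff * c

        for xi, op in zip(x, jw_d):
            accumulate(xi, op)
        if self._has_mode_poly:
            qv, _ = self._q_saturated(x)
            for k, ops in jw_modes.items():
                for qm, op in zip(qv**k / _factorial(k), ops):
                    accumulate(qm, op)
        elif self.hessian is not None:
            terms[()] = terms.get((), 0.0) + 0.5 * float(x @ self.hessian @ x)
        return QubitOperator(terms, active_space.n_qubits).prune(prune)

    def derivative_operator(self, geometry: Geometry, active_space: ActiveSpaceSpec,
                            atom: int, axis: int) -> QubitOperator:
        """dH/dR_{I,xi}: precomputed linear part plus mode-polynomial chain rule."""
        _, jw_d, jw_modes = self._jw_parts()
        i = 3 * atom + axis
        op = jw_d[i].copy()
        if self._has_mode_poly:
            x = self._x(geometry)
            qvals, dq = self._q_saturated(x)
            jac = self._mode_jacobian()[:, i]
            terms = dict(op.terms)

            def accumulate(coeff, opm):
                if coeff == 0.0:
                    return
                for w, c in opm.terms.items():
                    terms[w] = terms.get(w, 0.0) + coeff * c

            for k, ops in jw_modes.items():
                for m, opm in enumerate(ops):
                    accumulate(
                        qvals[m] ** (k - 1) / _factorial(k - 1) * dq[m] * jac[m], opm)
            op = QubitOperator(terms, active_space.n_qubits)
        elif self.hessian is not None:
            x = self._x(geometry)
            op = op + QubitOperator.identity(active_space.n_qubits,
                                             float(self.hessian[i] @ x))
        return op

    def spatial_integrals(self, geometry, active_space):
        x = self._x(geometry)
        h = self.eq.h + np.einsum("i,ipq->pq", x, self.dh)
        g = self.eq.g + np.einsum("i,ipqrs->pqrs", x, self.dg)
        core = self.eq.core_energy + float(self.dcore @ x)
        if self._has_mode_poly:
            qv, _ = self._q_saturated(x)
            for k, (hk, gk, ck) in self.mode_response.items():
                qk = qv**k / _factorial(k)
                h = h + np.einsum("m,mpq->pq", qk, hk)
                g = g + np.einsum("m,mpqrs->pqrs", qk, gk)
                core += float(qk @ ck)
        elif self.hessian is not None:
            # without integral curvature, carry the ground-state harmonic
            # term as a scalar so all surfaces stay bound near the reference
            core += 0.5 * float(x @ self.hessian @ x)
        return SpatialIntegrals(h, g, core, n_electrons=active_space.n_active_electrons)

    def cross_overlap(self, geom_bra, geom_ket, active_space):
        return np.eye(self.eq.n_orbitals)

    def dipole_matrices(self, geometry, active_space):
        if self._dipole is None:
            raise NotImplementedError("model was built without dipole data")
        d, const = self._dipole
        return d, const

    # ---------------------------------------------------------- text I/O
    def save(self, path) -> None:
        from .integrals import pack_g8

        n = self.eq.n_orbitals
        fmt = "%.9e"  # response coefficients; well above their FD noise floor
        with open(path, "w") as fh:
            fh.write(f"# vibronic expansion model: {len(self.reference.symbols)} atoms, "
                     f"{n} active orbitals\n")
            fh.write(" ".join(self.reference.symbols) + "\n")
            np.savetxt(fh, self.reference.coords, header="coords_bohr", comments="# ")
            np.savetxt(fh, self.reference.masses[None, :], header="masses_au", comments="# ")
            fh.write(f"# active {self.active_space.n_active_electrons} "
                     f"{self.active_space.n_active_orbitals}\n")
            fh.write(f"# core {self.eq.core_energy:.16e}\n")
            np.savetxt(fh, self.eq.h.ravel()[None, :], header="h_eq", comments="# ")
            np.savetxt(fh, pack_g8(self.eq.g)[None, :], header="g_eq_packed", comments="# ")
            np.savetxt(fh, self.dcore[None, :], header="dcore", comments="# ", fmt=fmt)
            np.savetxt(fh, self.dh.reshape(len(self.dcore), -1), header="dh",
                       comments="# ", fmt=fmt)
            np.savetxt(fh, np.array([pack_g8(gi) for gi in self.dg]),
                       header="dg_packed", comments="# ", fmt=fmt)
            if self.hessian is not None:
                np.savetxt(fh, self.hessian, header="hessian", comments="# ")
            if self._dipole is not None:
                d, const = self._dipole
                np.savetxt(fh, d.reshape(3, -1), header="dipole_active", comments="# ")
                np.savetxt(fh, const[None, :], header="dipole_const", comments="# ")
            if self._has_mode_poly:
                np.savetxt(fh, self.mode_vectors, header="mode_vectors", comments="# ")
                if self.mode_sigma is not None:
                    np.savetxt(fh, self.mode_sigma[None, :], header="mode_sigma",
                               comments="# ")
                for k, (hk, gk, ck) in self.mode_response.items():
                    nm = len(ck)
                    np.savetxt(fh, ck[None, :], header=f"mode{k}_core", comments="# ",
                               fmt=fmt)
                    np.savetxt(fh, hk.reshape(nm, -1), header=f"mode{k}_h",
                               comments="# ", fmt=fmt)
                    np.savetxt(fh, np.array([pack_g8(gm) for gm in gk]),
                               header=f"mode{k}_g_packed", comments="# ", fmt=fmt)

    @classmethod
    def load(cls, path) -> "VibronicExpansionProvider":
        from .integrals import unpack_g8

        with open(path) as fh:
            lines = fh.read().splitlines()
        symbols = tuple(lines[1].split())
        natom = len(symbols)
        blocks: dict[str, list[str]] = {}
        name = None
        for line in lines[2:]:
            if line.startswith("# "):
                name = line[2:].split()[0]
                blocks[name] = []
                if name == "active":
                    blocks[name] = line[2:].split()[1:]
                elif name == "core":
                    blocks[name] = [line[2:].split()[1]]
            elif name is not None:
                blocks[name].append(line)

        def arr(key):
            return np.loadtxt([" ".join(blocks[key])]) if len(blocks[key]) == 1 else \
                np.loadtxt(blocks[key])

        coords = arr("coords_bohr").reshape(natom, 3)
        masses = arr("masses_au").ravel()
        geometry = Geometry(symbols, coords, masses)
        ne, no = (int(v) for v in blocks["active"])
        aspace = ActiveSpaceSpec(ne, no)
        n = no
        eq = SpatialIntegrals(arr("h_eq").reshape(n, n),
                              unpack_g8(arr("g_eq_packed").ravel(), n),
                              float(blocks["core"][0]), n_electrons=ne)
        dcore = arr("dcore").ravel()
        dh = arr("dh").reshape(3 * natom, n, n)
        dg = np.array([unpack_g8(row, n) for row in
                       np.atleast_2d(arr("dg_packed"))])
        hessian = arr("hessian") if "hessian" in blocks else None
        dipole = None
        if "dipole_active" in blocks:
            dipole = (arr("dipole_active").reshape(3, n, n), arr("dipole_const").ravel())
        modes = None
        sigma = None
        response = {}
        if "mode_vectors" in blocks:
            modes = arr("mode_vectors").reshape(-1, 3 * natom)
            if "mode_sigma" in blocks:
                sigma = arr("mode_sigma").ravel()
            for key in blocks:
                if key.startswith("mode") and key.endswith("_core"):
                    k = int(key[4:-5])
                    ck = arr(f"mode{k}_core").ravel()
                    hk = arr(f"mode{k}_h").reshape(len(ck), n, n)
                    gk = np.array([unpack_g8(row, n) for row in
                                   np.atleast_2d(arr(f"mode{k}_g_packed"))])
                    response[k] = (hk, gk, ck)
        return cls(geometry, aspace, eq, dh, dg, dcore, hessian, dipole,
                   mode_vectors=modes, mode_response=response or None,
                   mode_sigma=sigma)


def _factorial(k: int) -> float:
    out = 1.0
    for i in range(2, k + 1):
        out *= i
    return out
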