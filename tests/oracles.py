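"""Independent brute-force oracles used by the test suite.

Everything here is deliberately written by a different route than the
package code it checks: fermionic operators as explicitly constructed
occupation-basis matrices (no Pauli algebra), wavefunction overlaps as
permutation sums over antisymmetrized products, electronic propagation as
direct integration of the adiabatic TDSE with analytic couplings, and a
plain NAC-based fewest-switches reference implementation.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.integrate import solve_ivp


# ------------------------- fermionic matrices in the occupation basis

def annihilation_matrix(mode: int, n_modes: int) -> np.ndarray:
    """a_mode as a dense matrix; bit q of the basis index is mode-q occupation."""
    dim = 2**n_modes
    mat = np.zeros((dim, dim))
    for b in range(dim):
        if (b >> mode) & 1:
            parity = bin(b & ((1 << mode) - 1)).count("1")
            mat[b ^ (1 << mode), b] = (-1.0) ** parity
    return mat


def creation_matrix(mode: int, n_modes: int) -> np.ndarray:
    return annihilation_matrix(mode, n_modes).T


def fermion_term_matrix(term, n_modes: int) -> np.ndarray:
    """Matrix of a product of elementary operators, applied right to left."""
    dim = 2**n_modes
    mat = np.eye(dim)
    for mode, dagger in term:
        op = creation_matrix(mode, n_modes) if dagger else annihilation_matrix(mode, n_modes)
        mat = mat @ op
    return mat


def fermion_operator_matrix(fop, n_modes: int) -> np.ndarray:
    dim = 2**n_modes
    mat = np.zeros((dim, dim), dtype=complex)
    for term, coeff in fop.terms.items():
        mat += coeff * fermion_term_matrix(term, n_modes)
    return mat


def hamiltonian_matrix_from_integrals(h, g, core, n_modes: int) -> np.ndarray:
    """Dense H = sum h a†a + 1/2 sum g a†a†aa + core by explicit algebra."""
    dim = 2**n_modes
    mat = core * np.eye(dim, dtype=complex)
    a = [annihilation_matrix(m, n_modes) for m in range(n_modes)]
    ad = [x.T for x in a]
    for r in range(n_modes):
        for s in range(n_modes):
            if abs(h[r, s]) > 0:
                mat += h[r, s] * ad[r] @ a[s]
    for p in range(n_modes):
        for q in range(n_modes):
            for r in range(n_modes):
                for s in range(n_modes):
                    if abs(g[p, q, r, s]) > 0:
                        mat += 0.5 * g[p, q, r, s] * ad[p] @ ad[q] @ a[s] @ a[r]
    return mat


# ------------------------------------ determinant overlap by permutations

def slater_overlap_bruteforce(occ_bra, occ_ket, S: np.ndarray) -> float:
    """<det(occ_bra)|det(occ_ket)> as an explicit sum over permutations."""
    n = len(occ_bra)
    if n != len(occ_ket):
        return 0.0
    if n == 0:
        return 1.0
    total = 0.0
    for perm in itertools.permutations(range(n)):
        sign = _perm_sign(perm)
        prod = 1.0
        for i, j in enumerate(perm):
            prod *= S[occ_bra[i], occ_ket[j]]
        total += sign * prod
    return total


def _perm_sign(perm) -> int:
    sign = 1
    seen = [False] * len(perm)
    for i in range(len(perm)):
        if seen[i]:
            continue
        j, length = i, 0
        while not seen[j]:
            seen[j] = True
            j = perm[j]
            length += 1
        if length % 2 == 0:
            sign = -sign
    return sign


# --------------------------------------- adiabatic TDSE with analytic NACs

def tdse_adiabatic_populations(model, r_of_t, v_of_t, a0, t_final_au, n_eval=200,
                               rtol=1e-10, atol=1e-12):
    """Integrate i da_m/dt = E_m a_m - i sum_l v g_ml a_l along a given path.

    ``model`` is an avoided-crossing model with analytic energies and NAC;
    ``r_of_t`` / ``v_of_t`` give the prescribed nuclear motion.  Returns
    (times, populations (n_eval, 2)).
    """

    def rhs(t, y):
        a = y[:2] + 1j * y[2:]
        r, v = r_of_t(t), v_of_t(t)
        e = model.adiabatic_energies(r)
        d01 = model.nac(r)
        sigma = np.array([[0.0, v * d01], [-v * d01, 0.0]])
        dadt = -1j * e * a - sigma @ a
        return np.concatenate([dadt.real, dadt.imag])

    y0 = np.concatenate([np.real(a0), np.imag(a0)])
    ts = np.linspace(0.0, t_final_au, n_eval)
    sol = solve_ivp(rhs, (0.0, t_final_au), y0, t_eval=ts, rtol=rtol, atol=atol,
                    method="DOP853")
    a = sol.y[:2] + 1j * sol.y[2:]
    return ts, (np.abs(a) ** 2).T


# ---------------------------------------- reference NAC-based FSSH driver

def fssh_reference_trajectory(model, mass, r0, v0, state0, dt_au, n_steps, rng,
                              decoherence_c=None):
    """Plain fewest-switches SH with analytic NACs (Tully's original recipe).

    Velocity-Verlet nuclei on the active adiabatic surface; coefficients
    integrated with RK4 of the adiabatic TDSE; hop probability
    g_ml = 2 dt Re(a_l a_m* v d_lm) / |a_m|^2; rescaling along the (1-D)
    velocity.  Returns (final_state, final_r, hops).
    """
    r, v, state = float(r0), float(v0), int(state0)
    a = np.zeros(2, complex)
    a[state] = 1.0
    eps = 1e-6

    def grad(rr, st):
        ep = model.adiabatic_energies(rr + eps)[st]
        em = model.adiabatic_energies(rr - eps)[st]
        return (ep - em) / (2 * eps)

    def deriv(rr, vv, aa):
        e = model.adiabatic_energies(rr)
        d01 = model.nac(rr)
        sigma = np.array([[0.0, vv * d01], [-vv * d01, 0.0]])
        return -1j * e * aa - sigma @ aa

    hops = []
    f = -grad(r, state)
    for _ in range(n_steps):
        # nuclear step
        r_new = r + v * dt_au + 0.5 * f / mass * dt_au**2
        f_new = -grad(r_new, state)
        v_new = v + 0.5 * (f + f_new) / mass * dt_au
        # electronic RK4 along interpolated path
        n_sub = 25
        h = dt_au / n_sub
        rr, vv = r, v
        for j in range(n_sub):
            frac0 = j / n_sub
            frac1 = (j + 1) / n_sub
            fracm = (j + 0.5) / n_sub
            r0s, rms, r1s = (r + fr * (r_new - r) for fr in (frac0, fracm, frac1))
            v0s, vms, v1s = (v + fr * (v_new - v) for fr in (frac0, fracm, frac1))
            k1 = deriv(r0s, v0s, a)
            k2 = deriv(rms, vms, a + 0.5 * h * k1)
            k3 = deriv(rms, vms, a + 0.5 * h * k2)
            k4 = deriv(r1s, v1s, a + h * k3)
            a = a + h / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
            # fewest-switches hop test per substep: the population flow
            # k -> l is 2 v d_kl Re(a_k* a_l) with d_kl = <k|d/dR|l>
            other = 1 - state
            d01 = model.nac(r + fracm * (r_new - r))
            d_kl = d01 if (state, other) == (0, 1) else -d01
            vmid = v + fracm * (v_new - v)
            flux = 2.0 * h * vmid * d_kl * (np.conj(a[state]) * a[other]).real
            pop = abs(a[state]) ** 2
            p_hop = max(0.0, flux / pop) if pop > 1e-12 else 0.0
            if rng.random() < p_hop:
                e = model.adiabatic_energies(r + fracm * (r_new - r))
                ekin = 0.5 * mass * vmid**2
                new_ekin = ekin + e[state] - e[other]
                if new_ekin > 0:
                    scale = np.sqrt(new_ekin / ekin)
                    v_new = v_new * scale
                    vv = vv * scale
                    state = other
                    hops.append(state)
                    f_new = -grad(r_new, state)
        if decoherence_c is not None:
            e = model.adiabatic_energies(r_new)
            ekin = 0.5 * mass * v_new**2
            other = 1 - state
            gap = abs(e[other] - e[state])
            if ekin > 1e-12 and gap > 1e-12:
                tau = (1.0 + decoherence_c / ekin) / gap
                a[other] *= np.exp(-dt_au / tau)
                if abs(a[state]) > 1e-14:
                    a[state] *= np.sqrt(max(1 - abs(a[other]) ** 2, 0.0)) / abs(a[state])
        r, v, f = r_new, v_new, f_new
    return state, r, hops
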