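"""Regenerate the packaged molecular fixture data.

Produces, using only the built-in RHF backend (no external programs):

* optimized ground-state geometries of ethylene and methanimine on the
  CASCI(4e,3o)/6-31G surface (XYZ),
* the corresponding active-space FCIDUMP files,
* the methanimine vibronic-expansion model (equilibrium integrals,
  Cartesian first-order integral response, ground-state Hessian, dipole
  matrices) used for backend-free dynamics and spectra,
* an H2/STO-3G bond-stretch FCIDUMP grid with FCI oracle energies.

Takes on the order of an hour on one CPU; run from the repository root:

    python scripts/make_fixtures.py [--quick]
"""

import argparse
import sys
import time
from pathlib import Path

import numpy as np
import scipy.optimize

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

import qnamd as q
from qnamd.constants import BOHR_PER_ANGSTROM as B
from qnamd.constants import EV_PER_HARTREE

DATA = Path(__file__).resolve().parents[1] / "src" / "qnamd" / "data"

ASPACE = q.ActiveSpaceSpec(4, 3)

# Symmetry-adapted internal-coordinate parametrizations (planar minima;
# the out-of-symmetry gradient vanishes identically, so optimizing inside
# the symmetric subspace locates the full minimum).

def ethylene_geometry(params):
    """D2h: params = (r_cc, r_ch, theta_hcc_deg); molecule in the xy plane."""
    r_cc, r_ch, theta = params
    th = np.radians(theta)
    cx = 0.5 * r_cc
    hx = cx + r_ch * abs(np.cos(th))
    hy = r_ch * np.sin(th)
    coords = np.array([
        [cx, 0.0, 0.0], [-cx, 0.0, 0.0],
        [hx, hy, 0.0], [hx, -hy, 0.0],
        [-hx, hy, 0.0], [-hx, -hy, 0.0],
    ])
    return q.Geometry(("C", "C", "H", "H", "H", "H"), coords * B)


def methanimine_geometry(params):
    """Cs planar: params = (r_cn, r_nh, r_ch_s, r_ch_a, a_hnc, a_hcn_s, a_hcn_a).

    The two CH bonds are inequivalent (syn/anti to the N-H hydrogen).
    """
    r_cn, r_nh, r_ch_s, r_ch_a, a_hnc, a_hcn_s, a_hcn_a = params
    coords = np.zeros((5, 3))
    coords[1] = [r_cn, 0.0, 0.0]
    # H on N, on the +y side
    th = np.radians(a_hnc)
    coords[4] = [r_cn - r_nh * np.cos(th), r_nh * np.sin(th), 0.0]
    # H's on C: syn (same side as N-H hydrogen, +y) and anti (-y)
    ths = np.radians(a_hcn_s)
    tha = np.radians(a_hcn_a)
    coords[2] = [r_ch_s * np.cos(ths), r_ch_s * np.sin(ths), 0.0]
    coords[3] = [r_ch_a * np.cos(tha), -r_ch_a * np.sin(tha), 0.0]
    return q.Geometry(("C", "N", "H", "H", "H"), coords * B)


PARAMETRIZATIONS = {
    "ethylene": (ethylene_geometry, np.array([1.33, 1.076, 121.5])),
    "methanimine": (methanimine_geometry,
                    np.array([1.27, 1.00, 1.08, 1.08, 110.5, 125.0, 119.0])),
}


def casci_energy_fn(provider, n_states=1):
    def energy(geom):
        H = q.build_qubit_hamiltonian(provider, geom, ASPACE)
        vals = q.exact_spectrum(H, n_states, n_electrons=4, sz=0.0, s2_target=0.0)
        return vals if n_states > 1 else float(vals[0])
    return energy


def optimize_geometry(name, gtol=1e-5):
    to_geometry, x0 = PARAMETRIZATIONS[name]
    provider = q.HartreeFockProvider("6-31g", cache_size=8)
    energy = casci_energy_fn(provider)
    n_eval = [0]

    def fun(x):
        n_eval[0] += 1
        return energy(to_geometry(x))

    t0 = time.time()
    res = scipy.optimize.minimize(
        fun, x0, method="BFGS", jac="3-point",
        options={"gtol": gtol, "maxiter": 60},
    )
    geom = to_geometry(res.x)
    print(f"[{name}] E_min = {res.fun:.8f} Eh, params = {np.round(res.x, 5)}, "
          f"|g| = {np.linalg.norm(res.jac):.2e}, {n_eval[0]} evals, "
          f"{time.time()-t0:.0f}s", flush=True)
    return geom, float(res.fun)


def dump_active_space(name, geom):
    provider = q.HartreeFockProvider("6-31g")
    provider.set_reference(geom)
    spatial = provider.spatial_integrals(geom, ASPACE)
    q.write_xyz(DATA / f"{name}_eq.xyz", geom, comment=f"{name} CASCI(4,3)/6-31G minimum")
    q.write_fcidump(DATA / f"{name}_4e3o.fcidump", spatial)
    H = q.build_qubit_hamiltonian(provider, geom, ASPACE)
    nb = q.count_native_pauli_bases(H)
    cl = len(q.group_commuting_cliques(H))
    vals = q.exact_spectrum(H, 3, n_electrons=4, sz=0.0, s2_target=0.0)
    print(f"[{name}] pauli strings {nb}, cliques {cl}, "
          f"vertical excitations {[f'{v:.3f}' for v in (vals[1:]-vals[0])*EV_PER_HARTREE]} eV",
          flush=True)
    return provider, spatial


def methanimine_model(geom, quick=False, hessian=None):
    provider = q.HartreeFockProvider("6-31g", cache_size=4)
    provider.set_reference(geom)
    energy = casci_energy_fn(provider)

    if hessian is None:
        t0 = time.time()
        hessian = q.numerical_hessian(energy, geom, displacement=0.01)
        print(f"[methanimine] hessian in {time.time()-t0:.0f}s", flush=True)
    modes = q.normal_modes(hessian, geom)
    print(f"[methanimine] frequencies (cm-1): {np.round(modes.frequencies_cm, 1)}, "
          f"imaginary: {modes.n_imaginary}", flush=True)

    eq = provider.spatial_integrals(geom, ASPACE)
    n = eq.n_orbitals
    ncart = 3 * geom.n_atoms
    dh = np.zeros((ncart, n, n))
    dg = np.zeros((ncart, n, n, n, n))
    dcore = np.zeros(ncart)
    delta = 0.005
    t0 = time.time()
    for i in range(ncart):
        atom, axis = divmod(i, 3)
        sp_p = provider.spatial_integrals(geom.displaced(atom, axis, +delta), ASPACE)
        sp_m = provider.spatial_integrals(geom.displaced(atom, axis, -delta), ASPACE)
        dh[i] = (sp_p.h - sp_m.h) / (2 * delta)
        dg[i] = (sp_p.g - sp_m.g) / (2 * delta)
        dcore[i] = (sp_p.core_energy - sp_m.core_energy) / (2 * delta)
    print(f"[methanimine] integral response in {time.time()-t0:.0f}s", flush=True)

    # diagonal polynomial integral response (orders 2-5) along the normal
    # modes, fitted at +-1 and +-2 ground-state sigma of each mode so the
    # expansion is exact at the amplitudes Wigner sampling visits.  The odd
    # orders carry the saturation of the out-of-plane sigma/pi coupling; the
    # even quartic tames the large-amplitude X-H stretch response.
    sqm_inv = 1.0 / np.sqrt(np.repeat(geom.masses, 3))
    n_modes = modes.n_modes
    response = {k: (np.zeros((n_modes, n, n)), np.zeros((n_modes, n, n, n, n)),
                    np.zeros(n_modes)) for k in (2, 3, 4, 5)}
    t0 = time.time()
    for m in range(n_modes):
        sig = float(np.sqrt(0.5 / modes.frequencies_au[m]))  # 1 sigma, mass-weighted
        vals = {}
        for s in (-2, -1, 1, 2):
            step = (modes.modes[m] * sqm_inv).reshape(-1, 3) * (s * sig)
            sp = provider.spatial_integrals(geom.with_coords(geom.coords + step), ASPACE)
            lin_h = np.einsum("i,ipq->pq", step.ravel(), dh)
            lin_g = np.einsum("i,ipqrs->pqrs", step.ravel(), dg)
            lin_c = float(dcore @ step.ravel())
            vals[s] = (sp.h - eq.h - lin_h, sp.g - eq.g - lin_g,
                       sp.core_energy - eq.core_energy - lin_c)
        for part in range(3):
            even1 = (vals[1][part] + vals[-1][part]) / 2.0
            even2 = (vals[2][part] + vals[-2][part]) / 2.0
            odd1 = (vals[1][part] - vals[-1][part]) / 2.0
            odd2 = (vals[2][part] - vals[-2][part]) / 2.0
            # solve  a2 s^2/2 + a4 s^4/24 = even  at s = sig, 2 sig
            a2 = (16.0 * even1 - even2) / (6.0 * sig**2)
            a4 = (even2 - 4.0 * even1) * 2.0 / sig**4
            # solve  a3 s^3/6 + a5 s^5/120 = odd  at s = sig, 2 sig
            a3 = (32.0 * odd1 - odd2) / (4.0 * sig**3)
            a5 = (odd2 - 8.0 * odd1) * 5.0 / sig**5
            for k, a in ((2, a2), (3, a3), (4, a4), (5, a5)):
                response[k][part][m] = a
    print(f"[methanimine] mode response (orders 2-5) in {time.time()-t0:.0f}s",
          flush=True)

    dip = provider.dipole_matrices(geom, ASPACE)
    model = q.VibronicExpansionProvider(geom, ASPACE, eq, dh, dg, dcore, hessian, dip,
                                        mode_vectors=modes.modes,
                                        mode_response=response,
                                        mode_sigma=np.sqrt(0.5 / modes.frequencies_au))
    model.save(DATA / "methanimine_vibronic.txt")

    # consistency: model reproduces ab initio excitations at a displaced point
    rng = np.random.default_rng(1)
    test_geom = geom.with_coords(geom.coords + rng.normal(0, 0.02, geom.coords.shape))
    e_model = casci_energy_fn(model, 3)(test_geom)
    e_ref = casci_energy_fn(provider, 3)(test_geom)
    print(f"[methanimine] model vs ab initio at displaced point (eV): "
          f"{(np.asarray(e_model)-np.asarray(e_ref))*EV_PER_HARTREE}", flush=True)


def h2_grid():
    grid_dir = DATA / "h2_grid"
    grid_dir.mkdir(exist_ok=True)
    fg = q.h2_stretch_grid(n_points=11)
    lines = ["index\tr_bohr\te0_hartree\te1_hartree\te2_hartree"]
    for i, (r, spatial, oracle) in enumerate(zip(fg.coordinates, fg.integrals, fg.oracle_energies)):
        q.write_fcidump(grid_dir / f"point_{i:02d}.fcidump", spatial)
        lines.append(f"{i}\t{r:.6f}\t" + "\t".join(f"{e:.12f}" for e in oracle))
    (grid_dir / "manifest.tsv").write_text("\n".join(lines) + "\n")
    print(f"[h2] grid of {len(fg.coordinates)} points written", flush=True)


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--quick", action="store_true", help="skip geometry optimization")
    ap.add_argument("--only",
                    choices=["ethylene", "methanimine", "methanimine-model", "h2"],
                    default=None)
    args = ap.parse_args()
    DATA.mkdir(exist_ok=True)

    if args.only in (None, "h2"):
        h2_grid()
    if args.only in (None, "ethylene"):
        geom, _ = optimize_geometry("ethylene")
        dump_active_space("ethylene", geom)
    if args.only in (None, "methanimine"):
        geom, _ = optimize_geometry("methanimine")
        _ = dump_active_space("methanimine", geom)
        methanimine_model(geom, quick=args.quick)
    if args.only == "methanimine-model":
        # refresh the vibronic model reusing the packaged geometry and the
        # Hessian stored in the existing model file
        geom = q.read_xyz(DATA / "methanimine_eq.xyz")
        hessian = _read_block(DATA / "methanimine_vibronic.txt", "hessian")
        methanimine_model(geom, quick=args.quick, hessian=hessian)


def _read_block(path, key):
    rows, active = [], False
    for line in Path(path).read_text().splitlines():
        if line.startswith("# "):
            active = line[2:].split()[0] == key
        elif active and line.strip():
            rows.append([float(x) for x in line.split()])
    return np.array(rows)


if __name__ == "__main__":
    main()
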