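# Methods

`qnamd` simulates photochemical relaxation by combining a variational
quantum electronic-structure solver with classical trajectory surface
hopping. This note records the model, the numerical choices, and what the
validation does and does not demonstrate.

## Electronic structure on qubits

The electronic problem is restricted to a small active space. A
closed-shell restricted Hartree–Fock calculation (built into the package:
McMurchie–Davidson integrals over s/p Cartesian Gaussians, STO-3G and
6-31G for H/C/N/O, DIIS convergence to 1e-10 Eh) supplies molecular
orbitals; the active-space one- and two-electron integrals define the
second-quantized Hamiltonian

    H(R) = E_core(R) + sum_rs h_rs(R) a†_r a_s
         + 1/2 sum_pqrs <pq|rs>(R) a†_p a†_q a_s a_r ,

with the nuclear repulsion and the frozen-core mean field absorbed into
`E_core`. Spin-orbitals are interleaved (alpha on even, beta on odd
indices), which keeps the paired-double excitation generators local after
the Jordan–Wigner transformation. Qubit-Hamiltonian coefficients below
1e-12 are pruned so that term counts are stable across geometries.

Active orbitals are selected by a window around the Fermi level (or
explicit indices) at a reference geometry and tracked to displaced
geometries by maximum overlap, with a sign fix against the reference. This
suppresses the discontinuities that orbital reordering would otherwise
inject into H(R) — the dominant failure mode of small active spaces along
trajectories.

**Measurement-cost counters.** Three counters quantify the measurement
cost of `<H>` on hardware: (i) `count_native_pauli_bases` — one native
basis per Pauli string (the identity term counts as a string), which is
the figure of merit before any grouping; (ii) `count_qubitwise_bases` —
greedy merging of words that agree qubit-wise (identity slots act as
wildcards), order-pinned for determinism; (iii) `group_commuting_cliques`
— greedy largest-first colouring of the full anticommutation graph with
lexicographic tie-breaks. For the ethylene (4e,3o)/6-31G Hamiltonian these
give 34, 9 and 3 respectively. The counters are intentionally separate
because the literature uses "number of bases" in more than one sense.

## Variational solver

The ansatz is k-UpCCGSD: per layer, all spin-adapted generalized singles
over spatial-orbital pairs p<q and all paired doubles moving an
alpha-beta pair p→q. Every generator conserves particle number, S_z and
(from a closed-shell reference) total spin, so no spin-penalty terms are
needed. Each generator's Pauli terms commute, hence its exponential
factorizes exactly into one rotation per term; the term order within a
generator is fixed lexicographically (a different order would define a
slightly different, equally valid ansatz — the order is pinned, not
optimized).

VQE minimizes `<H>` with BFGS (gradient norm 1e-6, 500-iteration cap)
using analytic parameter gradients from an adjoint reverse sweep over the
rotation product. Excited state n minimizes the deflated cost
`<H> + sum_j lambda_j |<Psi|Psi_j>|^2`; the default penalty weight is
|E_gs|, sufficient while the target state is bound. The overlap penalty is
evaluated directly between statevectors, which is mathematically identical
to the all-zero-projector form used on hardware.

Two optimization details matter in practice:

* **Warm starts.** Along a trajectory each state's converged angles seed
  the next step's optimization. This both reduces iteration counts and —
  more importantly — keeps the deflation tracking the same physical
  states through near-degeneracies.
* **Cold-start symmetry breaking.** With theta = 0 the reference
  determinant is a stationary trap of the deflated cost whenever the
  ground state is reference-dominated; cold-started excited states
  therefore begin from a small deterministic Gaussian perturbation
  (scale 0.1 rad, fixed seed). Without it VQD reliably collapses onto the
  ground state.

A one-layer ansatz on a (4e,3o) space has 6 angles and spans the ground
state's neighbourhood; full singlet-sector coverage (needed when three
states are tracked) requires k = 2. The per-state depth policy is
configurable (`uniform` k, or `grow` with one extra layer per state);
validation uses uniform k = 2 wherever exactness against the dense oracle
is asserted.

The dense oracle (`exact_spectrum`) diagonalizes the qubit Hamiltonian
restricted to the particle-number/S_z sector, optionally filtered by
`<S^2>`; it is capped at 12 qubits and used only for validation.

## Properties

Gradients are Hellmann–Feynman only: `grad E_m = <Psi_m| dH/dR |Psi_m>`,
with `dH/dR` built by central differences of the full qubit Hamiltonian
(shift 0.001 Å). Pulay (basis-set) forces are neglected; the test suite
checks the approximation against central differences of the energy itself
on the H2 fixture, where the two agree to 5e-5 hartree/bohr. Approximate
coupling vectors `d_ml = <Psi_m|dH/dR|Psi_l> / (E_l - E_m)` use the
signed gap (antisymmetric convention); pairs with |gap| < 1e-6 hartree
are flagged near-degenerate and magnitude-capped. The dynamics never
consumes these vectors — electronic propagation uses overlaps — so the
flagging is diagnostic. Oscillator strengths use the length gauge,
`f = (2/3) |dE| |mu|^2` in atomic units.

## Cross-step overlaps and local diabatization

Statevectors are converted to CI-type expansions by reading amplitudes off
the computational basis (threshold 1e-6; retained norm reported, warning
below 0.999). Determinants are stored spin-blocked with the reordering
sign folded into the coefficient, so the overlap of two determinants under
a cross-geometry MO overlap factorizes into alpha and beta block
determinants; block determinants are cached across the state matrix. The
MO cross-overlap comes from the provider (AO overlap between the two
geometries transformed by both MO sets; identity for frozen-orbital
models).

The electronic coefficients are propagated locally diabatically: from the
cross-step overlap matrix S, the transform T = S (SᵀS)^(-1/2) (Löwdin, via
SVD; smallest singular value below 1e-6 raises a trivial-crossing error
rather than silently regularizing), sign-fixed so diag(T) ≥ 0, with the
same sign flips applied to the stored states so phases stay consistent
across steps. The diabatic Hamiltonian is interpolated linearly from
diag(E(t)) to T diag(E(t+dt)) Tᵀ and integrated with the exponential
midpoint rule over the electronic substeps (0.02 fs by default under a
0.5 fs nuclear step); finally a(t+dt) = Tᵀ d(t+dt). The propagation is
unitary to 1e-8 by construction and reproduces a NAC-based adiabatic TDSE
reference to 1e-4 through an avoided crossing, with observed convergence
order ≥ 2 in the step size. At genuinely trivial crossings the scheme
transfers the population diabatically and the fewest-switches rule fires
with near-unit probability — the behaviour that NAC-based integrators
miss.

## Surface hopping

Hop probabilities use the propagator-flux (local-diabatization) form of
the fewest-switches rule: the active state's fractional population loss
over the step is apportioned to targets by the real part of their
propagator flux contribution, clamped at zero, with the total bounded by
one. This reduces to Tully's prescription in the fine-step limit; the
ensemble statistics are validated against an independent plain NAC-based
fewest-switches implementation on the analytic model (agreement within
combined binomial error at 150 trajectories).

On a successful hop, velocities are rescaled along the momentum direction
so total energy is conserved exactly; energetically forbidden attempts are
frustrated hops that change nothing (no velocity reversal). The
energy-based decoherence correction damps inactive amplitudes with
`tau = (1/|dE|)(1 + C/E_kin)`, C = 0.1 a.u.; the correction switches off
smoothly as the kinetic energy vanishes. Decoherence is applied after the
hop decision, with respect to the post-hop active state.

Trajectories stop at the configured maximum time, after a configured dwell
on the ground state (the analysis then holds them on their final state),
or when the total-energy drift exceeds 0.2 eV, in which case they are
flagged discarded — the protocol for the orbital-rotation failures of
small active spaces. Randomness is counter-based: base seed plus
trajectory index, so ensembles are reproducible and restartable.

## Initial conditions and spectra

The Hessian of the ground-state energy is fully numerical (double-sided
central differences, 0.01 bohr — large enough to sit above the 1e-10 Eh
SCF noise floor, small enough for O(h^2) accuracy), symmetrized, mass
weighted, and diagonalized after projecting out rigid translations and
rotations. Wigner sampling of the harmonic ground state draws Q and P per
mode from independent Gaussians with sigma_Q^2 = 1/(2 omega) and
sigma_P^2 = omega/2 (mass-weighted a.u.); no rotational sampling is
imposed. Spectra are sums of Gaussians of area f at the vertical
excitation energies over the ensemble (default FWHM 0.1 eV), and initial
states are selected by acceptance-rejection with probability f/p_norm
inside an excitation-energy window, p_norm defaulting to 1.01 times the
largest f encountered.

## Molecular models and fixtures

* **Analytic avoided crossing** — linear diabats ±slope·R coupled by a
  Gaussian V12 (gap = 2 V12(0) at the crossing); closed-form energies,
  mixing angle and coupling. Exposed both as a direct 2×2 driver and as a
  2-electron-in-2-orbital integral set whose closed-shell determinant
  block carries exactly the model matrix, with a Coulomb offset
  (pp|qq) = 0.5 Eh pushing the open-shell singlet and triplet out of the
  low-energy window. The same physics thus validates both the dynamics
  code path and the full variational-quantum stack.
* **H2/STO-3G stretch grid** — 11 FCIDUMP files with FCI singlet energies
  in a manifest, regenerated by `scripts/make_fixtures.py`.
* **Methanimine vibronic-expansion model** — active-space (4e,3o)/6-31G
  integrals at the CASCI-optimized planar minimum, expanded to first
  order in Cartesian displacements plus diagonal polynomials of order
  2–5 in the mass-weighted normal-mode coordinates, fitted so the model
  integrals are *exact* at ±1σ and ±2σ of every mode's ground-state
  amplitude. The odd orders are essential: the out-of-plane N–H wag
  couples the n and π* orbitals with a response that saturates away from
  planarity, and a linear (or even quadratic) expansion exaggerates that
  coupling enough to red-shift the nπ* band by ~0.4 eV. Beyond 2.2σ the
  mode coordinates are smoothly saturated (C¹ tanh clamp of width 0.4σ)
  so the fitted polynomials are never extrapolated; trajectories that
  ride the saturation knee should use a 0.25 fs nuclear step for clean
  energy conservation. Frozen-orbital dipole matrices give Condon-level
  oscillator strengths, and cross-geometry orbital overlaps are the
  identity. Against the RHF backend on Wigner-sampled geometries the
  model reproduces the S1 excitation with ~0.2 eV r.m.s. error and the
  ensemble mean to 0.01 eV.
  It does **not** describe bond breaking, the conical-intersection seam
  at strongly twisted geometries, orbital rotation, mode–mode coupling of
  the integral response, or rotational invariance beyond first order —
  so isomerization branching ratios and long-time lifetimes are outside
  its validity, and tests that pass on it certify the machinery
  (orthogonality, conservation, band positions), not the global
  photochemistry of the real molecule.

## Validation problem sizes

The shipped validation uses 500 Wigner geometries for the methanimine
band maximum, 150-trajectory ensembles for the hop-statistics comparison,
25 fs VQE/VQD trajectories for the orthogonality and conservation
checks, and noiseless plus 141/85-member synthetic ensembles for the
kinetic fits. Full ab initio trajectory ensembles over hundreds of
trajectories (isomerization quantum yields, hopping-geometry statistics,
absolute lifetimes) are supported by the same code paths via the
Hartree–Fock provider but are multi-hour computations; they are driven by
`scripts/` entry points rather than the test suite.

## Known limitations

* The built-in SCF is closed-shell RHF with s/p Gaussians only (no d
  functions, no open shells, no symmetry handling); 6-31G and STO-3G for
  H/C/N/O are the shipped basis sets.
* Hellmann–Feynman gradients neglect Pulay terms; the error is small at
  these basis sets near equilibrium but untested far from it.
* VQD with the default |E_gs| penalty can undershoot when the target
  state is unbound; the penalty is configurable per state.
* The hopping-probability formula is the propagator-flux variant; other
  fewest-switches variants differ at finite step size.
* One nuclear time step straddling a surface kink (trivial crossing)
  carries an O(dt) integration glitch on the kinked adiabat; halving the
  time step is the supported remedy.
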