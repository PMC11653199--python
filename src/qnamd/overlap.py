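"""Cross-timestep wavefunction overlaps and Löwdin orthonormalization.

The overlap matrix between electronic states at consecutive geometries,

    S_ml(t + dt) = <psi_m(t) | psi_l(t + dt)> ,

is evaluated from the CI-type determinant expansions of the two state sets
and the orbital overlap between the two geometries.  Each determinant pair
contributes the determinant of the occupied-orbital submatrix of the
cross-geometry orbital overlap, factorized over spin blocks; pair results
are cached because the same determinant pairs recur for every (m, l).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .properties import CIExpansion


class TrivialCrossingError(RuntimeError):
    """Raised when the overlap matrix is (nearly) singular."""


@dataclass
class OverlapMatrix:
    S: np.ndarray  # (n_states, n_states), S[m, l] = <bra_m | ket_l>
    warning: str | None = None


def determinant_pair_overlap(det_bra, det_ket, mo_cross_overlap: np.ndarray) -> float:
    """Overlap of two Slater determinants under a cross-geometry MO overlap.

    Determinants are (alpha, beta) tuples of occupied spatial orbitals.
    Returns 0 for mismatched electron counts (different-sector states).
    """
    (a_bra, b_bra), (a_ket, b_ket) = det_bra, det_ket
    if len(a_bra) != len(a_ket) or len(b_bra) != len(b_ket):
        return 0.0
    val = 1.0
    for occ_b, occ_k in ((a_bra, a_ket), (b_bra, b_ket)):
        if occ_b:
            sub = mo_cross_overlap[np.ix_(occ_b, occ_k)]
            val *= float(np.linalg.det(sub))
    return val


def ci_overlap_matrix(expansions_bra: list[CIExpansion], expansions_ket: list[CIExpansion],
                      mo_cross_overlap: np.ndarray,
                      norm_budget: float = 0.999) -> OverlapMatrix:
    """S_ml = sum_ij c_i^(m) c_j^(l) <det_i | det_j>, spin-block cached."""
    warn = None
    for e in (*expansions_bra, *expansions_ket):
        if e.norm_retained < norm_budget:
            warn = "truncated CI norm below budget on at least one state"

    block_cache: dict[tuple, float] = {}

    def block_det(occ_b, occ_k):
        if len(occ_b) != len(occ_k):
            return None
        key = (occ_b, occ_k)
        if key not in block_cache:
            if occ_b:
                sub = mo_cross_overlap[np.ix_(occ_b, occ_k)]
                block_cache[key] = float(np.linalg.det(sub))
            else:
                block_cache[key] = 1.0
        return block_cache[key]

    n_bra, n_ket = len(expansions_bra), len(expansions_ket)
    S = np.zeros((n_bra, n_ket))
    for m, eb in enumerate(expansions_bra):
        for l, ek in enumerate(expansions_ket):
            acc = 0.0
            for ci, (ab, bb) in zip(eb.coefficients, eb.determinants):
                for cj, (ak, bk) in zip(ek.coefficients, ek.determinants):
                    da = block_det(ab, ak)
                    if da is None or da == 0.0:
                        continue
                    db = block_det(bb, bk)
                    if db is None:
                        continue
                    acc += ci * cj * da * db
            S[m, l] = acc
    return OverlapMatrix(S, warn)


def lowdin_orthonormalize(S: np.ndarray, singular_tol: float = 1e-6) -> np.ndarray:
    """T = S (S^T S)^(-1/2): the orthogonal matrix closest to S (Frobenius).

    Computed as the polar factor U V^T of the SVD S = U diag(s) V^T.  A
    smallest singular value below ``singular_tol`` signals a rank-deficient
    overlap (a state left the spanned space within one step, the trivial
    crossing pathology) and raises :class:`TrivialCrossingError`.
    """
    S = np.asarray(S, float)
    if S.shape[0] != S.shape[1]:
        raise ValueError("overlap matrix must be square")
    U, s, Vt = np.linalg.svd(S)
    if s[-1] < singular_tol:
        k = int(np.argmin(s))
        direction = np.argmax(np.abs(U[:, k]))
        raise TrivialCrossingError(
            f"overlap matrix singular (s_min = {s[-1]:.2e}); state {direction} "
            "lost between steps — reduce the nuclear time step"
        )
    return U @ Vt
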