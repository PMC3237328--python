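"""Direct information via the inverse of the normalised MI matrix.

Mutual information between two columns mixes direct coupling with indirect
contributions routed through every other column.  Treating the MI matrix as
a covariance-like object, its inverse W yields partial correlations

    D_ij = -W_ij / sqrt(W_ii * W_jj)

which measure the coupling of i and j with all other columns held fixed,
suppressing transitive (chained) correlation.  Because the MI matrix can be
singular or nearly so, the inverse is the Moore-Penrose generalised inverse
computed from the singular value decomposition with a relative cutoff.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .alignment import Alignment
from .mi import EntropySet, ScoreMatrix, entropy_set, mi_matrix, score_matrix

logger = logging.getLogger(__name__)


@dataclass
class InverseResult:
    """Generalised inverse W of a symmetric matrix, with its numerical rank."""

    W: np.ndarray
    rank: int
    rcond: float


def generalized_inverse(A: np.ndarray, rcond: float = 1e-12) -> InverseResult:
    """Moore-Penrose pseudo-inverse of a symmetric matrix via SVD.

    Singular values below ``rcond`` times the largest singular value are
    treated as exactly zero, which keeps the inverse stable for the
    poorly conditioned matrices that arise from MI data.
    """
    A = np.asarray(A, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("input must be a square matrix")
    if not np.all(np.isfinite(A)):
        raise ValueError("input contains non-finite entries")
    U, s, Vt = np.linalg.svd(A, hermitian=True)
    if s.size == 0:
        raise ValueError("empty matrix")
    cutoff = rcond * s[0]
    keep = s > cutoff
    rank = int(keep.sum())
    s_inv = np.zeros_like(s)
    s_inv[keep] = 1.0 / s[keep]
    W = (Vt.T * s_inv) @ U.T
    return InverseResult(W=W, rank=rank, rcond=rcond)


def partial_correlation(inv: InverseResult | np.ndarray) -> ScoreMatrix:
    """Partial correlations D_ij = -W_ij / sqrt(W_ii W_jj); D_ii = 0.

    Rows whose diagonal entry of W is not strictly positive (a symptom of
    an ill-conditioned input) are zeroed with a warning rather than
    producing complex or infinite scores.
    """
    W = inv.W if isinstance(inv, InverseResult) else np.asarray(inv, dtype=float)
    d = np.diag(W).copy()
    bad = d <= 0
    if np.any(bad):
        logger.warning(
            "non-positive diagonal in inverse at %d position(s); "
            "their direct-information scores are set to 0",
            int(bad.sum()),
        )
        d[bad] = 1.0  # placeholder; rows are zeroed below
    denom = np.sqrt(np.outer(d, d))
    D = -W / denom
    D = 0.5 * (D + D.T)  # enforce exact symmetry against rounding
    D[bad, :] = 0.0
    D[:, bad] = 0.0
    np.fill_diagonal(D, 0.0)
    return ScoreMatrix(D, "DI")


def direct_information(
    aln: Alignment,
    score: str = "mip",
    rcond: float = 1e-12,
    base: float = 21.0,
    joint_base: float | None = None,
) -> ScoreMatrix:
    """Direct information of an alignment: score matrix -> pseudo-inverse -> D.

    The matrix that is inverted is the chosen MI variant (default MIp,
    the APC-corrected MI) with its diagonal restored to the per-column
    entropy S_i so that it behaves like a covariance matrix.
    """
    E = entropy_set(aln, base, joint_base)
    if score.lower() == "mi":
        M = mi_matrix(aln, base, joint_base, entropies=E)
    else:
        M = score_matrix(aln, score=score, base=base, joint_base=joint_base)
    V = M.values.copy()
    np.fill_diagonal(V, E.single)
    inv = generalized_inverse(V, rcond=rcond)
    D = partial_correlation(inv)
    D.meta.update({"score": score.lower(), "rcond": rcond, "rank": inv.rank})
    return D
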