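"""Column entropies, mutual information and its normalisations.

The alphabet has 21 symbols (20 amino acids plus the gap, which is treated
as an additional amino acid type). Frequencies carry a pseudo-count equal
to one amino acid spread evenly over the column:

    f_a = (c_a + p) / (n + 1),    p = 1/N

with N the alphabet size (21 for single columns, 441 for column pairs).
The single-column entropy S_i = -sum_a f_a log_N' f_a uses log base 21, so
a uniformly occupied column scores exactly 1 and a conserved column tends
to 0 as the number of sequences grows.  By default the joint entropy is
taken in base 21 as well, which makes M_ij = S_i + S_j - S_ij a true
mutual information bounded by [0, 1] at the uniform extremes; base 441
(joint entropy itself in [0, 1]) is available via ``joint_base``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .alignment import ALPHABET, ALPHABET_SIZE, Alignment

_SYM_TO_INT = {c: k for k, c in enumerate(ALPHABET)}

VALID_KINDS = ("MI", "MIr", "MIp", "MIa", "DI", "REBALANCED")


@dataclass
class ScoreMatrix:
    """An L x L symmetric pair-score matrix tagged by score kind."""

    values: np.ndarray
    kind: str
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("score matrix must be square")
        if not np.all(np.isfinite(v)):
            raise ValueError("score matrix contains non-finite entries")
        if not np.allclose(v, v.T, atol=1e-8):
            raise ValueError("score matrix is not symmetric")
        self.values = v

    @property
    def L(self) -> int:
        return self.values.shape[0]


@dataclass
class EntropySet:
    """Per-column entropies S_i and the L x L joint-entropy matrix S_ij."""

    single: np.ndarray
    joint: np.ndarray
    log_base: float


def encode(aln: Alignment) -> np.ndarray:
    """Integer-encode an alignment as an (n_seq, L) uint8 array."""
    flat = "".join(aln.rows)
    codes = np.frombuffer(flat.encode("ascii"), dtype=np.uint8)
    lut = np.full(128, _SYM_TO_INT["-"], dtype=np.uint8)
    for ch, k in _SYM_TO_INT.items():
        lut[ord(ch)] = k
    return lut[codes].reshape(aln.n_seq, aln.L)


def entropy_from_counts(
    counts: np.ndarray, n_seq: int, alphabet_size: int, base: float = 21.0
) -> float:
    """Shannon entropy of one column (or column pair) from symbol counts.

    Applies the pseudo-count p = 1/alphabet_size per symbol, denominator
    n + 1, and returns -sum f log_base f.  Counts may be a sparse subset as
    long as absent symbols are implied zero (their pseudo-count mass is
    still included).
    """
    counts = np.asarray(counts, dtype=float)
    p = 1.0 / alphabet_size
    f = (counts + p) / (n_seq + 1.0)
    ent = -np.sum(f * np.log(f))
    # symbols with zero count contribute the same pseudo-count term each
    n_absent = alphabet_size - counts.size
    if n_absent > 0:
        f0 = p / (n_seq + 1.0)
        ent += -n_absent * f0 * np.log(f0)
    return float(ent / np.log(base))


def column_entropy(aln: Alignment, i: int, base: float = 21.0) -> float:
    """Entropy S_i of column i, gaps counted as the 21st symbol."""
    enc = encode(aln)
    counts = np.bincount(enc[:, i], minlength=ALPHABET_SIZE)
    return entropy_from_counts(counts, aln.n_seq, ALPHABET_SIZE, base=base)


def joint_entropy(aln: Alignment, i: int, j: int, base: float = 21.0) -> float:
    """Joint entropy S_ij over the 441-pair alphabet, pair pseudo-count 1/441."""
    enc = encode(aln)
    pair = enc[:, i].astype(np.int32) * ALPHABET_SIZE + enc[:, j]
    counts = np.bincount(pair, minlength=ALPHABET_SIZE**2)
    return entropy_from_counts(counts, aln.n_seq, ALPHABET_SIZE**2, base=base)


def entropy_set(
    aln: Alignment, base: float = 21.0, joint_base: float | None = None
) -> EntropySet:
    """All single and pairwise entropies of an alignment.

    ``joint_base`` defaults to ``base`` (the [0,1]-bounded MI convention).
    """
    if joint_base is None:
        joint_base = base
    enc = encode(aln)
    n, L = enc.shape
    single = np.empty(L)
    for i in range(L):
        counts = np.bincount(enc[:, i], minlength=ALPHABET_SIZE)
        single[i] = entropy_from_counts(counts, n, ALPHABET_SIZE, base=base)

    joint = np.empty((L, L))
    A2 = ALPHABET_SIZE**2
    for i in range(L):
        # pair codes of column i against every column j >= i, one bincount
        codes = enc[:, i].astype(np.int64)[:, None] * ALPHABET_SIZE + enc[:, i:]
        codes += np.arange(L - i, dtype=np.int64) * A2
        flat = np.bincount(codes.ravel(), minlength=(L - i) * A2)
        for k in range(L - i):
            block = flat[k * A2 : (k + 1) * A2]
            nz = block[block > 0]
            s = entropy_from_counts(nz, n, A2, base=joint_base)
            joint[i, i + k] = s
            joint[i + k, i] = s
    return EntropySet(single=single, joint=joint, log_base=base)


def mi_matrix(
    aln: Alignment,
    base: float = 21.0,
    joint_base: float | None = None,
    entropies: EntropySet | None = None,
) -> ScoreMatrix:
    """Mutual information M_ij = S_i + S_j - S_ij.

    The diagonal is set to S_i (the value of the formula at i = j when the
    joint entropy of a column with itself equals its own entropy), which
    also gives the matrix a covariance-like diagonal for inversion.
    """
    E = entropies if entropies is not None else entropy_set(aln, base, joint_base)
    M = E.single[:, None] + E.single[None, :] - E.joint
    np.fill_diagonal(M, E.single)
    return ScoreMatrix(M, "MI", {"base": base, "entropies": E})


def mir_matrix(M: ScoreMatrix, E: EntropySet) -> ScoreMatrix:
    """MIr: mutual information normalised by the joint entropy, M'_ij = M_ij / S_ij."""
    if np.any(E.joint <= 0):
        raise FloatingPointError(
            "zero joint entropy encountered; pseudo-counts should prevent this"
        )
    return ScoreMatrix(M.values / E.joint, "MIr", dict(M.meta))


def background_correction(M: ScoreMatrix, mode: str = "APC") -> ScoreMatrix:
    """Subtract the estimated background from an MI (or MIr) matrix.

    The background at (i, j) combines the mean MI of row i and row j,
    relative to the overall mean, either geometrically (APC, giving MIp)
    or arithmetically (ASC, giving MIa):

        APC_ij = m_i * m_j / m        ASC_ij = m_i + m_j - m

    Means exclude the diagonal.  The diagonal of the output is carried
    over from the input unchanged.
    """
    if mode not in ("APC", "ASC"):
        raise ValueError(f"mode must be APC or ASC, got {mode!r}")
    V = M.values
    L = V.shape[0]
    if L < 2:
        raise ValueError("need at least two columns for background correction")
    off = ~np.eye(L, dtype=bool)
    row_means = (V.sum(axis=1) - np.diag(V)) / (L - 1)
    overall = V[off].mean()
    if mode == "APC":
        if overall == 0:
            raise ZeroDivisionError("overall mean MI is zero; APC undefined")
        bg = np.outer(row_means, row_means) / overall
    else:
        bg = row_means[:, None] + row_means[None, :] - overall
    out = V - bg
    np.fill_diagonal(out, np.diag(V))
    kind = "MIp" if mode == "APC" else "MIa"
    return ScoreMatrix(out, kind, dict(M.meta))


def score_matrix(
    aln: Alignment,
    score: str = "mi",
    base: float = 21.0,
    joint_base: float | None = None,
    correct_on: str = "mi",
) -> ScoreMatrix:
    """Compute any of the MI-family matrices for an alignment.

    score : one of mi, mir, mip, mia.  For mip/mia the correction is
    applied to raw MI by default; set ``correct_on='mir'`` to subtract the
    background from the joint-entropy-normalised matrix instead.
    """
    score = score.lower()
    E = entropy_set(aln, base, joint_base)
    M = mi_matrix(aln, base, joint_base, entropies=E)
    if score == "mi":
        return M
    if score == "mir":
        return mir_matrix(M, E)
    if score in ("mip", "mia"):
        basis = mir_matrix(M, E) if correct_on == "mir" else M
        return background_correction(basis, "APC" if score == "mip" else "ASC")
    raise ValueError(f"unknown score kind {score!r}")
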