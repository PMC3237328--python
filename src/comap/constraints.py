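"""Global structural constraints on predicted contact matrices.

Globular domains have reproducible bulk packing statistics: the total
number of side-chain contacts grows linearly with chain length, and both
the per-residue contact count and the sequence-separation count follow a
near-linear curve against fractional rank with a sharp reciprocal up-turn
at the dense end.  The default coefficients were derived from pseudo-
centroid contacts (8 A cutoff) over the SCOP40 domain set in the 100-200
residue range:

    P(N) = 3.21 N - 95.7            total contacts, sd about +/-50
    R(x) = 8 (1-x) + 1.0 (1/(x+0.2) - 1)   contacts per residue at rank x
    S(x) = 7 (1-x) + 0.8 (1/(x+0.2) - 1)   contacts at separation rank x

with x the fractional rank (0 = most contacts / closest pairs, 1 = least /
terminal).  A predicted score matrix is re-balanced toward these
statistics by (a) relaxing over-packed residues, multiplying an offender's
pair scores by (1 - fraction) per cycle, and (b) a Gaussian re-weighting
of the near-diagonal band that trades local against distant contacts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .mi import ScoreMatrix

logger = logging.getLogger(__name__)


@dataclass
class PackingModel:
    """Packing-curve coefficients for globular domains."""

    total_slope: float = 3.21
    total_intercept: float = -95.7
    total_sd: float = 50.0
    rank_coeffs: tuple[float, float, float] = (8.0, 1.0, 0.2)
    separation_coeffs: tuple[float, float, float] = (7.0, 0.8, 0.2)
    valid_length_range: tuple[int, int] = (100, 200)

    def expected_total_contacts(self, N: int) -> float:
        """Expected number of packed pairs for an N-residue protein (may be
        negative below ~30 residues; callers clamp at zero)."""
        if N <= 0:
            raise ValueError("protein length must be positive")
        return self.total_slope * N + self.total_intercept

    def rank_curve(self, x: float, which: str = "residue") -> float:
        """Contact count at fractional rank x in [0, 1]; negative values
        are clamped to 0 (a count cannot be negative)."""
        x = float(x)
        if not 0.0 <= x <= 1.0:
            raise ValueError(f"fractional rank must be in [0, 1], got {x}")
        if which == "residue":
            lin, rec, off = self.rank_coeffs
        elif which == "separation":
            lin, rec, off = self.separation_coeffs
        else:
            raise ValueError(f"which must be 'residue' or 'separation', got {which!r}")
        val = lin * (1.0 - x) + rec * (1.0 / (x + off) - 1.0)
        return max(val, 0.0)


DEFAULT_MODEL = PackingModel()


def expected_total_contacts(N: int, model: PackingModel = DEFAULT_MODEL) -> float:
    return model.expected_total_contacts(N)


def rank_curve(x: float, which: str = "residue", model: PackingModel = DEFAULT_MODEL) -> float:
    return model.rank_curve(x, which)


@dataclass
class ContactSet:
    """A set of residue pairs (i < j, 0-based) with optional scores."""

    pairs: list[tuple[int, int]]
    L: int
    scores: dict[tuple[int, int], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen = set()
        for i, j in self.pairs:
            if i >= j:
                raise ValueError(f"pairs must have i < j, got ({i}, {j})")
            if j >= self.L:
                raise ValueError(f"pair ({i}, {j}) exceeds length {self.L}")
            if (i, j) in seen:
                raise ValueError(f"duplicate pair ({i}, {j})")
            seen.add((i, j))

    def per_residue_counts(self) -> np.ndarray:
        counts = np.zeros(self.L, dtype=int)
        for i, j in self.pairs:
            counts[i] += 1
            counts[j] += 1
        return counts

    def separations(self) -> np.ndarray:
        return np.array([j - i for i, j in self.pairs], dtype=int)

    def as_set(self) -> set[tuple[int, int]]:
        return set(self.pairs)


def select_contacts(
    D: ScoreMatrix, N: int | None = None, model: PackingModel = DEFAULT_MODEL,
    n_contacts: int | None = None, min_sep: int = 1,
) -> ContactSet:
    """Pick the expected number of top-scoring pairs as predicted contacts.

    The count defaults to round(max(0, P(N))); ties are broken toward the
    lexicographically smaller (i, j) so the selection is deterministic.
    """
    V = D.values
    L = V.shape[0]
    if N is None:
        N = L
    if n_contacts is None:
        n_contacts = int(round(max(0.0, model.expected_total_contacts(N))))
    iu, ju = np.triu_indices(L, k=min_sep)
    scores = V[iu, ju]
    order = np.lexsort((ju, iu, -scores))  # score desc, then (i, j) asc
    if n_contacts > order.size:
        logger.warning(
            "requested %d contacts but only %d pairs available", n_contacts, order.size
        )
        n_contacts = order.size
    chosen = order[:n_contacts]
    pairs = [(int(iu[k]), int(ju[k])) for k in chosen]
    return ContactSet(
        pairs=pairs, L=L, scores={p: float(V[p]) for p in pairs}
    )


def _allowed_counts(counts: np.ndarray, model: PackingModel, pointwise: bool) -> np.ndarray:
    """Per-residue contact ceiling from the rank curve.

    Residues are ranked by count (0 = most contacts); each residue's limit
    is the curve read at its fractional rank.  With ``pointwise=False`` a
    single global cap, the curve value at rank 0, applies to every residue.
    """
    L = counts.size
    if not pointwise:
        return np.full(L, model.rank_curve(0.0, "residue"))
    order = np.argsort(-counts, kind="stable")
    xs = np.arange(L) / max(L - 1, 1)
    allowed = np.empty(L)
    for rank, res in enumerate(order):
        allowed[res] = model.rank_curve(xs[rank], "residue")
    return allowed


def relax_overpacked(
    D: ScoreMatrix,
    model: PackingModel = DEFAULT_MODEL,
    fraction: float = 0.005,
    max_cycles: int = 5,
    pointwise: bool = True,
    n_contacts: int | None = None,
) -> ScoreMatrix:
    """Damp the scores of residues predicted to make too many contacts.

    Each cycle derives the current contact set, tallies contacts per
    residue, and compares each tally to its rank-curve ceiling.  Starting
    with the worst violation, every pair score linking an offender to its
    current contact partners is reduced by ``fraction`` (multiplicatively,
    on both (i,j) and (j,i) to keep the matrix symmetric).  Stops when no
    violations remain or after ``max_cycles`` cycles.  No entry ever
    increases.
    """
    V = D.values.copy()
    L = V.shape[0]
    for _cycle in range(max_cycles):
        contacts = select_contacts(
            ScoreMatrix(V, D.kind, dict(D.meta)), N=L, model=model,
            n_contacts=n_contacts,
        )
        counts = contacts.per_residue_counts()
        allowed = _allowed_counts(counts, model, pointwise)
        violation = counts - allowed
        offenders = np.where(violation > 0)[0]
        if offenders.size == 0:
            break
        offenders = offenders[np.argsort(-violation[offenders], kind="stable")]
        partners: dict[int, list[int]] = {}
        for i, j in contacts.pairs:
            partners.setdefault(i, []).append(j)
            partners.setdefault(j, []).append(i)
        for res in offenders:
            for nb in partners.get(int(res), []):
                V[res, nb] *= 1.0 - fraction
                V[nb, res] = V[res, nb]
    return ScoreMatrix(V, "REBALANCED", dict(D.meta))


def separation_rescale(
    D: ScoreMatrix, a: float, sigma: float = 100.0
) -> ScoreMatrix:
    """Gaussian re-weighting of the near-diagonal band.

    Each entry is scaled by 1 - a * exp(-s^2 / (2 sigma^2)) with s = |i-j|
    the sequence separation.  A positive ``a`` shrinks short-range scores,
    promoting distant contacts in the ranking; a negative ``a`` boosts the
    local band.  ``sigma`` (the range from the diagonal) defaults to 100
    residues.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if abs(a) >= 1:
        logger.warning("correction |a| >= 1: the scale factor can cross zero")
    L = D.values.shape[0]
    s = np.abs(np.arange(L)[:, None] - np.arange(L)[None, :])
    factor = 1.0 - a * np.exp(-(s.astype(float) ** 2) / (2.0 * sigma**2))
    return ScoreMatrix(D.values * factor, D.kind, dict(D.meta))


def _rank_xy(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Sorted-descending values against their fractional rank."""
    y = np.sort(values)[::-1].astype(float)
    m = y.size
    x = np.arange(m) / max(m - 1, 1)
    return x, y


def fit_packing_model(
    records: list[tuple[int, list[tuple[int, int]]]],
    n_bins: int = 10,
    reciprocal_offset: float = 0.2,
) -> PackingModel:
    """Fit packing curves to per-protein (length, contact-pair list) records.

    The total-contact line is an ordinary least-squares fit of pair count
    against length.  The per-residue and separation curves are fit in their
    two free coefficients (the linear and reciprocal amplitudes; the rank
    offset stays fixed) by linear least squares over the pooled fractional-
    rank profiles of all proteins, mirroring the length-binned rank plots
    the default coefficients come from.
    """
    if len(records) < 2:
        raise ValueError("need at least two proteins to fit the total-contact line")
    lengths = np.array([L for L, _ in records], dtype=float)
    totals = np.array([len(pairs) for _, pairs in records], dtype=float)
    if np.ptp(lengths) == 0:
        raise ValueError("degenerate input: all proteins have the same length")
    slope, intercept = np.polyfit(lengths, totals, 1)
    resid = totals - (slope * lengths + intercept)
    sd = float(np.std(resid)) if len(records) > 2 else 50.0

    def fit_curve(xs: np.ndarray, ys: np.ndarray) -> tuple[float, float, float]:
        A = np.column_stack([1.0 - xs, 1.0 / (xs + reciprocal_offset) - 1.0])
        coef, *_ = np.linalg.lstsq(A, ys, rcond=None)
        return float(coef[0]), float(coef[1]), reciprocal_offset

    res_x, res_y, sep_x, sep_y = [], [], [], []
    for L, pairs in records:
        cs = ContactSet(pairs=list(pairs), L=L)
        x, y = _rank_xy(cs.per_residue_counts())
        res_x.append(x)
        res_y.append(y)
        seps = cs.separations()
        if seps.size:
            # count of contacts at each separation, ranked dense-first
            sep_counts = np.bincount(seps, minlength=L)[1:]
            x, y = _rank_xy(sep_counts)
            sep_x.append(x)
            sep_y.append(y)

    rank_coeffs = fit_curve(np.concatenate(res_x), np.concatenate(res_y))
    sep_coeffs = (
        fit_curve(np.concatenate(sep_x), np.concatenate(sep_y))
        if sep_x
        else DEFAULT_MODEL.separation_coeffs
    )
    lo, hi = int(lengths.min()), int(lengths.max())
    return PackingModel(
        total_slope=float(slope),
        total_intercept=float(intercept),
        total_sd=sd,
        rank_coeffs=rank_coeffs,
        separation_coeffs=sep_coeffs,
        valid_length_range=(lo, hi),
    )
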