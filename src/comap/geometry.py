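"""Structure-side geometry: pseudo-centroids, observed contacts, SSE axes,
reciprocal overlap area, and prediction evaluation.

Side-chain positions are approximated from the backbone alone by a
pseudo-centroid: a point 2 A from the alpha-carbon along the bisector of
the virtual bond angle CA(i-1)-CA(i)-CA(i+1), on the obtuse side, which
lands near the beta/gamma carbons of a trans side chain.  Contacts are
pseudo-centroid pairs within 8 A.  SSE-level interaction is measured
between fitted axis segments as the Reciprocal Overlap Area (ROA): the
mutual overlap length times the mean reciprocal point-to-line distance,
optionally screened for strand pairs separated within or across a sheet.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist, squareform

import biotite.structure as bst
from biotite.structure.io.pdb import PDBFile

from .constraints import ContactSet

logger = logging.getLogger(__name__)

CENTROID_OFFSET = 2.0  # A, along the obtuse bisector
CONTACT_CUTOFF = 8.0  # A, between pseudo-centroids


@dataclass
class CaTrace:
    """Ordered alpha-carbon coordinates of one chain, in Angstrom."""

    coords: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.coords, dtype=float)
        if c.ndim != 2 or c.shape[1] != 3:
            raise ValueError("coords must be an (L, 3) array")
        self.coords = c

    @property
    def L(self) -> int:
        return self.coords.shape[0]

    def virtual_bonds_plausible(self, lo: float = 2.5, hi: float = 4.5) -> bool:
        """Whether all consecutive CA-CA distances look like a real chain."""
        d = np.linalg.norm(np.diff(self.coords, axis=0), axis=1)
        return bool(np.all((d >= lo) & (d <= hi)))


def read_ca_trace(path: str, chain: str | None = None) -> CaTrace:
    """CA coordinates from a PDB file (ATOM records, altloc 'A' or blank)."""
    pdb = PDBFile.read(str(path))
    atoms = pdb.get_structure(model=1, altloc="first")
    atoms = atoms[~atoms.hetero]
    if chain is None:
        chain = atoms.chain_id[0]
    ca = atoms[(atoms.chain_id == chain) & (atoms.atom_name == "CA")]
    if ca.array_length() == 0:
        raise ValueError(f"no CA atoms for chain {chain!r} in {path}")
    return CaTrace(coords=np.array(ca.coord, dtype=float))


def write_ca_trace(trace: CaTrace, path: str, chain: str = "A") -> None:
    """Write a CA-only model in PDB format."""
    n = trace.L
    atoms = bst.AtomArray(n)
    atoms.coord = trace.coords.astype(np.float32)
    atoms.chain_id[:] = chain
    atoms.res_id[:] = np.arange(1, n + 1)
    atoms.res_name[:] = "ALA"
    atoms.atom_name[:] = "CA"
    atoms.element[:] = "C"
    atoms.hetero[:] = False
    pdb = PDBFile()
    pdb.set_structure(atoms)
    pdb.write(str(path))


@dataclass
class PseudoCentroidSet:
    """One surrogate side-chain point per residue."""

    positions: np.ndarray
    offset: float = CENTROID_OFFSET
    contact_cutoff: float = CONTACT_CUTOFF


def pseudo_centroids(trace: CaTrace, offset: float = CENTROID_OFFSET) -> PseudoCentroidSet:
    """Place each interior residue's centroid ``offset`` A from its CA.

    With u, v the unit vectors from CA_i toward its chain neighbours, the
    centroid sits at CA_i - offset * (u+v)/|u+v| — on the obtuse side of
    the virtual bond angle, opposite the bisector.  Terminal residues, and
    interior residues whose neighbours are collinear, use the CA itself.
    All residue types are treated alike: the trace carries no side-chain
    identity.
    """
    if trace.L < 3:
        raise ValueError("need at least 3 residues to build pseudo-centroids")
    C = trace.coords
    P = C.copy()
    for i in range(1, trace.L - 1):
        u = C[i - 1] - C[i]
        v = C[i + 1] - C[i]
        u = u / np.linalg.norm(u)
        v = v / np.linalg.norm(v)
        b = u + v
        nb = np.linalg.norm(b)
        if nb < 1e-6:
            logger.warning("collinear neighbours at residue %d; using CA position", i)
            continue
        P[i] = C[i] - offset * b / nb
    return PseudoCentroidSet(positions=P, offset=offset)


def observed_contacts(
    centroids: PseudoCentroidSet, cutoff: float = CONTACT_CUTOFF, min_sep: int = 3
) -> ContactSet:
    """All residue pairs with centroid distance < cutoff and |i-j| >= min_sep."""
    P = centroids.positions
    L = P.shape[0]
    dist = squareform(pdist(P))
    pairs = []
    for i in range(L):
        for j in range(i + min_sep, L):
            if dist[i, j] < cutoff:
                pairs.append((i, j))
    return ContactSet(pairs=pairs, L=L)


@dataclass
class AxisSegment:
    """A fitted SSE axis: a directed line segment, oriented N -> C."""

    start: np.ndarray
    end: np.ndarray

    @property
    def direction(self) -> np.ndarray:
        d = self.end - self.start
        return d / np.linalg.norm(d)

    @property
    def length(self) -> float:
        return float(np.linalg.norm(self.end - self.start))


def sse_axes(trace: CaTrace, windows) -> list[AxisSegment | None]:
    """Principal-component axis through each window's core CA coordinates.

    Endpoints are the projections of the first and last core CA onto the
    fitted line; the direction is oriented from N to C.  Windows with
    fewer than 3 core residues are skipped (None in the output).
    """
    out: list[AxisSegment | None] = []
    for w in windows:
        core = trace.coords[w.core_start : w.core_end + 1]
        if core.shape[0] < 3:
            logger.warning(
                "SSE core [%d, %d] has fewer than 3 residues; skipped",
                w.core_start, w.core_end,
            )
            out.append(None)
            continue
        mean = core.mean(axis=0)
        _, _, Vt = np.linalg.svd(core - mean)
        direction = Vt[0]
        if np.dot(core[-1] - core[0], direction) < 0:
            direction = -direction
        t0 = float(np.dot(core[0] - mean, direction))
        t1 = float(np.dot(core[-1] - mean, direction))
        out.append(AxisSegment(start=mean + t0 * direction, end=mean + t1 * direction))
    return out


def _point_to_line_distance(p: np.ndarray, seg: AxisSegment) -> float:
    d = seg.direction
    v = p - seg.start
    return float(np.linalg.norm(v - np.dot(v, d) * d))


def _projection_param(p: np.ndarray, seg: AxisSegment) -> float:
    """Parameter of p's projection onto seg's line, 0 at start, length at end."""
    return float(np.dot(p - seg.start, seg.direction))


def _samples(seg: AxisSegment, step: float) -> np.ndarray:
    n = max(int(np.ceil(seg.length / step)), 1) + 1
    t = np.linspace(0.0, seg.length, n)
    return seg.start[None, :] + t[:, None] * seg.direction[None, :]


def roa(seg_i: AxisSegment, seg_j: AxisSegment, step: float = 1.0) -> float:
    """Reciprocal overlap area of two axis segments.

    Each segment is sampled at ``step`` intervals; a sample contributes
    when its projection onto the other segment's line falls within that
    segment (mutual overlap).  The score is the mean reciprocal distance
    from contributing samples to the other segment's line, times the
    overlap length (averaged over the two segments).  Zero when the
    projections miss entirely.
    """
    if seg_i.length <= 0 or seg_j.length <= 0:
        raise ValueError("segments must have positive length")
    total_inv = 0.0
    n_contrib = 0
    overlap_lens = []
    for a, b in ((seg_i, seg_j), (seg_j, seg_i)):
        pts = _samples(a, step)
        inside = np.array(
            [0.0 <= _projection_param(p, b) <= b.length for p in pts]
        )
        k = int(inside.sum())
        overlap_lens.append(a.length * k / pts.shape[0])
        for p in pts[inside]:
            d = _point_to_line_distance(p, b)
            if d < 1e-9:
                d = 1e-9  # touching lines: cap rather than diverge
            total_inv += 1.0 / d
            n_contrib += 1
    if n_contrib == 0:
        return 0.0
    overlap = 0.5 * (overlap_lens[0] + overlap_lens[1])
    return overlap * total_inv / n_contrib


def segment_cosine(seg_i: AxisSegment, seg_j: AxisSegment) -> float:
    """Cosine of the angle between the two directed axes (signed: positive
    for parallel, negative for antiparallel packing)."""
    return float(np.clip(np.dot(seg_i.direction, seg_j.direction), -1.0, 1.0))


def screen(
    roa_value: float, n_adj: int = 1, opposite_sides: bool = False, base: float = 4.0
) -> float:
    """Sheet screening of an ROA value.

    Strand pairs on opposite sides of a beta-sheet are zeroed; pairs in
    the same layer are damped geometrically by their adjacency N (nearest
    neighbours N=1 unscaled, factor base^(1-N) beyond).  Side and
    adjacency labels are inputs from a layer description.
    """
    if opposite_sides:
        return 0.0
    if n_adj < 1:
        raise ValueError("adjacency must be >= 1 for in-layer pairs")
    return roa_value * base ** (1 - n_adj)


def combined_score(
    A: float, c: float, T: float, P_pol: float, w_u: float = 1.0, w_o: float = 1.0
) -> float:
    """Oriented SSE-pair score R = A * (w_u * T + w_o * c * P).

    Combines an un-oriented term (total predicted interaction T) with an
    oriented term that rewards agreement between the observed axis cosine
    c and the predicted polarity P; both are signed, so disagreement
    contributes negatively.  A is the (screened) ROA.
    """
    return A * (w_u * T + w_o * c * P_pol)


@dataclass
class EvaluationMetrics:
    """Top-k precision/recall of a predicted contact set, plus the count
    profiles used for rank-curve comparisons."""

    precision: float
    recall: float
    n_predicted: int
    n_observed: int
    n_correct: int
    pred_residue_counts: np.ndarray = field(repr=False)
    obs_residue_counts: np.ndarray = field(repr=False)
    pred_separations: np.ndarray = field(repr=False)
    obs_separations: np.ndarray = field(repr=False)


def evaluate_prediction(
    pred: ContactSet, obs: ContactSet, top_k: int | None = None
) -> EvaluationMetrics:
    """Compare predicted against observed contacts.

    When the predicted set carries scores, the top_k highest-scoring pairs
    are evaluated (score ties toward smaller (i, j)); otherwise the first
    top_k pairs in order.
    """
    if pred.L != obs.L:
        raise ValueError(f"length mismatch: predicted {pred.L} vs observed {obs.L}")
    pairs = pred.pairs
    if top_k is not None and top_k < len(pairs):
        if pred.scores:
            pairs = sorted(pairs, key=lambda p: (-pred.scores.get(p, 0.0), p))[:top_k]
        else:
            pairs = pairs[:top_k]
    chosen = ContactSet(pairs=list(pairs), L=pred.L)
    inter = chosen.as_set() & obs.as_set()
    n_pred, n_obs = len(pairs), len(obs.pairs)
    return EvaluationMetrics(
        precision=len(inter) / n_pred if n_pred else 0.0,
        recall=len(inter) / n_obs if n_obs else 0.0,
        n_predicted=n_pred,
        n_observed=n_obs,
        n_correct=len(inter),
        pred_residue_counts=chosen.per_residue_counts(),
        obs_residue_counts=obs.per_residue_counts(),
        pred_separations=chosen.separations(),
        obs_separations=obs.separations(),
    )
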