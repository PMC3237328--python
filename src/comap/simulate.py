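"""Seeded synthetic generators: coupled-column alignments, toy CA traces
and hub score matrices.

These emulate the signal the analysis modules look for — covarying column
pairs (with optional chain couplings that create purely indirect
correlation), SSE-like contact geometry, and over-packed contact hubs —
against an otherwise independent background.  Every generator takes an
explicit seed and draws from its own pseudo-random stream, so identical
calls are byte-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .alignment import AMINO_ACIDS, Alignment
from .geometry import CaTrace
from .mi import ScoreMatrix


@dataclass
class CouplingSpec:
    """Recipe for a coupled-column alignment.

    coupled_pairs: (i, j, p) — column j copies column i with probability p.
    chain_triples: (i, j, k, p) — j copies i and k copies j, each with
    probability p, so i and k correlate only through j.
    """

    L: int
    n: int
    coupled_pairs: list[tuple[int, int, float]] = field(default_factory=list)
    chain_triples: list[tuple[int, int, int, float]] = field(default_factory=list)
    background: str = "uniform"  # or "dirichlet"
    dirichlet_alpha: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        for i, j, p in self.coupled_pairs:
            if not (0 <= i < self.L and 0 <= j < self.L):
                raise ValueError(f"pair indices ({i}, {j}) out of range")
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"copy probability {p} outside [0, 1]")
        for i, j, k, p in self.chain_triples:
            if not all(0 <= x < self.L for x in (i, j, k)):
                raise ValueError(f"triple indices ({i}, {j}, {k}) out of range")
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"copy probability {p} outside [0, 1]")


def gen_coupled_msa(spec: CouplingSpec) -> Alignment:
    """Generate a gap-free alignment with planted column couplings.

    Background symbols are drawn independently per sequence and column,
    either uniformly over the 20 amino acids or from per-column Dirichlet
    profiles.  Copy links are then applied: first the pair list, then each
    chain triple in order i->j->k.
    """
    rng = np.random.default_rng(spec.seed)
    n_aa = len(AMINO_ACIDS)
    if spec.background == "uniform":
        codes = rng.integers(0, n_aa, size=(spec.n, spec.L))
    elif spec.background == "dirichlet":
        profiles = rng.dirichlet([spec.dirichlet_alpha] * n_aa, size=spec.L)
        codes = np.empty((spec.n, spec.L), dtype=np.int64)
        for col in range(spec.L):
            codes[:, col] = rng.choice(n_aa, size=spec.n, p=profiles[col])
    else:
        raise ValueError(f"unknown background {spec.background!r}")

    def apply_copy(src: int, dst: int, p: float) -> None:
        copy = rng.random(spec.n) < p
        codes[copy, dst] = codes[copy, src]

    for i, j, p in spec.coupled_pairs:
        apply_copy(i, j, p)
    for i, j, k, p in spec.chain_triples:
        apply_copy(i, j, p)
        apply_copy(j, k, p)

    rows = ["".join(AMINO_ACIDS[c] for c in row) for row in codes]
    ids = [f"seq{k:05d}" for k in range(spec.n)]
    return Alignment(ids=ids, rows=rows, target_index=0)


def _arc(p0: np.ndarray, p1: np.ndarray, n_points: int, bulge: float = 4.0) -> np.ndarray:
    """Points on a smooth arc from p0 to p1, bulging in +z, excluding ends."""
    t = np.linspace(0.0, 1.0, n_points + 2)[1:-1]
    base = p0[None, :] + t[:, None] * (p1 - p0)[None, :]
    base[:, 2] += bulge * np.sin(np.pi * t)
    return base


def gen_toy_trace(kind: str, **params) -> CaTrace:
    """Parametric toy CA traces.

    ideal_helix: n residues on a helix (rise 1.5 A, twist 100 deg,
    radius 2.3 A).  strand_pair_parallel / strand_pair_antiparallel: two
    extended strands 4.8 A apart joined by an arc loop, the second strand
    running with or against the first.  hub: one central residue with
    ``n_partners`` residues placed within contact range of it.
    """
    if kind == "ideal_helix":
        n = params.get("n", 18)
        rise = params.get("rise", 1.5)
        twist = np.deg2rad(params.get("twist_deg", 100.0))
        radius = params.get("radius", 2.3)
        k = np.arange(n)
        coords = np.column_stack(
            [radius * np.cos(k * twist), radius * np.sin(k * twist), rise * k]
        )
        return CaTrace(coords=coords)

    if kind in ("strand_pair_parallel", "strand_pair_antiparallel"):
        m = params.get("n_per_strand", 6)
        spacing = params.get("spacing", 4.8)
        step = params.get("ca_step", 3.5)
        s1 = np.column_stack([step * np.arange(m), np.zeros(m), np.zeros(m)])
        xs = step * np.arange(m)
        if kind == "strand_pair_antiparallel":
            xs = xs[::-1]
        s2 = np.column_stack([xs, np.full(m, spacing), np.zeros(m)])
        gap = np.linalg.norm(s2[0] - s1[-1])
        n_loop = max(int(np.ceil(gap / 3.0)), 2)
        loop = _arc(s1[-1], s2[0], n_loop)
        return CaTrace(coords=np.vstack([s1, loop, s2]))

    if kind == "hub":
        n_partners = params.get("n_partners", 18)
        radius = params.get("radius", 5.0)
        rng = np.random.default_rng(params.get("seed", 0))
        center = np.zeros(3)
        # partners spread over a sphere around the hub, inside contact range
        pts = rng.normal(size=(n_partners, 3))
        pts = radius * pts / np.linalg.norm(pts, axis=1, keepdims=True)
        coords = np.vstack([pts[: n_partners // 2], center[None, :], pts[n_partners // 2 :]])
        return CaTrace(coords=coords)

    raise ValueError(f"unknown trace kind {kind!r}")


def gen_hub_matrix(
    L: int = 148,
    hub: int = 70,
    n_partners: int = 18,
    seed: int = 0,
    background_pairs: int = 450,
    max_background_degree: int = 7,
) -> ScoreMatrix:
    """A score matrix whose contact selection yields one over-packed hub.

    The hub residue carries ``n_partners`` pair scores graded just above a
    tight band of background pairs, so that multiplicative damping pushes
    them below the selection threshold a few at a time.  Background pairs
    (scores in [0.97, 1.0]) are degree-capped so no residue other than
    the hub exceeds a plausible contact count; everything else is near-
    zero noise.  Used to exercise the over-packing relaxation.
    """
    rng = np.random.default_rng(seed)
    V = np.abs(rng.normal(0.0, 1e-3, size=(L, L)))
    V = 0.5 * (V + V.T)
    partners = [r for r in range(L) if r != hub][:: max(1, (L - 1) // n_partners)]
    partners = partners[:n_partners]
    hub_scores = np.linspace(1.0, 1.10, n_partners)
    for p, sc in zip(partners, hub_scores):
        i, j = min(hub, p), max(hub, p)
        V[i, j] = V[j, i] = sc
    degree = np.zeros(L, dtype=int)
    count = 0
    attempts = 0
    while count < background_pairs and attempts < background_pairs * 100:
        attempts += 1
        i, j = sorted(rng.integers(0, L, size=2))
        if i == j or hub in (i, j) or V[i, j] > 0.9:
            continue
        if degree[i] >= max_background_degree or degree[j] >= max_background_degree:
            continue
        V[i, j] = V[j, i] = rng.uniform(0.97, 1.0)
        degree[i] += 1
        degree[j] += 1
        count += 1
    np.fill_diagonal(V, 0.0)
    return ScoreMatrix(V, "DI", {"hub": hub, "partners": partners})
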