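"""Secondary-structure-element windows and pair polarity scoring.

Helices and strands impose local order on a contact map: contacts between
two SSEs packed in parallel cluster along the sub-matrix diagonal, while
antiparallel packing clusters orthogonal to it.  Aggregating predicted
contact scores over SSE pairs averages out residue-level noise and yields
a signed polarity: the sub-matrix is split into quadrants at its weighted
centroid, and

    polarity = ((S_NN + S_CC) - (S_NC + S_CN)) / T

is positive for parallel and negative for antiparallel packing, bounded in
[-1, 1].  Because predicted SSE boundaries are uncertain, each window
carries up to three flanking residues per side (never past halfway to the
next SSE) at half weight.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .mi import ScoreMatrix

logger = logging.getLogger(__name__)


@dataclass
class SSEWindow:
    """An SSE core with half-weighted flanks.  Indices are 0-based inclusive."""

    sse_type: str  # 'H' or 'E'
    core_start: int
    core_end: int
    flank_left: int = 0  # number of flank residues before core_start
    flank_right: int = 0

    def __post_init__(self) -> None:
        if self.sse_type not in ("H", "E"):
            raise ValueError(f"sse_type must be H or E, got {self.sse_type!r}")
        if self.core_start > self.core_end:
            raise ValueError("core_start must not exceed core_end")
        if self.flank_left < 0 or self.flank_right < 0:
            raise ValueError("flank extents must be non-negative")

    @property
    def start(self) -> int:
        return self.core_start - self.flank_left

    @property
    def end(self) -> int:
        return self.core_end + self.flank_right

    def residues(self) -> list[int]:
        return list(range(self.start, self.end + 1))

    def weight(self, r: int) -> float:
        if self.core_start <= r <= self.core_end:
            return 1.0
        if self.start <= r <= self.end:
            return 0.5
        raise ValueError(f"residue {r} outside window [{self.start}, {self.end}]")

    def weights(self) -> np.ndarray:
        return np.array([self.weight(r) for r in self.residues()])


def build_windows(sse_string: str, flank: int = 3) -> list[SSEWindow]:
    """Turn a per-residue H/E/C string into SSE windows.

    Each maximal run of H or E becomes a core; flanks extend into the
    adjacent coil by up to ``flank`` residues but never past halfway to
    the neighbouring SSE (terminal coils are only limited by the sequence
    end).  Adjacent SSEs with no coil between them get zero flank on that
    side.
    """
    s = sse_string.strip().upper()
    if any(c not in "HEC" for c in s):
        bad = sorted({c for c in s if c not in "HEC"})
        raise ValueError(f"SSE string contains invalid symbols: {bad}")
    runs: list[tuple[str, int, int]] = []
    k = 0
    while k < len(s):
        if s[k] in "HE":
            start = k
            while k < len(s) and s[k] == s[start]:
                k += 1
            runs.append((s[start], start, k - 1))
        else:
            k += 1
    windows: list[SSEWindow] = []
    for idx, (typ, start, end) in enumerate(runs):
        prev_end = runs[idx - 1][2] if idx > 0 else None
        next_start = runs[idx + 1][1] if idx + 1 < len(runs) else None
        if prev_end is None:
            left = min(flank, start)
        else:
            gap = start - prev_end - 1
            left = min(flank, gap // 2)
        if next_start is None:
            right = min(flank, len(s) - 1 - end)
        else:
            gap = next_start - end - 1
            right = min(flank, gap // 2)
        windows.append(
            SSEWindow(
                sse_type=typ, core_start=start, core_end=end,
                flank_left=left, flank_right=right,
            )
        )
    return windows


@dataclass
class SSEPairScore:
    """Aggregate contact scores between two SSE windows."""

    T: float  # total weighted interaction
    quadrants: dict[str, float]  # NN, NC, CN, CC sums
    centroid: tuple[float, float]
    polarity: float
    defined: bool  # False when T <= 0 (polarity reported as 0)


def pair_interaction(
    D: ScoreMatrix, wi: SSEWindow, wj: SSEWindow, normalize: bool = True
) -> SSEPairScore:
    """Total interaction, quadrant split and polarity for one SSE pair.

    T is the weighted sum of all score entries in the (wi x wj) sub-matrix
    (flank-flank cells weigh 0.25).  The weighted centroid of the score
    mass divides the sub-matrix into quadrants N/C on each axis; a residue
    exactly at the centroid coordinate counts to the N side.  With
    ``normalize=False`` the raw quadrant difference is returned in place
    of the bounded polarity.
    """
    ri = np.array(wi.residues())
    rj = np.array(wj.residues())
    L = D.values.shape[0]
    if ri.min() < 0 or rj.min() < 0 or ri.max() >= L or rj.max() >= L:
        raise ValueError("SSE window extends beyond the score matrix")
    W = np.outer(wi.weights(), wj.weights())
    sub = W * D.values[np.ix_(ri, rj)]
    T = float(sub.sum())
    if T <= 0:
        logger.warning(
            "non-positive total interaction (T=%.4g) for SSE pair; polarity undefined",
            T,
        )
        return SSEPairScore(
            T=T, quadrants=dict.fromkeys(("NN", "NC", "CN", "CC"), 0.0),
            centroid=(float("nan"), float("nan")), polarity=0.0, defined=False,
        )
    ci = float((ri[:, None] * sub).sum() / T)
    cj = float((rj[None, :] * sub).sum() / T)
    n_i = ri <= ci  # ties go to the N-terminal side
    n_j = rj <= cj
    quadrants = {
        "NN": float(sub[np.ix_(n_i, n_j)].sum()),
        "NC": float(sub[np.ix_(n_i, ~n_j)].sum()),
        "CN": float(sub[np.ix_(~n_i, n_j)].sum()),
        "CC": float(sub[np.ix_(~n_i, ~n_j)].sum()),
    }
    contrast = (quadrants["NN"] + quadrants["CC"]) - (quadrants["NC"] + quadrants["CN"])
    polarity = contrast / T if normalize else contrast
    return SSEPairScore(
        T=T, quadrants=quadrants, centroid=(ci, cj), polarity=polarity, defined=True
    )


def score_all_pairs(
    D: ScoreMatrix, windows: list[SSEWindow], normalize: bool = True
) -> list[tuple[int, int, SSEPairScore]]:
    """Polarity scores for every window pair (cores must not overlap)."""
    out = []
    for a in range(len(windows)):
        for b in range(a + 1, len(windows)):
            out.append((a, b, pair_interaction(D, windows[a], windows[b], normalize)))
    return out


def read_sse(path: str) -> str:
    """Read an SSE assignment: either a single H/E/C line, or a 3-column
    segment list (type, start, end; 1-based) preceded by a length line
    ``L <n>``."""
    with open(path) as fh:
        lines = [ln.strip() for ln in fh if ln.strip() and not ln.startswith("#")]
    if not lines:
        raise ValueError(f"empty SSE file {path}")
    first = lines[0].split()
    if len(first) == 1 and set(first[0]) <= set("HEChec"):
        return first[0].upper()
    if first[0].upper() == "L":
        L = int(first[1])
        chars = ["C"] * L
        for ln in lines[1:]:
            typ, start, end = ln.split()[:3]
            for r in range(int(start) - 1, int(end)):
                chars[r] = typ.upper()
        return "".join(chars)
    raise ValueError(f"cannot interpret SSE file {path}")
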