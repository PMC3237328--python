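"""Plain-text score-matrix and contact-list formats.

Square matrices are whitespace-delimited with one header line holding the
dimension, score kind and log base.  Sparse output is a 3-column
(i, j, score) list and contact sets a 2-column pair list, both 1-based.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .constraints import ContactSet
from .mi import ScoreMatrix


def write_matrix(M: ScoreMatrix, path: str | Path) -> None:
    base = M.meta.get("base", "")
    with open(path, "w") as fh:
        fh.write(f"{M.L} {M.kind} {base}\n")
        for row in M.values:
            fh.write(" ".join(f"{v:.10g}" for v in row) + "\n")


def read_matrix(path: str | Path) -> ScoreMatrix:
    with open(path) as fh:
        header = fh.readline().split()
        L = int(header[0])
        kind = header[1] if len(header) > 1 else "MI"
        meta = {}
        if len(header) > 2 and header[2]:
            meta["base"] = float(header[2])
        values = np.loadtxt(fh, ndmin=2)
    if values.shape != (L, L):
        raise ValueError(f"matrix in {path} is {values.shape}, header says {L}x{L}")
    return ScoreMatrix(values, kind, meta)


def write_sparse(M: ScoreMatrix, path: str | Path) -> None:
    with open(path, "w") as fh:
        for i in range(M.L):
            for j in range(i + 1, M.L):
                fh.write(f"{i + 1} {j + 1} {M.values[i, j]:.10g}\n")


def write_contacts(contacts: ContactSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for i, j in contacts.pairs:
            if contacts.scores:
                fh.write(f"{i + 1} {j + 1} {contacts.scores[(i, j)]:.10g}\n")
            else:
                fh.write(f"{i + 1} {j + 1}\n")


def read_contacts(path: str | Path, L: int) -> ContactSet:
    pairs = []
    scores = {}
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            i, j = int(parts[0]) - 1, int(parts[1]) - 1
            i, j = min(i, j), max(i, j)
            pairs.append((i, j))
            if len(parts) > 2:
                scores[(i, j)] = float(parts[2])
    return ContactSet(pairs=pairs, L=L, scores=scores)
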