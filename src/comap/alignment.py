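"""Multiple sequence alignment handling: parsing, target masking and
redundancy/gap filtering.

An alignment is held as a rectangular block of upper-case symbols over the
20 standard amino acids plus a single gap character ``-``.  All downstream
statistics treat the gap as a 21st amino acid type, so any symbol that is
not a standard residue (``X``, ``B``, ``Z``, ``U``, ``O``, ``*`` ...) is
mapped to the gap on input.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable

from Bio import AlignIO

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
GAP = "-"
ALPHABET = AMINO_ACIDS + GAP  # gap is symbol index 20
ALPHABET_SIZE = len(ALPHABET)

_VALID = set(ALPHABET)


class AlignmentError(ValueError):
    """Raised for unparseable, ragged or otherwise invalid alignments."""


def _normalize_row(row: str) -> str:
    """Upper-case a row and unify '.', '-' and unknown symbols to GAP."""
    out = []
    for ch in row.upper():
        if ch in (".", "-"):
            out.append(GAP)
        elif ch in _VALID:
            out.append(ch)
        else:
            out.append(GAP)
    return "".join(out)


@dataclass
class Alignment:
    """A rectangular multiple sequence alignment with a designated target row.

    Attributes
    ----------
    ids : list of str
        Sequence identifiers, one per row.
    rows : list of str
        Equal-length symbol strings over the 21-letter alphabet.
    target_index : int
        Index of the target (query) row.
    """

    ids: list[str]
    rows: list[str]
    target_index: int = 0

    def __post_init__(self) -> None:
        if not self.rows:
            raise AlignmentError("alignment has no sequences")
        L = len(self.rows[0])
        if any(len(r) != L for r in self.rows):
            raise AlignmentError("ragged alignment: rows differ in length")
        if L < 1:
            raise AlignmentError("alignment has zero columns")
        if len(self.ids) != len(self.rows):
            raise AlignmentError("ids and rows differ in count")
        if not (0 <= self.target_index < len(self.rows)):
            raise AlignmentError("target_index out of range")

    @property
    def n_seq(self) -> int:
        return len(self.rows)

    @property
    def L(self) -> int:
        return len(self.rows[0])

    @property
    def target(self) -> str:
        return self.rows[self.target_index]

    def with_target(self, target_id: str) -> "Alignment":
        """Return a copy with the target row set to the row named target_id."""
        try:
            idx = self.ids.index(target_id)
        except ValueError:
            raise KeyError(f"target id {target_id!r} not in alignment") from None
        return replace(self, target_index=idx)


def read_alignment(
    path: str | Path, format: str = "fasta", target_id: str | None = None
) -> Alignment:
    """Read an alignment from FASTA or Stockholm.

    Symbols are case-normalised; '.', '-' and lowercase-insert conventions
    all map to the single gap character.  The target defaults to the first
    record unless ``target_id`` is given.
    """
    if format not in ("fasta", "stockholm"):
        raise AlignmentError(f"unsupported alignment format {format!r}")
    try:
        msa = AlignIO.read(str(path), format)
    except Exception as exc:  # Bio raises bare ValueError on parse failure
        raise AlignmentError(f"cannot parse {path} as {format}: {exc}") from exc
    ids = [rec.id for rec in msa]
    rows = [_normalize_row(str(rec.seq)) for rec in msa]
    aln = Alignment(ids=ids, rows=rows)
    if target_id is not None:
        aln = aln.with_target(target_id)
    return aln


def write_fasta(aln: Alignment, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, row in zip(aln.ids, aln.rows):
            fh.write(f">{name}\n{row}\n")


def mask_to_target(aln: Alignment, target_id: str | None = None) -> Alignment:
    """Drop every column where the target row carries a gap.

    Column indices of the result then map one-to-one onto target residue
    positions. Idempotent.
    """
    if target_id is not None:
        aln = aln.with_target(target_id)
    keep = [k for k, ch in enumerate(aln.target) if ch != GAP]
    if not keep:
        raise AlignmentError("target row is entirely gaps; nothing to analyse")
    rows = ["".join(r[k] for k in keep) for r in aln.rows]
    return Alignment(ids=list(aln.ids), rows=rows, target_index=aln.target_index)


def _identity(a: str, b: str) -> float:
    """Fractional identity over the full (target-masked) column range.

    Positions where both rows hold the same symbol count as matches, gaps
    included: the denominator is the target-ungapped length, per the
    percentage convention used by the redundancy filter.
    """
    return sum(x == y for x, y in zip(a, b)) / len(a)


def _gap_fraction(row: str) -> float:
    return row.count(GAP) / len(row)


def filter_redundancy(
    aln: Alignment,
    max_ident: float = 0.95,
    max_gapfrac: float = 0.20,
    literal_preceding: bool = False,
) -> Alignment:
    """Single-pass redundancy and gap filter.

    Rows are scanned in file order; a row is dropped when its identity to
    the preceding retained row exceeds ``max_ident`` or when more than
    ``max_gapfrac`` of its positions are gaps.  Both fractions are computed
    over the target-ungapped columns, so the alignment must already be
    masked to the target.  The target row itself is never dropped.

    With ``literal_preceding=True`` the identity comparison uses the
    immediately preceding file row whether or not it was retained (the
    non-idempotent literal reading).
    """
    keep: list[int] = []
    prev_retained: str | None = None
    for k, row in enumerate(aln.rows):
        if k == aln.target_index:
            keep.append(k)
            prev_retained = row
            continue
        reference = aln.rows[k - 1] if (literal_preceding and k > 0) else prev_retained
        drop = _gap_fraction(row) > max_gapfrac
        if not drop and reference is not None:
            drop = _identity(row, reference) > max_ident
        if not drop:
            keep.append(k)
            prev_retained = row
    ids = [aln.ids[k] for k in keep]
    rows = [aln.rows[k] for k in keep]
    return Alignment(ids=ids, rows=rows, target_index=keep.index(aln.target_index))
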