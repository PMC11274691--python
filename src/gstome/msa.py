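"""Alignment-indexed sequence analytics.

Every residue-level result downstream (interface occupancy, binding-site
occupancy, pathway visits, B-factor profiles) is reported against "MSA
numbers": 1-based column indices of one fixed multiple sequence alignment
of the family.  This module owns that coordinate system — the bidirectional
map between ungapped sequence positions and alignment columns — together
with column conservation, gap statistics, pairwise identity and formal
charge.
"""

from __future__ import annotations

import io
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import AlignIO

from .chem import AMINO_ACIDS, NEGATIVE_AA, POSITIVE_AA

GAP = "-"
_VALID = AMINO_ACIDS | {GAP}


class AlignmentError(ValueError):
    pass


@dataclass
class AlignedSequenceSet:
    """An alignment: rows over the 20 amino-acid letters plus '-'.

    MSA numbers are 1-based column indices.  ``class_labels`` optionally
    tags each row with its family class (e.g. GST Delta/Epsilon/...).
    """

    ids: list[str]
    rows: list[str]
    class_labels: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.rows:
            raise AlignmentError("empty alignment")
        if len(self.ids) != len(self.rows):
            raise AlignmentError("ids/rows length mismatch")
        ncols = len(self.rows[0])
        for rid, row in zip(self.ids, self.rows):
            if len(row) != ncols:
                raise AlignmentError(f"ragged alignment: row {rid!r} has length {len(row)}, expected {ncols}")
        if len(set(self.ids)) != len(self.ids):
            raise AlignmentError("duplicated sequence ids")
        for i, row in enumerate(self.rows):
            for j, letter in enumerate(row):
                if letter not in _VALID:
                    raise AlignmentError(
                        f"invalid letter {letter!r} in row {self.ids[i]!r}, column {j + 1}"
                    )

    @property
    def nrows(self) -> int:
        return len(self.rows)

    @property
    def ncols(self) -> int:
        return len(self.rows[0])

    def row(self, row_id: str) -> str:
        try:
            return self.rows[self.ids.index(row_id)]
        except ValueError:
            raise KeyError(f"no sequence {row_id!r} in alignment") from None

    def ungapped(self, row_id: str) -> str:
        return self.row(row_id).replace(GAP, "")

    def column(self, msa_number: int) -> str:
        if not 1 <= msa_number <= self.ncols:
            raise IndexError(f"MSA number {msa_number} outside 1..{self.ncols}")
        return "".join(row[msa_number - 1] for row in self.rows)


def read_alignment(
    fasta_text: str, class_labels: dict[str, str] | None = None
) -> AlignedSequenceSet:
    """Read an aligned FASTA (equal-length rows) into an AlignedSequenceSet."""
    try:
        aln = AlignIO.read(io.StringIO(fasta_text), "fasta")
    except ValueError as exc:
        raise AlignmentError(f"bad aligned FASTA: {exc}") from exc
    return AlignedSequenceSet(
        ids=[rec.id for rec in aln],
        rows=[str(rec.seq).upper() for rec in aln],
        class_labels=dict(class_labels or {}),
    )


def write_alignment(aln: AlignedSequenceSet) -> str:
    return "".join(f">{rid}\n{row}\n" for rid, row in zip(aln.ids, aln.rows))


@dataclass
class ConservationProfile:
    """Per-column amino-acid frequencies in % of all rows.

    A column is fully conserved iff a single amino acid fills every row,
    so any gap in the column defeats full conservation.
    """

    frequencies: pd.DataFrame  # index = MSA number, columns = 20 AAs, values %
    gap_counts: np.ndarray
    majority_residue: list[str]
    majority_score: np.ndarray  # %

    @property
    def ncols(self) -> int:
        return len(self.frequencies)


def conservation_profile(aln: AlignedSequenceSet) -> ConservationProfile:
    aas = sorted(AMINO_ACIDS)
    n = aln.nrows
    freq = np.zeros((aln.ncols, len(aas)))
    gaps = np.zeros(aln.ncols, dtype=int)
    majority: list[str] = []
    major_score = np.zeros(aln.ncols)
    for c in range(aln.ncols):
        col = aln.column(c + 1)
        counts = Counter(col)
        gaps[c] = counts.pop(GAP, 0)
        for k, aa in enumerate(aas):
            freq[c, k] = 100.0 * counts.get(aa, 0) / n
        if counts:
            best = max(sorted(counts), key=counts.get)
            majority.append(best)
            major_score[c] = 100.0 * counts[best] / n
        else:
            majority.append(GAP)
    df = pd.DataFrame(freq, index=pd.RangeIndex(1, aln.ncols + 1, name="msa_number"), columns=aas)
    return ConservationProfile(df, gaps, majority, major_score)


def fully_conserved_columns(aln: AlignedSequenceSet) -> list[int]:
    """MSA numbers where one amino acid occupies every row (no gaps)."""
    out = []
    for c in range(1, aln.ncols + 1):
        col = aln.column(c)
        if GAP not in col and len(set(col)) == 1:
            out.append(c)
    return out


def gap_profile(aln: AlignedSequenceSet) -> tuple[np.ndarray, np.ndarray]:
    """(per-column gap counts, per-row gap totals)."""
    arr = np.array([[ch == GAP for ch in row] for row in aln.rows], dtype=int)
    return arr.sum(axis=0), arr.sum(axis=1)


def pairwise_identity(row_a: str, row_b: str, denominator: str = "union") -> float:
    """Percent identity between two aligned rows.

    ``denominator`` picks the normalization:
      * ``union`` (default): columns where at least one row is non-gap —
        indels count against identity;
      * ``shorter``: ungapped length of the shorter sequence;
      * ``alignment``: full alignment length.
    """
    if len(row_a) != len(row_b):
        raise AlignmentError("rows have different aligned lengths")
    matches = 0
    union = 0
    for a, b in zip(row_a, row_b):
        if a == GAP and b == GAP:
            continue
        union += 1
        if a == b:
            matches += 1
    if union == 0:
        raise AlignmentError("both rows are all-gap")
    if denominator == "union":
        denom = union
    elif denominator == "shorter":
        denom = min(len(row_a.replace(GAP, "")), len(row_b.replace(GAP, "")))
    elif denominator == "alignment":
        denom = len(row_a)
    else:
        raise ValueError(f"unknown denominator {denominator!r}")
    return 100.0 * matches / denom


def identity_matrix(aln: AlignedSequenceSet, denominator: str = "union") -> pd.DataFrame:
    """Symmetric pairwise identity matrix (%), 100 on the diagonal."""
    n = aln.nrows
    mat = np.full((n, n), 100.0)
    for i in range(n):
        for j in range(i + 1, n):
            val = pairwise_identity(aln.rows[i], aln.rows[j], denominator)
            mat[i, j] = mat[j, i] = val
    return pd.DataFrame(mat, index=aln.ids, columns=aln.ids)


def class_average_identity(
    matrix: pd.DataFrame, labels: dict[str, str]
) -> pd.DataFrame:
    """Mean identity per class pair, excluding the diagonal.

    Raises on ids in the matrix without a class label.
    """
    missing = [rid for rid in matrix.index if rid not in labels]
    if missing:
        raise KeyError(f"unlabelled sequences: {missing}")
    classes = sorted(set(labels[rid] for rid in matrix.index))
    out = pd.DataFrame(np.nan, index=classes, columns=classes)
    for ca in classes:
        ids_a = [rid for rid in matrix.index if labels[rid] == ca]
        for cb in classes:
            ids_b = [rid for rid in matrix.index if labels[rid] == cb]
            block = matrix.loc[ids_a, ids_b].to_numpy(copy=True)
            if ca == cb:
                mask = ~np.eye(len(ids_a), dtype=bool)
                vals = block[mask]
            else:
                vals = block.ravel()
            if vals.size:
                out.loc[ca, cb] = float(vals.mean())
    return out


def formal_charge(seq: str, his_positive: bool = False) -> int:
    """Formal charge of an ungapped sequence: #(Lys,Arg) − #(Asp,Glu),
    with His counted +1 only when ``his_positive`` is set."""
    pos = sum(1 for aa in seq if aa in POSITIVE_AA)
    neg = sum(1 for aa in seq if aa in NEGATIVE_AA)
    if his_positive:
        pos += seq.count("H")
    return pos - neg


def charge_by_msa(aln: AlignedSequenceSet, row_id: str, his_positive: bool = False) -> np.ndarray:
    """Per-column charge contribution (+1/0/−1) of one row; 0 at gaps."""
    row = aln.row(row_id)
    out = np.zeros(aln.ncols, dtype=int)
    for c, aa in enumerate(row):
        if aa in POSITIVE_AA or (his_positive and aa == "H"):
            out[c] = 1
        elif aa in NEGATIVE_AA:
            out[c] = -1
    return out


def map_position(aln: AlignedSequenceSet, row_id: str, seq_index: int) -> int:
    """MSA number (1-based column) of the ``seq_index``-th (1-based)
    residue of the ungapped sequence ``row_id``."""
    row = aln.row(row_id)
    count = 0
    for c, aa in enumerate(row, start=1):
        if aa != GAP:
            count += 1
            if count == seq_index:
                return c
    raise IndexError(f"sequence index {seq_index} beyond ungapped length {count}")


def msa_to_seq_position(aln: AlignedSequenceSet, row_id: str, msa_number: int) -> int | None:
    """Inverse of :func:`map_position`; None when the column is a gap in
    that row."""
    row = aln.row(row_id)
    if not 1 <= msa_number <= aln.ncols:
        raise IndexError(f"MSA number {msa_number} outside 1..{aln.ncols}")
    if row[msa_number - 1] == GAP:
        return None
    return sum(1 for aa in row[:msa_number] if aa != GAP)


def conservation_table(aln: AlignedSequenceSet) -> pd.DataFrame:
    """Flat per-column table (one row per MSA number) for TSV export."""
    prof = conservation_profile(aln)
    df = prof.frequencies.copy()
    df["gap_count"] = prof.gap_counts
    df["majority_residue"] = prof.majority_residue
    df["majority_score"] = prof.majority_score
    return df
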