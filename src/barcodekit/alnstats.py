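"""Alignment validation and site-pattern statistics.

Variable and parsimony-informative site counts follow the convention of
distance-era phylogenetics software: gaps and IUPAC ambiguity codes are
excluded from a column's state multiset, so a column is classified on its
unambiguous A/C/G/T residues only.  A ``gap_as_state`` flag treats the gap
as a fifth character state instead.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import cached_property
from typing import Sequence

import numpy as np

from barcodekit.errors import RaggedAlignmentError
from barcodekit.records import SequenceRecord

# Encoding: A,C,G,T -> 0..3; gap -> 4; anything else (ambiguity) -> 5.
_CODE = np.full(256, 5, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i
_CODE[ord("-")] = 4

GAP_CODE = 4
AMBIG_CODE = 5


def encode_sequences(seqs: Sequence[str]) -> np.ndarray:
    """Encode equal-length sequences as a (n, ncols) uint8 matrix."""
    arr = np.frombuffer("".join(seqs).encode("ascii"), dtype=np.uint8)
    return _CODE[arr].reshape(len(seqs), -1)


@dataclass
class Alignment:
    """Rectangular matrix of gapped sequences with per-row metadata."""

    records: list[SequenceRecord]
    ncols: int

    @property
    def nrows(self) -> int:
        return len(self.records)

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def species_of(self) -> dict[str, str]:
        return {r.id: r.species for r in self.records}

    @cached_property
    def matrix(self) -> np.ndarray:
        """Encoded (nrows, ncols) uint8 matrix; cached."""
        return encode_sequences([r.seq for r in self.records])

    def subset(self, ids: Sequence[str]) -> "Alignment":
        wanted = set(ids)
        rows = [r for r in self.records if r.id in wanted]
        return Alignment(rows, self.ncols)

    def resample_columns(self, cols: np.ndarray) -> np.ndarray:
        """Encoded matrix restricted to the given column indices (bootstrap)."""
        return self.matrix[:, cols]


def validate_alignment(rows: Sequence[SequenceRecord]) -> Alignment:
    """Check rectangularity and alphabet; return an :class:`Alignment`.

    Raises :class:`RaggedAlignmentError` naming the first offending row.
    (Alphabet violations are impossible for rows that passed
    :class:`SequenceRecord` construction, which validates characters.)
    """
    if not rows:
        raise ValueError("alignment must have at least one row")
    ncols = len(rows[0].seq)
    for r in rows:
        if len(r.seq) != ncols:
            raise RaggedAlignmentError(
                f"row {r.id!r} has gapped length {len(r.seq)}, expected {ncols}"
            )
    return Alignment(list(rows), ncols)


def _state_counts(aln: Alignment, gap_as_state: bool) -> np.ndarray:
    """Per-column counts of each counted state: shape (n_states, ncols)."""
    m = aln.matrix
    n_states = 5 if gap_as_state else 4
    return np.stack([(m == s).sum(axis=0) for s in range(n_states)])


def count_variable_sites(aln: Alignment, gap_as_state: bool = False) -> int:
    """Columns with >= 2 distinct counted states."""
    if aln.nrows < 2:
        raise ValueError("variable-site count needs at least 2 rows")
    counts = _state_counts(aln, gap_as_state)
    return int(((counts > 0).sum(axis=0) >= 2).sum())


def count_parsimony_informative(aln: Alignment, gap_as_state: bool = False) -> int:
    """Columns with >= 2 counted states each present in >= 2 rows."""
    if aln.nrows < 4:
        return 0
    counts = _state_counts(aln, gap_as_state)
    return int(((counts >= 2).sum(axis=0) >= 2).sum())


def alignment_summary(aln: Alignment, gap_as_state: bool = False) -> dict:
    """The per-locus summary row: aligned length, variable and PI sites."""
    return {
        "aligned_length": aln.ncols,
        "variable_sites": count_variable_sites(aln, gap_as_state),
        "parsimony_informative_sites": count_parsimony_informative(aln, gap_as_state),
    }
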