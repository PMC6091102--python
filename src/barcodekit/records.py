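"""Reading, screening and bookkeeping of species-labelled sequences.

Sequences arrive as FASTA with structured headers (default schema
``species|individual|locus|accession``) or with a TSV metadata sidecar.
Screening mirrors common barcode-study practice: keep records longer than a
minimum number of non-gap bases (strictly more than 300 bp by default) that
carry a voucher/individual identifier.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as BioSeqRecord

from barcodekit.errors import HeaderParseError, SequenceAlphabetError

#: IUPAC nucleotide codes plus gap.
NUCLEOTIDE_ALPHABET = frozenset("ACGTRYSWKMBDHVN-")

#: Unambiguous bases.
CANONICAL_BASES = frozenset("ACGT")

DEFAULT_SCHEMA_FIELDS = ("species", "individual", "locus", "accession")


def normalize_species(name: str) -> str:
    """Normalize a species name: underscores to spaces, collapse whitespace."""
    return re.sub(r"\s+", " ", name.replace("_", " ")).strip()


@dataclass(frozen=True)
class HeaderSchema:
    """Ordered header fields joined by a delimiter.

    Fields beyond ``species`` are optional in the header (trailing fields
    may be omitted); unknown field names raise at construction.
    """

    fields: tuple[str, ...] = DEFAULT_SCHEMA_FIELDS
    delimiter: str = "|"

    def __post_init__(self) -> None:
        known = {"species", "individual", "locus", "accession", "id"}
        bad = [f for f in self.fields if f not in known]
        if bad:
            raise ValueError(f"unknown header schema fields: {bad}")
        if "species" not in self.fields:
            raise ValueError("header schema must include a 'species' field")

    @classmethod
    def from_string(cls, spec: str, delimiter: str = "|") -> "HeaderSchema":
        """Build a schema from e.g. ``"species|individual|locus|accession"``."""
        return cls(tuple(spec.split(delimiter)), delimiter)

    def parse(self, header: str) -> dict[str, str]:
        parts = header.split(self.delimiter)
        if len(parts) > len(self.fields) or not parts[0]:
            raise HeaderParseError(
                f"header {header!r} does not fit schema "
                f"{self.delimiter.join(self.fields)!r}"
            )
        out = {f: "" for f in self.fields}
        for name, value in zip(self.fields, parts):
            out[name] = value.strip()
        if not out["species"]:
            raise HeaderParseError(f"header {header!r} has an empty species field")
        out["species"] = normalize_species(out["species"])
        return out

    def format(self, rec: "SequenceRecord") -> str:
        values = {
            "species": rec.species.replace(" ", "_"),
            "individual": rec.individual,
            "locus": rec.locus,
            "accession": rec.accession,
            "id": rec.id,
        }
        return self.delimiter.join(values[f] for f in self.fields)


@dataclass(frozen=True)
class SequenceRecord:
    """One nucleotide sequence with its species/voucher/locus metadata."""

    id: str
    species: str
    individual: str
    locus: str
    seq: str
    accession: str = ""

    def __post_init__(self) -> None:
        if not self.species:
            raise ValueError(f"record {self.id!r}: species must be non-empty")
        bad = set(self.seq) - NUCLEOTIDE_ALPHABET
        if bad:
            pos = next(i for i, c in enumerate(self.seq) if c in bad)
            raise SequenceAlphabetError(
                f"record {self.id!r}: illegal character {self.seq[pos]!r} "
                f"at position {pos}"
            )

    @property
    def length(self) -> int:
        """Number of non-gap characters."""
        return len(self.seq) - self.seq.count("-")

    @property
    def gapped_length(self) -> int:
        return len(self.seq)

    def replace_seq(self, seq: str) -> "SequenceRecord":
        return SequenceRecord(self.id, self.species, self.individual,
                              self.locus, seq, self.accession)


@dataclass
class Dataset:
    """Single-locus collection of records with a species index.

    Each record id lives in exactly one species bucket; the number of
    individuals is the number of records (one record per individual per
    locus, the convention of barcode-study sample tables).
    """

    records: list[SequenceRecord]
    species_index: dict[str, list[str]] = field(init=False)

    def __post_init__(self) -> None:
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate record ids: {dupes}")
        self.species_index = {}
        for r in self.records:
            self.species_index.setdefault(r.species, []).append(r.id)

    @property
    def n_species(self) -> int:
        return len(self.species_index)

    @property
    def n_individuals(self) -> int:
        return len(self.records)

    def species_of(self) -> dict[str, str]:
        return {r.id: r.species for r in self.records}

    def by_id(self, rec_id: str) -> SequenceRecord:
        for r in self.records:
            if r.id == rec_id:
                return r
        raise KeyError(rec_id)


@dataclass(frozen=True)
class DatasetSummary:
    n_species: int
    n_individuals: int
    per_species_counts: dict[str, int]


def dataset_summary(ds: Dataset) -> DatasetSummary:
    """Species/individual counts in the sample-table convention."""
    counts = {sp: len(ids) for sp, ids in ds.species_index.items()}
    return DatasetSummary(len(counts), sum(counts.values()), counts)


def read_metadata_tsv(path: str | Path) -> dict[str, dict[str, str]]:
    """Read a metadata sidecar (columns: id, species, individual, locus, accession)."""
    out: dict[str, dict[str, str]] = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            if "id" not in row or "species" not in row:
                raise HeaderParseError(
                    f"metadata file {path} must have 'id' and 'species' columns"
                )
            out[row["id"]] = {
                "species": normalize_species(row["species"]),
                "individual": row.get("individual", "") or "",
                "locus": row.get("locus", "") or "",
                "accession": row.get("accession", "") or "",
            }
    return out


def read_fasta(
    path: str | Path,
    schema: HeaderSchema | None = None,
    metadata: Mapping[str, dict[str, str]] | None = None,
    default_locus: str = "",
) -> list[SequenceRecord]:
    """Read species-labelled sequences from FASTA.

    Headers are parsed under ``schema`` unless ``metadata`` (a mapping from
    record id to fields, e.g. from :func:`read_metadata_tsv`) supplies the
    fields instead, in which case the header up to the first whitespace is
    the id.  Sequences are uppercased.  Record ids are made unique by
    construction (``species|individual|locus`` plus a disambiguating index
    if needed).
    """
    schema = schema or HeaderSchema()
    records: list[SequenceRecord] = []
    seen: dict[str, int] = {}
    for entry in SeqIO.parse(str(path), "fasta"):
        header = entry.description.strip()
        seq = str(entry.seq).upper()
        if metadata is not None:
            key = entry.id
            if key not in metadata:
                raise HeaderParseError(f"record {key!r} missing from metadata sidecar")
            fields = dict(metadata[key])
            rec_id = key
        else:
            fields = schema.parse(header)
            rec_id = fields.get("id", "") or "|".join(
                x for x in (fields["species"].replace(" ", "_"),
                            fields.get("individual", ""),
                            fields.get("locus", "") or default_locus)
                if x
            )
        if rec_id in seen:
            seen[rec_id] += 1
            rec_id = f"{rec_id}#{seen[rec_id]}"
        else:
            seen[rec_id] = 0
        records.append(
            SequenceRecord(
                id=rec_id,
                species=fields["species"],
                individual=fields.get("individual", ""),
                locus=fields.get("locus", "") or default_locus,
                accession=fields.get("accession", ""),
                seq=seq,
            )
        )
    return records


def write_fasta(
    records: Iterable[SequenceRecord],
    path: str | Path,
    schema: HeaderSchema | None = None,
) -> None:
    """Write records to FASTA with schema-formatted headers."""
    schema = schema or HeaderSchema()
    bio = [
        BioSeqRecord(Seq(r.seq), id=schema.format(r), description="")
        for r in records
    ]
    SeqIO.write(bio, str(path), "fasta-2line")


@dataclass(frozen=True)
class Rejection:
    record: SequenceRecord
    reason: str


def filter_records(
    records: Sequence[SequenceRecord],
    min_length_exclusive: int = 300,
    require_voucher: bool = True,
) -> tuple[list[SequenceRecord], list[Rejection]]:
    """Apply the screening rules: length strictly above the minimum, voucher present.

    Never fails; returns (kept, rejected-with-reasons) forming a disjoint
    partition of the input.  A record failing both rules is reported with
    the combined reason ``"length;no_voucher"``.
    """
    kept: list[SequenceRecord] = []
    rejected: list[Rejection] = []
    for r in records:
        reasons = []
        if r.length <= min_length_exclusive:
            reasons.append("length")
        if require_voucher and not r.individual:
            reasons.append("no_voucher")
        if reasons:
            rejected.append(Rejection(r, ";".join(reasons)))
        else:
            kept.append(r)
    return kept, rejected
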