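"""Multilocus concatenation by strict intersection of individuals.

Combined candidates (e.g. ITS+matK) are built from the individuals present
in every member locus — no missing-data padding by default, because
combined sample sizes in barcode studies shrink relative to the single
loci.  A gap-fill mode pads absent loci with gaps for exploration.
"""

from __future__ import annotations

from dataclasses import dataclass

from barcodekit.alnstats import Alignment, validate_alignment
from barcodekit.records import Dataset, SequenceRecord


def _key(rec: SequenceRecord, key: str) -> str:
    if key == "individual":
        return rec.individual
    if key == "species+individual":
        return f"{rec.species}|{rec.individual}"
    raise ValueError(f"unknown matching key {key!r}")


def match_individuals(
    datasets: list[Dataset], key: str = "species+individual"
) -> tuple[list[str], dict[int, list[str]]]:
    """Individuals present in every dataset under the matching key.

    Returns (sorted matched keys, per-dataset orphan keys).  A duplicate
    key within one dataset is an error: the strict-intersection join would
    be ambiguous.
    """
    if len(datasets) < 2:
        raise ValueError("matching needs at least 2 datasets")
    keysets = []
    for idx, ds in enumerate(datasets):
        keys = [_key(r, key) for r in ds.records]
        dupes = sorted({k for k in keys if keys.count(k) > 1})
        if dupes:
            raise ValueError(f"dataset {idx}: duplicate keys {dupes}")
        keysets.append(set(keys))
    matched = set.intersection(*keysets)
    orphans = {i: sorted(ks - matched) for i, ks in enumerate(keysets)}
    return sorted(matched), orphans


@dataclass
class ConcatenatedAlignment(Alignment):
    """Alignment of per-locus segments with their column spans.

    ``spans`` are (locus, start, end) in half-open 0-based coordinates,
    tiling [0, ncols).
    """

    spans: list[tuple[str, int, int]] = None


def concatenate(
    alignments: dict[str, Alignment],
    matched: list[str],
    key: str = "species+individual",
    pad_missing: bool = False,
) -> ConcatenatedAlignment:
    """Join per-locus alignments row-wise over the matched individuals.

    Loci are concatenated in the dict's order.  With ``pad_missing`` an
    individual absent from a locus contributes all-gap columns there
    (exploratory mode); otherwise absence is an error.
    """
    if not matched:
        raise ValueError("no matched individuals to concatenate")
    spans: list[tuple[str, int, int]] = []
    start = 0
    by_locus: list[dict[str, SequenceRecord]] = []
    for locus, aln in alignments.items():
        idx = {_key(r, key): r for r in aln.records}
        by_locus.append(idx)
        spans.append((locus, start, start + aln.ncols))
        start += aln.ncols
    rows: list[SequenceRecord] = []
    locus_names = list(alignments)
    for k in matched:
        segments = []
        template: SequenceRecord | None = None
        for (locus, aln), idx in zip(alignments.items(), by_locus):
            rec = idx.get(k)
            if rec is None:
                if not pad_missing:
                    raise ValueError(f"individual {k!r} missing from locus {locus!r}")
                segments.append("-" * aln.ncols)
            else:
                template = template or rec
                segments.append(rec.seq)
        rows.append(
            SequenceRecord(
                id=k.replace(" ", "_"),
                species=template.species,
                individual=template.individual,
                locus="+".join(locus_names),
                seq="".join(segments),
                accession=template.accession,
            )
        )
    aln = validate_alignment(rows)
    return ConcatenatedAlignment(aln.records, aln.ncols, spans=spans)
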