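"""End-to-end evaluation of barcode candidates and ranked reporting.

For every locus, and every requested multilocus combination, the pipeline
runs: screening -> alignment statistics -> K2P distances -> intra/inter
summaries -> barcoding-gap analysis -> leave-one-out identification ->
(bootstrapped) NJ tree -> per-species monophyly.  Each candidate yields
one report row; a stage failure is attached to its row without aborting
the other candidates.  Candidates are ranked by discrimination rate, then
best-close-match correct percentage, then gap width.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from barcodekit._version import __version__ as _pkg_version
from barcodekit.alnstats import alignment_summary, validate_alignment
from barcodekit.distances import (
    PartitionSummary,
    distance_matrix,
    partition_and_summarize,
    partition_distances,
)
from barcodekit.errors import BarcodekitError, ThresholdError
from barcodekit.gap import GapReport, gap_analysis
from barcodekit.identify import (
    IdentificationSummary,
    intraspecific_threshold,
    run_criterion,
    summarize_identification,
)
from barcodekit.multilocus import concatenate, match_individuals
from barcodekit.njtree import (
    bootstrap_support,
    neighbor_joining,
    root_with_outgroup,
    species_monophyly,
    to_newick,
)
from barcodekit.records import Dataset, SequenceRecord, filter_records


@dataclass
class CandidateResult:
    """One evaluated barcode candidate (a locus or a combination)."""

    name: str
    error: str | None = None
    n_species: int = 0
    n_individuals: int = 0
    n_rejected: int = 0
    aligned_length: int = 0
    variable_sites: int | None = None
    parsimony_informative_sites: int | None = None
    intra: PartitionSummary | None = None
    inter: PartitionSummary | None = None
    gap: GapReport | None = None
    identification: dict[str, IdentificationSummary] = field(default_factory=dict)
    threshold_pct: float | None = None
    discrimination_rate: float | None = None
    discrimination_rate_with_singletons: float | None = None
    n_undefined_pairs: int = 0
    bootstrap_completed: int = 0
    bootstrap_skipped: int = 0
    newick: str | None = None

    @property
    def gap_exists(self) -> bool | None:
        return self.gap.gap_exists if self.gap else None

    @property
    def gap_width(self) -> float:
        return self.gap.gap_width if self.gap and self.gap.gap_exists else 0.0


@dataclass
class EvaluationReport:
    rows: list[CandidateResult]
    metadata: dict

    def row(self, name: str) -> CandidateResult:
        for r in self.rows:
            if r.name == name:
                return r
        raise KeyError(name)

    def to_json(self) -> str:
        """Deterministic JSON (sorted keys, NaN rendered as null, no timestamps)."""
        return json.dumps(_jsonable(self), indent=2, sort_keys=True, allow_nan=False)

    def to_dataframe(self) -> pd.DataFrame:
        """One row per candidate, percentages to 2 decimals."""
        rows = []
        for r in self.rows:
            bm = r.identification.get("best_match")
            bcm = r.identification.get("best_close_match")
            asb = r.identification.get("all_species_barcodes")
            rows.append({
                "candidate": r.name,
                "error": r.error or "",
                "n_species": r.n_species,
                "n_individuals": r.n_individuals,
                "aligned_length": r.aligned_length,
                "variable_sites": r.variable_sites,
                "parsimony_informative_sites": r.parsimony_informative_sites,
                "intra_min_pct": _r2(r.intra.min) if r.intra and r.intra.available else None,
                "intra_max_pct": _r2(r.intra.max) if r.intra and r.intra.available else None,
                "intra_mean_pct": _r2(r.intra.mean) if r.intra and r.intra.available else None,
                "inter_min_pct": _r2(r.inter.min) if r.inter and r.inter.available else None,
                "inter_max_pct": _r2(r.inter.max) if r.inter and r.inter.available else None,
                "inter_mean_pct": _r2(r.inter.mean) if r.inter and r.inter.available else None,
                "gap_exists": r.gap_exists,
                "gap_width_pct": _r2(r.gap_width),
                "best_match_correct_pct": _r2(bm.pct_correct) if bm else None,
                "best_close_match_correct_pct": _r2(bcm.pct_correct) if bcm else None,
                "all_species_barcodes_correct_pct": _r2(asb.pct_correct) if asb else None,
                "threshold_pct": _r2(r.threshold_pct) if r.threshold_pct is not None else None,
                "discrimination_pct": _r2(r.discrimination_rate)
                if r.discrimination_rate is not None else None,
            })
        return pd.DataFrame(rows)


def _r2(x: float) -> float | None:
    return None if x is None or (isinstance(x, float) and math.isnan(x)) else round(x, 2)


def _clean(x):
    if isinstance(x, float) and (math.isnan(x) or math.isinf(x)):
        return None
    return x


def _jsonable(obj):
    if isinstance(obj, EvaluationReport):
        return {"metadata": _jsonable(obj.metadata),
                "candidates": [_jsonable(r) for r in obj.rows]}
    if isinstance(obj, CandidateResult):
        d = {k: _jsonable(v) for k, v in vars(obj).items()}
        d["gap_exists"] = obj.gap_exists
        d["gap_width_pct"] = _clean(obj.gap_width)
        return d
    if isinstance(obj, (PartitionSummary, IdentificationSummary)):
        return {k: _clean(v) for k, v in vars(obj).items()}
    if isinstance(obj, GapReport):
        return {
            "intra_available": obj.intra_available,
            "inter_available": obj.inter_available,
            "max_intra_pct": _clean(obj.max_intra),
            "min_inter_pct": _clean(obj.min_inter),
            "gap_exists": obj.gap_exists,
            "gap_width_pct": _clean(obj.gap_width),
            "histogram_intra": list(obj.histogram_intra.counts),
            "histogram_inter": list(obj.histogram_inter.counts),
            "bin_width_pct": obj.histogram_intra.bin_width,
        }
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return _clean(obj)


def _evaluate_candidate(
    name: str,
    records: Sequence[SequenceRecord],
    *,
    already_screened: bool,
    min_length_exclusive: int,
    require_voucher: bool,
    percentile: float,
    bootstrap_replicates: int,
    bin_width: float,
    seed: int,
    outgroup_species: str | None,
) -> CandidateResult:
    res = CandidateResult(name=name)
    if already_screened:
        kept, rejected = list(records), []
    else:
        kept, rejected = filter_records(records, min_length_exclusive, require_voucher)
    res.n_rejected = len(rejected)
    if len(kept) < 2:
        res.error = "fewer than 2 records after screening"
        return res
    ds = Dataset(kept)
    og_ids = {r.id for r in kept if r.species == outgroup_species}
    ingroup = [r for r in kept if r.species != outgroup_species]
    res.n_species = len({r.species for r in ingroup})
    res.n_individuals = len(ingroup)

    aln = validate_alignment(kept)
    res.aligned_length = aln.ncols
    if aln.nrows >= 2:
        stats = alignment_summary(aln)
        res.variable_sites = stats["variable_sites"]
        res.parsimony_informative_sites = stats["parsimony_informative_sites"]

    if len(ingroup) >= 2:
        in_aln = validate_alignment(ingroup)
        dm = distance_matrix(in_aln)
        res.n_undefined_pairs = dm.n_undefined_pairs
        res.intra, res.inter = (s := partition_and_summarize(dm))["intra"], s["inter"]
        res.gap = gap_analysis(partition_distances(dm), bin_width)
        res.identification["best_match"] = summarize_identification(
            run_criterion(dm, "best_match")
        )
        try:
            res.threshold_pct = intraspecific_threshold(dm, percentile)
            for crit in ("best_close_match", "all_species_barcodes"):
                outcomes = run_criterion(dm, crit, res.threshold_pct)
                if any(o is not None for o in outcomes):
                    res.identification[crit] = summarize_identification(outcomes)
        except ThresholdError:
            pass  # no intraspecific pairs: threshold criteria unavailable

    if aln.nrows >= 3:
        if bootstrap_replicates > 0:
            bs = bootstrap_support(aln, bootstrap_replicates, seed)
            tree = bs.tree
            res.bootstrap_completed, res.bootstrap_skipped = bs.n_completed, bs.n_skipped
        else:
            tree = neighbor_joining(distance_matrix(aln))
        if og_ids:
            tree = root_with_outgroup(tree, og_ids)
        else:
            # no outgroup: monophyly is assessed with the NJ join point as root
            tree.is_rooted = True
        res.newick = to_newick(tree)
        species_of = ds.species_of()
        exclude = {outgroup_species} if outgroup_species else set()
        _, res.discrimination_rate = species_monophyly(
            tree, species_of, count_singletons=False, exclude_species=exclude
        )
        _, res.discrimination_rate_with_singletons = species_monophyly(
            tree, species_of, count_singletons=True, exclude_species=exclude
        )
    return res


def run_evaluation(
    loci: dict[str, Sequence[SequenceRecord]],
    combinations: Sequence[tuple[str, ...]] | None = None,
    *,
    already_screened: bool = False,
    min_length_exclusive: int = 300,
    require_voucher: bool = True,
    percentile: float = 95.0,
    bootstrap_replicates: int = 0,
    bin_width: float = 0.05,
    seed: int = 0,
    outgroup_species: str | None = None,
    match_key: str = "species+individual",
) -> EvaluationReport:
    """Evaluate every locus and combination; one report row per candidate.

    ``combinations`` defaults to all unordered pairs of loci.  The
    outgroup species, when named, is kept for tree building and rooting
    but excluded from distance summaries, identification and the
    discrimination denominator.  Deterministic given ``seed``.
    """
    names = list(loci)
    if combinations is None:
        combinations = [
            (names[i], names[j])
            for i in range(len(names)) for j in range(i + 1, len(names))
        ] if len(names) > 1 else []
    opts = dict(
        min_length_exclusive=min_length_exclusive,
        require_voucher=require_voucher,
        percentile=percentile,
        bootstrap_replicates=bootstrap_replicates,
        bin_width=bin_width,
        outgroup_species=outgroup_species,
    )
    rows: list[CandidateResult] = []
    screened: dict[str, list[SequenceRecord]] = {}
    for k, name in enumerate(names):
        try:
            if already_screened:
                screened[name] = list(loci[name])
            else:
                screened[name], _ = filter_records(
                    loci[name], min_length_exclusive, require_voucher)
            rows.append(_evaluate_candidate(
                name, loci[name], already_screened=already_screened,
                seed=seed + k, **opts))
        except (BarcodekitError, ValueError) as exc:
            rows.append(CandidateResult(name=name, error=str(exc)))
    for k, combo in enumerate(combinations):
        cname = "+".join(combo)
        try:
            missing = [c for c in combo if c not in screened]
            if missing:
                raise ValueError(f"member locus failed or absent: {missing}")
            datasets = [Dataset(screened[c]) for c in combo]
            matched, _ = match_individuals(datasets, match_key)
            if not matched:
                raise ValueError("no shared individuals across member loci")
            alns = {c: validate_alignment(screened[c]) for c in combo}
            concat = concatenate(alns, matched, match_key)
            rows.append(_evaluate_candidate(
                cname, concat.records, already_screened=True,
                seed=seed + 1000 + k, **opts))
        except (BarcodekitError, ValueError) as exc:
            rows.append(CandidateResult(name=cname, error=str(exc)))
    metadata = {
        "version": _pkg_version,
        "seed": seed,
        "loci": names,
        "combinations": ["+".join(c) for c in combinations],
        "min_length_exclusive": min_length_exclusive,
        "require_voucher": require_voucher,
        "percentile": percentile,
        "bootstrap_replicates": bootstrap_replicates,
        "bin_width_pct": bin_width,
        "outgroup_species": outgroup_species,
        "match_key": match_key,
    }
    return EvaluationReport(rows, metadata)


def rank_candidates(report: EvaluationReport) -> list[tuple[int, str]]:
    """Rank candidates by (discrimination, best-close-match correct, gap width).

    Returns (rank, candidate-name) pairs, best first; candidates tied on
    the full key share a rank.  Errored rows sort last.
    """
    def sort_key(r: CandidateResult):
        disc = r.discrimination_rate
        bcm = r.identification.get("best_close_match")
        return (
            -(disc if disc is not None and not math.isnan(disc) else -math.inf),
            -(bcm.pct_correct if bcm else -math.inf),
            -r.gap_width,
        )

    ordered = sorted(report.rows, key=sort_key)
    out: list[tuple[int, str]] = []
    rank = 0
    prev_key = None
    for i, r in enumerate(ordered):
        k = sort_key(r)
        if k != prev_key:
            rank = i + 1
            prev_key = k
        out.append((rank, r.name))
    return out
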