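"""Leave-one-out identification success under nearest-neighbour criteria.

Every record in turn is treated as an unknown query against the rest of
the dataset, and scored under three criteria:

* best match — the query's nearest neighbours (exact-distance ties form
  the nearest set) are all conspecific (correct), all heterospecific
  (incorrect), or mixed (ambiguous).
* best close match — as best match, but a query whose nearest neighbour
  lies beyond a distance threshold gets no match at all.  The threshold
  defaults to the 95th percentile of all intraspecific distances.
* all species barcodes — correct only when every conspecific record is
  strictly closer to the query than the closest heterospecific record;
  a tie in that decisive comparison is ambiguous; also threshold-gated.

Distances equal within a small tolerance count as tied, so float noise
cannot manufacture a unique nearest neighbour.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from barcodekit.distances import DistanceMatrix, partition_distances
from barcodekit.errors import ThresholdError

Criterion = Literal["best_match", "best_close_match", "all_species_barcodes"]
Verdict = Literal["correct", "ambiguous", "incorrect", "no_match"]

TIE_TOL = 1e-12


@dataclass(frozen=True)
class MatchOutcome:
    query_id: str
    criterion: Criterion
    verdict: Verdict
    nearest_ids: tuple[str, ...]
    nearest_distance: float  # percent


def _neighbour_distances(query: str, dm: DistanceMatrix) -> tuple[np.ndarray, list[str]]:
    """Defined distances from the query to every other record."""
    qi = dm.index[query]
    d = dm.values[qi].copy()
    others = [i for i in range(len(dm.ids)) if i != qi and not math.isnan(d[i])]
    return d[others], [dm.ids[i] for i in others]


def _tied_verdict(query_sp: str, tied_species: Sequence[str]) -> Verdict:
    con = any(sp == query_sp for sp in tied_species)
    het = any(sp != query_sp for sp in tied_species)
    if con and het:
        return "ambiguous"
    return "correct" if con else "incorrect"


def best_match(query: str, dm: DistanceMatrix, tie_tol: float = TIE_TOL) -> MatchOutcome | None:
    """Score the query by its tied set of nearest neighbours.

    Returns None when every distance from the query is undefined (the
    record cannot be queried and is excluded from summaries).
    """
    dists, ids = _neighbour_distances(query, dm)
    if not ids:
        return None
    dmin = dists.min()
    tied = [ids[k] for k in range(len(ids)) if dists[k] <= dmin + tie_tol]
    verdict = _tied_verdict(dm.species_of[query], [dm.species_of[t] for t in tied])
    return MatchOutcome(query, "best_match", verdict, tuple(sorted(tied)), float(dmin) * 100.0)


def intraspecific_threshold(dm: DistanceMatrix, percentile: float = 95.0) -> float:
    """Percentile of all defined intraspecific distances, in percent.

    Linear interpolation between order statistics.  Raises
    :class:`ThresholdError` when the dataset has no intraspecific pair,
    in which case a manual threshold must be supplied.
    """
    part = partition_distances(dm)
    vals = part.intra_values()
    if not vals:
        raise ThresholdError(
            "no defined intraspecific distances; supply a manual threshold"
        )
    return float(np.percentile(np.asarray(vals), percentile)) * 100.0


def best_close_match(
    query: str, dm: DistanceMatrix, threshold: float, tie_tol: float = TIE_TOL
) -> MatchOutcome | None:
    """Best match gated by a threshold (percent): beyond it, no match."""
    base = best_match(query, dm, tie_tol)
    if base is None:
        return None
    verdict: Verdict = "no_match" if base.nearest_distance > threshold else base.verdict
    return MatchOutcome(query, "best_close_match", verdict, base.nearest_ids,
                        base.nearest_distance)


def all_species_barcodes(
    query: str, dm: DistanceMatrix, threshold: float, tie_tol: float = TIE_TOL
) -> MatchOutcome | None:
    """Score whether the query's whole species forms its best-match set.

    Singleton-species queries (no conspecific record) return None and are
    excluded from this criterion's summary.
    """
    dists, ids = _neighbour_distances(query, dm)
    if not ids:
        return None
    qsp = dm.species_of[query]
    con = [dists[k] for k in range(len(ids)) if dm.species_of[ids[k]] == qsp]
    het = [dists[k] for k in range(len(ids)) if dm.species_of[ids[k]] != qsp]
    if not con:
        return None
    dmin = float(min(dists))
    tied = tuple(sorted(ids[k] for k in range(len(ids)) if dists[k] <= dmin + tie_tol))
    if dmin * 100.0 > threshold:
        return MatchOutcome(query, "all_species_barcodes", "no_match", tied, dmin * 100.0)
    if not het:
        verdict: Verdict = "correct"
    else:
        worst_con, best_het = max(con), min(het)
        if worst_con < best_het - tie_tol:
            verdict = "correct"
        elif abs(worst_con - best_het) <= tie_tol:
            verdict = "ambiguous"
        else:
            verdict = "incorrect"
    return MatchOutcome(query, "all_species_barcodes", verdict, tied, dmin * 100.0)


@dataclass(frozen=True)
class IdentificationSummary:
    criterion: Criterion
    n_queried: int
    n_excluded: int
    pct_correct: float
    pct_ambiguous: float
    pct_incorrect: float
    pct_no_match: float


def run_criterion(
    dm: DistanceMatrix,
    criterion: Criterion,
    threshold: float | None = None,
    tie_tol: float = TIE_TOL,
) -> list[MatchOutcome | None]:
    """Leave-one-out over all records; None entries mark excluded queries."""
    if criterion == "best_match":
        return [best_match(q, dm, tie_tol) for q in dm.ids]
    if threshold is None:
        threshold = intraspecific_threshold(dm)
    fn = best_close_match if criterion == "best_close_match" else all_species_barcodes
    return [fn(q, dm, threshold, tie_tol) for q in dm.ids]


def summarize_identification(
    outcomes: Sequence[MatchOutcome | None],
) -> IdentificationSummary:
    """Percentages of correct/ambiguous/incorrect/no-match over queried records."""
    scored = [o for o in outcomes if o is not None]
    if not scored:
        raise ValueError("no queryable records")
    crit = scored[0].criterion
    n = len(scored)
    tally = {v: 0 for v in ("correct", "ambiguous", "incorrect", "no_match")}
    for o in scored:
        tally[o.verdict] += 1
    return IdentificationSummary(
        crit, n, len(outcomes) - n,
        100.0 * tally["correct"] / n,
        100.0 * tally["ambiguous"] / n,
        100.0 * tally["incorrect"] / n,
        100.0 * tally["no_match"] / n,
    )


def outcomes_to_dataframe(outcomes: Sequence[MatchOutcome | None]) -> pd.DataFrame:
    rows = [
        (o.query_id, o.criterion, o.verdict, ";".join(o.nearest_ids), o.nearest_distance)
        for o in outcomes if o is not None
    ]
    return pd.DataFrame(
        rows, columns=["query", "criterion", "verdict", "nearest_ids", "nearest_distance_pct"]
    )
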