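"""Kimura 2-parameter pairwise distances with pairwise deletion.

For each sequence pair, alignment columns where either member carries a gap
or an ambiguity code are excluded (pairwise deletion).  Over the remaining
sites, P is the proportion of transition differences (A<->G, C<->T) and Q
the proportion of transversion differences, and

    d = -1/2 * ln(1 - 2P - Q) - 1/4 * ln(1 - 2Q)

in substitutions per site.  Pairs with no comparable sites or with a
saturated (non-positive) log argument have an undefined distance, stored as
NaN and excluded from summaries rather than clamped.  Summaries are
reported on a percent scale, matching how barcode studies print them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from barcodekit.alnstats import Alignment, encode_sequences
from barcodekit.errors import UndefinedDistanceError


@dataclass(frozen=True)
class PairwiseCounts:
    """Comparable-site and mismatch counts for one sequence pair."""

    n_sites: int
    transitions: int
    transversions: int

    @property
    def P(self) -> float:
        return self.transitions / self.n_sites if self.n_sites else math.nan

    @property
    def Q(self) -> float:
        return self.transversions / self.n_sites if self.n_sites else math.nan


def pairwise_counts(a: str, b: str) -> PairwiseCounts:
    """Count comparable sites, transitions and transversions for two gapped sequences."""
    if len(a) != len(b):
        raise ValueError(f"gapped lengths differ: {len(a)} vs {len(b)}")
    m = encode_sequences([a, b])
    return _counts_from_rows(m[0], m[1])


def _counts_from_rows(x: np.ndarray, y: np.ndarray) -> PairwiseCounts:
    valid = (x < 4) & (y < 4)
    xv, yv = x[valid], y[valid]
    diff = xv != yv
    # purines are codes 0 (A) and 2 (G): same parity of (code & 1)
    transition = diff & ((xv & 1) == (yv & 1))
    n_ts = int(transition.sum())
    n_diff = int(diff.sum())
    return PairwiseCounts(int(valid.sum()), n_ts, n_diff - n_ts)


def k2p_from_pq(P: float, Q: float) -> float:
    """K2P distance from transition/transversion proportions; NaN if saturated."""
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0.0 or w2 <= 0.0 or math.isnan(w1) or math.isnan(w2):
        return math.nan
    return -0.5 * math.log(w1) - 0.25 * math.log(w2)


def k2p(counts: PairwiseCounts) -> float:
    """K2P distance from pairwise counts; NaN when undefined (saturated or no sites)."""
    if counts.n_sites == 0:
        return math.nan
    return k2p_from_pq(counts.P, counts.Q)


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distance matrix keyed by record id.

    Undefined distances are NaN.  ``species_of`` maps id -> species and
    drives the intra/inter partition.
    """

    ids: list[str]
    values: np.ndarray
    species_of: dict[str, str]
    index: dict[str, int] = field(init=False)

    def __post_init__(self) -> None:
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("distance matrix shape does not match ids")
        self.index = {rid: i for i, rid in enumerate(self.ids)}

    def get(self, a: str, b: str) -> float:
        return float(self.values[self.index[a], self.index[b]])

    def pairs(self) -> Iterator[tuple[str, str, float]]:
        """All unordered pairs (id1, id2, distance), including undefined ones."""
        n = len(self.ids)
        for i in range(n):
            for j in range(i + 1, n):
                yield self.ids[i], self.ids[j], float(self.values[i, j])

    @property
    def n_undefined_pairs(self) -> int:
        iu = np.triu_indices(len(self.ids), k=1)
        return int(np.isnan(self.values[iu]).sum())

    @property
    def is_fully_defined(self) -> bool:
        return self.n_undefined_pairs == 0

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)

    def to_long_dataframe(self) -> pd.DataFrame:
        """Long format: id1, id2, species1, species2, partition, distance."""
        rows = []
        for a, b, d in self.pairs():
            sa, sb = self.species_of[a], self.species_of[b]
            rows.append(
                (a, b, sa, sb, "intra" if sa == sb else "inter", d)
            )
        return pd.DataFrame(
            rows,
            columns=["id1", "id2", "species1", "species2", "partition", "distance"],
        )


def k2p_matrix_from_codes(m: np.ndarray) -> np.ndarray:
    """All-pairs K2P distances from an encoded (n, ncols) uint8 matrix.

    Vectorised row-against-block; NaN marks undefined entries.  This is the
    hot path for bootstrap replicates.
    """
    n = m.shape[0]
    valid = m < 4
    parity = (m & 1).astype(np.uint8)
    d = np.zeros((n, n))
    with np.errstate(divide="ignore", invalid="ignore"):
        for i in range(n - 1):
            both = valid[i] & valid[i + 1:]
            diff = (m[i] != m[i + 1:]) & both
            ts = diff & (parity[i] == parity[i + 1:])
            ns = both.sum(axis=1).astype(float)
            ns[ns == 0] = np.nan
            P = ts.sum(axis=1) / ns
            Q = (diff.sum(axis=1) - ts.sum(axis=1)) / ns
            w1 = 1.0 - 2.0 * P - Q
            w2 = 1.0 - 2.0 * Q
            row = -0.5 * np.log(w1) - 0.25 * np.log(w2)
            row[(w1 <= 0) | (w2 <= 0)] = np.nan
            d[i, i + 1:] = row
            d[i + 1:, i] = row
    return d


def distance_matrix(aln: Alignment) -> DistanceMatrix:
    """K2P distance matrix over all rows of a validated alignment."""
    if aln.nrows < 2:
        raise ValueError("distance matrix needs at least 2 rows")
    return DistanceMatrix(aln.ids, k2p_matrix_from_codes(aln.matrix), aln.species_of())


@dataclass
class DistancePartition:
    """Unordered pairs split into intra- and inter-specific sets."""

    intra: list[tuple[tuple[str, str], float]]
    inter: list[tuple[tuple[str, str], float]]

    def intra_values(self, defined_only: bool = True) -> list[float]:
        return [d for _, d in self.intra if not (defined_only and math.isnan(d))]

    def inter_values(self, defined_only: bool = True) -> list[float]:
        return [d for _, d in self.inter if not (defined_only and math.isnan(d))]


def partition_distances(dm: DistanceMatrix) -> DistancePartition:
    """Split all unordered pairs by whether the two records are conspecific."""
    intra, inter = [], []
    for a, b, d in dm.pairs():
        (intra if dm.species_of[a] == dm.species_of[b] else inter).append(((a, b), d))
    return DistancePartition(intra, inter)


@dataclass(frozen=True)
class PartitionSummary:
    """Min/max/mean of one partition's defined distances, percent scale."""

    available: bool
    n_pairs: int
    n_undefined: int
    min: float = math.nan
    max: float = math.nan
    mean: float = math.nan


def summarize_values(values: Sequence[float], n_total: int) -> PartitionSummary:
    vals = [v for v in values if not math.isnan(v)]
    if not vals:
        return PartitionSummary(False, n_total, n_total - len(vals))
    arr = np.asarray(vals)
    return PartitionSummary(
        True, n_total, n_total - len(vals),
        float(arr.min()) * 100.0, float(arr.max()) * 100.0, float(arr.mean()) * 100.0,
    )


def partition_and_summarize(dm: DistanceMatrix) -> dict[str, PartitionSummary]:
    """Intra- and inter-specific (min, max, mean) on the percent scale.

    Undefined distances are excluded from the summaries (and counted); an
    empty partition yields an unavailable summary, never zeros.
    """
    part = partition_distances(dm)
    return {
        "intra": summarize_values([d for _, d in part.intra], len(part.intra)),
        "inter": summarize_values([d for _, d in part.inter], len(part.inter)),
    }
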