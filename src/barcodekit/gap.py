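"""Barcoding-gap analysis: distance distributions and the min/max gap rule.

A barcoding gap exists when the minimum inter-specific distance strictly
exceeds the maximum intra-specific distance.  Distributions are binned at a
fixed interval (default 0.05 on the percent scale) into half-open bins
[k*w, (k+1)*w); a value on a boundary opens the higher bin.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from barcodekit.distances import DistanceMatrix, DistancePartition


@dataclass(frozen=True)
class Histogram:
    bin_width: float
    counts: tuple[int, ...]

    @property
    def n_values(self) -> int:
        return sum(self.counts)

    def edges(self) -> list[tuple[float, float]]:
        w = self.bin_width
        return [(k * w, (k + 1) * w) for k in range(len(self.counts))]


def histogram(values: Sequence[float], bin_width: float = 0.05) -> Histogram:
    """Bin non-negative values into half-open bins [k*w, (k+1)*w)."""
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    vals = [v for v in values if not math.isnan(v)]
    if any(v < 0 for v in vals):
        raise ValueError("distances must be non-negative")
    if not vals:
        return Histogram(bin_width, ())
    # tiny relative epsilon so a boundary value hit through float division
    # (e.g. 0.15/0.05) still lands in the bin it opens
    idx = np.floor(np.asarray(vals) / bin_width + 1e-9).astype(int)
    counts = np.bincount(idx)
    return Histogram(bin_width, tuple(int(c) for c in counts))


@dataclass
class GapReport:
    """Global gap verdict with the two binned distributions attached."""

    intra_available: bool
    inter_available: bool
    max_intra: float = math.nan   # percent
    min_inter: float = math.nan   # percent
    gap_exists: bool | None = None
    gap_width: float = math.nan   # percent; 0 when no gap
    histogram_intra: Histogram = field(default_factory=lambda: Histogram(0.05, ()))
    histogram_inter: Histogram = field(default_factory=lambda: Histogram(0.05, ()))


def gap_analysis(part: DistancePartition, bin_width: float = 0.05) -> GapReport:
    """Apply the strict min-inter > max-intra rule and attach histograms.

    Distances in ``part`` are in substitutions/site; the report is on the
    percent scale.  A side with no defined distances leaves the report
    marked unavailable on that side and the verdict undecided.
    """
    intra = [d * 100.0 for d in part.intra_values()]
    inter = [d * 100.0 for d in part.inter_values()]
    rep = GapReport(
        intra_available=bool(intra),
        inter_available=bool(inter),
        histogram_intra=histogram(intra, bin_width),
        histogram_inter=histogram(inter, bin_width),
    )
    if intra:
        rep.max_intra = max(intra)
    if inter:
        rep.min_inter = min(inter)
    if intra and inter:
        rep.gap_exists = rep.min_inter > rep.max_intra
        rep.gap_width = rep.min_inter - rep.max_intra if rep.gap_exists else 0.0
    return rep


@dataclass(frozen=True)
class SpeciesGap:
    """Per-species gap: max intra distance vs distance to the nearest non-member."""

    species: str
    n_members: int
    max_intra: float | None      # percent; None for singletons
    min_inter: float | None      # percent; None if no defined inter distance
    local_gap: bool | None       # None when either side is undefined


def per_species_gap(dm: DistanceMatrix) -> list[SpeciesGap]:
    """For each species, its own intra maximum and nearest-neighbour distance.

    A species-level gap for every species does not imply a global gap:
    different species' intra ranges can interleave.
    """
    species = sorted(set(dm.species_of.values()))
    if len(species) < 2:
        raise ValueError("per-species gap needs at least 2 species")
    sp_arr = np.array([dm.species_of[i] for i in dm.ids])
    out = []
    for sp in species:
        mask = sp_arr == sp
        block = dm.values[np.ix_(mask, mask)]
        iu = np.triu_indices(block.shape[0], k=1)
        intra_vals = block[iu]
        intra_vals = intra_vals[~np.isnan(intra_vals)]
        inter_block = dm.values[np.ix_(mask, ~mask)]
        inter_vals = inter_block[~np.isnan(inter_block)]
        max_intra = float(intra_vals.max()) * 100.0 if intra_vals.size else None
        min_inter = float(inter_vals.min()) * 100.0 if inter_vals.size else None
        local = (min_inter > max_intra) if (max_intra is not None and min_inter is not None) else None
        out.append(SpeciesGap(sp, int(mask.sum()), max_intra, min_inter, local))
    return out


def histograms_to_dataframe(rep: GapReport) -> pd.DataFrame:
    """Joint binned table: bin_low, bin_high, count_intra, count_inter."""
    w = rep.histogram_intra.bin_width
    nbins = max(len(rep.histogram_intra.counts), len(rep.histogram_inter.counts))
    rows = []
    for k in range(nbins):
        ci = rep.histogram_intra.counts[k] if k < len(rep.histogram_intra.counts) else 0
        cj = rep.histogram_inter.counts[k] if k < len(rep.histogram_inter.counts) else 0
        rows.append((k * w, (k + 1) * w, ci, cj))
    return pd.DataFrame(rows, columns=["bin_low", "bin_high", "count_intra", "count_inter"])


def plot_distributions(rep: GapReport, path: str) -> None:
    """Save a paired-bar plot of the intra/inter distance distributions."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = histograms_to_dataframe(rep)
    x = df["bin_low"].to_numpy()
    w = rep.histogram_intra.bin_width
    fig, ax = plt.subplots(figsize=(7, 4))
    ax.bar(x, df["count_intra"], width=w * 0.45, align="edge",
           label="intraspecific", color="tab:blue")
    ax.bar(x + w * 0.45, df["count_inter"], width=w * 0.45, align="edge",
           label="interspecific", color="tab:orange")
    ax.set_xlabel("K2P distance (%)")
    ax.set_ylabel("number of pairs")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
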