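"""Species-structured sequence simulation under a two-parameter process.

The generator evolves already-aligned sequences (no indels) along a star
or random-bifurcating species tree, then hangs individuals off their
species ancestor.  Substitutions follow the Kimura two-parameter model
with transition/transversion rate ratio kappa, applied through the exact
finite-time transition probabilities, so the expected K2P distance between
two sequences equals the path length separating them — parameter recovery
by the K2P estimator is then unbiased by construction.

Branch lengths are in expected substitutions per site.  With a star tree,
two individuals of the same species are separated by ``intra_divergence``
and individuals of different species by ``inter_divergence +
intra_divergence`` (the species ancestors are ``inter_divergence`` apart
and each individual lineage adds ``intra_divergence / 2``); the per-pair
expectations are recorded in the dataset's truth block.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from barcodekit.alnstats import Alignment, validate_alignment
from barcodekit.records import Dataset, SequenceRecord

_BASES = np.array(list("ACGT"))
# transition partner of codes A,C,G,T = G,T,A,C
_TS_PARTNER = np.array([2, 3, 0, 1], dtype=np.uint8)
# the two transversion partners of each code
_TV_PARTNERS = np.array([[1, 3], [0, 2], [1, 3], [0, 2]], dtype=np.uint8)


@dataclass(frozen=True)
class LocusConfig:
    name: str
    length: int


@dataclass(frozen=True)
class SimulationConfig:
    """Study-shaped simulation: few individuals per species, low intra- and
    higher inter-specific divergence, an optional distant outgroup."""

    n_species: int = 10
    individuals_per_species: int | tuple[int, ...] = 3
    seq_length: int = 1000
    intra_divergence: float = 0.01
    inter_divergence: float = 0.10
    kappa: float = 2.0
    loci: tuple[LocusConfig, ...] | None = None
    shared_fraction: float = 1.0
    outgroup_divergence: float = 0.30
    include_outgroup: bool = False
    tree_shape: str = "star"  # or "random"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.inter_divergence < self.intra_divergence or self.intra_divergence < 0:
            raise ValueError("need inter_divergence >= intra_divergence >= 0")
        if self.seq_length < 1:
            raise ValueError("seq_length must be >= 1")
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")
        if self.n_species < 1:
            raise ValueError("n_species must be >= 1")
        if not 0.0 <= self.shared_fraction <= 1.0:
            raise ValueError("shared_fraction must be in [0, 1]")
        if self.tree_shape not in ("star", "random"):
            raise ValueError("tree_shape must be 'star' or 'random'")

    def locus_list(self) -> tuple[LocusConfig, ...]:
        return self.loci or (LocusConfig("LOC", self.seq_length),)

    def counts(self) -> tuple[int, ...]:
        if isinstance(self.individuals_per_species, int):
            return (self.individuals_per_species,) * self.n_species
        if len(self.individuals_per_species) != self.n_species:
            raise ValueError("per-species counts must have n_species entries")
        return tuple(self.individuals_per_species)


def k2p_event_probs(t: float, kappa: float) -> tuple[float, float]:
    """Exact (transition, total transversion) substitution probabilities
    after expected divergence t under the two-parameter model.

    Rates are scaled so alpha + 2*beta = 1 substitution/site/unit time;
    inverting these probabilities with the K2P formula returns t exactly.
    """
    beta = 1.0 / (kappa + 2.0)
    alpha = kappa * beta
    p_ts = 0.25 + 0.25 * math.exp(-4.0 * beta * t) - 0.5 * math.exp(-2.0 * (alpha + beta) * t)
    p_tv = 0.5 - 0.5 * math.exp(-4.0 * beta * t)
    return p_ts, p_tv


def evolve(codes: np.ndarray, t: float, kappa: float, rng: np.random.Generator) -> np.ndarray:
    """Evolve an encoded sequence along a branch of expected length t."""
    if t == 0.0:
        return codes.copy()
    p_ts, p_tv = k2p_event_probs(t, kappa)
    u = rng.random(codes.shape[0])
    out = codes.copy()
    ts = u < p_ts
    out[ts] = _TS_PARTNER[codes[ts]]
    tv = (u >= p_ts) & (u < p_ts + p_tv)
    which = rng.integers(0, 2, size=int(tv.sum()))
    out[tv] = _TV_PARTNERS[codes[tv], which]
    return out


def _codes_to_str(codes: np.ndarray) -> str:
    return "".join(_BASES[codes])


@dataclass
class SimulatedDataset:
    """Per-locus aligned records plus the generating truth."""

    records: dict[str, list[SequenceRecord]]  # locus -> records
    truth: dict = field(default_factory=dict)

    def alignment(self, locus: str) -> Alignment:
        return validate_alignment(self.records[locus])

    def dataset(self, locus: str) -> Dataset:
        return Dataset(self.records[locus])

    def ingroup_records(self, locus: str) -> list[SequenceRecord]:
        og = self.truth.get("outgroup_species")
        return [r for r in self.records[locus] if r.species != og]

    def expected_pair_divergence(self, species_a: str, species_b: str) -> float:
        """Truth expectation for a pair of individuals (star tree)."""
        cfg = self.truth["config"]
        if species_a == species_b:
            return cfg.intra_divergence
        og = self.truth.get("outgroup_species")
        if og in (species_a, species_b):
            return cfg.outgroup_divergence + cfg.inter_divergence / 2.0 + cfg.intra_divergence / 2.0
        return cfg.inter_divergence + cfg.intra_divergence


def _species_names(n: int) -> list[str]:
    return [f"Species {i + 1:03d}" for i in range(n)]


def simulate_species_ancestors(
    cfg: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[dict[str, dict[str, np.ndarray]], dict]:
    """Ancestral sequence per species per locus, plus the species tree.

    Star shape: every ancestor sits ``inter_divergence / 2`` from a common
    root (uniform base composition), so each ancestor pair is separated by
    ``inter_divergence`` in expectation.  Random shape: a random ultrametric
    bifurcating tree of depth ``inter_divergence / 2`` (pair separation up
    to ``inter_divergence``).  The outgroup ancestor, when enabled, sits
    ``outgroup_divergence`` from the root.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    names = _species_names(cfg.n_species)
    half = cfg.inter_divergence / 2.0
    ancestors: dict[str, dict[str, np.ndarray]] = {sp: {} for sp in names}
    tree_desc: dict = {"shape": cfg.tree_shape, "depth": half}
    for locus in cfg.locus_list():
        root = rng.integers(0, 4, size=locus.length).astype(np.uint8)
        if cfg.tree_shape == "star" or cfg.n_species == 1:
            for sp in names:
                ancestors[sp][locus.name] = evolve(root, half, cfg.kappa, rng)
        else:
            # random ultrametric splits: every tip ends up exactly `half`
            # below the root, pairwise separation is at most inter_divergence
            def split(members: list[str], seq: np.ndarray, remaining: float) -> None:
                if len(members) == 1:
                    ancestors[members[0]][locus.name] = evolve(seq, remaining, cfg.kappa, rng)
                    return
                child_depth = rng.uniform(0.0, remaining)
                k = int(rng.integers(1, len(members)))
                perm = rng.permutation(len(members))
                left = [members[i] for i in perm[:k]]
                right = [members[i] for i in perm[k:]]
                node = evolve(seq, remaining - child_depth, cfg.kappa, rng)
                split(left, node, child_depth)
                split(right, node, child_depth)
            split(list(names), root, half)
        if cfg.include_outgroup:
            ancestors.setdefault("Outgroup taxon", {})[locus.name] = evolve(
                root, cfg.outgroup_divergence, cfg.kappa, rng
            )
    return ancestors, tree_desc


def evolve_individuals(
    ancestors: dict[str, dict[str, np.ndarray]],
    cfg: SimulationConfig,
    rng: np.random.Generator | None = None,
    tree_desc: dict | None = None,
) -> SimulatedDataset:
    """Hang individuals off their species ancestors and package the records.

    Each individual lineage accrues ``intra_divergence / 2`` expected
    substitutions, independently per locus.  With several loci, a fraction
    ``shared_fraction`` of individuals carries every locus; each remaining
    individual is assigned to one random locus.  The outgroup contributes
    one individual (all loci).
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed + 1)
    names = _species_names(cfg.n_species)
    counts = cfg.counts()
    loci = cfg.locus_list()
    per_locus: dict[str, list[SequenceRecord]] = {lc.name: [] for lc in loci}
    half = cfg.intra_divergence / 2.0
    for sp, n_ind in zip(names, counts):
        for k in range(n_ind):
            voucher = f"V{k + 1:02d}"
            if len(loci) == 1 or rng.random() < cfg.shared_fraction:
                in_loci = [lc.name for lc in loci]
            else:
                in_loci = [loci[int(rng.integers(0, len(loci)))].name]
            for lc in loci:
                if lc.name not in in_loci:
                    continue
                seq = evolve(ancestors[sp][lc.name], half, cfg.kappa, rng)
                per_locus[lc.name].append(
                    SequenceRecord(
                        id=f"{sp.replace(' ', '_')}|{voucher}|{lc.name}",
                        species=sp,
                        individual=voucher,
                        locus=lc.name,
                        seq=_codes_to_str(seq),
                    )
                )
    outgroup_species = None
    if cfg.include_outgroup:
        outgroup_species = "Outgroup taxon"
        for lc in loci:
            seq = ancestors[outgroup_species][lc.name]
            per_locus[lc.name].append(
                SequenceRecord(
                    id=f"Outgroup_taxon|V01|{lc.name}",
                    species=outgroup_species,
                    individual="V01",
                    locus=lc.name,
                    seq=_codes_to_str(seq),
                )
            )
    truth = {
        "config": cfg,
        "species_tree": tree_desc or {"shape": cfg.tree_shape},
        "outgroup_species": outgroup_species,
        "expected_intra": cfg.intra_divergence,
        "expected_inter": cfg.inter_divergence + cfg.intra_divergence,
    }
    return SimulatedDataset(per_locus, truth)


def simulate_dataset(cfg: SimulationConfig) -> SimulatedDataset:
    """One-call generation: ancestors then individuals, seeded from cfg."""
    rng = np.random.default_rng(cfg.seed)
    ancestors, tree_desc = simulate_species_ancestors(cfg, rng)
    return evolve_individuals(ancestors, cfg, rng, tree_desc)


# ---------------------------------------------------------------------------
# Synthetic stand-in for a published accession table
# ---------------------------------------------------------------------------

def emulate_genbank_structure(seed: int = 0) -> SimulatedDataset:
    """SYNTHETIC stand-in reproducing the marginal structure of the
    *Nepenthes* GenBank survey this pipeline was designed around.

    The real accession list is a supplementary file; this generator builds
    a dataset with the same bookkeeping margins so the counting path can
    be exercised end to end: 317 records in total — ITS 183 records / 88
    species, rbcL 33 / 17, matK 101 / 35 — with pairwise shared
    individuals 18 (ITS+rbcL), 78 (ITS+matK), 18 (rbcL+matK) spanning 8,
    24 and 15 species respectively.  Sequences are simulated (length 350,
    above the >300 bp screen) and are NOT the real accessions.
    """
    rng = np.random.default_rng(seed)
    # individual-level locus patterns solving the published margins:
    # pure ITS 93, pure rbcL 3, pure matK 11, ITS+rbcL 12, ITS+matK 72,
    # rbcL+matK 12, all three 6  -> 209 individuals, 317 records
    loci = ("ITS", "rbcL", "matK")
    plan: list[tuple[str, tuple[str, ...]]] = []  # (species, loci of one individual)

    def add(species: str, pattern: tuple[str, ...], n: int) -> None:
        for _ in range(n):
            plan.append((species, pattern))

    sp_id = iter(f"Taxon {i + 1:03d}" for i in range(200))
    triple = [next(sp_id) for _ in range(6)]
    for i, sp in enumerate(triple):
        add(sp, ("ITS", "rbcL", "matK"), 1)
    # 3 pure-rbcL individuals live inside triple species (no new rbcL species)
    for sp in triple[:3]:
        add(sp, ("rbcL",), 1)
    # ITS+rbcL: 12 shared individuals over 2 further species (8 species total)
    for i, sp in enumerate(next(sp_id) for _ in range(2)):
        add(sp, ("ITS", "rbcL"), 6)
    # ITS+matK: 72 shared individuals over 18 further species (24 total)
    for sp in (next(sp_id) for _ in range(18)):
        add(sp, ("ITS", "matK"), 4)
    # rbcL+matK: 12 shared individuals over 9 further species (15 total)
    rm = [next(sp_id) for _ in range(9)]
    for i, sp in enumerate(rm):
        add(sp, ("rbcL", "matK"), 2 if i < 3 else 1)
    # ITS-only species: 62 species holding 93 pure-ITS individuals
    for i, sp in enumerate(next(sp_id) for _ in range(62)):
        add(sp, ("ITS",), 2 if i < 31 else 1)
    # matK-only species: 2 species holding 11 pure-matK individuals
    mk = [next(sp_id) for _ in range(2)]
    add(mk[0], ("matK",), 6)
    add(mk[1], ("matK",), 5)

    species_names = sorted({sp for sp, _ in plan})
    length = 350
    roots = {lc: rng.integers(0, 4, size=length).astype(np.uint8) for lc in loci}
    anc = {
        sp: {lc: evolve(roots[lc], 0.05, 2.0, rng) for lc in loci}
        for sp in species_names
    }
    per_locus: dict[str, list[SequenceRecord]] = {lc: [] for lc in loci}
    counter: dict[str, int] = {}
    acc = iter(range(100001, 100001 + 400))
    for sp, pattern in plan:
        counter[sp] = counter.get(sp, 0) + 1
        voucher = f"V{counter[sp]:02d}"
        for lc in pattern:
            seq = evolve(anc[sp][lc], 0.005, 2.0, rng)
            per_locus[lc].append(
                SequenceRecord(
                    id=f"{sp.replace(' ', '_')}|{voucher}|{lc}",
                    species=sp,
                    individual=voucher,
                    locus=lc,
                    seq=_codes_to_str(seq),
                    accession=f"SYN{next(acc)}",
                )
            )
    truth = {
        "synthetic": True,
        "margins": {
            "total_records": 317,
            "per_locus_records": {"ITS": 183, "rbcL": 33, "matK": 101},
            "per_locus_species": {"ITS": 88, "rbcL": 17, "matK": 35},
            "shared_individuals": {"ITS+rbcL": 18, "ITS+matK": 78, "rbcL+matK": 18},
            "shared_species": {"ITS+rbcL": 8, "ITS+matK": 24, "rbcL+matK": 15},
        },
    }
    return SimulatedDataset(per_locus, truth)
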