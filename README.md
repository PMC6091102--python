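# barcodekit

Evaluation toolkit for candidate DNA barcode loci in plants (and any other
group where short standardized markers such as ITS, *rbcL* and *matK* are
screened for species discrimination).

Given species-labelled, pre-aligned sequences — one FASTA per locus, with
structured headers or a TSV metadata sidecar — the package answers the
question every barcode survey asks: *which locus, or which multilocus
combination, separates species best?*  It does so with the four standard
instruments of the field, for single loci and for strict-intersection
concatenations:

1. **K2P distance partitions.**  Pairwise Kimura 2-parameter distances with
   pairwise deletion of gap/ambiguous sites,

   *d* = −½·ln(1 − 2*P* − *Q*) − ¼·ln(1 − 2*Q*),

   where *P* and *Q* are the transition (A↔G, C↔T) and transversion
   proportions, split into intra- and inter-specific sets and summarised as
   min/max/mean on the percent scale.
2. **Barcoding gap.**  A gap exists when the minimum inter-specific
   distance strictly exceeds the maximum intra-specific distance; binned
   distance distributions (default interval 0.05%) and per-species local
   gaps are reported alongside the global verdict.
3. **Identification success.**  Leave-one-out nearest-neighbour scoring
   under the three TaxonDNA-style criteria — *best match*, *best close
   match* (threshold = 95th percentile of intra-specific distances by
   default), and *all species barcodes* — each query scored correct /
   ambiguous / incorrect / no match, with exact-tie semantics.
4. **Tree-based discrimination.**  Deterministic neighbor-joining on the
   K2P matrix, column-resampling bootstrap support, outgroup rooting, and
   per-species monophyly: the fraction of multi-sampled species that form
   clades is the locus's "ability to discriminate".

A sequence simulator generates species-structured datasets under the exact
two-parameter substitution process the estimator assumes (configurable
intra-/inter-specific divergence, transition/transversion ratio κ, multiple
loci with partial individual overlap, a distant outgroup), so the whole
pipeline is testable without any database download.

## Worked example

Simulate a two-locus survey of 8 species (3 individuals each, intra-specific
divergence 0.01 and inter-specific 0.10 substitutions/site, κ = 2, plus a
distant outgroup) and evaluate both loci and their concatenation:

```python
from barcodekit import run_evaluation, rank_candidates
from barcodekit.simulate import SimulationConfig, LocusConfig, simulate_dataset

cfg = SimulationConfig(
    n_species=8, individuals_per_species=3, seed=11,
    intra_divergence=0.01, inter_divergence=0.10, kappa=2.0,
    loci=(LocusConfig("ITS", 600), LocusConfig("matK", 800)),
    include_outgroup=True,
)
sim = simulate_dataset(cfg)
report = run_evaluation(
    sim.records, outgroup_species="Outgroup taxon",
    bootstrap_replicates=100, seed=1,
)
print(report.to_dataframe()[[
    "candidate", "n_species", "n_individuals", "aligned_length",
    "intra_mean_pct", "inter_mean_pct", "gap_exists", "gap_width_pct",
    "best_close_match_correct_pct", "discrimination_pct"]].to_string(index=False))
for rank, name in rank_candidates(report):
    print(f"{rank}. {name}")
```

prints

```
candidate  n_species  n_individuals  aligned_length  intra_mean_pct  inter_mean_pct  gap_exists  gap_width_pct  best_close_match_correct_pct  discrimination_pct
      ITS          8             24             600            1.01           10.09        True           5.33                         100.0               100.0
     matK          8             24             800            1.08           11.19        True           6.84                         100.0               100.0
 ITS+matK          8             24            1400            1.05           10.71        True           7.53                         100.0               100.0

1. ITS+matK
2. matK
3. ITS
```

The mean intra- and inter-specific distances recover the generating values
(1% and ~11% — the species ancestors are 10% apart and each individual
lineage adds 0.5%); every candidate shows a barcoding gap, whose width
grows with alignment length because longer alignments tighten the distance
estimates; identification and NJ monophyly are perfect in this wide-gap
regime; and the concatenation ranks first on the
(discrimination, identification, gap width) key.

The same stages are available from the shell:

```bash
barcodekit simulate --config cfg.json --seed 11 --out data/
barcodekit filter    --in data/ITS.fasta --min-len 300 --out screened/
barcodekit distances --in data/ITS.fasta --out dist/
barcodekit gap       --in data/ITS.fasta --bin-width 0.05 --out gap/
barcodekit identify  --in data/ITS.fasta --percentile 95 --out id/
barcodekit tree      --in data/ITS.fasta --outgroup "Outgroup taxon" \
                     --bootstrap 1000 --seed 42 --out tree/
barcodekit concat    --loci data/ITS.fasta --loci data/matK.fasta --out comb/
barcodekit evaluate  --config run.json --out results/
```

## Layout

```
src/barcodekit/
  records.py     FASTA/TSV I/O, header schemas, screening, dataset bookkeeping
  alnstats.py    alignment validation, variable / parsimony-informative sites
  distances.py   K2P pairwise distances, intra/inter partitions and summaries
  gap.py         histograms, global and per-species barcoding-gap reports
  identify.py    leave-one-out identification criteria and summaries
  njtree.py      neighbor joining, bootstrap, rooting, monophyly, Newick
  multilocus.py  individual matching and alignment concatenation
  simulate.py    two-parameter sequence simulator and structure emulator
  report.py      orchestration, report rows, candidate ranking
  cli.py         click command-line interface
```

See `docs/methods.md` for the model assumptions, parameter conventions and
numerical choices.
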