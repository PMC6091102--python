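# Methods

This note records the models, conventions and numerical choices behind
each pipeline stage, what the synthetic-data generator does and does not
emulate, and the known limitations.

## Screening and bookkeeping

Records are screened by two rules: non-gap sequence length strictly
greater than a minimum (default 300 bp, so a 300-bp record is rejected),
and presence of a voucher/individual identifier.  "Has a voucher" is
operationalised as a non-empty individual field; no attempt is made to
validate voucher codes against collections.  The length rule applies to
the raw (non-gap) length, not the aligned column count, since screening
conceptually precedes alignment.  Species names are normalised by mapping
underscores to spaces and collapsing repeated whitespace; synonym
resolution against nomenclatural services is out of scope.

Sample-table conventions: one record = one individual at one locus; the
number of individuals of a dataset is its record count, and the number of
species is the number of non-empty species buckets.

## Alignment statistics

The pipeline consumes pre-aligned matrices; it never aligns.  A variable
site is a column with at least two distinct unambiguous states (A/C/G/T);
a parsimony-informative site additionally requires two states each present
in at least two rows.  Gaps and IUPAC ambiguity codes are excluded from a
column's state multiset — the default behaviour of the distance-era MEGA
family of tools — with a `gap_as_state` flag that instead counts the gap
as a fifth state.  Columns that are entirely gap/ambiguous contribute to
the aligned length but to neither count.  With fewer than four rows the
parsimony-informative count is zero by definition.

## K2P distances

For each pair, columns where either sequence carries a gap or ambiguity
code are deleted (pairwise deletion); ambiguity codes never count as
matches or mismatches.  Over the n comparable sites, P = transitions/n,
Q = transversions/n, and

    d = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q)    [substitutions/site]

A pair with n = 0 or with a non-positive log argument (saturation) has an
*undefined* distance, stored as NaN, excluded from every summary, and
counted in the run log — never clamped to a ceiling, because a clamped
value would contaminate means and gap verdicts with an arbitrary constant.
Distances are held in substitutions/site internally; the percent scale is
applied only at reporting time, matching how barcode surveys print their
tables.

## Barcoding gap

The global rule is strict: a gap exists iff min(inter) > max(intra) over
defined distances.  Ties are "no gap".  Distributions are binned at a
fixed interval, default 0.05 on the percent scale (survey figures are
drawn in percent), into half-open bins [k·w, (k+1)·w); a value exactly on
a boundary opens the higher bin.  A 1e-9 absolute epsilon absorbs float
division noise at bin boundaries — distances are O(10%) so this is five
orders below the bin width.  Per-species reports give each species its
own intra maximum and the distance to its nearest non-member; every
species can have a local gap while the global gap fails, because
different species' ranges can interleave.  Group-level (e.g. subgenus)
analyses are supported by running the pipeline on user-defined record
subsets; no taxonomy is hard-coded.

## Identification criteria

All records are queried in turn against the remainder (leave-one-out).
Distances equal within a tolerance (default 1e-12, configurable) are
tied; the tied set of nearest records decides the verdict:

* best match — correct if all tied nearest neighbours are conspecific,
  incorrect if all are heterospecific, ambiguous if mixed;
* best close match — as best match, but no_match when the nearest
  distance exceeds a threshold.  The threshold defaults to the 95th
  percentile (linear interpolation between order statistics) of all
  defined intra-specific distances — the TaxonDNA convention — and is
  always printed in the report so runs are auditable.  With no
  intra-specific pairs the pipeline refuses to invent a threshold and
  asks for a manual one;
* all species barcodes — correct only when every conspecific record is
  strictly closer than the closest heterospecific one; a tie in that
  decisive comparison is ambiguous; also threshold-gated.  Queries from
  singleton species have no conspecifics and are excluded (and counted).

Two limit identities pin the semantics: best close match at threshold +∞
reproduces best match exactly, and raising the threshold moves a verdict
from no_match to the best-match verdict, never through a third state.
Percentages are over queried (non-excluded) records and the denominators
are reported.

## Neighbor joining, bootstrap, monophyly

NJ is the classic agglomeration: join the pair minimising
Q(i,j) = (n-2)·d(i,j) - R(i) - R(j), branch lengths
v_i = d(i,j)/2 + (R_i - R_j)/(2(n-2)), replacement distances
d(u,k) = (d(i,k) + d(j,k) - d(i,j))/2, ending in the standard
trifurcating unrooted representation.  Q-ties are broken toward the
lexicographically smallest pair of minimum tip ids, making the topology
reproducible across platforms.  Negative branch-length estimates are
clamped to zero by default with the total deficit recorded on the tree
(`clamped_deficit`); a flag preserves them unclamped.  On additive
matrices the implementation recovers topology and path lengths exactly
(checked to 1e-10), and it agrees with scikit-bio's independent NJ.

Bootstrap support resamples alignment columns with replacement, rebuilds
K2P + NJ per replicate, and scores each internal bipartition of the
original tree by the percentage of completed replicates containing it.
Replicates with any undefined distance are skipped and counted, and the
support denominator is the number of completed replicates.  Support is
keyed by bipartition (the side not containing a fixed reference tip), so
it survives rerooting.  Rendered Newick shows integer supports at or
above 50% by default, the usual display convention.

Rooting places the root at the midpoint of the edge whose bipartition
equals the outgroup tip set; a non-clade outgroup is an error, not a
silent approximation.  Without an outgroup, monophyly is assessed with
the NJ join point as root (stated in the report).  A species with ≥ 2
tips is monophyletic iff the MRCA of its tips has exactly those tips as
descendants; the discrimination rate is the percentage of monophyletic
species among assessable (≥ 2 tips) species.  Because the convention for
singletons is genuinely open, both rates are always computed: the default
excludes singletons (monophyly of one tip is vacuous) and a companion
figure counts them as monophyletic.

## Multilocus concatenation

Combined candidates are built from the strict intersection of individuals
across member loci, keyed by species+individual by default (a bare
voucher key risks cross-species collisions; both keys are available and
the key used is echoed in the report).  Strict intersection — rather than
gap-padding — is the default because combined sample sizes in barcode
surveys shrink relative to single loci; a `pad_missing` mode gap-fills
absent loci for exploration.  Segments are joined in declared locus
order, with half-open 0-based column spans reported.  Concatenation
commutes with the distance machinery exactly: per-pair comparable sites,
transitions and transversions add across loci (an identity the tests
check), so a concatenated distance is the site-weighted pooling of its
parts.

## The simulator

Sequences evolve along a star (default) or random-bifurcating species
tree under the Kimura two-parameter process with transition/transversion
rate ratio κ, applied through the exact finite-time substitution
probabilities (rates scaled so α + 2β = 1 per unit branch length).  The
K2P estimator inverts those probabilities exactly, so the expected
estimated distance between two sequences equals the path length
separating them — parameter recovery is a clean acceptance surface rather
than an approximation.  The generator produces already-aligned sequences
(no indel process, alignment being out of scope), uniform base
composition, and no rate heterogeneity across sites.

Branch-length conventions: species ancestors sit inter_divergence/2 from
the root (so ancestor pairs are inter_divergence apart in expectation);
each individual lineage adds intra_divergence/2; the outgroup sits
outgroup_divergence from the root.  Hence two conspecific individuals are
intra apart, heterospecific individuals inter + intra apart, and the
outgroup is the most distant tip whenever outgroup_divergence is set well
above inter (default 0.30 vs 0.10).  The defaults — 10 species × 3
individuals, 1000 sites, intra 0.01, inter 0.10, κ = 2 — describe a
marker with a wide barcoding gap and shallow within-species variation,
the regime a usable barcode must occupy.  Multi-locus runs give a
configurable fraction of individuals all loci; the rest carry one random
locus, emulating the patchy locus coverage of database-derived datasets.

What the simulator does *not* emulate — indels and alignment error, rate
variation among sites and lineages, base-composition bias, introgression
or incomplete lineage sorting, misidentified reference sequences — is
exactly what separates its clean results from real surveys.  Passing
tests demonstrate that the pipeline measures what it claims under the
generating model, not that any particular real locus will show a gap.

A separate generator (`emulate_genbank_structure`) is a synthetic
stand-in for a published three-locus accession table: it reproduces the
bookkeeping margins (317 records; ITS 183 records / 88 species, rbcL
33/17, matK 101/35; pairwise shared individuals 18/78/18 over 8/24/15
species) so the counting and matching paths can be exercised end to end.
Its sequences are simulated, not real, and its per-locus species-count
total (140) matches the published figure only under the summation
convention, which cannot be reconciled with the non-empty pairwise
overlaps as a set union — the constructed union is 99 species.

## Orchestration and reporting

`run_evaluation` executes screen → alignment stats → distances →
partition summaries → gap → identification → (bootstrapped) tree →
monophyly per candidate; a stage failure is attached to its row without
aborting other candidates.  The outgroup species is kept for tree
building and rooting but excluded from distance summaries, identification
and the discrimination denominator.  Every numeric cell in the report is
the direct output of one upstream operation — the reporter never
recomputes.  Reports carry the full configuration echo and are
byte-identical across runs at the same seed (no timestamps; JSON with
sorted keys; NaN rendered as null).  Candidates are ranked by
discrimination rate, then best-close-match correct percentage, then gap
width — an explicit convention, since survey prose typically reaches its
recommendation without stating a tie-break order — and ties share a rank.
Percentages in tabular output are rendered to 2 decimals.

## Problem sizes used in the checks

The automated checks run at desk scale, chosen to exercise every code
path with comfortable statistical margins: 1000 random pairs (L =
200–800) for the K2P oracle comparison at 1e-12; 50 random additive
matrices (n = 5–10) for NJ consistency at 1e-10; 20 simulated datasets of
the default configuration for parameter recovery (3-SE bands), gap
detection, identification and monophyly; 100 random fixtures for each
limit identity; and a duplicated 100-replicate bootstrap run for
determinism.  The whole suite and the acceptance script each complete in
well under a minute on one CPU.

## Known limitations

* K2P only; no model selection and no alternative estimators (JC, HKY,
  GTR) — the evaluation design is distance-based by construction.
* No statistical test of distribution overlap beyond the min/max gap
  rule; a single aberrant pair can flip the verdict, which is a property
  of the rule itself.
* NJ only; no likelihood or Bayesian trees, and no tree visualisation
  beyond Newick and a basic histogram plot.
* Monophyly on an unrooted NJ tree without an outgroup depends on the
  arbitrary join-point root; supply an outgroup for defensible rates.
* The identification criteria inherit the reference-library assumption:
  mislabelled references silently degrade "correct" percentages.
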