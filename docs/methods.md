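# Methods

This note documents the models and conventions behind `scatdiet`: what the
synthetic-run generator emulates, how each stage of the read-to-diet workflow
is defined where the field's tool chain leaves choices open, and what the
test suite does and does not establish about real data.

## The experimental design being modelled

A faecal metabarcoding study of two sympatric felids: DNA extracted from
field-collected scats, a ~100 bp hypervariable fragment of the mitochondrial
12S rRNA gene ("12SV5") amplified with vertebrate-universal primers, each
PCR tagged at both 5′ ends with a unique 9-nt tag (`CC` + 7 variable
nucleotides, pairwise Hamming distance ≥ 3), a blocking oligonucleotide
suppressing the predator's own template, seven template-free negative-control
PCRs, and 2 × 100 nt paired-end sequencing so the mates overlap across the
insert. Predator species are confirmed separately from a diagnostic fragment
of the 16S rRNA gene in which the two felids differ at 15 positions.

## Synthetic data generator (`simdata`)

The generator produces a reference database, a tag scheme, per-sample diet
profiles and tagged mate pairs, with per-read ground truth, so that every
downstream stage can be scored exactly.

**Reference database.** Each pool taxon gets a random insert (default length
drawn uniformly from 90–105 nt, inside the 60–120 nt band typical of the
barcode) framed by the exact primer sites and 15-nt random flanks. The upper
default of 105 nt keeps the mate overlap of a 2 × 100 nt run at ≥ 41 nt, so
a clean merge clears the score-40 quality threshold; real 12SV5 inserts sit
in the same ~100 bp range. A predator record and a human record are appended
automatically so that host reads and human contamination are assignable and
removable downstream.

**Diet profiles.** Each sample draws its number of prey taxa uniformly from
`taxa_per_sample_range` (default 1–7, the observed range of taxa per faecal
sample in this kind of study) and its proportions from a symmetric Dirichlet
(concentration `abundance_skew`, default 1.0) floored at
`min_prey_fraction = 0.08` and renormalised:
`p = floor + (1 − k·floor)·Dirichlet`. The floor encodes the assumption that
a prey item present in a faecal sample contributes a non-trivial share of
amplifiable template; numerically it keeps every true item's expected
per-sample count (≥ 0.08 × ~1,400 prey reads ≈ 110 at the default depth of
1,500 reads/sample) well above the 50-read per-sample detection threshold,
so that ground-truth recovery is a meaningful target rather than a coin flip.

**Read model.** The amplicon is
`tag + fwd_primer + insert + revcomp(rev_primer) + revcomp(tag)` (the same
tag on both ends of a PCR, so a tag-jump chimera matches no registered pair);
mate 1 is its first 100 nt, mate 2 the first 100 nt of its reverse
complement. Substitution errors only, uniform across positions at
`per_base_error_rate` (default 1e-3); qualities are two-level, Phred 40
everywhere and 10 at error sites. A `tag_jump_rate` fraction of reads
(default 1 %) is emitted under another random PCR's tag pair. The predator
template makes up `predator_prior_share = 0.6` of amplifiable DNA before
blocking and appears at `share × (1 − blocking_efficiency)` after (default
efficiency 0.9). Human contamination enters every sample at
`contaminant_rate` (default 0.1 %); negative controls receive only a
Poisson-thin spray of contaminant reads drawn uniformly from the taxon pool
plus human.

What the generator does **not** emulate: PCR chimeras between taxa, indel
sequencing errors (off by default), position-dependent quality profiles,
real 12S sequence divergence structure (inserts are random, so inter-taxon
identities are far lower than between congeneric vertebrates), and
amplification bias between taxa. Passing recovery tests therefore
demonstrates the correctness of the pipeline's bookkeeping and filtering
logic under a controlled noise model — not robustness to the full error
structure of a real sequencing run.

## Read cascade (`reads`)

**Merge score.** The merging tools this stage mirrors do not publish their
score formula; here the score is defined as matches − mismatches over the
best ungapped overlap (≥ 10 nt), floored at 0, with the consensus taking the
higher-quality base at disagreements (ties favour mate 1; ties between
offsets favour the smallest). A "quality score < 40" removal therefore
demands a substantial clean overlap; users recalibrating against another
merger should adjust `min_score` accordingly. Same-shape pairs are processed
in a vectorised batch that is tested element-for-element against the scalar
path.

**Boundary semantics.** All removal thresholds are strict as stated: score
40, length 80 bp, dataset-wide count 1,000 and per-sample count 50 are all
*kept*.

**Demultiplexing.** Both orientations of a merged read are checked; tags
must match exactly (any N defeats the match), primer sites tolerate ≤ 2
mismatches (N counts as a mismatch), and tags/primers are trimmed from the
retained insert.

**Denoising.** Within each PCR a directed edge `u → v` is drawn when the
two sequences differ by exactly one substitution or one indel and
`count(v)/count(u) < 0.5`; a sequence with an incoming edge is a variant
("internal"), one with only outgoing edges a "head", an isolated one a
"singleton". Per-PCR statuses are aggregated by majority vote (ties resolve
head > singleton > internal, i.e. towards retention), and aggregate
"internal" sequences are discarded without merging their counts into the
parent (a `merge_variants` mode adds them to the most abundant adjacent
parent instead). The ratio 0.5 and the no-merge default are this package's
choices where the cited tool chain leaves parameters unstated.

## Taxonomic assignment (`assign`)

**Identity** is global-alignment identity: Needleman–Wunsch with match +1,
mismatch 0 and linear gap −1; identity = matches / alignment columns, gap
columns included. Among co-optimal traceback moves the order diagonal → up →
left is fixed, which makes the value reproducible bit-for-bit.

**LCA.** The best-hit set contains every reference species within 1e-9 of
the maximum identity; the provisional assignment is the lowest taxon whose
lineage contains all of them (species → genus → family → order → class, with
a pseudo-root above class).

**Local refinement.** With ≥ 98 % identity: a single local best hit is
assigned at species rank; among tied hits a unique local member wins, several
local members give their LCA. In the 94–98 % band the assignment is the LCA
of the local species among the top hits; a single non-local top hit is
replaced by its alphabetically-first local congener when one exists
(flagged `substituted`), otherwise by the lowest ancestor containing at
least one local species — which can terminate as high as order rank. Below
94 % the sequence is discarded with a machine-readable reason. The clause
"lowest taxon containing all of the species" is implemented over the *local*
members of the tie set, the reading consistent with family-level outcomes
for songbird ties. Note that rules 2 and 3 can sharpen the rank below the
provisional LCA precisely because they inject local-occurrence knowledge;
such assignments are exactly the species-rank outcomes of those rules.

**Per-sample filter.** Removal conditions are OR-combined (the conservative
reading of "< 0.1 % or 50 reads or less than the negative-control count"):
a count is zeroed when it is below 0.1 % of the sample's food-read total
(computed after predator/human removal), below 50 reads, or does not
*exceed* the sequence's maximum count across the negative controls (`≤` —
exact equality removes, again conservative). Reads assigned to the sample's
own predator or to human are removed regardless of count. Samples left
empty are flagged "no food detected" and excluded from diet denominators.

**Collapse.** Single-linkage clustering over pairs with identity ≥ 0.98;
each cluster becomes one discrete taxon labelled by the assignment of its
most abundant member ("relative abundance" read as: the label comes from the
dominant sequence; an abundance-weighted consensus was considered and not
implemented). Clusters mixing assignments from different orders are split by
assigned order with a warning. The collapse runs *after* the ≥ 94 % identity
filter; the alternative order is not distinguishable from the published
description. Collapsing a collapsed table is a no-op.

## Diet statistics (`dietstats`)

All niche indices use `p` = %TX proportions at the discrete-taxon level;
this choice is validated by exact reproduction of the published values from
the packaged occurrence counts (B_A 0.27/0.64, H 2.78/2.80, J 0.77/0.93 for
the leopard cat / golden cat).

- **Wilson intervals** delegate to `statsmodels`' score-interval
  implementation, cross-checked in the tests against direct inversion of the
  score test by bisection.
- **Exact Wilcoxon** builds the full null distribution of W+ (sum of
  positive ranks) over all 2^m sign assignments by dynamic programming on
  doubled ranks (midranks for ties); the two-sided p-value is
  `P(|W+ − R/2| ≥ |w − R/2|)`, valid because the null distribution stays
  symmetric about half the total rank sum even with midranks. The normal
  mode uses the tie-corrected variance and a 0.5 continuity correction, and
  reports a signed Z.
- **Fisher R×C** enumerates every table with the observed margins (network
  recursion with margin-bound pruning) and sums probabilities not exceeding
  the observed table's, with a relative tie tolerance of 1e-12; tables whose
  enumeration would exceed the budget raise an explicit error advising the
  Monte Carlo mode (Patefield sampling via `scipy.stats.random_table`, with
  the (k+1)/(n+1) estimator).
- **Pianka's overlap** significance uses a label-permutation null — group
  labels shuffled across samples, %TX profiles recomputed, overlap compared
  with a ≥ tolerance of 1e-12 — with the (k+1)/(n_perm+1) correction and an
  explicit seed. This is one defensible null among several; the published
  analyses do not name theirs.
- **Altitude classes** are left-closed: [min, 1500), [1500, 2000),
  [2000, 2500), [2500, max]; 1,500 m itself falls in "lower-middle", an
  ambiguity the verbal class definitions leave open. Months 3–5 map to
  spring, 9–11 to autumn, others are excluded with a warning.
- Reported percentages are rounded to integers and indices to two decimals,
  matching conventional presentation; internal values keep full precision.

## Packaged fixture

`load_table1_fixture()` returns the 40 discrete prey taxa of the two-felid
study with occurrence counts in 93 LPC and 10 AGC samples, ranks, lineage
columns and orders. The fixture stores occurrence *counts* only — no
per-sample matrix was published — so statistics that need per-sample rows
(mean taxa per faeces, seasonal or altitudinal splits, overlap permutation
tests) run only on synthetic or user data. Two published round-offs resist
recomputation from the counts (a vole's %FC printed as 40 % against 35/93 ≈
38 %, and a lagomorph %TX printed as 18 % against 71/381 ≈ 19 %); they are
documented here as discrepancies and not asserted anywhere.

## Problem sizes used by the test suite

End-to-end recovery runs at 50 samples × 10 prey taxa × 1,500 reads/sample
(75,000 reads per run). The noise-free configuration must reproduce the
ground-truth occurrence matrix *exactly*; the noisy configuration (0.5 %
per-base error, 1 % tag jumps) must reach a mean per-sample Jaccard
similarity ≥ 0.9 between recovered and true taxon sets over 20 seeded
replicates, and in practice sits at 1.0. Oracle-equivalence suites compare
the exact Wilcoxon against full 2^m enumeration up to m = 12, Fisher R×C
against exact-rational full-table enumeration, alignment identity against a
recursive DP oracle on 500 short pairs, and the denoiser against an
exhaustive pairwise edit-distance oracle on instances of ≤ 12 sequences.

## Known limitations

- The simulator's random reference sequences make taxonomic assignment
  artificially easy (every true taxon is a 100 % identity match); the
  refinement rules are instead exercised directly on hand-built taxonomies
  with controlled identity bands.
- Chimera formation is not modelled or filtered, a deliberate divergence
  from some amplicon pipelines.
- The exact Fisher enumeration is exponential in table size; beyond the
  budget only the Monte Carlo estimate is available.
- Predator identification is implemented against short diagnostic 16S
  fragments; full-length marker analysis is out of scope.
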