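# scatdiet

Faecal-DNA metabarcoding diet analysis for carnivores, end to end: from
tag-multiplexed paired-end amplicon reads, through the standard filter and
denoising cascade, reference-based taxonomic assignment refined by local
species-occurrence knowledge, to dietary composition and niche statistics.
The package targets the kind of study where the vertebrate prey of elusive
predators — here modelled on two sympatric felids, the leopard cat
(*Prionailurus bengalensis*) and the Asiatic golden cat
(*Catopuma temminckii*) in the mountain forests of Southwest China — is read
out of faecal samples with a short mitochondrial 12S barcode (~100 bp,
"12SV5") amplified with per-PCR 9-nt tags and a predator-blocking
oligonucleotide, and sequenced as overlapping 100-nt mate pairs.

It is aimed at molecular ecologists who want a tested, scriptable and fully
reproducible version of this workflow: every stage is a plain Python function
over explicit data types, a synthetic-run generator with per-read ground
truth replaces the raw sequencer output for development and testing, and the
published per-taxon occurrence table for the two felids ships as a packaged
fixture.

## What it computes

**Read cascade** (`scatdiet.reads`): best-overlap mate merging with
quality-weighted consensus; removal of merges scoring `< 40`
(score = matches − mismatches over the overlap); demultiplexing on exactly
matching tag pairs with ≤ 2 primer mismatches; dereplication into unique
sequences with per-PCR counts; removal of sequences `< 80` bp or with
dataset-wide count `< 1,000`; single-variant graph denoising (a sequence one
substitution or indel away from a ≥ 2× more abundant one is a PCR/sequencing
error).

**Taxonomic assignment** (`scatdiet.assign`): reference amplicons cut from
source sequences by in-silico PCR (≤ 3 primer mismatches); global-alignment
identity; best-hit set and lowest-common-ancestor assignment; refinement
against a local species list (species at ≥ 98 % identity to a single local
species; LCA of local tie members otherwise; genus/family/order fallback and
local-congener substitution in the 94–98 % band; discard below 94 %);
per-sample removal of predator/human reads, of counts `< 0.1 %` of the
sample or `< 50` reads, and of anything not exceeding its negative-control
background; collapse of surviving sequences into discrete prey taxa at 2 %
divergence.

**Diet statistics** (`scatdiet.dietstats`), with `p` the %TX
proportion-of-occurrence profile:

- frequency of occurrence `%FC_i = N_i / N` and proportions
  `%TX_i = N_i / Σ_j N_j`;
- Levins' niche breadth `B = 1/Σ p_i²`, standardised
  `B_A = (B − 1)/(n − 1)`;
- Shannon diversity `H = −Σ p_i ln p_i` and Pielou evenness `J = H / ln n`;
- Pianka's niche overlap `O_jk = Σ p_ij p_ik / √(Σ p_ij² Σ p_ik²)` with a
  label-permutation significance test;
- 95 % Wilson score intervals, the exact (full-enumeration) Wilcoxon
  signed-rank test, Fisher's exact test for general R×C tables, and
  season/altitude stratification (altitude classes < 1,500, 1,500–2,000,
  2,000–2,500, > 2,500 m).

## Worked example

The packaged fixture holds the 40 discrete prey taxa identified in 93
leopard-cat (LPC) and 10 Asiatic-golden-cat (AGC) faecal samples, with
occurrence counts, ranks and orders:

```python
from scatdiet import load_table1_fixture, niche_stats, percent_tx, percent_fc

counts, meta = load_table1_fixture()
for col, n in (("lpc", 93), ("agc", 10)):
    c = counts[col]
    ns = niche_stats(c[c > 0])
    tx = percent_tx(c, "order", taxon_meta=meta)
    print(f"{col.upper()}: n_taxa={ns.n}  B={ns.B:.2f}  B_A={ns.B_A:.2f}  "
          f"H={ns.H:.2f}  J={ns.J:.2f}  Rodentia %TX={100*tx['Rodentia']:.0f}%")
print(f"Pika %FC (LPC): {100*percent_fc(counts['lpc'], 'Ochotona spp.', 93):.0f}%")
```

prints

```
LPC: n_taxa=37  B=10.63  B_A=0.27  H=2.78  J=0.77  Rodentia %TX=51%
AGC: n_taxa=20  B=13.17  B_A=0.64  H=2.80  J=0.93  Rodentia %TX=31%
Pika %FC (LPC): 76%
```

i.e. the leopard cat's diet (37 taxa, dominated by rodents at 51 % of all
occurrences and pikas in 76 % of samples) is much less even than the golden
cat's (20 taxa, `B_A` 0.64, evenness 0.93), although the two have almost the
same Shannon diversity.

A full synthetic run — simulate tagged reads with noise, recover the
occurrence matrix, score it against the generator's ground truth — is a few
lines:

```python
from scatdiet import simdata, pipeline

pool = simdata.random_taxa_pool(10, seed=3)
cfg = pipeline.RunConfig(sim=simdata.SimConfig(taxa_pool=pool, n_samples=50, seed=1))
result = pipeline.run_pipeline(cfg)
print(result.ledger.to_frame())          # per-stage casualty counts
print(result.occurrence.matrix.head())   # samples × prey taxa
```

The same stages are exposed on the command line (`scatdiet simulate`,
`scatdiet reads`, `scatdiet stats`, `scatdiet run`, `scatdiet fixture`).

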