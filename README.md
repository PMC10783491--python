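# unmet

Per-base **difficulty-to-sequence scoring** of protein-coding genome
positions from short-read variant-calling evidence.

Clinical short-read sequencing needs to know, at single-nucleotide
resolution, where variant calls cannot be trusted: inside segmental
duplications, tandem repeats, homopolymer runs and other low-mappability
sequence, variant callers systematically produce calls that fail quality
filters. This package derives a percentile-rank **UNMET score** for every
coding (CDS) position by

1. **labeling** positions as *unreliable* or *reliable* from windowed
   variant-filter statistics in a flag-annotated variant catalog (VCF),
2. **extracting** ten per-base genomic features,
3. **training** a gradient-boosted tree classifier to discriminate the two
   classes, and
4. **normalizing** raw predictions to percentile ranks with difficulty
   banding and browser-track export.

It is aimed at method developers and bioinformaticians who want to build
or stress-test such difficulty maps on their own catalogs; a deterministic
synthetic-data module generates a complete toy study (genome with planted
difficult regions, CDS annotation, flagged VCF, coverage track, ground
truth) so the entire pipeline runs and is testable with no downloads.

## The statistics at the core

For a position *p* and window flank *N* = 12 (window size 2*N*+1 = 25 bp):

- **VD** (variant density) = (number of variant records in the closed
  window [*p*−*N*, *p*+*N*]) / (2*N*+1). Records are counted per
  alternate allele.
- **VFR** (variant filter rate) = (filtered records in the window) /
  (all records in the window); undefined when the window has no variants.

A CDS SNV position is labeled **unreliable** (positive) when VFR = 1.0 and
VD ≥ 0.12 — i.e. at least three variants in the 25-bp window, all
filtered — and **reliable** (negative) when VFR = 0.0 and VD ≥ 0.12.
Example: a 25-bp window holding 8 variants of which 2 are filtered has
VD = 8/25 = 0.32 and VFR = 2/8 = 0.25 (and stays unlabeled).

The ten features are: standardized coverage depth |z| (per chromosome),
(K,E)-mappability (1/occurrences of the length-K word within Hamming
distance E on either strand, K = 100, E = 2), homopolymer mask (runs ≥ 7 bp,
±12 bp flank), tandem-repeat mask, interspersed-repeat mask, segmental-
duplication mask, DUST-style low-complexity mask (level 30), structural-
variant mask, %GC and Shannon entropy of the centered 25-bp window.

Balanced classes (negatives down-sampled to the positive count) are split
8:2; hyperparameters are grid-searched with 5-fold cross-validation on
accuracy; the model is evaluated by ROC-AUC and the Matthews correlation
coefficient MCC = (CPU·CPR − PU·PR) / √((CPU+PU)(CPU+PR)(CPR+PU)(CPR+PR)).
Raw scores over all CDS positions become UNMET scores by percentile rank
(fraction of scored positions with raw score ≤ the focal one), banded as
reliable (< 0.93), error-prone ([0.93, 0.97)) and difficult-to-sequence
(≥ 0.97); contiguous difficult runs ≥ 50 nt are exported as BED regions.

## Worked example

Run the full pipeline on the standard synthetic bundle (100-kb genome,
planted duplications/repeats/homopolymers/GC extremes, filter probability
0.95 inside planted regions vs 0.02 outside, seed 1):

```
unmet pipeline --seed 1 --outdir demo/
```

which prints (also stored in `demo/manifest.json`):

```json
{
  "auc": 0.9998016266613767,
  "mcc": 0.9859154929577465,
  "confusion": {"cpu": 141, "cpr": 141, "pu": 1, "pr": 1},
  "median_unmet_inside_planted": 0.9613423503206935,
  "median_unmet_outside_planted": 0.4629256903630948
}
```

Reading the numbers: from 20 717 simulated variants, 709 unreliable and
10 753 reliable positions were labeled; after balancing, 1 134 positions
trained the model and 284 held-out positions evaluated it. Held-out
ROC-AUC 0.9998 and MCC 0.986 mean the classifier recovers the planted
difficulty almost perfectly (1 false positive + 1 false negative among
284). The 74 526 scoreable CDS positions split into 69 309 reliable,
2 915 error-prone and 2 302 difficult positions, and the median UNMET
score is 0.96 inside planted regions versus 0.46 outside. `demo/` also
contains the simulated inputs (`genome.fa`, `cds.bed`, `variants.vcf`,
`coverage.bedgraph`, `truth.bed`) and the exported tracks
(`unmet.bedgraph`, `bands.bed`, `difficult_regions.bed`), which load
directly into IGV or any genome browser.

The same stages are available as library calls (`unmet.run_pipeline`,
`unmet.window_stats`, `unmet.label_sites`, `unmet.mappability`, …) and as
the CLI subcommands `simulate`, `features`, `label`, `train` and `score`
for running individual steps on your own FASTA/BED/VCF/bedGraph inputs.

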