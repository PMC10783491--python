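# Methods

This note documents the models, parameter choices, numerical conventions
and limitations of the package. It states nothing that the test suite or
`scripts/acceptance.py` does not itself compute.

## Windowed variant statistics and labeling

Every statistic is computed over the closed window [p−N, p+N] with
N = 12 (25 bp), the same window used for the sequence features. Variant
density VD = (records in window)/(2N+1); variant filter rate
VFR = (filtered records)/(records), undefined (not 0) when the window is
empty. Conventions:

- **Per-allele counting.** Records are per alternate allele (multi-allelic
  VCF rows are split on read), so a biallelic position contributes 2 to
  VD. This matches how flag-annotated catalogs store one FILTER status
  per allele; it is the main counting ambiguity in this problem and is
  therefore stated prominently.
- **The focal variant counts in its own window.** This makes the labeling
  rule self-consistent: VFR = 1.0 can only hold when the focal variant is
  itself filtered.
- **Fixed denominator at chromosome ends.** Windows overhanging an end are
  truncated for counting but VD keeps denominator 2N+1.
- Labels attach to deduplicated positions, are restricted to CDS SNV
  positions (indel positions are held out for evaluation), and require
  VD ≥ 0.12 — the smallest count satisfying it in a 25-bp window is 3
  variants. Variants outside the CDS (e.g. in exon flanks) still count in
  the windows of CDS positions: they are real observed variants.

## The ten features

| feature | type | convention |
|---|---|---|
| coverage_z | continuous | abs z-value of depth, per chromosome, **population** SD (the whole chromosome track is the population) |
| mappability | continuous | 1/occ of the K-mer at p, K=100, E=2 Hamming, both strands |
| homopolymer | binary | runs ≥ 7 bp of one base, ±12 bp flank |
| tandem | binary | built-in detector (below) or external BED, ±12 bp flank |
| repeatmasker | binary | BED input only (rasterized) |
| segdup | binary | BED input only |
| lcr | binary | DUST-style detector (below) or external BED |
| sv | binary | BED input only |
| gc | continuous | (#G+#C)/25 over the centered window |
| entropy | continuous | Shannon entropy (bits) of A/C/G/T counts over the centered window |

Window anchoring for GC/entropy is **centered** on the scored position
(±12), consistent with the VD/VFR window; trailing windows would be the
other defensible choice and differ only by a 12-bp phase shift.
N handling: N bases occupy window positions but join neither the GC
numerator nor the entropy frequency vector; mappability treats N as
mismatching every symbol including N (conservative and deterministic), and
a window whose occurrence count is 0 under that rule is reported undefined.
Continuous tracks mark positions whose window overruns the chromosome as
NaN; feature-matrix rows containing any NaN are dropped and logged rather
than imputed (no defensible imputation rule exists for these features).

**Mappability algorithm.** occ(p) is the number of length-K windows on
either strand of the whole genome within Hamming distance E of the window
at p; the score is 1/occ ∈ (0,1], 1 ⇔ unique. The search is exact via
pigeonhole seeding: the query is cut into E+1 blocks; any window within
distance E must match ≥ 1 block exactly, so candidates come from hash
lookups of the blocks and are verified by full Hamming comparison. An
all-pairs brute-force implementation is kept as the test oracle; the two
agree exhaustively on kilobase-scale genomes (tests cover K ≤ 30, E ≤ 1
over 200 randomized instances).

**Tandem detector.** Maximal exact tandem arrays with unit length
2–25 bp, at least two full copies and array length ≥ 12 bp, found by the
period-shift equality scan; pure single-base arrays are excluded (they
belong to the homopolymer feature). This is a simplified stand-in for
alignment-based tandem finders: it finds exact arrays only, which is what
binary interval fidelity requires; users with TRF output can pass it as an
override BED, which bypasses the detector entirely.

**Low-complexity detector.** Sliding 64-bp windows are scored by
S = Σ_t c_t(c_t−1)/2 over overlapping-triplet counts c_t, normalized by
(#triplets − 1); a window is masked when S > level/10 with level = 30.
The level/10 scale is the DustMasker convention: at level 30 a random
50%-GC window scores ≈ 0.5 (far below 3.0) while an AAAT-type repeat
scores ≈ 7, so the threshold separates them cleanly. Triplets containing
N are not counted. Interval boundaries of the real DustMasker's
perfect-interval refinement are not reproduced; masked unions agree on
the clear cases, which is what the binary feature needs.

## Classifier

XGBoost gradient-boosted trees (100 trees), single-threaded with fixed
seeds so training is deterministic. Grid search over max_depth {3,4,5,6},
learning_rate {0.1,0.01,0.001}, gamma {0,0.1,0.01}, subsample {0.5,0.8,1},
colsample_bytree {0.5,0.8,1} with stratified 5-fold cross-validation;
selection maximizes **accuracy** (fraction correct at threshold 0.5), and
the selected point is refit on the full training set. A reduced grid
(max_depth {3,5}, learning_rate 0.1, gamma 0, subsample 0.8,
colsample_bytree 0.8) is the default for pipeline runs at toy scale,
where the full 324-point grid adds cost but no discrimination. Trees use
the exact greedy split finder: on small training sets with strongly
separated features, histogram binning can place thresholds at the edge of
the class gap instead of its midpoint, misclassifying margin samples.

Classes are balanced by down-sampling the majority class (seeded), then
split 8:2 stratified (seeded). AUC uses the midrank tie convention (an
all-pairs rank oracle backs it in tests); MCC is computed from the
CPU/CPR/PU/PR cells and defined as 0 with a warning when a denominator
factor is zero; the formula agrees exhaustively with the standard
TP/TN/FP/FN formulation for all count vectors with total ≤ 30.

The leakage check removes test positions whose centered 25-mer matches any
training-position 25-mer at ≥ ⌈0.80·25⌉ = 20 positions, ungapped, on either
strand; 25-mers are too short for gaps to move a call across that
threshold. Logistic-regression and random-forest baselines sit behind the
same train/evaluate interface; single-feature (univariate) models use the
same protocol per feature.

## UNMET score, bands, regions

UNMET(p) = (#scored positions with raw ≤ raw(p)) / (#scored positions),
computed **globally** over all scored CDS positions (per-chromosome
percentiles would make scores incomparable across chromosomes). Ties share
the maximum rank, so the score range is (0, 1] and with distinct raw
scores the ≥ 0.97 band is literally the top 3%. Bands partition the
scored positions: difficult ≥ 0.97, error-prone [0.93, 0.97) (half-open so
the partition is exact), reliable < 0.93. Difficult regions are maximal
runs of **consecutive scored** positions with UNMET ≥ 0.97 and length
≥ 50 nt ("longer than 50 nt" is read as ≥ 50 and exposed as a flag); runs
never cross chromosome boundaries or gaps in scored positions. Indel
evaluation compares UNMET scores at positions with ≥ 2 filtered indel
alleles against all other indel positions with Welch's two-sample t-test
(sample SDs reported). Exports are plain bedGraph/BED; no viewer session
files are generated since the tracks load directly into IGV-class
browsers.

## Synthetic data

The simulator emulates the empirical structure the method learns from and
defines the package's study conditions; defaults are the standard bundle:
100-kb genome in two chromosomes, uniform ~50% GC background with planted
non-overlapping features — 4 exact-copy 800-bp duplications (exact copies
make mappability ground truth analytic; both copies are truth records),
6 tandem arrays (unit 4 bp, 60 bp), 8 homopolymer runs (15 bp),
4 GC-extreme windows (300 bp, alternating 90%/10% GC) — together covering
roughly 10% of the sequence. CDS blocks of 250–450 bp separated by
80–160 bp gaps tile ≳ 70% of each chromosome. Variants land per base with
probability 0.2 (at which ~18% of positions carry at least one variant,
the density regime of large aggregate catalogs); 10% are 1–3 bp indels and
30% of indel sites carry a second allele, so recurrently filtered indel
sites exist at toy scale. Each variant is flagged filtered with
probability 0.95 inside planted regions and 0.02 outside. Coverage is
Gaussian (mean 30, SD 6), multiplied by 0.4 inside planted regions and
clipped at 0. One global seed drives every generator through per-operation
substreams, so outputs are byte-reproducible and independent of call
order. Truth-derived BEDs stand in for the annotation features (segdup
from the planted duplications, interspersed repeats from the planted
repeat classes, an empty structural-variant set).

What the simulator does **not** emulate — realistic mutation spectra,
allele frequencies, haplotype structure, diverged (non-exact) duplication
copies, N gaps, pseudo-autosomal regions, GFF-grade gene models — bounds
what passing tests show: they demonstrate that the pipeline's machinery is
correct and recovers planted structure, not that the learned model
transfers to real catalogs, whose headline metrics depend on
population-scale data.

## Problem sizes and numerical choices

Pipeline runs and tests use the 100-kb standard bundle with the reduced
grid and, in unit tests, an 8-kb bundle with mappability K = 50; oracle
comparisons use kilobase genomes with K ≤ 30 — sizes chosen so exhaustive
brute-force oracles remain feasible while every code path (duplication
hits, seeding, truncation at ends) is exercised. Floating comparisons in
tests use numpy's default relative tolerance; rank and count quantities
are compared exactly. Degenerate inputs are contracts, not accidents:
zero-variance coverage and single-class training sets raise by name,
empty windows yield undefined VFR, a 1-vs-1 training set splits with a
warning, and a constant feature scores AUC 0.5 in the univariate table.

## Known limitations

- Mappability is exact but the seeding index is memory-resident; genomes
  far beyond megabase scale would need an FM-index-backed implementation.
- The tandem and low-complexity detectors are exact-match simplifications
  with override hooks for the external tools' BED output.
- Coverage is consumed as a track; computing it from alignments (BAM
  pileup) is out of scope.
- X/Y pseudo-autosomal special-casing for mappability and coverage
  pooling is not implemented; synthetic genomes have no PARs, and real-
  data users standardizing sex chromosomes should pre-split their tracks.
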