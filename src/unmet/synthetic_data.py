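"""Deterministic simulator of a toy genome with planted difficult regions.

The generator emulates the empirical structure this pipeline is built to
learn from: a reference genome containing segmental duplications (exact
copies, so mappability ground truth is analytic), tandem arrays,
homopolymer runs and GC-extreme windows; a variant catalog whose
filter flags are strongly enriched inside those planted regions; and a
coverage track depressed there. Ground truth (which positions are
difficult and why) is retained so every downstream stage is testable
without any download.

All randomness flows from one global seed; each generator draws from a
substream derived from (seed, operation id), so outputs are
byte-reproducible and independent of call order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io_formats import (
    CoverageTrack,
    FILTERED,
    GenomeSequence,
    IntervalSet,
    PASSED,
    VariantSite,
    make_variant_site,
    write_bed,
    write_bedgraph,
    write_fasta,
    write_vcf,
)

_BASES = "ACGT"

# substream ids: one per generator so outputs don't depend on call order
_GENOME_STREAM = 1
_CDS_STREAM = 2
_VARIANT_STREAM = 3
_COVERAGE_STREAM = 4


@dataclass
class SyntheticConfig:
    """Study conditions for the simulator.

    Defaults give the standard 100-kb bundle: two 50-kb chromosomes with
    planted duplications/repeats covering roughly 10% of the sequence, a
    variant rate of 0.2/bp (matching the density at which ~18% of coding
    positions carry at least one observed variant), filter probability
    0.95 inside difficult regions vs 0.02 outside, and read depth 30x
    depressed to 40% inside difficult regions.
    """

    seed: int = 1
    genome_length: int = 100_000
    n_chromosomes: int = 2
    segdup_count: int = 4
    segdup_length: int = 800
    tandem_count: int = 6
    tandem_period: int = 4
    tandem_length: int = 60
    homopolymer_count: int = 8
    homopolymer_length: int = 15
    gc_window_count: int = 4
    gc_window_length: int = 300
    gc_extreme: float = 0.9
    variant_rate: float = 0.2
    indel_fraction: float = 0.1
    indel_multiallelic: float = 0.3
    p_diff: float = 0.95
    p_bg: float = 0.02
    coverage_mean: float = 30.0
    coverage_sd: float = 6.0
    coverage_depression: float = 0.4

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_bg < self.p_diff <= 1.0):
            raise ValueError("require 0 <= p_bg < p_diff <= 1")
        for name in (
            "genome_length",
            "n_chromosomes",
            "segdup_length",
            "tandem_length",
            "homopolymer_length",
            "gc_window_length",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 <= self.indel_fraction <= 1.0:
            raise ValueError("indel_fraction must be in [0, 1]")
        if not 0.0 <= self.indel_multiallelic <= 1.0:
            raise ValueError("indel_multiallelic must be in [0, 1]")
        if not 0.0 < self.gc_extreme < 1.0:
            raise ValueError("gc_extreme must be in (0, 1)")

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), int(stream)])

    @property
    def chrom_lengths(self) -> dict[str, int]:
        per = self.genome_length // self.n_chromosomes
        return {f"chr{i + 1}": per for i in range(self.n_chromosomes)}


@dataclass
class SyntheticTruth:
    """Planted difficult regions with type labels and per-base truth."""

    regions: IntervalSet
    difficulty: dict[str, np.ndarray] = field(repr=False, default_factory=dict)


def _place(
    rng: np.random.Generator,
    occupied: dict[str, list[tuple[int, int]]],
    lengths: dict[str, int],
    chrom: str,
    size: int,
    margin: int = 30,
) -> int:
    """Pick a start for a plant of ``size`` bp that avoids existing plants."""
    L = lengths[chrom]
    if size + 2 * margin >= L:
        raise ValueError(f"plant of {size} bp exceeds chromosome length {L}")
    for _ in range(500):
        start = int(rng.integers(margin, L - size - margin))
        if all(start + size + margin <= s or start >= e + margin for s, e in occupied[chrom]):
            occupied[chrom].append((start, start + size))
            return start
    raise ValueError(f"could not place a {size}-bp plant on {chrom}; genome too crowded")


def make_genome(config: SyntheticConfig) -> tuple[GenomeSequence, SyntheticTruth]:
    """Random ~50%-GC background with planted difficult regions.

    Segmental duplications are planted as exact copies (two truth records
    per duplication, one per copy); tandem arrays use a random
    non-homopolymeric unit; GC-extreme windows alternate high/low GC.
    """
    rng = config.rng(_GENOME_STREAM)
    lengths = config.chrom_lengths
    chroms = list(lengths)
    arrays = {c: rng.integers(0, 4, size=n, dtype=np.uint8) for c, n in lengths.items()}
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    records: list[tuple[str, int, int, str]] = []

    def next_chrom(i: int) -> str:
        return chroms[i % len(chroms)]

    for i in range(config.homopolymer_count):
        chrom = next_chrom(i)
        size = config.homopolymer_length
        start = _place(rng, occupied, lengths, chrom, size)
        arrays[chrom][start : start + size] = rng.integers(0, 4)
        records.append((chrom, start, start + size, "homopolymer"))

    for i in range(config.tandem_count):
        chrom = next_chrom(i)
        size = config.tandem_length
        start = _place(rng, occupied, lengths, chrom, size)
        period = max(2, config.tandem_period)
        unit = rng.integers(0, 4, size=period, dtype=np.uint8)
        while len(np.unique(unit)) == 1:
            unit = rng.integers(0, 4, size=period, dtype=np.uint8)
        tile = np.tile(unit, size // period + 1)[:size]
        arrays[chrom][start : start + size] = tile
        records.append((chrom, start, start + size, "tandem"))

    for i in range(config.gc_window_count):
        chrom = next_chrom(i)
        size = config.gc_window_length
        start = _place(rng, occupied, lengths, chrom, size)
        gc = config.gc_extreme if i % 2 == 0 else 1.0 - config.gc_extreme
        p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
        arrays[chrom][start : start + size] = rng.choice(4, size=size, p=p).astype(np.uint8)
        records.append((chrom, start, start + size, "gc_extreme"))

    # Duplications last: copy the *final* source content so copies are exact.
    for i in range(config.segdup_count):
        size = config.segdup_length
        chrom_a = next_chrom(i)
        chrom_b = next_chrom(i + 1)
        start_a = _place(rng, occupied, lengths, chrom_a, size)
        start_b = _place(rng, occupied, lengths, chrom_b, size)
        arrays[chrom_b][start_b : start_b + size] = arrays[chrom_a][start_a : start_a + size]
        records.append((chrom_a, start_a, start_a + size, "segdup"))
        records.append((chrom_b, start_b, start_b + size, "segdup"))

    sequences = {
        c: "".join(_BASES[b] for b in arrays[c]) for c in chroms
    }
    genome = GenomeSequence(sequences)
    regions = IntervalSet.from_records(records)
    difficulty = regions.to_mask(lengths)
    return genome, SyntheticTruth(regions=regions, difficulty=difficulty)


def make_cds(genome: GenomeSequence, config: SyntheticConfig) -> IntervalSet:
    """Non-overlapping CDS intervals tiling >= 50% of each chromosome.

    Tiles alternate a short intergenic gap with a CDS block, so planted
    regions are overlapped by CDS intervals with high probability.
    """
    rng = config.rng(_CDS_STREAM)
    records = []
    for chrom, length in genome.lengths.items():
        pos = int(rng.integers(20, 80))
        idx = 0
        while pos < length - 100:
            cds_len = int(rng.integers(250, 451))
            end = min(pos + cds_len, length)
            records.append((chrom, pos, end, f"{chrom}_cds{idx}"))
            idx += 1
            pos = end + int(rng.integers(80, 161))
    return IntervalSet.from_records(records)


def make_variants(
    genome: GenomeSequence, truth: SyntheticTruth, config: SyntheticConfig
) -> list[VariantSite]:
    """Variant catalog: SNVs plus a fraction of 1-3 bp indels.

    Variants land at each base independently with probability
    ``variant_rate``; each is flagged filtered with probability ``p_diff``
    inside planted difficult regions and ``p_bg`` outside — emulating
    catalogs in which all variant calls around a hard-to-map site fail
    quality filters together.
    """
    rng = config.rng(_VARIANT_STREAM)
    sites: list[VariantSite] = []
    for chrom, seq in genome.sequences.items():
        L = len(seq)
        hits = np.flatnonzero(rng.random(L) < config.variant_rate)
        is_indel = rng.random(len(hits)) < config.indel_fraction
        in_truth = truth.difficulty[chrom][hits].astype(bool)
        p_filter = np.where(in_truth, config.p_diff, config.p_bg)
        filtered = rng.random(len(hits)) < p_filter
        for pos, indel, filt, p in zip(hits, is_indel, filtered, p_filter):
            pos = int(pos)
            p = float(p)
            ref_base = seq[pos]
            if ref_base == "N":
                continue
            status = FILTERED if filt else PASSED
            if not indel:
                alt = _BASES[(_BASES.index(ref_base) + int(rng.integers(1, 4))) % 4]
                sites.append(make_variant_site(chrom, pos, ref_base, alt, status))
            else:
                # possibly multi-allelic: a second indel allele mirrors the
                # catalogs in which recurrently filtered indels share a site
                n_alleles = 2 if rng.random() < config.indel_multiallelic else 1
                for j, size in enumerate(rng.permutation(3)[:n_alleles] + 1):
                    size = int(size)
                    st = status if j == 0 else (FILTERED if rng.random() < p else PASSED)
                    if (
                        rng.random() < 0.5
                        and pos + size + 1 <= L
                        and "N" not in seq[pos : pos + size + 1]
                    ):
                        ref = seq[pos : pos + size + 1]  # deletion
                        sites.append(make_variant_site(chrom, pos, ref, ref_base, st))
                    else:
                        ins = "".join(_BASES[b] for b in rng.integers(0, 4, size=size))
                        sites.append(
                            make_variant_site(chrom, pos, ref_base, ref_base + ins, st)
                        )
    sites.sort(key=lambda s: (s.chrom, s.pos, s.ref, s.alt))
    return sites


def make_coverage(
    genome: GenomeSequence, truth: SyntheticTruth, config: SyntheticConfig
) -> CoverageTrack:
    """Gaussian read depth, multiplied by the depression factor inside
    planted regions and clipped at zero."""
    rng = config.rng(_COVERAGE_STREAM)
    depth = {}
    for chrom, length in genome.lengths.items():
        vec = rng.normal(config.coverage_mean, config.coverage_sd, size=length)
        vec = np.where(truth.difficulty[chrom] > 0, vec * config.coverage_depression, vec)
        depth[chrom] = np.clip(vec, 0.0, None)
    return CoverageTrack(depth)


@dataclass
class SyntheticBundle:
    """Everything the pipeline consumes, generated from one config."""

    config: SyntheticConfig
    genome: GenomeSequence
    truth: SyntheticTruth
    cds: IntervalSet
    sites: list[VariantSite]
    coverage: CoverageTrack


def simulate_bundle(config: SyntheticConfig) -> SyntheticBundle:
    genome, truth = make_genome(config)
    cds = make_cds(genome, config)
    sites = make_variants(genome, truth, config)
    coverage = make_coverage(genome, truth, config)
    return SyntheticBundle(config, genome, truth, cds, sites, coverage)


def write_bundle(bundle: SyntheticBundle, outdir: str | Path) -> dict[str, Path]:
    """Write the bundle as FASTA + BED (CDS, truth) + VCF + bedGraph."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "genome": outdir / "genome.fa",
        "cds": outdir / "cds.bed",
        "truth": outdir / "truth.bed",
        "variants": outdir / "variants.vcf",
        "coverage": outdir / "coverage.bedgraph",
    }
    write_fasta(bundle.genome, paths["genome"])
    write_bed(bundle.cds, paths["cds"])
    write_bed(bundle.truth.regions, paths["truth"])
    write_vcf(bundle.sites, bundle.genome, paths["variants"])
    write_bedgraph(bundle.coverage, paths["coverage"])
    return paths
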