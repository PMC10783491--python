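"""Sequence-derived features against direct-counting and brute-force
oracles, plus the structural properties of masks and mappability."""

import numpy as np
import pytest

from unmet import io_formats as io
from unmet import sequence_features as sf

from conftest import random_genome

P = sf.FeatureParams  # shorthand


def genome_of(seq: str, name: str = "c") -> io.GenomeSequence:
    return io.GenomeSequence({name: seq})


# ---------------------------------------------------------------------------
# GC content and entropy
# ---------------------------------------------------------------------------


def test_gc_saturation_and_zero():
    params = P(kmer_length=5)
    assert sf.gc_content(genome_of("G" * 25), params).data["c"][12] == 1.0
    assert sf.gc_content(genome_of("A" * 25), params).data["c"][12] == 0.0


def test_gc_ends_undefined():
    track = sf.gc_content(genome_of("ACGT" * 10), P(kmer_length=5))
    vec = track.data["c"]
    assert np.isnan(vec[:12]).all() and np.isnan(vec[-12:]).all()
    assert not np.isnan(vec[12:-12]).any()


def test_gc_matches_counting_oracle():
    rng = np.random.default_rng(11)
    seq = random_genome(rng, 300, "ACGTN")
    vec = sf.gc_content(genome_of(seq), P(kmer_length=5)).data["c"]
    for p in rng.integers(12, 288, size=40):
        window = seq[p - 12 : p + 13]
        expected = (window.count("G") + window.count("C")) / 25
        assert vec[p] == pytest.approx(expected)


def test_gc_plus_at_is_one_on_n_free_windows():
    rng = np.random.default_rng(12)
    seq = random_genome(rng, 200)
    vec = sf.gc_content(genome_of(seq), P(kmer_length=5)).data["c"]
    at = np.array(
        [(seq[p - 12 : p + 13].count("A") + seq[p - 12 : p + 13].count("T")) / 25
         for p in range(12, 188)]
    )
    assert np.allclose(vec[12:188] + at, 1.0)


def test_entropy_homopolymer_window_is_zero():
    assert sf.sequence_entropy(genome_of("T" * 25), P(kmer_length=5)).data["c"][12] == 0.0


def test_entropy_near_uniform_window():
    # 25-mer of repeated ACGT has counts (7, 6, 6, 6)
    seq = ("ACGT" * 7)[:25]
    value = sf.sequence_entropy(genome_of(seq), P(kmer_length=5)).data["c"][12]
    counts = np.array([7, 6, 6, 6]) / 25
    expected = float(-(counts * np.log2(counts)).sum())
    assert value == pytest.approx(expected)
    assert value == pytest.approx(1.9966, abs=1e-4)


def test_entropy_bounded_zero_two():
    rng = np.random.default_rng(13)
    seq = random_genome(rng, 500, "ACGTN")
    vec = sf.sequence_entropy(genome_of(seq), P(kmer_length=5)).data["c"]
    defined = vec[~np.isnan(vec)]
    assert ((defined >= 0) & (defined <= 2)).all()


# ---------------------------------------------------------------------------
# Homopolymer mask
# ---------------------------------------------------------------------------


def test_homopolymer_seven_run_masks_31_positions():
    seq = ("ACGC" * 10) + "TTTTTTT" + ("GACA" * 10)  # run flanked by C and G
    mask = sf.homopolymer_mask(genome_of(seq), P(kmer_length=5)).data["c"]
    assert int(mask.sum()) == 7 + 12 + 12
    assert mask[40 - 12 : 40 + 7 + 12].all()


def test_homopolymer_six_run_not_masked():
    seq = ("ACGC" * 10) + "TTTTTT" + ("GACA" * 10)
    mask = sf.homopolymer_mask(genome_of(seq), P(kmer_length=5)).data["c"]
    assert int(mask.sum()) == 0


def test_homopolymer_run_at_origin_clipped():
    seq = "A" * 8 + ("CGTG" * 10)
    mask = sf.homopolymer_mask(genome_of(seq), P(kmer_length=5)).data["c"]
    assert mask[0] == 1 and int(mask.sum()) == 8 + 12


def test_flank_extension_monotone():
    rng = np.random.default_rng(14)
    seq = random_genome(rng, 400) + "A" * 9 + random_genome(rng, 100)
    g = genome_of(seq)
    m1 = sf.homopolymer_mask(g, P(kmer_length=5, mask_flank=3)).data["c"]
    m2 = sf.homopolymer_mask(g, P(kmer_length=5, mask_flank=12)).data["c"]
    assert (m2 >= m1).all()


# ---------------------------------------------------------------------------
# Tandem repeats
# ---------------------------------------------------------------------------


def brute_force_tandem_mask(seq: str, max_period: int, min_len: int) -> np.ndarray:
    """Independent per-position scan for membership in an exact tandem array."""
    L = len(seq)
    mask = np.zeros(L, dtype=np.uint8)
    for p in range(2, max_period + 1):
        for s in range(L - 2 * p + 1):
            e = s + p
            while e < L and seq[e] == seq[e - p]:
                e += 1
            if e - s >= max(2 * p, min_len) and len(set(seq[s:e])) > 1:
                mask[s:e] = 1
    return mask


def test_tandem_period_two_detected():
    arrays = sf.tandem_repeat_arrays(genome_of("ACACACACACAC"), P(kmer_length=5))
    assert [(iv.start, iv.end) for iv in arrays] == [(0, 12)]


def test_pure_homopolymer_excluded_from_tandem():
    arrays = sf.tandem_repeat_arrays(genome_of("A" * 30), P(kmer_length=5))
    assert len(arrays) == 0


def test_tandem_override_bypasses_detector():
    g = genome_of("ACACACACACAC" + "G" * 50)
    override = io.IntervalSet.from_records([("c", 30, 40)])
    mask = sf.tandem_repeat_mask(g, P(kmer_length=5), override=override).data["c"]
    expected = np.zeros(62, dtype=np.uint8)
    expected[30 - 12 : 40 + 12] = 1
    assert (mask == expected).all()


def test_tandem_detector_matches_brute_force():
    rng = np.random.default_rng(15)
    for _ in range(10):
        pieces = [random_genome(rng, 150)]
        unit = random_genome(rng, int(rng.integers(2, 8)))
        if len(set(unit)) > 1:
            pieces.append(unit * int(rng.integers(3, 8)))
        pieces.append(random_genome(rng, 150))
        seq = "".join(pieces)
        params = P(kmer_length=5, mask_flank=0)
        got = sf.tandem_repeat_mask(genome_of(seq), params).data["c"]
        expected = brute_force_tandem_mask(
            seq, params.tandem_max_period, params.tandem_min_length
        )
        assert (got == expected).all()


# ---------------------------------------------------------------------------
# Low complexity (DUST-style)
# ---------------------------------------------------------------------------


def dust_window_score(seq: str) -> float:
    triplets = [seq[i : i + 3] for i in range(len(seq) - 2) if "N" not in seq[i : i + 3]]
    counts: dict[str, int] = {}
    for t in triplets:
        counts[t] = counts.get(t, 0) + 1
    s = sum(c * (c - 1) // 2 for c in counts.values())
    return s / (len(triplets) - 1)


def test_low_complexity_repeat_masked_at_level_30():
    seq = "AAAT" * 16  # one 64-bp window
    assert dust_window_score(seq) > 3.0  # oracle confirms above level 30
    mask = sf.low_complexity_mask(genome_of(seq), P(kmer_length=5)).data["c"]
    assert mask.all()


def test_low_complexity_random_sequence_unmasked():
    rng = np.random.default_rng(16)
    seq = random_genome(rng, 400)
    for i in range(0, 400 - 64):  # oracle: every window far below threshold
        assert dust_window_score(seq[i : i + 64]) < 3.0
    mask = sf.low_complexity_mask(genome_of(seq), P(kmer_length=5)).data["c"]
    assert int(mask.sum()) == 0


def test_low_complexity_matches_windowed_oracle():
    rng = np.random.default_rng(17)
    seq = random_genome(rng, 200) + "ATATATAT" * 12 + random_genome(rng, 200)
    mask = sf.low_complexity_mask(genome_of(seq), P(kmer_length=5)).data["c"]
    expected = np.zeros(len(seq), dtype=np.uint8)
    for i in range(len(seq) - 64 + 1):
        if dust_window_score(seq[i : i + 64]) > 3.0:
            expected[i : i + 64] = 1
    assert (mask == expected).all()


def test_low_complexity_override():
    g = genome_of("ACGT" * 30)
    override = io.IntervalSet.from_records([("c", 20, 30)])
    mask = sf.low_complexity_mask(g, P(kmer_length=5, mask_flank=0), override=override)
    expected = np.zeros(120, dtype=np.uint8)
    expected[20:30] = 1
    assert (mask.data["c"] == expected).all()


# ---------------------------------------------------------------------------
# Mappability
# ---------------------------------------------------------------------------


def test_mappability_unique_genome_is_one():
    rng = np.random.default_rng(18)
    seq = random_genome(rng, 300)
    params = P(kmer_length=20, error_budget=0)
    track = sf.mappability(genome_of(seq), params).data["c"]
    oracle = sf.mappability_bruteforce(genome_of(seq), params).data["c"]
    assert np.allclose(track, oracle, equal_nan=True)
    if (oracle[~np.isnan(oracle)] == 1.0).all():  # seed chosen gives unique k-mers
        assert (track[~np.isnan(track)] == 1.0).all()


def test_mappability_exact_duplication_halves_score():
    rng = np.random.default_rng(19)
    s = random_genome(rng, 200)
    genome = genome_of(s + s)
    params = P(kmer_length=20, error_budget=0)
    track = sf.mappability(genome, params).data["c"]
    # interior windows fully inside either copy occur exactly twice
    assert np.allclose(track[:181], 0.5)
    assert np.allclose(track[200:381], 0.5)


def test_mappability_matches_bruteforce_with_errors():
    rng = np.random.default_rng(20)
    s = random_genome(rng, 400)
    mutated = list(s)
    mutated[50] = "T" if s[50] != "T" else "A"  # near-copy within Hamming 1
    genome = io.GenomeSequence({"c1": s, "c2": "".join(mutated)})
    params = P(kmer_length=15, error_budget=1)
    got = sf.mappability(genome, params)
    expected = sf.mappability_bruteforce(genome, params)
    for chrom in genome.chromosomes:
        assert np.allclose(got.data[chrom], expected.data[chrom], equal_nan=True)


def test_mappability_tail_undefined_and_k_too_large():
    seq = "ACGTACGTACGT"
    track = sf.mappability(genome_of(seq), P(kmer_length=8, error_budget=0)).data["c"]
    assert np.isnan(track[-7:]).all() and not np.isnan(track[:5]).any()
    with pytest.raises(ValueError, match="exceeds length"):
        sf.mappability(genome_of(seq), P(kmer_length=50, error_budget=0))


def test_mappability_invariant_under_reverse_complement():
    rng = np.random.default_rng(21)
    s = random_genome(rng, 150)
    genome = genome_of(s + s[:60])  # some repetition
    params = P(kmer_length=12, error_budget=1)
    fwd = sf.mappability(genome, params).data["c"]
    rc = sf.mappability(genome.reverse_complemented(), params).data["c"]
    # position p maps to L-K-p on the reverse-complemented genome
    L, K = len(genome.sequences["c"]), params.kmer_length
    defined = slice(0, L - K + 1)
    assert np.allclose(fwd[defined], rc[defined][::-1])


def test_binary_mask_intervals_round_trip(small_bundle, small_params):
    mask = sf.homopolymer_mask(small_bundle.genome, small_params)
    ivs = mask.as_intervals()
    raster = ivs.to_mask(small_bundle.genome.lengths)
    for chrom, vec in mask.data.items():
        assert (raster[chrom] == vec).all()
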