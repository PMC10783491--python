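"""Per-base features computed from the genome sequence alone.

Six of the ten classifier features come straight from the reference
sequence: %GC and Shannon entropy of the centered 25-bp window,
homopolymer and tandem-repeat masks (both flank-extended), a DUST-style
low-complexity mask, and (K,E)-mappability — the reciprocal of the number
of length-K genome windows on either strand within Hamming distance E of
the window starting at each position.

Continuous tracks use NaN as the explicit undefined marker (window
overruns a chromosome end); binary masks are plain 0/1 vectors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .io_formats import (
    GenomeSequence,
    IntervalSet,
    N_CODE,
    reverse_complement_codes,
)

logger = logging.getLogger("unmet")


@dataclass
class FeatureParams:
    """Tunable parameters of the sequence-derived features.

    flank
        Half-width N of the scoring window; the window is 2N+1 bases
        centered on the scored position (default 12, i.e. 25 bp). The
        same window is used for GC, entropy, and the variant statistics.
    kmer_length, error_budget
        Mappability word length K and allowed mismatches E (defaults 100/2).
    homopolymer_min_run
        Minimum single-base run length masked as a homopolymer (default 7).
    mask_flank
        Flank added to homopolymer/tandem (and override-BED) masks, default 12.
    dust_level
        Low-complexity level threshold; a 64-bp window is masked when its
        normalized triplet score Σc(c−1)/2 / (k−1) exceeds level/10.
    tandem_max_period, tandem_min_length
        Built-in tandem detector caps: repeat unit length ≤ max period and
        total array length ≥ min length (and ≥ two full copies).
    """

    flank: int = 12
    kmer_length: int = 100
    error_budget: int = 2
    homopolymer_min_run: int = 7
    mask_flank: int = 12
    dust_level: float = 30.0
    tandem_max_period: int = 25
    tandem_min_length: int = 12

    def __post_init__(self) -> None:
        if self.flank < 1:
            raise ValueError("flank must be >= 1")
        if not self.kmer_length > self.error_budget >= 0:
            raise ValueError("require K > E >= 0")
        if self.homopolymer_min_run < 2:
            raise ValueError("homopolymer_min_run must be >= 2")
        if self.dust_level <= 0:
            raise ValueError("dust_level must be > 0")
        if self.mask_flank < 0:
            raise ValueError("mask_flank must be >= 0")

    @property
    def window(self) -> int:
        """Full window width 2N+1."""
        return 2 * self.flank + 1


@dataclass
class PerBaseTrack:
    """One value per base per chromosome; NaN marks undefined positions."""

    data: dict[str, np.ndarray]
    binary: bool = False

    def __post_init__(self) -> None:
        if self.binary:
            for chrom, vec in self.data.items():
                vals = np.unique(vec)
                if not np.isin(vals, [0, 1]).all():
                    raise ValueError(f"binary track for {chrom} has values outside {{0,1}}")

    @property
    def lengths(self) -> dict[str, int]:
        return {chrom: len(v) for chrom, v in self.data.items()}

    def as_intervals(self, name: str = "") -> IntervalSet:
        """Maximal runs of 1s of a binary mask as an IntervalSet."""
        if not self.binary:
            raise ValueError("as_intervals only applies to binary tracks")
        records = []
        for chrom in sorted(self.data):
            vec = np.asarray(self.data[chrom]) != 0
            if not vec.any():
                continue
            padded = np.concatenate([[False], vec, [False]])
            edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
            for s, e in zip(edges[::2], edges[1::2]):
                records.append((chrom, int(s), int(e), name))
        if not records:
            return IntervalSet.empty()
        return IntervalSet.from_records(records)


def _window_sums(indicator: np.ndarray, width: int) -> np.ndarray:
    """Sum of ``indicator`` over every length-``width`` window (valid positions)."""
    csum = np.concatenate([[0], np.cumsum(indicator, dtype=np.int64)])
    return csum[width:] - csum[:-width]


def _centered(values: np.ndarray, length: int, flank: int) -> np.ndarray:
    """Place window values (one per full window) at window centers; ends NaN."""
    out = np.full(length, np.nan)
    if len(values):
        out[flank : flank + len(values)] = values
    return out


def gc_content(genome: GenomeSequence, params: FeatureParams) -> PerBaseTrack:
    """%GC of the 2N+1 window centered on each position, in [0, 1].

    N bases count toward the fixed window-size denominator but never the
    numerator. Positions within N of a chromosome end are undefined.
    """
    data = {}
    w = params.window
    for chrom in genome.chromosomes:
        codes = genome.codes(chrom)
        if len(codes) < w:
            data[chrom] = np.full(len(codes), np.nan)
            continue
        gc = ((codes == 1) | (codes == 2)).astype(np.int64)
        data[chrom] = _centered(_window_sums(gc, w) / w, len(codes), params.flank)
    return PerBaseTrack(data)


def sequence_entropy(genome: GenomeSequence, params: FeatureParams) -> PerBaseTrack:
    """Shannon entropy (bits) of base frequencies in the centered 2N+1 window.

    Frequencies are counts of A/C/G/T over the fixed window size 2N+1
    (N bases are excluded from the frequency vector but occupy window
    positions); 0·log0 := 0, so the range is [0, 2] bits.
    """
    data = {}
    w = params.window
    for chrom in genome.chromosomes:
        codes = genome.codes(chrom)
        if len(codes) < w:
            data[chrom] = np.full(len(codes), np.nan)
            continue
        ent = np.zeros(len(codes) - w + 1)
        for b in range(4):
            p = _window_sums((codes == b).astype(np.int64), w) / w
            logp = np.zeros_like(p)
            np.log2(p, out=logp, where=p > 0)
            ent -= p * logp
        data[chrom] = _centered(ent, len(codes), params.flank)
    return PerBaseTrack(data)


# ---------------------------------------------------------------------------
# Binary masks
# ---------------------------------------------------------------------------


def _mask_from_intervals(
    records: list[tuple], lengths: Mapping[str, int], flank: int
) -> PerBaseTrack:
    if records:
        ivs = IntervalSet.from_records(records)
        masks = ivs.to_mask(lengths, flank=flank)
    else:
        masks = {chrom: np.zeros(n, dtype=np.uint8) for chrom, n in lengths.items()}
    return PerBaseTrack(masks, binary=True)


def homopolymer_runs(genome: GenomeSequence, min_run: int) -> IntervalSet:
    """Maximal runs of one base (A/C/G/T) with length >= min_run, unflanked."""
    records = []
    for chrom in genome.chromosomes:
        codes = genome.codes(chrom)
        if len(codes) == 0:
            continue
        change = np.flatnonzero(np.diff(codes)) + 1
        starts = np.concatenate([[0], change])
        ends = np.concatenate([change, [len(codes)]])
        for s, e in zip(starts, ends):
            if e - s >= min_run and codes[s] != N_CODE:
                records.append((chrom, int(s), int(e), "homopolymer"))
    return IntervalSet.from_records(records) if records else IntervalSet.empty()


def homopolymer_mask(genome: GenomeSequence, params: FeatureParams) -> PerBaseTrack:
    """Binary mask over homopolymer runs >= min length, flank-extended."""
    runs = homopolymer_runs(genome, params.homopolymer_min_run)
    return _mask_from_intervals(
        [(iv.chrom, iv.start, iv.end) for iv in runs], genome.lengths, params.mask_flank
    )


def tandem_repeat_arrays(genome: GenomeSequence, params: FeatureParams) -> IntervalSet:
    """Maximal exact tandem arrays: period 2..max_period, >= 2 full copies,
    total array length >= tandem_min_length; pure single-base arrays are
    left to the homopolymer feature. Unflanked intervals."""
    records = []
    for chrom in genome.chromosomes:
        codes = genome.codes(chrom)
        L = len(codes)
        for period in range(2, params.tandem_max_period + 1):
            if L < 2 * period:
                break
            eq = (codes[:-period] == codes[period:]) & (codes[:-period] != N_CODE)
            if not eq.any():
                continue
            padded = np.concatenate([[False], eq, [False]])
            edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
            for s, e in zip(edges[::2], edges[1::2]):
                m = e - s  # match-run length; array spans [s, s + m + period)
                if m < period:
                    continue  # fewer than two full copies
                if m + period < params.tandem_min_length:
                    continue
                if np.all(codes[s : s + m + period] == codes[s]):
                    continue  # period-1 array in disguise
                records.append((chrom, int(s), int(s + m + period), f"period{period}"))
    if not records:
        return IntervalSet.empty()
    return IntervalSet.from_records(records).merged()


def tandem_repeat_mask(
    genome: GenomeSequence,
    params: FeatureParams,
    override: IntervalSet | None = None,
) -> PerBaseTrack:
    """Binary tandem-repeat mask, flank-extended.

    If ``override`` intervals are supplied (e.g. external TRF output as
    BED) they are rasterized directly and the built-in detector is skipped.
    """
    if override is not None:
        return PerBaseTrack(
            override.to_mask(genome.lengths, flank=params.mask_flank), binary=True
        )
    arrays = tandem_repeat_arrays(genome, params)
    return _mask_from_intervals(
        [(iv.chrom, iv.start, iv.end) for iv in arrays], genome.lengths, params.mask_flank
    )


_DUST_WINDOW = 64


def low_complexity_mask(
    genome: GenomeSequence,
    params: FeatureParams,
    override: IntervalSet | None = None,
) -> PerBaseTrack:
    """DUST-style low-complexity mask.

    Sliding 64-bp windows are scored by their overlapping-triplet counts:
    S = Σ_t c_t(c_t−1)/2 normalized by (#triplets − 1); windows whose score
    exceeds level/10 are masked (level 30 -> 3.0, the DustMasker default
    scale). Triplets containing N are not counted. ``override`` BED output
    from an external masker is honored as in :func:`tandem_repeat_mask`.
    """
    if override is not None:
        return PerBaseTrack(
            override.to_mask(genome.lengths, flank=params.mask_flank), binary=True
        )
    threshold = params.dust_level / 10.0
    data = {}
    for chrom in genome.chromosomes:
        codes = genome.codes(chrom)
        L = len(codes)
        mask = np.zeros(L, dtype=np.uint8)
        if L >= 3:
            valid = (
                (codes[:-2] != N_CODE) & (codes[1:-1] != N_CODE) & (codes[2:] != N_CODE)
            )
            tri = codes[:-2].astype(np.int32) * 16 + codes[1:-1] * 4 + codes[2:]
            tri = np.where(valid, tri, -1)
            w = min(_DUST_WINDOW, L)
            n_tri_win = w - 2  # triplets per base-window
            counts = np.zeros(64, dtype=np.int64)
            S = 0
            k = 0
            # prime the first window's triplets
            for t in tri[:n_tri_win]:
                if t >= 0:
                    S += counts[t]
                    counts[t] += 1
                    k += 1
            diff = np.zeros(L + 1, dtype=np.int8)
            n_windows = L - w + 1
            for i in range(n_windows):
                if k >= 2 and S / (k - 1) > threshold:
                    diff[i] += 1
                    diff[i + w] -= 1
                if i + 1 < n_windows:
                    t_out = tri[i]
                    if t_out >= 0:
                        counts[t_out] -= 1
                        S -= counts[t_out]
                        k -= 1
                    t_in = tri[i + n_tri_win]
                    if t_in >= 0:
                        S += counts[t_in]
                        counts[t_in] += 1
                        k += 1
            mask = (np.cumsum(diff[:-1]) > 0).astype(np.uint8)
        data[chrom] = mask
    return PerBaseTrack(data, binary=True)


# ---------------------------------------------------------------------------
# (K,E)-mappability
# ---------------------------------------------------------------------------


def _window_view(codes: np.ndarray, k: int) -> np.ndarray:
    """(n_windows, k) strided view of all length-k windows (no copy)."""
    n = len(codes) - k + 1
    return np.lib.stride_tricks.as_strided(
        codes, shape=(n, k), strides=(codes.strides[0], codes.strides[0])
    )


def mappability(genome: GenomeSequence, params: FeatureParams) -> PerBaseTrack:
    """Per-base (K,E)-mappability: 1 / occ(p).

    occ(p) counts length-K windows anywhere in the genome, on either
    strand, whose Hamming distance to the forward window starting at p is
    at most E; a value of 1 means the window is unique. N mismatches every
    symbol (including N). Positions within K−1 of the 3' end are
    undefined (NaN), as are windows whose occurrence count is zero under
    the N rule.

    The search uses pigeonhole seeding: the query is split into E+1
    blocks, and any window within distance E must match at least one
    block exactly; exact block matches are found by hashing, then full
    Hamming verification is applied to the candidates.
    """
    K, E = params.kmer_length, params.error_budget
    for chrom, n in genome.lengths.items():
        if K > n:
            raise ValueError(f"K={K} exceeds length of chromosome {chrom} ({n})")

    # Window collection: forward and reverse-complement of every chromosome.
    sources: list[np.ndarray] = []
    views: list[np.ndarray] = []
    for chrom in genome.chromosomes:
        fwd = genome.codes(chrom)
        sources.append(fwd)
        sources.append(reverse_complement_codes(fwd))
    for arr in sources:
        views.append(_window_view(np.ascontiguousarray(arr), K))

    # Block boundaries for pigeonhole seeding.
    n_blocks = E + 1
    bounds = np.linspace(0, K, n_blocks + 1).astype(int)
    blocks = list(zip(bounds[:-1], bounds[1:]))

    index: dict[bytes, list[tuple[int, int]]] = {}
    for src_id, arr in enumerate(sources):
        has_n = arr == N_CODE
        for b, (bs, be) in enumerate(blocks):
            tag = bytes([b])
            # windows whose block [off+bs, off+be) is N-free
            n_in_block = _window_sums(has_n.astype(np.int64), be - bs)
            for off in range(len(arr) - K + 1):
                if n_in_block[off + bs] == 0:
                    key = tag + arr[off + bs : off + be].tobytes()
                    index.setdefault(key, []).append((src_id, off))

    data = {}
    for ci, chrom in enumerate(genome.chromosomes):
        codes = genome.codes(chrom)
        L = len(codes)
        out = np.full(L, np.nan)
        src_id = 2 * ci  # forward source of this chromosome
        for p in range(L - K + 1):
            q = codes[p : p + K]
            cands: set[tuple[int, int]] = set()
            for b, (bs, be) in enumerate(blocks):
                block = q[bs:be]
                if (block == N_CODE).any():
                    continue
                hits = index.get(bytes([b]) + block.tobytes())
                if hits:
                    cands.update(hits)
            occ = 0
            for cs, co in cands:
                cand = views[cs][co]
                mism = (cand != q) | (cand == N_CODE) | (q == N_CODE)
                if int(mism.sum()) <= E:
                    occ += 1
            if occ > 0:
                out[p] = 1.0 / occ
            else:
                logger.debug("mappability undefined (occ=0) at %s:%d", chrom, p)
        data[chrom] = out
    return PerBaseTrack(data)


def mappability_bruteforce(genome: GenomeSequence, params: FeatureParams) -> PerBaseTrack:
    """All-pairs Hamming reference implementation (small genomes only)."""
    K, E = params.kmer_length, params.error_budget
    for chrom, n in genome.lengths.items():
        if K > n:
            raise ValueError(f"K={K} exceeds length of chromosome {chrom} ({n})")
    all_windows = []
    for chrom in genome.chromosomes:
        fwd = genome.codes(chrom)
        for arr in (fwd, reverse_complement_codes(fwd)):
            all_windows.append(np.array(_window_view(np.ascontiguousarray(arr), K)))
    W = np.concatenate(all_windows, axis=0)  # (n_windows, K)
    w_is_n = W == N_CODE
    data = {}
    for chrom in genome.chromosomes:
        codes = genome.codes(chrom)
        L = len(codes)
        out = np.full(L, np.nan)
        for p in range(L - K + 1):
            q = codes[p : p + K]
            mism = (W != q) | w_is_n | (q == N_CODE)
            occ = int((mism.sum(axis=1) <= E).sum())
            if occ > 0:
                out[p] = 1.0 / occ
        data[chrom] = out
    return PerBaseTrack(data)
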