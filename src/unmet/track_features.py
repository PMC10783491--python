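"""Per-base features from external tracks: standardized coverage depth and
annotation-derived binary masks (interspersed repeats, segmental
duplications, structural variants), plus assembly of the 10-column
feature matrix consumed by the classifier."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import CoverageTrack, GenomeSequence, IntervalSet
from .sequence_features import PerBaseTrack

logger = logging.getLogger("unmet")

#: Fixed column order of the assembled feature matrix.
FEATURE_COLUMNS = [
    "coverage_z",
    "mappability",
    "homopolymer",
    "tandem",
    "repeatmasker",
    "segdup",
    "lcr",
    "sv",
    "gc",
    "entropy",
]


@dataclass
class StandardizedCoverage:
    """Per-base absolute coverage z-values, standardized per chromosome."""

    values: dict[str, np.ndarray]


def standardize_coverage(track: CoverageTrack) -> StandardizedCoverage:
    """Absolute z-value of depth, |depth − mean| / sd, per chromosome.

    Mean and standard deviation are computed over the defined (non-NaN)
    positions of each chromosome, using the population convention
    (ddof=0): the whole chromosome track *is* the population. Chromosomes
    with fewer than two defined positions or zero depth variance are
    rejected by name.
    """
    values = {}
    for chrom, depth in track.depth.items():
        defined = ~np.isnan(depth)
        if defined.sum() < 2:
            raise ValueError(f"coverage for {chrom} has fewer than 2 defined positions")
        mean = float(np.mean(depth[defined]))
        sd = float(np.std(depth[defined]))  # population sd
        if sd == 0.0:
            raise ValueError(f"coverage for {chrom} has zero variance")
        values[chrom] = np.abs(depth - mean) / sd
    return StandardizedCoverage(values)


def annotation_mask(
    intervals: IntervalSet, genome: GenomeSequence, flank: int = 0
) -> PerBaseTrack:
    """Binary rasterization of annotation intervals onto the genome,
    optionally flank-extended (used for RepeatMasker, segmental
    duplication, and structural-variant BED inputs)."""
    return PerBaseTrack(intervals.to_mask(genome.lengths, flank=flank), binary=True)


def _column_vectors(track) -> Mapping[str, np.ndarray]:
    if isinstance(track, PerBaseTrack):
        return track.data
    if isinstance(track, StandardizedCoverage):
        return track.values
    if isinstance(track, CoverageTrack):
        return track.depth
    if isinstance(track, Mapping):
        return track
    raise TypeError(f"unsupported track type {type(track)!r}")


def assemble_feature_matrix(
    positions: IntervalSet | Sequence[tuple[str, int]],
    tracks: Mapping[str, object],
) -> pd.DataFrame:
    """One row per requested position with the 10 named feature columns.

    ``positions`` is either an IntervalSet (every base of every interval)
    or an explicit (chrom, pos) sequence. ``tracks`` maps each name in
    :data:`FEATURE_COLUMNS` to a per-base track. Rows where any feature
    is undefined (NaN) are dropped and the count logged; column order is
    fixed and stable across runs.
    """
    missing = [c for c in FEATURE_COLUMNS if c not in tracks]
    if missing:
        raise ValueError(f"missing feature tracks: {missing}")
    if isinstance(positions, IntervalSet):
        chroms: list[np.ndarray] = []
        pos_arrays: list[np.ndarray] = []
        for iv in positions.merged():
            p = np.arange(iv.start, iv.end, dtype=np.int64)
            pos_arrays.append(p)
            chroms.append(np.repeat(iv.chrom, len(p)))
        chrom_arr = np.concatenate(chroms) if chroms else np.array([], dtype=object)
        pos_arr = np.concatenate(pos_arrays) if pos_arrays else np.array([], dtype=np.int64)
    else:
        chrom_arr = np.array([c for c, _ in positions], dtype=object)
        pos_arr = np.array([p for _, p in positions], dtype=np.int64)

    data = {"chrom": chrom_arr, "pos": pos_arr}
    vectors = {name: _column_vectors(tracks[name]) for name in FEATURE_COLUMNS}
    for name in FEATURE_COLUMNS:
        col = np.full(len(pos_arr), np.nan)
        for chrom in np.unique(chrom_arr):
            sel = chrom_arr == chrom
            vec = np.asarray(vectors[name][chrom], dtype=float)
            p = pos_arr[sel]
            if len(p) and (p.max() >= len(vec) or p.min() < 0):
                raise ValueError(f"position beyond track length for {name} on {chrom}")
            col[sel] = vec[p]
        data[name] = col

    df = pd.DataFrame(data)
    n_before = len(df)
    df = df.dropna(subset=FEATURE_COLUMNS).reset_index(drop=True)
    n_dropped = n_before - len(df)
    if n_dropped:
        logger.info(
            "assemble_feature_matrix: dropped %d/%d positions with undefined features",
            n_dropped,
            n_before,
        )
    return df
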