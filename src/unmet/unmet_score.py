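"""UNMET scoring: percentile-rank normalization, banding, region
extraction, indel score-group comparison, track export, and the
end-to-end pipeline.

The raw classifier score of every scoreable CDS position is converted to
a percentile rank over all scored positions — the UNMET score, in
(0, 1]; values near 1 mark positions where short-read variant calls are
unreliable. Scores are banded into reliable (< 0.93), error-prone
([0.93, 0.97)) and difficult-to-sequence (>= 0.97), and contiguous
difficult runs of at least 50 nt are emitted as a BED region list.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.stats import rankdata
from sklearn.model_selection import ParameterGrid

from . import classifier as clf
from . import sequence_features as sf
from . import synthetic_data as syn
from . import track_features as tf
from . import variant_windows as vw
from .io_formats import (
    INDEL,
    FILTERED,
    IntervalSet,
    VariantSite,
    write_bed,
    write_bedgraph,
)

logger = logging.getLogger("unmet")

BAND_RELIABLE = "reliable"
BAND_ERROR_PRONE = "error_prone"
BAND_DIFFICULT = "difficult"


@dataclass(frozen=True)
class BandThresholds:
    """UNMET banding cut-points: difficult >= 0.97, error-prone [0.93, 0.97)."""

    difficult: float = 0.97
    error_prone: float = 0.93

    def __post_init__(self) -> None:
        if not 0.0 < self.error_prone < self.difficult < 1.0:
            raise ValueError("require 0 < error_prone < difficult < 1")


def score_positions(
    model: clf.TrainedClassifier,
    cds: IntervalSet,
    tracks: dict[str, object],
) -> pd.DataFrame:
    """Raw classifier score for every scoreable CDS position.

    Positions with any undefined feature are dropped (and logged) by the
    matrix assembly. Returns a frame with chrom, pos, raw."""
    matrix = tf.assemble_feature_matrix(cds, tracks)
    out = matrix[["chrom", "pos"]].copy()
    out["raw"] = model.predict_raw(matrix[tf.FEATURE_COLUMNS])
    return out


def percentile_rank(raw_df: pd.DataFrame) -> pd.DataFrame:
    """UNMET score: fraction of scored positions with raw score <= this one.

    Ties share the maximum rank, so the largest raw score always maps to
    exactly 1.0 and constant scores map everywhere to 1.0; range (0, 1]."""
    if len(raw_df) == 0:
        raise ValueError("no scored positions")
    out = raw_df.copy()
    out["unmet"] = rankdata(out["raw"].to_numpy(), method="max") / len(out)
    return out


def assign_bands(
    score_df: pd.DataFrame, thresholds: BandThresholds = BandThresholds()
) -> pd.DataFrame:
    """Band every scored position by its UNMET score alone."""
    u = score_df["unmet"].to_numpy()
    band = np.where(
        u >= thresholds.difficult,
        BAND_DIFFICULT,
        np.where(u >= thresholds.error_prone, BAND_ERROR_PRONE, BAND_RELIABLE),
    )
    out = score_df.copy()
    out["band"] = band
    return out


def difficult_regions(
    score_df: pd.DataFrame,
    min_len: int = 50,
    threshold: float = 0.97,
) -> IntervalSet:
    """Maximal runs of consecutive scored positions with UNMET >= threshold
    and run length >= min_len, as 0-based half-open intervals.

    Runs never span chromosome boundaries or gaps in the scored
    positions; a single sub-threshold base splits a run in two."""
    records = []
    for chrom, grp in score_df.groupby("chrom", sort=True):
        pos = grp["pos"].to_numpy()
        order = np.argsort(pos)
        pos = pos[order]
        hot = grp["unmet"].to_numpy()[order] >= threshold
        run_start = None
        prev = None
        for p, h in zip(pos, hot):
            contiguous = prev is not None and p == prev + 1
            if h and run_start is not None and contiguous:
                prev = p
                continue
            if run_start is not None and prev - run_start + 1 >= min_len:
                records.append((chrom, int(run_start), int(prev) + 1, "difficult"))
            run_start = p if h else None
            prev = p
        if run_start is not None and prev - run_start + 1 >= min_len:
            records.append((chrom, int(run_start), int(prev) + 1, "difficult"))
    if not records:
        return IntervalSet.empty()
    return IntervalSet.from_records(records)


class GroupComparison(NamedTuple):
    mean_a: float
    sd_a: float
    mean_b: float
    sd_b: float
    t_statistic: float
    p_value: float


def compare_score_groups(
    score_df: pd.DataFrame,
    group_a: Sequence[tuple[str, int]],
    group_b: Sequence[tuple[str, int]],
) -> GroupComparison:
    """Welch two-sample t-test on the UNMET scores of two position sets.

    Positions absent from the score track are ignored; an empty group is
    an error. Standard deviations are sample (ddof=1) values."""
    lookup = score_df.set_index(["chrom", "pos"])["unmet"]

    def pick(group: Sequence[tuple[str, int]]) -> np.ndarray:
        idx = [g for g in group if g in lookup.index]
        return lookup.loc[idx].to_numpy() if idx else np.array([])

    a, b = pick(list(group_a)), pick(list(group_b))
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must contain scored positions")
    t, p = sps.ttest_ind(a, b, equal_var=False)
    if np.array_equal(np.sort(a), np.sort(b)):
        t, p = 0.0, 1.0
    sd = lambda x: float(np.std(x, ddof=1)) if len(x) > 1 else 0.0
    return GroupComparison(
        float(np.mean(a)), sd(a), float(np.mean(b)), sd(b), float(t), float(p)
    )


def select_indel_groups(
    sites: Sequence[VariantSite], flank: int = 12
) -> tuple[list[tuple[str, int]], list[tuple[str, int]]]:
    """Split indel positions by recurrent filtering.

    Group A: positions with >= 2 filtered indel records; group B: every
    other position carrying at least one indel record."""
    counts: dict[tuple[str, int], list[int]] = {}
    for s in sites:
        if s.var_class == INDEL:
            counts.setdefault((s.chrom, s.pos), []).append(1 if s.status == FILTERED else 0)
    recurrent = sorted(k for k, v in counts.items() if sum(v) >= 2)
    other = sorted(k for k, v in counts.items() if sum(v) < 2)
    return recurrent, other


def export_tracks(
    score_df: pd.DataFrame,
    outdir: str | Path,
    thresholds: BandThresholds = BandThresholds(),
    min_region_len: int = 50,
) -> dict[str, Path]:
    """Write browser tracks: UNMET bedGraph, band BED4 and difficult-region BED."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    banded = score_df if "band" in score_df else assign_bands(score_df, thresholds)

    values: dict[str, np.ndarray] = {}
    band_records = []
    for chrom, grp in banded.groupby("chrom", sort=True):
        n = int(grp["pos"].max()) + 1
        vec = np.full(n, np.nan)
        vec[grp["pos"].to_numpy()] = grp["unmet"].to_numpy()
        values[chrom] = vec
        pos = grp["pos"].to_numpy()
        order = np.argsort(pos)
        pos = pos[order]
        bands = grp["band"].to_numpy()[order]
        run_start = prev_pos = None
        prev_band = None
        for p, b in zip(pos, bands):
            if run_start is not None and b == prev_band and p == prev_pos + 1:
                prev_pos = p
                continue
            if run_start is not None:
                band_records.append((chrom, int(run_start), int(prev_pos) + 1, prev_band))
            run_start, prev_pos, prev_band = p, p, b
        if run_start is not None:
            band_records.append((chrom, int(run_start), int(prev_pos) + 1, prev_band))

    paths = {
        "unmet": outdir / "unmet.bedgraph",
        "bands": outdir / "bands.bed",
        "difficult_regions": outdir / "difficult_regions.bed",
    }
    write_bedgraph(values, paths["unmet"])
    write_bed(IntervalSet.from_records(band_records), paths["bands"])
    write_bed(
        difficult_regions(banded, min_len=min_region_len, threshold=thresholds.difficult),
        paths["difficult_regions"],
    )
    return paths


# ---------------------------------------------------------------------------
# End-to-end pipeline
# ---------------------------------------------------------------------------


@dataclass
class PipelineConfig:
    """Configuration of the full synthetic-bundle pipeline run."""

    synthetic: syn.SyntheticConfig = field(default_factory=syn.SyntheticConfig)
    features: sf.FeatureParams = field(default_factory=sf.FeatureParams)
    train: clf.TrainConfig = field(default_factory=lambda: clf.TrainConfig(reduced_grid=True))
    thresholds: BandThresholds = field(default_factory=BandThresholds)
    vd_min: float = vw.DEFAULT_VD_MIN
    min_region_len: int = 50
    outdir: Path | None = None


def standard_pipeline_config(seed: int = 1, outdir: str | Path | None = None) -> PipelineConfig:
    """The standard synthetic bundle: 100-kb genome, p_diff=0.95, p_bg=0.02,
    reduced hyperparameter grid, all feature parameters at their defaults."""
    return PipelineConfig(
        synthetic=syn.SyntheticConfig(seed=seed, p_diff=0.95, p_bg=0.02),
        train=clf.TrainConfig(balance_seed=seed, split_seed=seed, reduced_grid=True),
        outdir=Path(outdir) if outdir is not None else None,
    )


@dataclass
class PipelineResult:
    config: PipelineConfig
    bundle: syn.SyntheticBundle
    tracks: dict[str, object]
    labeled: list[vw.LabeledSite]
    train_df: pd.DataFrame
    test_df: pd.DataFrame
    model: clf.TrainedClassifier
    evaluation: clf.EvalResult
    scores: pd.DataFrame
    regions: IntervalSet
    manifest: dict


def build_tracks(
    bundle: syn.SyntheticBundle, params: sf.FeatureParams
) -> dict[str, object]:
    """All 10 feature tracks for a synthetic bundle.

    Annotation-derived features use truth-derived BEDs: segdup from the
    planted duplications, repeatmasker from the planted repeat classes
    (tandem + homopolymer), and an empty structural-variant set (nothing
    structural is planted beyond the duplications)."""
    genome = bundle.genome
    truth = bundle.truth.regions
    segdup = truth.subset("segdup")
    repeats = IntervalSet(
        truth.df[truth.df["name"].isin(["tandem", "homopolymer"])]
    )
    return {
        "coverage_z": tf.standardize_coverage(bundle.coverage),
        "mappability": sf.mappability(genome, params),
        "homopolymer": sf.homopolymer_mask(genome, params),
        "tandem": sf.tandem_repeat_mask(genome, params),
        "repeatmasker": tf.annotation_mask(repeats, genome),
        "segdup": tf.annotation_mask(segdup, genome),
        "lcr": sf.low_complexity_mask(genome, params),
        "sv": tf.annotation_mask(IntervalSet.empty(), genome),
        "gc": sf.gc_content(genome, params),
        "entropy": sf.sequence_entropy(genome, params),
    }


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """simulate -> features -> label -> train -> score -> band -> export.

    Returns every in-memory artifact and a manifest of seeds, sizes and
    metrics; when ``config.outdir`` is set, the synthetic bundle, tracks
    and manifest.json are written there."""
    logger.info("pipeline: simulating bundle (seed=%d)", config.synthetic.seed)
    bundle = syn.simulate_bundle(config.synthetic)

    logger.info("pipeline: computing feature tracks")
    tracks = build_tracks(bundle, config.features)

    logger.info("pipeline: labeling sites")
    labeled = vw.label_sites(
        bundle.sites, bundle.cds, flank=config.features.flank, vd_min=config.vd_min
    )
    n_pos = sum(1 for ls in labeled if ls.label == vw.UNRELIABLE)
    n_neg = len(labeled) - n_pos
    logger.info("pipeline: %d unreliable / %d reliable labels", n_pos, n_neg)

    positions = [(ls.chrom, ls.pos) for ls in labeled]
    features = tf.assemble_feature_matrix(positions, tracks)
    train_df, test_df = clf.build_training_set(labeled, features, config.train)

    logger.info("pipeline: training (grid of %d points)", len(list(ParameterGrid(config.train.effective_grid))))
    model = clf.train(train_df, config.train)
    evaluation = clf.evaluate(model, test_df)
    logger.info("pipeline: held-out AUC=%.4f MCC=%.4f", evaluation.auc, evaluation.mcc)

    scores = score_positions(model, bundle.cds, tracks)
    scores = percentile_rank(scores)
    scores = assign_bands(scores, config.thresholds)
    regions = difficult_regions(
        scores, min_len=config.min_region_len, threshold=config.thresholds.difficult
    )

    # planted-vs-background summary over scored positions
    inside_parts, outside_parts = [], []
    for chrom, grp in scores.groupby("chrom", sort=True):
        mask = bundle.truth.difficulty[chrom][grp["pos"].to_numpy()] > 0
        inside_parts.append(grp["unmet"].to_numpy()[mask])
        outside_parts.append(grp["unmet"].to_numpy()[~mask])
    inside = np.concatenate(inside_parts) if inside_parts else np.array([])
    outside = np.concatenate(outside_parts) if outside_parts else np.array([])

    band_counts = scores["band"].value_counts().to_dict()
    manifest = {
        "seeds": {
            "synthetic": config.synthetic.seed,
            "balance": config.train.balance_seed,
            "split": config.train.split_seed,
        },
        "sizes": {
            "genome_length": config.synthetic.genome_length,
            "n_variants": len(bundle.sites),
            "n_labeled_unreliable": n_pos,
            "n_labeled_reliable": n_neg,
            "n_train": len(train_df),
            "n_test": len(test_df),
            "n_scored": len(scores),
        },
        "model": {
            "best_params": model.best_params,
            "cv_accuracy": None if np.isnan(model.cv_accuracy) else model.cv_accuracy,
            "importances": {k: float(v) for k, v in model.importances.items()},
        },
        "metrics": {
            "auc": evaluation.auc,
            "mcc": evaluation.mcc,
            "confusion": dataclasses.asdict(evaluation.confusion),
            "median_unmet_inside_planted": float(np.median(inside)) if len(inside) else None,
            "median_unmet_outside_planted": float(np.median(outside)) if len(outside) else None,
        },
        "bands": {b: int(band_counts.get(b, 0)) for b in
                  (BAND_RELIABLE, BAND_ERROR_PRONE, BAND_DIFFICULT)},
        "n_difficult_regions": len(regions),
    }

    if config.outdir is not None:
        outdir = Path(config.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = syn.write_bundle(bundle, outdir)
        paths.update(export_tracks(scores, outdir, config.thresholds, config.min_region_len))
        manifest["files"] = {k: _sha256(p) for k, p in sorted(paths.items())}
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)

    return PipelineResult(
        config=config,
        bundle=bundle,
        tracks=tracks,
        labeled=labeled,
        train_df=train_df,
        test_df=test_df,
        model=model,
        evaluation=evaluation,
        scores=scores,
        regions=regions,
        manifest=manifest,
    )
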