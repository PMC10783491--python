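"""Training-set assembly, gradient-boosted tree training and evaluation.

The discriminator between unreliable and reliable positions is a
gradient-boosted decision tree ensemble (XGBoost). Hyperparameters are
chosen by grid search with 5-fold cross-validation maximizing accuracy
(fraction correct at threshold 0.5); the selected point is refit on the
full training set. Evaluation reports ROC-AUC, the Matthews correlation
coefficient over the four confusion cells, and the cells themselves:
CPU (unreliable predicted unreliable), CPR (reliable predicted
reliable), PU (reliable predicted unreliable), PR (unreliable predicted
reliable).

Logistic-regression and random-forest baselines are provided behind the
same interface; the boosted ensemble is the deliverable.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import GridSearchCV, ParameterGrid, StratifiedKFold, train_test_split
from xgboost import XGBClassifier

from .io_formats import GenomeSequence, encode_sequence, reverse_complement_codes
from .track_features import FEATURE_COLUMNS
from .variant_windows import LabeledSite, UNRELIABLE

logger = logging.getLogger("unmet")

#: Hyperparameter grid searched with 5-fold CV.
FULL_GRID: dict[str, list] = {
    "max_depth": [3, 4, 5, 6],
    "learning_rate": [0.1, 0.01, 0.001],
    "gamma": [0, 0.1, 0.01],
    "subsample": [0.5, 0.8, 1],
    "colsample_bytree": [0.5, 0.8, 1],
}

#: Small grid for desk-scale runs; spans the depths that matter most.
REDUCED_GRID: dict[str, list] = {
    "max_depth": [3, 5],
    "learning_rate": [0.1],
    "gamma": [0],
    "subsample": [0.8],
    "colsample_bytree": [0.8],
}


@dataclass
class TrainConfig:
    balance_seed: int = 0
    split_seed: int = 0
    test_fraction: float = 0.2
    cv_folds: int = 5
    n_estimators: int = 100
    reduced_grid: bool = False
    grid: dict[str, list] | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.test_fraction < 1.0:
            raise ValueError("test_fraction must be in (0, 1)")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if self.grid is not None and not self.grid:
            raise ValueError("grid must be non-empty")

    @property
    def effective_grid(self) -> dict[str, list]:
        if self.grid is not None:
            return self.grid
        return REDUCED_GRID if self.reduced_grid else FULL_GRID


@dataclass(frozen=True)
class ConfusionCounts:
    """Four-cell confusion counts at a fixed threshold."""

    cpu: int  # true unreliable predicted unreliable
    cpr: int  # true reliable predicted reliable
    pu: int  # true reliable predicted unreliable
    pr: int  # true unreliable predicted reliable

    def __post_init__(self) -> None:
        if min(self.cpu, self.cpr, self.pu, self.pr) < 0:
            raise ValueError("confusion counts must be >= 0")

    @property
    def total(self) -> int:
        return self.cpu + self.cpr + self.pu + self.pr


@dataclass
class TrainedClassifier:
    """Fitted ensemble plus the metadata needed to reproduce it."""

    model: object
    best_params: dict
    cv_accuracy: float
    importances: pd.Series
    metadata: dict = field(default_factory=dict)

    def predict_raw(self, X: pd.DataFrame | np.ndarray) -> np.ndarray:
        """Raw classifier score in [0, 1] (probability of unreliable)."""
        return np.asarray(self.model.predict_proba(X)[:, 1])


def mcc(c: ConfusionCounts) -> float:
    """Matthews correlation coefficient from the four confusion cells.

    MCC = (CPU·CPR − PU·PR) / sqrt((CPU+PU)(CPU+PR)(CPR+PU)(CPR+PR));
    defined as 0 (with a warning) when any denominator factor is zero.
    """
    num = c.cpu * c.cpr - c.pu * c.pr
    factors = [c.cpu + c.pu, c.cpu + c.pr, c.cpr + c.pu, c.cpr + c.pr]
    if 0 in factors:
        warnings.warn("MCC denominator has a zero factor; returning 0", stacklevel=2)
        return 0.0
    return num / math.sqrt(float(factors[0]) * factors[1] * factors[2] * factors[3])


def build_training_set(
    labeled: Sequence[LabeledSite],
    features: pd.DataFrame,
    config: TrainConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Balance the classes and split 8:2 into train/test frames.

    The majority class (normally the reliable negatives) is down-sampled
    with ``balance_seed`` to the minority count; the combined set is then
    shuffled and split stratified by class with ``split_seed``, so the
    50/50 ratio is preserved within ±1 sample in both splits. Labeled
    positions missing from the feature matrix (undefined features) are
    skipped. Returned frames carry chrom, pos, the 10 feature columns,
    and a binary ``label`` column (1 = unreliable).
    """
    lab_df = pd.DataFrame(
        {
            "chrom": [ls.chrom for ls in labeled],
            "pos": [ls.pos for ls in labeled],
            "label": [1 if ls.label == UNRELIABLE else 0 for ls in labeled],
        }
    )
    df = lab_df.merge(features, on=["chrom", "pos"], how="inner")
    n_missing = len(lab_df) - len(df)
    if n_missing:
        logger.info("build_training_set: %d labeled sites lack defined features", n_missing)
    n_pos = int((df["label"] == 1).sum())
    n_neg = int((df["label"] == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError(f"need both classes; got {n_pos} positive / {n_neg} negative")

    rng = np.random.default_rng(config.balance_seed)
    n_keep = min(n_pos, n_neg)
    if n_neg > n_keep:
        neg = df[df["label"] == 0].sample(n=n_keep, random_state=rng.integers(2**31))
        df = pd.concat([df[df["label"] == 1], neg])
    elif n_pos > n_keep:
        logger.warning("fewer negatives than positives; down-sampling positives")
        pos = df[df["label"] == 1].sample(n=n_keep, random_state=rng.integers(2**31))
        df = pd.concat([pos, df[df["label"] == 0]])
    df = df.reset_index(drop=True)

    if n_keep == 1:
        warnings.warn("degenerate 1-vs-1 training set", stacklevel=2)
    try:
        train_df, test_df = train_test_split(
            df,
            test_size=config.test_fraction,
            random_state=config.split_seed,
            shuffle=True,
            stratify=df["label"],
        )
    except ValueError:
        warnings.warn("class too small to stratify; plain shuffled split", stacklevel=2)
        train_df, test_df = train_test_split(
            df, test_size=config.test_fraction, random_state=config.split_seed, shuffle=True
        )
    return train_df.reset_index(drop=True), test_df.reset_index(drop=True)


def _xgb(config: TrainConfig, **params) -> XGBClassifier:
    # exact greedy splits: thresholds at gap midpoints, which matters for
    # small training sets with strongly separated features
    return XGBClassifier(
        n_estimators=config.n_estimators,
        tree_method="exact",
        n_jobs=1,
        random_state=config.split_seed,
        eval_metric="logloss",
        **params,
    )


def train(
    train_df: pd.DataFrame,
    config: TrainConfig,
    feature_columns: Sequence[str] | None = None,
) -> TrainedClassifier:
    """Grid-search 5-fold CV on accuracy, then refit the best point.

    A single-point grid skips the search and fits directly. Deterministic
    given the config seeds (single-threaded histogram trees, seeded CV
    shuffle).
    """
    cols = list(feature_columns) if feature_columns is not None else FEATURE_COLUMNS
    X = train_df[cols]
    y = train_df["label"].to_numpy()
    if len(X) == 0:
        raise ValueError("empty training set")
    if len(np.unique(y)) < 2:
        raise ValueError("training set contains a single class")

    grid = config.effective_grid
    points = list(ParameterGrid(grid))
    if len(points) == 1:
        model = _xgb(config, **points[0]).fit(X, y)
        best_params, cv_accuracy = points[0], float("nan")
    else:
        folds = min(config.cv_folds, int(np.bincount(y).min()))
        cv = StratifiedKFold(n_splits=max(2, folds), shuffle=True, random_state=config.split_seed)
        search = GridSearchCV(
            _xgb(config), grid, scoring="accuracy", cv=cv, n_jobs=1, refit=True
        )
        search.fit(X, y)
        model = search.best_estimator_
        best_params = dict(search.best_params_)
        cv_accuracy = float(search.best_score_)

    raw = np.asarray(model.feature_importances_, dtype=float)
    total = raw.sum()
    importances = pd.Series(raw / total if total > 0 else raw, index=cols)
    meta = {
        "n_train": int(len(X)),
        "feature_columns": cols,
        "balance_seed": config.balance_seed,
        "split_seed": config.split_seed,
        "cv_folds": config.cv_folds,
        "grid_points": len(points),
    }
    return TrainedClassifier(model, best_params, cv_accuracy, importances, meta)


@dataclass(frozen=True)
class EvalResult:
    auc: float
    mcc: float
    confusion: ConfusionCounts


def evaluate(
    classifier: TrainedClassifier,
    test_df: pd.DataFrame,
    threshold: float = 0.5,
) -> EvalResult:
    """ROC-AUC (midrank tie convention), MCC and confusion counts at
    ``threshold`` on a held-out frame."""
    cols = classifier.metadata.get("feature_columns", FEATURE_COLUMNS)
    y = test_df["label"].to_numpy()
    scores = classifier.predict_raw(test_df[cols])
    if len(np.unique(y)) < 2:
        warnings.warn("single-class test set; AUC undefined", stacklevel=2)
        auc = float("nan")
    else:
        auc = float(roc_auc_score(y, scores))
    pred = (scores >= threshold).astype(int)
    c = ConfusionCounts(
        cpu=int(((y == 1) & (pred == 1)).sum()),
        cpr=int(((y == 0) & (pred == 0)).sum()),
        pu=int(((y == 0) & (pred == 1)).sum()),
        pr=int(((y == 1) & (pred == 0)).sum()),
    )
    return EvalResult(auc=auc, mcc=mcc(c), confusion=c)


def similarity_filter(
    test_df: pd.DataFrame,
    train_df: pd.DataFrame,
    genome: GenomeSequence,
    flank: int = 12,
    threshold: float = 0.80,
) -> tuple[pd.DataFrame, int]:
    """Drop test sites whose centered (2N+1)-mer resembles a training site.

    A test site is removed when its window matches any training-site
    window at >= ceil(threshold · (2N+1)) positions, ungapped, on either
    strand — the leakage check for near-duplicate repeat copies landing
    on both sides of the split. Sites whose window overruns a chromosome
    end are kept. Returns the surviving subset and the removal count.
    """
    k = 2 * flank + 1
    min_match = math.ceil(threshold * k)

    def kmer(chrom: str, pos: int) -> np.ndarray | None:
        seq = genome.sequences[chrom]
        if pos - flank < 0 or pos + flank + 1 > len(seq):
            return None
        return encode_sequence(seq[pos - flank : pos + flank + 1])

    train_kmers = []
    for row in train_df.itertuples(index=False):
        km = kmer(row.chrom, int(row.pos))
        if km is not None:
            train_kmers.append(km)
            train_kmers.append(reverse_complement_codes(km))
    if not train_kmers:
        return test_df.reset_index(drop=True), 0
    T = np.stack(train_kmers)  # (2·n_train, k)

    keep = np.ones(len(test_df), dtype=bool)
    for i, row in enumerate(test_df.itertuples(index=False)):
        km = kmer(row.chrom, int(row.pos))
        if km is None:
            continue
        matches = (T == km).sum(axis=1)
        if int(matches.max()) >= min_match:
            keep[i] = False
    removed = int((~keep).sum())
    return test_df[keep].reset_index(drop=True), removed


def univariate_analysis(
    train_df: pd.DataFrame,
    test_df: pd.DataFrame,
    config: TrainConfig,
) -> pd.DataFrame:
    """Train one single-feature model per feature, same protocol.

    Returns a table (feature, auc, mcc) sorted by AUC descending — the
    check that no single feature outperforms the combined model."""
    rows = []
    for col in FEATURE_COLUMNS:
        if train_df[col].nunique() < 2:
            rows.append({"feature": col, "auc": 0.5, "mcc": 0.0})
            continue
        tc = train(train_df, config, feature_columns=[col])
        res = evaluate(tc, test_df)
        rows.append({"feature": col, "auc": res.auc, "mcc": res.mcc})
    return (
        pd.DataFrame(rows).sort_values("auc", ascending=False).reset_index(drop=True)
    )


def train_baseline(
    train_df: pd.DataFrame,
    config: TrainConfig,
    kind: str = "logistic",
    feature_columns: Sequence[str] | None = None,
) -> TrainedClassifier:
    """Logistic-regression or random-forest baseline behind the same interface."""
    cols = list(feature_columns) if feature_columns is not None else FEATURE_COLUMNS
    X, y = train_df[cols], train_df["label"].to_numpy()
    if kind == "logistic":
        model = LogisticRegression(max_iter=2000)
        model.fit(X, y)
        w = np.abs(model.coef_[0])
    elif kind == "random_forest":
        model = RandomForestClassifier(
            n_estimators=200, random_state=config.split_seed, n_jobs=1
        )
        model.fit(X, y)
        w = np.asarray(model.feature_importances_)
    else:
        raise ValueError(f"unknown baseline kind {kind!r}")
    total = w.sum()
    importances = pd.Series(w / total if total > 0 else w, index=cols)
    meta = {"n_train": int(len(X)), "feature_columns": cols, "baseline": kind}
    return TrainedClassifier(model, {}, float("nan"), importances, meta)
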