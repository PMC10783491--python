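"""Training-set assembly, grid-searched boosted trees, MCC/AUC, the
similarity leakage filter and the univariate comparison."""

import numpy as np
import pandas as pd
import pytest

from unmet import classifier as clf
from unmet import io_formats as io
from unmet import track_features as tf
from unmet import variant_windows as vw


def make_labeled(n_pos, n_neg, rng, separation=3.0):
    """Labeled sites plus a feature frame where the first three features
    separate the classes with a strict margin (uniform noise), the rest
    are pure Gaussian noise."""
    labeled, rows = [], []
    stats = vw.SiteWindowStats("c", 0, 5, 0, 0.2, 0.0)
    for i in range(n_pos + n_neg):
        is_pos = i < n_pos
        labeled.append(
            vw.LabeledSite("c", i, vw.UNRELIABLE if is_pos else vw.RELIABLE, stats)
        )
        row = {"chrom": "c", "pos": i}
        for j, col in enumerate(tf.FEATURE_COLUMNS):
            if j < 3:
                row[col] = (separation if is_pos else 0.0) + rng.uniform(0, 1)
            else:
                row[col] = rng.normal(0.0, 1.0)
        rows.append(row)
    return labeled, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# build_training_set
# ---------------------------------------------------------------------------


def test_balanced_split_arithmetic():
    rng = np.random.default_rng(0)
    labeled, features = make_labeled(100, 1000, rng)
    config = clf.TrainConfig(balance_seed=1, split_seed=1)
    train_df, test_df = clf.build_training_set(labeled, features, config)
    assert len(train_df) == 160 and len(test_df) == 40
    assert train_df["label"].sum() == 80 and test_df["label"].sum() == 20


def test_split_deterministic_under_seeds():
    rng = np.random.default_rng(0)
    labeled, features = make_labeled(50, 200, rng)
    config = clf.TrainConfig(balance_seed=4, split_seed=5)
    a = clf.build_training_set(labeled, features, config)
    b = clf.build_training_set(labeled, features, config)
    assert a[0].equals(b[0]) and a[1].equals(b[1])


def test_degenerate_one_vs_one_warns():
    rng = np.random.default_rng(0)
    labeled, features = make_labeled(1, 1, rng)
    with pytest.warns(UserWarning):
        train_df, test_df = clf.build_training_set(
            labeled, features, clf.TrainConfig()
        )
    assert len(train_df) + len(test_df) == 2


def test_single_class_rejected():
    rng = np.random.default_rng(0)
    labeled, features = make_labeled(10, 0, rng)
    with pytest.raises(ValueError, match="both classes"):
        clf.build_training_set(labeled, features, clf.TrainConfig())


# ---------------------------------------------------------------------------
# train / evaluate
# ---------------------------------------------------------------------------


@pytest.fixture(scope="module")
def separable_split():
    rng = np.random.default_rng(7)
    labeled, features = make_labeled(80, 300, rng, separation=5.0)
    config = clf.TrainConfig(balance_seed=2, split_seed=2, reduced_grid=True)
    train_df, test_df = clf.build_training_set(labeled, features, config)
    return train_df, test_df, config


def test_separable_features_reach_perfect_cv_accuracy(separable_split):
    train_df, test_df, config = separable_split
    model = clf.train(train_df, config)
    assert model.cv_accuracy == pytest.approx(1.0)
    result = clf.evaluate(model, test_df)
    assert result.auc == pytest.approx(1.0)
    assert result.mcc == pytest.approx(1.0)
    assert result.confusion.pu == 0 and result.confusion.pr == 0


def test_importances_nonnegative_sum_one(separable_split):
    train_df, _, config = separable_split
    model = clf.train(train_df, config)
    assert (model.importances >= 0).all()
    assert model.importances.sum() == pytest.approx(1.0)
    assert list(model.importances.index) == tf.FEATURE_COLUMNS


def test_training_deterministic(separable_split):
    train_df, test_df, config = separable_split
    m1, m2 = clf.train(train_df, config), clf.train(train_df, config)
    assert m1.best_params == m2.best_params
    assert np.allclose(m1.predict_raw(test_df[tf.FEATURE_COLUMNS]),
                       m2.predict_raw(test_df[tf.FEATURE_COLUMNS]))


def test_single_point_grid_skips_search(separable_split):
    train_df, _, _ = separable_split
    config = clf.TrainConfig(grid={"max_depth": [3]})
    model = clf.train(train_df, config)
    assert model.best_params == {"max_depth": 3}
    assert np.isnan(model.cv_accuracy)


def test_single_class_training_rejected(separable_split):
    train_df, _, config = separable_split
    pos_only = train_df[train_df["label"] == 1]
    with pytest.raises(ValueError, match="single class"):
        clf.train(pos_only, config)


def test_shuffled_labels_give_chance_auc(separable_split):
    train_df, test_df, config = separable_split
    rng = np.random.default_rng(8)
    shuffled = train_df.copy()
    shuffled["label"] = rng.permutation(shuffled["label"].to_numpy())
    test_shuffled = test_df.copy()
    test_shuffled["label"] = rng.permutation(test_shuffled["label"].to_numpy())
    model = clf.train(shuffled, clf.TrainConfig(grid={"max_depth": [3]}))
    result = clf.evaluate(model, test_shuffled)
    assert abs(result.auc - 0.5) < 0.25  # Monte-Carlo tolerance at n=32


# ---------------------------------------------------------------------------
# MCC
# ---------------------------------------------------------------------------


def test_mcc_perfect_and_hand_example():
    assert clf.mcc(clf.ConfusionCounts(10, 10, 0, 0)) == pytest.approx(1.0)
    # (3·4 − 1·2) / sqrt(4·5·5·6) = 10/sqrt(600)
    assert clf.mcc(clf.ConfusionCounts(3, 4, 1, 2)) == pytest.approx(10 / np.sqrt(600))


def test_mcc_degenerate_denominator_is_zero_with_warning():
    with pytest.warns(UserWarning, match="zero factor"):
        assert clf.mcc(clf.ConfusionCounts(5, 0, 0, 0)) == 0.0


def test_mcc_negative_counts_rejected():
    with pytest.raises(ValueError):
        clf.ConfusionCounts(-1, 0, 0, 0)


# ---------------------------------------------------------------------------
# similarity filter
# ---------------------------------------------------------------------------


def _site_frame(positions):
    rows = [{"chrom": "c", "pos": p, "label": 0} for p in positions]
    df = pd.DataFrame(rows)
    for col in tf.FEATURE_COLUMNS:
        df[col] = 0.0
    return df


def test_identical_windows_removed():
    rng = np.random.default_rng(9)
    s = "".join(rng.choice(list("ACGT"), size=200))
    genome = io.GenomeSequence({"c": s + s})  # position p and p+200 share a 25-mer
    test_df = _site_frame([50])
    train_df = _site_frame([250])
    kept, removed = clf.similarity_filter(test_df, train_df, genome)
    assert removed == 1 and len(kept) == 0


def test_similarity_threshold_boundary_20_of_25():
    rng = np.random.default_rng(10)
    base = rng.choice(list("ACGT"), size=25)

    def variant_of(n_mismatch):
        out = base.copy()
        for i in range(n_mismatch):
            out[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[out[i]]
        return "".join(out)

    flank = "".join(rng.choice(list("ACGT"), size=100))
    # train window at pos 112 of chr t; test windows on separate chromosomes
    genome = io.GenomeSequence(
        {
            "t": flank + "".join(base) + flank,
            "m5": flank + variant_of(5) + flank,   # 20/25 matches -> removed
            "m6": flank + variant_of(6) + flank,   # 19/25 matches -> kept
        }
    )
    train_df = _site_frame([112]).assign(chrom="t")
    removed_df = _site_frame([112]).assign(chrom="m5")
    kept_df = _site_frame([112]).assign(chrom="m6")
    _, n_removed = clf.similarity_filter(removed_df, train_df, genome)
    assert n_removed == 1
    _, n_kept_removed = clf.similarity_filter(kept_df, train_df, genome)
    assert n_kept_removed == 0


def test_reverse_strand_similarity_detected():
    rng = np.random.default_rng(11)
    s = "".join(rng.choice(list("ACGT"), size=25))
    flank1 = "".join(rng.choice(list("ACGT"), size=50))
    flank2 = "".join(rng.choice(list("ACGT"), size=50))
    genome = io.GenomeSequence(
        {"a": flank1 + s + flank1, "b": flank2 + io.reverse_complement(s) + flank2}
    )
    test_df = _site_frame([62]).assign(chrom="b")
    train_df = _site_frame([62]).assign(chrom="a")
    _, removed = clf.similarity_filter(test_df, train_df, genome)
    assert removed == 1


def test_empty_train_set_leaves_test_unchanged():
    genome = io.GenomeSequence({"c": "ACGT" * 100})
    test_df = _site_frame([100, 200])
    kept, removed = clf.similarity_filter(test_df, test_df.iloc[0:0], genome)
    assert removed == 0 and len(kept) == 2


# ---------------------------------------------------------------------------
# univariate analysis
# ---------------------------------------------------------------------------


def test_univariate_ranking_and_constant_feature(separable_split):
    train_df, test_df, config = separable_split
    train_df = train_df.copy()
    test_df = test_df.copy()
    train_df["sv"] = 0.0  # constant feature scores exactly chance
    test_df["sv"] = 0.0
    single = clf.TrainConfig(grid={"max_depth": [3]})
    table = clf.univariate_analysis(train_df, test_df, single)
    assert set(table["feature"]) == set(tf.FEATURE_COLUMNS)
    assert table.loc[table["feature"] == "sv", "auc"].iloc[0] == 0.5
    # informative features (class means shifted) dominate the ranking
    assert table.iloc[0]["feature"] in tf.FEATURE_COLUMNS[:3]
    assert table.iloc[0]["auc"] > 0.9
    assert table["auc"].is_monotonic_decreasing


def test_baselines_fit_behind_same_interface(separable_split):
    train_df, test_df, config = separable_split
    for kind in ("logistic", "random_forest"):
        model = clf.train_baseline(train_df, config, kind=kind)
        result = clf.evaluate(model, test_df)
        assert result.auc > 0.9
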