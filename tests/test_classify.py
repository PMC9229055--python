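"""Dataset assembly, splitting, training and the evaluation algebra."""

import numpy as np
import pandas as pd
import pytest

from cagevib import (
    AXIS_MASKS,
    ConfigError,
    ContractError,
    Dataset,
    EvalReport,
    FormatError,
    LabeledWindow,
    SplitSpec,
    TrainConfig,
    ablation,
    build_dataset,
    class_shares,
    evaluate,
    load_bundle,
    save_bundle,
    split,
    train,
)
from cagevib.features import FEATURE_NAMES
from cagevib.sim import CLASS_ORDER, ActivityClass

CLASSES = tuple(c.value for c in CLASS_ORDER)


def feature_frame(n, seed=0):
    rng = np.random.default_rng(seed)
    table = pd.DataFrame(rng.normal(size=(n, 11)), columns=list(FEATURE_NAMES))
    table.insert(0, "start_time", np.arange(n) * 15.0)
    table.insert(0, "window_index", np.arange(n))
    return table


def labels_for(n, classes=None, seed=0):
    rng = np.random.default_rng(seed)
    picks = classes if classes is not None else rng.choice(CLASSES, n)
    return [LabeledWindow(i, i * 15.0, 10.0, ActivityClass(picks[i])) for i in range(n)]


def separable_dataset(n=300, seed=0):
    """Three classes split cleanly by the first feature."""
    rng = np.random.default_rng(seed)
    y = np.array(CLASSES)[np.arange(n) % 3]
    X = rng.normal(0, 0.05, (n, 11))
    X[:, 0] += (np.arange(n) % 3) * 5.0
    return Dataset(np.arange(n), X, y)


class TestBuildDataset:
    def test_full_match(self):
        ds = build_dataset(feature_frame(5), labels_for(5))
        assert len(ds) == 5

    def test_partial_match_drops_rows(self):
        ds = build_dataset(feature_frame(5), labels_for(4))
        assert len(ds) == 4

    def test_invalid_labels_dropped(self):
        labels = labels_for(5)
        labels[2] = LabeledWindow(2, 30.0, float("nan"), ActivityClass.RESTING, valid=False)
        assert len(build_dataset(feature_frame(5), labels)) == 4

    def test_zero_overlap_is_error(self):
        labels = [LabeledWindow(100 + i, 0.0, 1.0, ActivityClass.RESTING) for i in range(3)]
        with pytest.raises(FormatError):
            build_dataset(feature_frame(3), labels)


class TestSplit:
    def test_study_scale_split(self):
        ds = build_dataset(feature_frame(3880), labels_for(3880))
        train_set, test_set = split(ds, SplitSpec(n_test=1000, seed=1))
        assert len(train_set) == 2880
        assert len(test_set) == 1000
        assert len(train_set) / len(ds) == pytest.approx(0.74, abs=0.005)

    def test_seeded_reproducibility_and_disjointness(self):
        ds = separable_dataset(100)
        a = split(ds, SplitSpec(n_test=30, seed=5))
        b = split(ds, SplitSpec(n_test=30, seed=5))
        np.testing.assert_array_equal(a[1].ids, b[1].ids)
        assert set(a[0].ids).isdisjoint(a[1].ids)

    def test_degenerate_sizes_rejected(self):
        with pytest.raises(ContractError):
            SplitSpec(n_test=0)
        with pytest.raises(ContractError):
            split(separable_dataset(10), SplitSpec(n_test=10))


class TestShares:
    def test_study_training_shares(self):
        y = np.array(
            ["resting"] * 1105 + ["stationary"] * 1317 + ["locomotion"] * 458, dtype=object
        )
        shares = class_shares(y)
        assert shares["resting"] == pytest.approx(38.37, abs=0.005)
        assert shares["stationary"] == pytest.approx(45.73, abs=0.005)
        assert shares["locomotion"] == pytest.approx(15.90, abs=0.005)


class TestEvalReport:
    def test_hand_arithmetic(self):
        report = EvalReport(np.array([[8, 2, 0], [1, 7, 2], [0, 3, 7]]), CLASSES)
        assert report.accuracy == pytest.approx(22 / 30)
        np.testing.assert_allclose(report.tpr, [0.8, 0.7, 0.7])
        np.testing.assert_allclose(report.ppv, [8 / 9, 7 / 12, 7 / 9])

    def test_against_brute_force_counting_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            n = int(rng.integers(10, 200))
            truth = rng.choice(CLASSES, n)
            pred = rng.choice(CLASSES, n)
            confusion = np.zeros((3, 3), dtype=int)
            for c_t, c_p in zip(truth, pred):
                confusion[CLASSES.index(c_t), CLASSES.index(c_p)] += 1
            report = EvalReport(confusion, CLASSES)
            # brute-force re-counts, one comparison at a time
            assert report.n == n
            assert report.accuracy == pytest.approx(
                sum(t == p for t, p in zip(truth, pred)) / n)
            binary = sum(
                (t == "resting") == (p == "resting") for t, p in zip(truth, pred)
            ) / n
            assert report.binary_accuracy == pytest.approx(binary)
            for i, c in enumerate(CLASSES):
                n_true = sum(t == c for t in truth)
                n_pred = sum(p == c for p in pred)
                hits = sum(t == p == c for t, p in zip(truth, pred))
                if n_true:
                    assert report.tpr[i] == pytest.approx(hits / n_true)
                if n_pred:
                    assert report.ppv[i] == pytest.approx(hits / n_pred)

    def test_perfect_predictions(self):
        report = EvalReport(np.diag([10, 10, 10]), CLASSES)
        assert report.accuracy == 1.0
        np.testing.assert_array_equal(report.tpr, 1.0)
        np.testing.assert_array_equal(report.ppv, 1.0)
        assert report.binary_accuracy == 1.0


class TestTraining:
    def test_separable_data_high_cv_accuracy(self):
        bundle = train(separable_dataset(), TrainConfig(seed=0, n_candidates=3))
        assert bundle.cv_accuracy >= 0.99

    def test_shuffled_labels_at_chance(self):
        ds = separable_dataset(300, seed=1)
        rng = np.random.default_rng(2)
        y = ds.y.copy()
        rng.shuffle(y)
        shuffled = Dataset(ds.ids, ds.X, y)
        bundle = train(shuffled, TrainConfig(seed=0, n_candidates=3))
        prior = max(class_shares(y).values()) / 100.0
        assert bundle.cv_accuracy == pytest.approx(prior, abs=0.05)

    def test_single_class_rejected(self):
        ds = separable_dataset(60)
        mono = Dataset(ds.ids, ds.X, np.full(60, "resting", dtype=object))
        with pytest.raises(ConfigError):
            train(mono)

    def test_evaluate_requires_matching_features(self):
        ds = separable_dataset(120)
        bundle = train(ds.select_features(AXIS_MASKS["x"]),
                       TrainConfig(seed=0, n_candidates=2))
        with pytest.raises(ContractError):
            evaluate(bundle, ds)

    def test_zero_feature_mask_rejected(self):
        with pytest.raises(ContractError):
            separable_dataset(30).select_features(())


class TestAblation:
    def test_five_masks_five_rows(self):
        table = ablation(separable_dataset(200), SplitSpec(n_test=50, seed=0),
                         config=TrainConfig(seed=0, n_candidates=2))
        assert list(table.index) == ["all", "xz", "x", "y", "z"]
        assert len(table) == 5
        # the informative feature sits on the X axis in this toy dataset
        assert table.loc["x", "accuracy"] >= table.loc["y", "accuracy"]


class TestPersistence:
    def test_round_trip(self, tmp_path):
        ds = separable_dataset(120)
        bundle = train(ds, TrainConfig(seed=0, n_candidates=2))
        path = tmp_path / "model.joblib"
        save_bundle(bundle, path)
        back = load_bundle(path)
        np.testing.assert_array_equal(back.predict(ds.X), bundle.predict(ds.X))
        assert back.feature_names == bundle.feature_names

    def test_feature_mismatch_refused(self, tmp_path):
        ds = separable_dataset(120)
        bundle = train(ds.select_features(AXIS_MASKS["x"]),
                       TrainConfig(seed=0, n_candidates=2))
        path = tmp_path / "model.joblib"
        save_bundle(bundle, path)
        with pytest.raises(FormatError):
            load_bundle(path, expect_features=FEATURE_NAMES)
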