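"""Standardization, SMOTE geometry, perceptron training, LOOCV, metrics."""

import numpy as np
import pytest

from otoshape import (
    ClassifierConfig,
    ConfusionMatrix,
    confusion_metrics,
    load_shad_confusion,
    loocv_classify,
    smote_oversample,
    standardize_fit_apply,
    train_mlp,
)
from otoshape.classify import smote_balance


def make_blobs(rng, n_per=20, sep=10.0, dims=3):
    X = np.vstack([
        rng.normal(0.0, 1.0, size=(n_per, dims)),
        rng.normal(sep, 1.0, size=(n_per, dims)),
    ])
    y = np.repeat(["north", "south"], n_per)
    return X, y


class TestStandardize:
    def test_hand_formula(self):
        train = np.array([[3.0], [5.0], [7.0]])  # mean 5, sample SD 2
        _, test = standardize_fit_apply(train, np.array([[9.0]]))
        assert test[0, 0] == pytest.approx(2.0)

    def test_train_columns_standardized(self, rng):
        X = rng.normal(5, 3, size=(30, 4))
        Xs, _ = standardize_fit_apply(X, X[:2])
        assert np.abs(Xs.mean(axis=0)).max() < 1e-12
        assert np.abs(Xs.std(axis=0, ddof=1) - 1).max() < 1e-12

    def test_constant_column_centered_with_warning(self, rng):
        X = rng.normal(size=(10, 2))
        X[:, 1] = 4.0
        with pytest.warns(UserWarning, match="constant column"):
            Xs, _ = standardize_fit_apply(X, X[:1])
        assert np.abs(Xs[:, 1]).max() == 0.0


class TestSmote:
    def test_two_point_class_interpolates_on_segment(self, rng):
        X = np.array([[0.0, 0.0], [1.0, 1.0]])
        synth = smote_oversample(X, k=1, n_new=50, rng=rng)
        assert synth.shape == (50, 2)
        assert np.allclose(synth[:, 0], synth[:, 1])
        assert np.all((synth >= 0.0) & (synth <= 1.0))

    def test_zero_requested_empty(self, rng):
        X = np.array([[0.0], [1.0]])
        assert smote_oversample(X, n_new=0, rng=rng).shape == (0, 1)

    def test_synthetic_points_stay_in_bounding_box(self, rng):
        X = rng.normal(size=(15, 4))
        synth = smote_oversample(X, k=5, n_new=1000, rng=rng)
        assert np.all(synth >= X.min(axis=0) - 1e-12)
        assert np.all(synth <= X.max(axis=0) + 1e-12)

    def test_singleton_class_errors(self, rng):
        with pytest.raises(ValueError, match="at least 2"):
            smote_oversample(np.array([[1.0, 2.0]]), n_new=5, rng=rng)
        X = np.vstack([np.zeros((1, 2)), np.ones((5, 2))])
        y = np.array(["rare"] + ["common"] * 5)
        with pytest.raises(ValueError, match="rare"):
            smote_balance(X, y, rng=rng)

    def test_balance_reaches_majority_count(self, rng):
        X = np.vstack([rng.normal(0, 1, (5, 2)), rng.normal(4, 1, (45, 2))])
        y = np.array(["min"] * 5 + ["maj"] * 45)
        Xb, yb = smote_balance(X, y, k=3, rng=rng)
        _, counts = np.unique(yb, return_counts=True)
        assert counts.tolist() == [45, 45]


class TestTrainMlp:
    def test_separable_blobs_perfect_training_accuracy(self, rng):
        X, y = make_blobs(rng, n_per=20, sep=10.0)
        Xs, _ = standardize_fit_apply(X, X[:1])
        clf = train_mlp(Xs, y, hidden_units=5, seed=0)
        assert np.mean(clf.predict(Xs) == y) == 1.0

    def test_deterministic_given_seed(self, rng):
        X, y = make_blobs(rng, n_per=15, sep=3.0)
        p1 = train_mlp(X, y, hidden_units=5, seed=11).predict(X)
        p2 = train_mlp(X, y, hidden_units=5, seed=11).predict(X)
        assert np.array_equal(p1, p2)

    def test_single_class_errors(self, rng):
        X = rng.normal(size=(10, 2))
        with pytest.raises(ValueError, match="single class"):
            train_mlp(X, np.repeat("only", 10), hidden_units=3)


class TestLoocv:
    CFG = dict(hidden_units_grid=(5,), repeats=2, seed=3, max_epochs=200)

    def test_separated_populations_high_accuracy(self, rng):
        X, y = make_blobs(rng, n_per=12, sep=10.0, dims=2)
        res = loocv_classify(X, y, ClassifierConfig(**self.CFG))
        m = confusion_metrics(res.matrix)
        assert m.accuracy > 0.95

    def test_column_sums_equal_class_counts(self, rng):
        X, y = make_blobs(rng, n_per=8, sep=2.0, dims=2)
        res = loocv_classify(X, y, ClassifierConfig(**self.CFG))
        col_sums = res.matrix.counts.sum(axis=0)
        assert np.allclose(col_sums, [8, 8])
        assert res.matrix.total == pytest.approx(16)

    def test_shuffled_labels_near_chance(self, rng):
        X = rng.normal(size=(30, 3))
        y = np.repeat(["a", "b"], 15)
        res = loocv_classify(X, y, ClassifierConfig(**self.CFG))
        acc = confusion_metrics(res.matrix).accuracy
        assert 0.2 <= acc <= 0.8  # chance 0.5 +- generous Monte-Carlo margin

    def test_no_leakage_of_held_out_point(self, rng, monkeypatch):
        """SMOTE sees only training folds: the held-out extreme outlier never
        reaches the oversampler, in any fold."""
        import otoshape.classify as clf_mod

        outlier = np.array([50.0, 50.0])
        X = np.vstack([rng.normal(0, 0.5, (6, 2)),
                       rng.normal(4, 0.5, (5, 2)),
                       [outlier]])  # outlier belongs to the smaller class
        y = np.array(["a"] * 6 + ["b"] * 6)
        outlier_row = len(X) - 1
        seen_raw_inputs = []
        real_fit_fold = clf_mod._fit_fold

        def spy_fit_fold(X_tr, y_tr, X_te, hidden, cfg, rng_, seed):
            seen_raw_inputs.append(np.asarray(X_tr).copy())
            return real_fit_fold(X_tr, y_tr, X_te, hidden, cfg, rng_, seed)

        monkeypatch.setattr(clf_mod, "_fit_fold", spy_fit_fold)
        res = loocv_classify(X, y, ClassifierConfig(hidden_units_grid=(4,),
                                                    repeats=1, seed=0))
        assert res.matrix.total == 12
        assert len(seen_raw_inputs) == 12  # one fit per fold (single-point grid)
        # every fold trains on exactly N-1 raw rows, and exactly one fold
        # (the one holding the outlier out) trains without the outlier
        assert all(M.shape[0] == 11 for M in seen_raw_inputs)
        holds_outlier = [bool(np.any(np.all(M == outlier, axis=1)))
                         for M in seen_raw_inputs]
        assert sum(holds_outlier) == 11

    def test_minority_recall_with_smote_not_worse(self, rng):
        X = np.vstack([rng.normal(0, 1.0, (5, 2)), rng.normal(3, 1.0, (45, 2))])
        y = np.array(["min"] * 5 + ["maj"] * 45)
        res = loocv_classify(X, y, ClassifierConfig(hidden_units_grid=(5,),
                                                    repeats=1, seed=5))
        m = confusion_metrics(res.matrix)
        assert m.per_class_accuracy["min"] >= 0.2  # SMOTE keeps minority visible

    def test_singleton_class_rejected_upfront(self, rng):
        X = rng.normal(size=(7, 2))
        y = np.array(["a"] * 6 + ["b"])
        with pytest.raises(ValueError, match="single member"):
            loocv_classify(X, y, ClassifierConfig(**self.CFG))


class TestConfusionMetrics:
    def test_reference_shad_table(self):
        """Published 11-river worked example: accuracy 0.9089, kappa 0.8945."""
        cm = load_shad_confusion()
        m = confusion_metrics(cm)
        assert cm.total == 1141
        assert m.accuracy == pytest.approx(0.9089, abs=5e-5)
        assert m.kappa == pytest.approx(0.8945, abs=5e-5)
        assert m.per_class_accuracy["STJ"] * 100 == pytest.approx(82.13, abs=0.005)
        for river in ("DEL", "YOR", "JAM"):
            assert m.per_class_accuracy[river] == pytest.approx(1.0)

    def test_chance_matrix(self):
        cm = ConfusionMatrix(np.array([[25.0, 25.0], [25.0, 25.0]]), ["a", "b"])
        m = confusion_metrics(cm)
        assert m.accuracy == pytest.approx(0.5)
        assert m.kappa == pytest.approx(0.0, abs=1e-12)

    def test_kappa_one_iff_diagonal(self):
        cm = ConfusionMatrix(np.diag([10.0, 20.0, 5.0]), ["a", "b", "c"])
        assert confusion_metrics(cm).kappa == pytest.approx(1.0)

    def test_degenerate_margins_kappa_nan(self):
        cm = ConfusionMatrix(np.array([[7.0, 0.0], [0.0, 0.0]]), ["a", "b"])
        with pytest.warns(UserWarning, match="kappa undefined"):
            m = confusion_metrics(cm)
        assert np.isnan(m.kappa)


class TestPcImportance:
    def test_informative_component_ranked_first(self, rng):
        from otoshape.classify import pc_importance

        n = 40
        y = np.repeat(["a", "b"], n // 2)
        X = rng.normal(size=(n, 10))
        X[:, 3] += np.where(y == "a", -3.0, 3.0)  # single informative column
        cfg = ClassifierConfig(hidden_units_grid=(5,), seed=0, max_epochs=200)
        table = pc_importance(X, y, cfg, n_models=3, n_shuffles=3)
        assert table.iloc[0]["component"] == 4  # 1-based index of column 3
        assert table.iloc[0]["importance"] > 0

    def test_all_noise_importances_near_zero(self, rng):
        from otoshape.classify import pc_importance

        X = rng.normal(size=(30, 6))
        y = np.repeat(["a", "b"], 15)
        cfg = ClassifierConfig(hidden_units_grid=(3,), seed=1, max_epochs=150)
        table = pc_importance(X, y, cfg, n_models=3, n_shuffles=3)
        assert np.abs(table["importance"]).max() < 0.35
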