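"""Sequential layer-wise training, inference, evaluation and the harness."""

import numpy as np
import pytest
from sklearn.base import clone
from sklearn.linear_model import LogisticRegression

from fpnet import (
    ForwardProjectionClassifier,
    ForwardProjectionConvClassifier,
    evaluate,
    few_shot_harness,
    load_model,
    make_images,
    make_tabular,
    save_model,
)
from fpnet.targets import derive_seed


@pytest.fixture(scope="module")
def blobs():
    # linearly separable two-class Gaussian blobs
    return make_tabular(200, d=10, n_classes=2, nonlinearity_depth=0,
                        noise_sd=0.3, centres_per_class=1, seed=0)


class TestFit:
    def test_separable_blobs_are_learned(self, blobs):
        margin_oracle = LogisticRegression(max_iter=1000).fit(blobs.X, blobs.labels)
        assert margin_oracle.score(blobs.X, blobs.labels) >= 0.99
        clf = ForwardProjectionClassifier((50,), random_state=0).fit(blobs.X, blobs.labels)
        assert evaluate(clf, blobs.X, blobs.labels)["accuracy"] > 0.95

    def test_random_features_mode_keeps_seeded_hidden_weights(self, blobs):
        rf = ForwardProjectionClassifier((50,), fit_mode="rf", random_state=3)
        rf.fit(blobs.X, blobs.labels)
        rng = np.random.default_rng(derive_seed(3, 0))
        expected = rng.normal(0.0, 1.0 / np.sqrt(10), (10, 50))
        np.testing.assert_array_equal(rf.layers_[0].W, expected)

    def test_refit_is_bit_identical(self, blobs):
        fits = []
        for _ in range(2):
            clf = ForwardProjectionClassifier((20, 10), random_state=7)
            clf.fit(blobs.X, blobs.labels)
            fits.append(clf)
        for l1, l2 in zip(fits[0].layers_, fits[1].layers_):
            np.testing.assert_array_equal(l1.W, l2.W)
        np.testing.assert_array_equal(fits[0].readout_W_, fits[1].readout_W_)

    def test_no_feedback_audit(self, blobs):
        """Early-layer weights are identical whether or not deeper layers
        exist: nothing flows backwards through the fit."""
        shallow = ForwardProjectionClassifier((30,), random_state=1).fit(blobs.X, blobs.labels)
        deep = ForwardProjectionClassifier((30, 20, 10), random_state=1).fit(blobs.X, blobs.labels)
        np.testing.assert_array_equal(shallow.layers_[0].W, deep.layers_[0].W)

    def test_batch_size_does_not_change_solution(self, blobs):
        w = []
        for bs in (None, 32, 64):
            clf = ForwardProjectionClassifier((20,), batch_size=bs, random_state=0)
            clf.fit(blobs.X, blobs.labels)
            w.append(clf.layers_[0].W)
        np.testing.assert_allclose(w[0], w[1], atol=1e-8)
        np.testing.assert_allclose(w[0], w[2], atol=1e-8)

    def test_empty_and_single_class_rejected(self):
        clf = ForwardProjectionClassifier((5,))
        with pytest.raises(ValueError, match="empty"):
            clf.fit(np.zeros((0, 3)), np.zeros(0))
        with pytest.raises(ValueError, match="two classes"):
            clf.fit(np.zeros((4, 3)), np.zeros(4))

    def test_shape_mismatch_raises_before_fitting(self):
        clf = ForwardProjectionClassifier((5,))
        with pytest.raises(ValueError, match="2-D"):
            clf.fit(np.zeros((4, 2, 3)), [0, 1, 0, 1])

    def test_sklearn_clone_round_trip(self):
        clf = ForwardProjectionClassifier((9,), lam=0.5, fit_mode="rf", random_state=5)
        c2 = clone(clf)
        assert c2.get_params() == clf.get_params()


class TestPredict:
    def test_tied_scores_break_to_lowest_class_index(self, blobs):
        clf = ForwardProjectionClassifier((10,), random_state=0).fit(blobs.X, blobs.labels)
        clf.readout_W_ = np.zeros_like(clf.readout_W_)  # all scores tie at 0
        assert np.all(clf.predict(blobs.X[:5]) == clf.classes_[0])

    def test_scores_shape_and_finiteness(self, blobs):
        clf = ForwardProjectionClassifier((10,), random_state=0).fit(blobs.X, blobs.labels)
        scores = clf.decision_function(blobs.X[:17])
        assert scores.shape == (17, 2)
        assert np.all(np.isfinite(scores))

    def test_predict_proba_rows_normalised(self, blobs):
        clf = ForwardProjectionClassifier((10,), random_state=0).fit(blobs.X, blobs.labels)
        p = clf.predict_proba(blobs.X[:5])
        np.testing.assert_allclose(p.sum(axis=1), 1.0)

    def test_input_shape_checked(self, blobs):
        clf = ForwardProjectionClassifier((10,), random_state=0).fit(blobs.X, blobs.labels)
        with pytest.raises(ValueError, match="shape"):
            clf.predict(np.zeros((3, 7)))


class TestEvaluate:
    def test_perfect_and_inverted_scores(self, blobs):
        clf = ForwardProjectionClassifier((50,), random_state=0).fit(blobs.X, blobs.labels)
        metrics = evaluate(clf, blobs.X, blobs.labels)
        assert metrics["auc"] == 100.0
        # anti-correlated scores: swap the readout columns
        clf.readout_W_ = clf.readout_W_[:, ::-1]
        assert evaluate(clf, blobs.X, blobs.labels)["auc"] == 0.0

    def test_null_model_auc_near_chance(self):
        # labels independent of features: a fitted model's test AUC ~ 50
        rng = np.random.default_rng(0)
        x_train = rng.normal(size=(300, 10))
        y_train = np.arange(300) % 2
        clf = ForwardProjectionClassifier((20,), random_state=0).fit(x_train, y_train)
        x_test = rng.normal(size=(2000, 10))
        y_test = np.arange(2000) % 2
        assert abs(evaluate(clf, x_test, y_test)["auc"] - 50.0) < 3.0

    def test_single_class_auc_undefined(self, blobs):
        clf = ForwardProjectionClassifier((10,), random_state=0).fit(blobs.X, blobs.labels)
        keep = blobs.labels == 0
        with pytest.raises(ValueError, match="single class"):
            evaluate(clf, blobs.X[keep], blobs.labels[keep])

    def test_multiclass_macro_auc(self):
        ds = make_tabular(300, d=10, n_classes=3, nonlinearity_depth=0,
                          noise_sd=0.2, centres_per_class=1, seed=2)
        clf = ForwardProjectionClassifier((40,), random_state=0).fit(ds.X, ds.labels)
        metrics = evaluate(clf, ds.X, ds.labels)
        assert 90.0 < metrics["auc"] <= 100.0


class TestFewShot:
    def test_full_sample_reduces_to_plain_fit(self, blobs):
        est = ForwardProjectionClassifier((20,), random_state=0)
        table = few_shot_harness(est, blobs.X, blobs.labels, blobs.X, blobs.labels,
                                 n_per_class=[None], n_repeats=1, random_state=0)
        ref = clone(est)
        ref.set_params(random_state=derive_seed(0, 9000, 0))
        ref.fit(blobs.X, blobs.labels)
        assert table.loc[0, "auc_mean"] == pytest.approx(
            evaluate(ref, blobs.X, blobs.labels)["auc"]
        )

    def test_subsamples_are_within_class_and_disjoint(self, blobs):
        # draws without replacement: exactly n unique indices per class
        from fpnet.model import _coerce_labels

        labels, classes = _coerce_labels(blobs.labels)
        rng = np.random.default_rng(derive_seed(0, 0))
        idx = np.concatenate(
            [rng.choice(np.nonzero(labels == c)[0], size=10, replace=False) for c in classes]
        )
        assert len(np.unique(idx)) == 20
        drawn = labels[idx]
        assert (drawn == 0).sum() == 10 and (drawn == 1).sum() == 10

    def test_oversized_request_raises(self, blobs):
        est = ForwardProjectionClassifier((5,))
        with pytest.raises(ValueError, match="available"):
            few_shot_harness(est, blobs.X, blobs.labels, blobs.X, blobs.labels,
                             n_per_class=[1000], n_repeats=1)

    def test_lesion_image_auc_non_decreasing_in_shots(self):
        """More training images per class never hurt the mean test AUC
        (paired repeats on the planted-lesion task)."""
        tr = make_images(160, size=64, lesion_contrast=0.2, seed=derive_seed(0, 1))
        te = make_images(100, size=64, lesion_contrast=0.2, seed=derive_seed(0, 2))
        est = ForwardProjectionConvClassifier(n_blocks=2, base_filters=8, random_state=0)
        table = few_shot_harness(est, tr.X, tr.labels, te.X, te.labels,
                                 n_per_class=[5, 15, 45], n_repeats=10, random_state=0)
        aucs = table["auc_mean"].to_numpy()
        assert aucs[1] >= aucs[0] - 1.0
        assert aucs[2] >= aucs[1] - 1.0
        assert aucs[2] > aucs[0]


class TestPersistence:
    def test_save_load_round_trip_mlp(self, blobs, tmp_path):
        clf = ForwardProjectionClassifier((15, 10), random_state=4).fit(blobs.X, blobs.labels)
        save_model(clf, tmp_path / "m")
        back = load_model(tmp_path / "m")
        np.testing.assert_array_equal(back.decision_function(blobs.X), clf.decision_function(blobs.X))
        assert back.train_residuals_ == clf.train_residuals_

    def test_save_load_round_trip_conv(self, tmp_path, rng):
        x = rng.normal(size=(30, 2, 20))
        y = np.arange(30) % 2
        clf = ForwardProjectionConvClassifier(n_blocks=1, base_filters=4, random_state=0).fit(x, y)
        save_model(clf, tmp_path / "m")
        back = load_model(tmp_path / "m")
        np.testing.assert_array_equal(back.decision_function(x), clf.decision_function(x))
        # regenerated projection pairs are bit-identical (seeded)
        np.testing.assert_array_equal(back.layers_[0].pair.Q, clf.layers_[0].pair.Q)
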