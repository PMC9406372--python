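import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cytocoral import evalmetrics as em
from cytocoral import imagesim, nets
from cytocoral.errors import ContractError, DomainError
from cytocoral.types import BethesdaClass, SOURCE_STYLE


def auc_pair_oracle(truth, scores):
    """Concordant-pair count with half credit for ties."""
    pos = [s for t, s in zip(truth, scores) if t == 1]
    neg = [s for t, s in zip(truth, scores) if t == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class TestConfusionMatrix:
    def test_perfect_predictions_diagonal(self):
        y = [0, 1, 2, 3, 2, 1]
        cm = em.confusion_matrix(y, y)
        assert np.array_equal(cm, np.diag([1, 2, 2, 1]))

    def test_hand_counted_binary(self):
        cm = em.confusion_matrix([0, 0, 1], [0, 1, 1], n_classes=2)
        assert np.array_equal(cm, [[1, 1], [0, 1]])

    def test_empty_input_zero_matrix(self):
        assert em.confusion_matrix([], []).sum() == 0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ContractError):
            em.confusion_matrix([0, 1], [0])

    def test_row_sums_are_supports(self):
        rng = np.random.default_rng(0)
        t, p = rng.integers(0, 4, 50), rng.integers(0, 4, 50)
        cm = em.confusion_matrix(t, p)
        assert np.array_equal(cm.sum(axis=1), np.bincount(t, minlength=4))


class TestClassificationReport:
    def test_diagonal_matrix_perfect_metrics(self):
        rep = em.classification_report(np.diag([5, 3, 4, 2]))
        assert rep.accuracy == 1.0
        assert rep.fpr == 0.0 and rep.fnr == 0.0
        assert rep.f1 == pytest.approx(1.0)

    def test_hand_worked_binary(self):
        rep = em.classification_report(np.array([[8, 2], [1, 9]]))
        assert rep.accuracy == pytest.approx(0.85)
        assert rep.precision_per_class[1] == pytest.approx(9 / 11)
        assert rep.recall_per_class[1] == pytest.approx(0.9)

    def test_all_one_class_on_balanced_data_chance(self):
        cm = np.zeros((4, 4), dtype=int)
        cm[:, 0] = 10  # everything predicted NILM
        rep = em.classification_report(cm)
        assert rep.accuracy == pytest.approx(0.25)

    def test_zero_support_warns_not_nan(self):
        cm = np.array([[5, 0], [0, 0]])
        with pytest.warns(UserWarning):
            rep = em.classification_report(cm)
        assert np.isfinite([rep.precision, rep.recall, rep.f1]).all()

    @given(st.lists(st.integers(0, 20), min_size=16, max_size=16))
    @settings(max_examples=50)
    def test_accuracy_equals_weighted_recall_equals_trace_ratio(self, flat):
        cm = np.array(flat).reshape(4, 4)
        if cm.sum() == 0 or (cm.sum(axis=1) == 0).any():
            return
        rep = em.classification_report(cm)
        assert rep.accuracy == pytest.approx(cm.trace() / cm.sum())
        assert rep.recall == pytest.approx(rep.accuracy)


class TestRocAuc:
    def test_perfect_ranking(self):
        out = em.roc_auc([1, 1, 0, 0], np.array([[0, .9], [0, .8], [0, .2],
                                                 [0, .1]])[:, 1],
                         scheme="binary")
        assert out["auc"] == 1.0

    def test_inverted_ranking(self):
        out = em.roc_auc([1, 1, 0, 0], np.array([.1, .2, .8, .9]),
                         scheme="binary")
        assert out["auc"] == 0.0

    def test_hand_worked_three_quarters(self):
        # pairs: (0.9,0.6)+, (0.9,0.1)+, (0.4,0.6)-, (0.4,0.1)+ -> 3/4
        out = em.roc_auc([2, 2, 0, 0], np.array([.9, .4, .6, .1]),
                         scheme="binary")
        assert out["auc"] == pytest.approx(0.75)

    def test_single_class_truth_rejected(self):
        with pytest.raises(DomainError):
            em.roc_auc([1, 1], np.array([.5, .6]), scheme="binary")

    def test_multiclass_macro_is_mean_of_per_class(self):
        rng = np.random.default_rng(1)
        truth = rng.integers(0, 4, 40)
        S = rng.random((40, 4))
        out = em.roc_auc(truth, S)
        assert out["auc"] == pytest.approx(
            np.mean(list(out["per_class_auc"].values())))

    @given(st.lists(st.tuples(st.integers(0, 1),
                              st.integers(0, 5)), min_size=4, max_size=20))
    @settings(max_examples=60)
    def test_matches_pair_count_oracle(self, pairs):
        truth = np.array([t for t, _ in pairs])
        scores = np.array([s / 5 for _, s in pairs])
        if truth.min() == truth.max():
            return
        out = em.roc_auc(truth, scores, scheme="binary")
        assert out["auc"] == pytest.approx(auc_pair_oracle(truth, scores))

    def test_curve_points_monotone(self):
        rng = np.random.default_rng(2)
        truth = rng.integers(0, 2, 30)
        scores = rng.random(30)
        fpr, tpr = em.roc_auc(truth, scores, scheme="binary")["curves"]["positive"]
        assert (np.diff(fpr) >= 0).all() and (np.diff(tpr) >= 0).all()
        assert fpr[-1] == 1.0 and tpr[-1] == 1.0


class TestBinarize:
    def test_negative_group(self):
        assert np.array_equal(em.binarize_labels([0, 1]), [0, 0])

    def test_positive_group(self):
        assert np.array_equal(em.binarize_labels([2, 3]), [1, 1])

    def test_empty(self):
        assert em.binarize_labels([]).size == 0

    def test_block_collapse_equals_binarized_confusion(self):
        rng = np.random.default_rng(3)
        t, p = rng.integers(0, 4, 100), rng.integers(0, 4, 100)
        cm4 = em.confusion_matrix(t, p)
        cm2 = em.confusion_matrix(em.binarize_labels(t),
                                  em.binarize_labels(p), n_classes=2)
        assert np.array_equal(em.collapse_confusion_binary(cm4), cm2)


class TestConsistencyStudy:
    def test_closed_form_two_runs(self):
        summary = em.consistency_study(lambda s: {0: 0.99, 1: 0.97}[s],
                                       seeds=[0, 1])
        assert summary.mean == pytest.approx(0.98)
        assert summary.std == pytest.approx(0.014142, abs=1e-6)

    def test_identical_runs_zero_std(self):
        summary = em.consistency_study(lambda s: 0.5, seeds=range(4))
        assert summary.std == 0.0

    def test_five_stub_runs_summary(self):
        vals = {0: .9, 1: .8, 2: .7, 3: .6, 4: .5}
        summary = em.consistency_study(lambda s: vals[s], seeds=range(5))
        assert summary.mean == pytest.approx(0.7)
        assert summary.max == 0.9 and summary.min == 0.5
        assert summary.min <= summary.mean <= summary.max

    def test_failures_flagged_not_fatal(self):
        def flaky(s):
            if s == 1:
                raise RuntimeError("boom")
            return 0.5
        summary = em.consistency_study(flaky, seeds=range(3))
        assert summary.failures == [1]
        assert len(summary.accuracies) == 2

    def test_too_few_runs_rejected(self):
        with pytest.raises(DomainError):
            em.consistency_study(lambda s: 0.5, seeds=[0])


class TestGradientSaliency:
    def _linear_model(self, w):
        from cytocoral.nets import Dense, Flatten, Sequential
        h, wd, c = w.shape
        d = Dense(h * wd * c, 2, rng=np.random.default_rng(0))
        d.params[0][...] = np.stack([w.ravel(), np.zeros(w.size)], axis=1)
        d.params[1][...] = 0
        return Sequential([Flatten(), d])

    def test_linear_scorer_heatmap_proportional_to_weights(self):
        rng = np.random.default_rng(4)
        w = rng.normal(size=(8, 8, 3))
        model = self._linear_model(w)
        heat = em.gradient_saliency(model, np.full((8, 8, 3), 0.5), 0)
        expected = np.abs(w).max(axis=-1)
        expected = (expected - expected.min()) / np.ptp(expected)
        assert np.allclose(heat, expected, atol=1e-12)

    def test_constant_model_all_zero_map(self):
        model = self._linear_model(np.zeros((8, 8, 3)))
        heat = em.gradient_saliency(model, np.ones((8, 8, 3)) * 0.3, 0)
        assert np.array_equal(heat, np.zeros((8, 8)))

    def test_shape_and_range(self):
        model = nets.build_from_spec(nets.small_cnn_spec(24), seed=0)
        img = imagesim.synth_cell_image(BethesdaClass.SCC, SOURCE_STYLE, 1,
                                        size=24)
        heat = em.gradient_saliency(model, img.pixels, 3)
        assert heat.shape == (24, 24)
        assert heat.min() >= 0.0 and heat.max() <= 1.0

    def test_trained_model_focuses_on_cells(self, two_class_arrays):
        # mean saliency inside ground-truth cell masks exceeds outside,
        # aggregated over 20 fresh images
        X, y = two_class_arrays
        model = nets.build_from_spec(nets.small_cnn_spec(24), seed=0)
        cfg = nets.TrainingConfig(epochs=30, learning_rate=1e-3, seed=0)
        model, _ = nets.train_classifier(model, (X, y), None, cfg)
        inside, outside = [], []
        for s in range(10):
            for cls in (BethesdaClass.NILM, BethesdaClass.SCC):
                img = imagesim.synth_cell_image(cls, SOURCE_STYLE, 500 + s,
                                                size=24)
                pred = int(model.predict(img.pixels[None]).argmax())
                heat = em.gradient_saliency(model, img.pixels, pred)
                inside.append(heat[img.cell_mask].mean())
                outside.append(heat[~img.cell_mask].mean())
        assert np.mean(inside) > np.mean(outside)
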