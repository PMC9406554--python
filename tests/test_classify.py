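"""Threshold classification: Max / SVM cut points, confusion metrics, CV."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from iasmark.classify import (
    PREDICT_ABOVE,
    PREDICT_BELOW,
    ConfusionSummary,
    ThresholdModel,
    ThresholdRule,
    cross_validate,
    evaluate,
    max_threshold,
    svm_threshold,
)

from _oracles import dense_grid_best_accuracy, stratified_cv_reference, svm_dual_boundary


class TestMaxThreshold:
    def test_hand_enumeration(self):
        """Values (1,2,3,4), labels (S,S,F,F): the optimal cut is 2.5."""
        rule, conf = max_threshold([1, 2, 3, 4], [0, 0, 1, 1], PREDICT_ABOVE)
        assert rule.threshold == pytest.approx(2.5)
        assert conf.accuracy == 1.0

    def test_separable_below_direction(self):
        rule, conf = max_threshold([0.1, 0.2, 5.0, 6.0], [1, 1, 0, 0], PREDICT_BELOW)
        assert conf.accuracy == 1.0
        assert 0.2 < rule.threshold < 5.0

    def test_matches_dense_grid_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            n = int(rng.integers(10, 60))
            values = np.concatenate([rng.normal(0, 1, n), rng.normal(1, 1, n)])
            labels = np.concatenate([np.zeros(n, bool), np.ones(n, bool)])
            _, conf = max_threshold(values, labels, PREDICT_ABOVE)
            assert conf.accuracy == pytest.approx(
                dense_grid_best_accuracy(values, labels, True), abs=1e-12)

    def test_single_class_degenerates(self):
        with pytest.warns(UserWarning, match="one outcome class"):
            rule, conf = max_threshold([1.0, 2.0], [1, 1], PREDICT_ABOVE)
        assert rule.threshold == -np.inf
        assert conf.accuracy == 1.0

    def test_tie_break_widest_interval(self):
        """With ties, the cut falls in the widest optimal gap."""
        rule, conf = max_threshold([0.0, 1.0, 10.0, 11.0], [0, 0, 1, 1],
                                   PREDICT_ABOVE)
        assert rule.threshold == pytest.approx(5.5)


class TestSvmThreshold:
    def test_symmetric_clusters_cut_at_zero(self):
        values = np.array([-1.2, -1.0, -0.8, 0.8, 1.0, 1.2])
        labels = np.array([0, 0, 0, 1, 1, 1])
        rule, conf = svm_threshold(values, labels, PREDICT_ABOVE)
        assert rule.threshold == pytest.approx(0.0, abs=1e-6)
        assert conf.accuracy == 1.0

    def test_never_beats_max_on_training_data(self):
        rng = np.random.default_rng(1)
        for _ in range(15):
            n = int(rng.integers(8, 40))
            values = np.concatenate([rng.normal(0, 1, n), rng.normal(0.8, 1.2, n)])
            labels = np.concatenate([np.zeros(n, bool), np.ones(n, bool)])
            _, conf_max = max_threshold(values, labels, PREDICT_ABOVE)
            _, conf_svm = svm_threshold(values, labels, PREDICT_ABOVE)
            assert conf_max.accuracy >= conf_svm.accuracy - 1e-12

    def test_matches_qp_dual_oracle(self):
        """The boundary agrees with an independent soft-margin dual QP."""
        rng = np.random.default_rng(2)
        values = np.concatenate([rng.normal(0, 1, 15), rng.normal(1.5, 1, 15)])
        labels = np.concatenate([np.zeros(15, bool), np.ones(15, bool)])
        rule, _ = svm_threshold(values, labels, PREDICT_ABOVE, C=1.0)
        z = (values - values.mean()) / values.std()
        z_star = svm_dual_boundary(z, np.where(labels, 1.0, -1.0), C=1.0)
        thr_oracle = values.mean() + values.std() * z_star
        assert rule.threshold == pytest.approx(thr_oracle, abs=1e-4)

    def test_identical_values_rejected(self):
        with pytest.raises(ValueError, match="identical"):
            svm_threshold([1.0, 1.0, 1.0], [0, 1, 0], PREDICT_ABOVE)


class TestEvaluate:
    def test_printed_triple_arithmetic(self):
        """The (49, 2, 13, 7) matrix yields 62/71, 49/51 and 13/20."""
        c = ConfusionSummary(tp=49, fn=2, tn=13, fp=7)
        assert c.accuracy == pytest.approx(62 / 71)
        assert c.sensitivity == pytest.approx(49 / 51)
        assert c.specificity == pytest.approx(13 / 20)

    def test_degenerate_rule_predicts_everything(self):
        rule = ThresholdRule(-np.inf, PREDICT_ABOVE, "max")
        c = evaluate(rule, [1.0, 2.0, 3.0], [1, 0, 1])
        assert c.sensitivity == 1.0 and c.specificity == 0.0

    @given(
        st.lists(st.floats(min_value=-100, max_value=100,
                           allow_nan=False), min_size=2, max_size=50),
        st.data(),
    )
    def test_confusion_identities(self, values, data):
        labels = data.draw(st.lists(st.booleans(), min_size=len(values),
                                    max_size=len(values)))
        thr = data.draw(st.floats(min_value=-100, max_value=100))
        rule = ThresholdRule(thr, PREDICT_ABOVE, "max")
        c = evaluate(rule, values, labels)
        assert c.total == len(values)
        assert c.accuracy == pytest.approx((c.tp + c.tn) / c.total)
        assert c.tp + c.fn == int(np.sum(labels))


class TestCrossValidate:
    def _overlapping(self, rng, n=40):
        values = np.concatenate([rng.normal(0, 1, n), rng.normal(1.2, 1, n)])
        labels = np.concatenate([np.zeros(n, bool), np.ones(n, bool)])
        return values, labels

    def test_separable_data_perfect_holdout(self):
        values = np.concatenate([np.arange(10), np.arange(20, 30)]).astype(float)
        labels = np.concatenate([np.zeros(10, bool), np.ones(10, bool)])
        rep = cross_validate(values, labels, PREDICT_ABOVE, "max", k=5,
                             replicates=3, seed=0)
        assert rep.mean_holdout_accuracy == 1.0

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(3)
        values, labels = self._overlapping(rng)
        a = cross_validate(values, labels, PREDICT_ABOVE, "max", 5, 10, seed=9)
        b = cross_validate(values, labels, PREDICT_ABOVE, "max", 5, 10, seed=9)
        np.testing.assert_array_equal(a.holdout_accuracies, b.holdout_accuracies)
        np.testing.assert_array_equal(a.train_accuracies, b.train_accuracies)

    def test_holdout_below_training_and_matches_reference_loop(self):
        """On exchangeable overlapping data the holdout mean sits below the
        training mean, and within Monte-Carlo error of an independently
        written stratified-CV loop."""
        rng = np.random.default_rng(4)
        values, labels = self._overlapping(rng)
        rep = cross_validate(values, labels, PREDICT_ABOVE, "max", 5, 40, seed=2)
        assert rep.mean_holdout_accuracy < rep.mean_train_accuracy
        ref = stratified_cv_reference(values, labels, k=5, replicates=40,
                                      seed=123, direction_above=True)
        assert rep.mean_holdout_accuracy == pytest.approx(ref, abs=0.05)

    def test_tiny_minority_class_rejected(self):
        with pytest.raises(ValueError, match="each class"):
            cross_validate([1, 2, 3, 4, 5, 6.0], [1, 0, 0, 0, 0, 0],
                           PREDICT_ABOVE, "max", k=5, replicates=1, seed=0)


class TestThresholdModel:
    def test_direction_inferred_from_kind(self):
        m = ThresholdModel([1, 2, 3, 4.0], [0, 0, 1, 1], kind="q2_ratio")
        assert m.direction == PREDICT_ABOVE
        m2 = ThresholdModel([1, 2, 3, 4.0], [1, 1, 0, 0], kind="ap_ratio_final")
        assert m2.direction == PREDICT_BELOW

    def test_summary_mentions_metrics(self):
        res = ThresholdModel([1, 2, 3, 4.0], [0, 0, 1, 1], kind="q2_ratio").fit("max")
        text = res.summary()
        assert "sensitivity" in text and "threshold" in text
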