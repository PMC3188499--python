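"""Labeled sets, ROC/AUC and threshold calibration."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import caaxbind as cb
from caaxbind.evaluation import (
    CalibrationTarget,
    LabeledPeptideSet,
    PeptideRecord,
    calibrate_thresholds,
    rates_at_threshold,
    read_labeled_set,
    roc_curve,
)

TSV = "sequence\tlabel\tscore\nCVIM\tMTO\t-2.5\nCRKD\tNON\t0.3\nCYLE\tSTO\t-1.9\n"


class TestReadLabeledSet:
    def test_three_rows(self):
        lset = read_labeled_set(TSV)
        assert len(lset.records) == 3
        assert lset.counts() == {"MTO": 1, "NON": 1, "STO": 1}
        assert lset.scores() == pytest.approx([-2.5, 0.3, -1.9])

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError, match="FOO"):
            read_labeled_set("sequence\tlabel\nCVIM\tFOO\n")

    def test_duplicate_sequence_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            read_labeled_set("sequence\tlabel\nCVIM\tMTO\nCVIM\tNON\n")

    def test_score_column_optional(self):
        lset = read_labeled_set("sequence\tlabel\nCVIM\tMTO\nCAAA\tNON\n")
        with pytest.raises(ValueError):
            lset.scores()

    def test_binary_labels(self):
        lset = read_labeled_set(TSV)
        assert list(lset.binary_labels({"MTO"})) == [True, False, False]
        assert list(lset.binary_labels({"MTO", "STO"})) == [True, False, True]


class TestROC:
    def test_perfect_separation(self):
        curve = roc_curve([-3, -2, 1, 2], [True, True, False, False])
        assert curve.auc == 1.0

    def test_all_ties_give_half(self):
        curve = roc_curve([0.0] * 6, [True, False] * 3)
        assert curve.auc == pytest.approx(0.5)

    def test_interleaved_concordant_pairs(self):
        # positives {-3,-1}, negatives {-2,0}: 3 of 4 pairs concordant
        curve = roc_curve([-3, -1, -2, 0], [True, True, False, False])
        assert curve.auc == pytest.approx(0.75)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_curve([1.0, 2.0], [True, True])

    def test_curve_endpoints_and_monotonicity(self):
        rng = np.random.default_rng(0)
        scores = rng.normal(size=40)
        labels = rng.random(40) < 0.5
        labels[0], labels[1] = True, False
        curve = roc_curve(scores, labels)
        assert curve.fpr[0] == 0 and curve.tpr[0] == 0
        assert curve.fpr[-1] == 1 and curve.tpr[-1] == 1
        assert (np.diff(curve.fpr) >= 0).all()
        assert (np.diff(curve.tpr) >= 0).all()

    @given(st.integers(0, 10_000))
    @settings(max_examples=30, deadline=None)
    def test_trapezoid_equals_concordant_pairs_and_sklearn(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 60))
        scores = np.round(rng.normal(size=n), 1)  # rounding forces ties
        labels = rng.random(n) < 0.5
        labels[0], labels[1] = True, False
        curve = roc_curve(scores, labels)  # raises internally on mismatch
        from sklearn.metrics import roc_auc_score

        # sklearn assumes higher = positive, so negate
        assert curve.auc == pytest.approx(
            roc_auc_score(labels, -scores), abs=1e-9
        )

    @given(st.integers(0, 10_000))
    @settings(max_examples=20, deadline=None)
    def test_negation_symmetry(self, seed):
        rng = np.random.default_rng(seed)
        scores = rng.normal(size=30)
        labels = rng.random(30) < 0.4
        labels[0], labels[1] = True, False
        a = roc_curve(scores, labels).auc
        b = roc_curve(-scores, ~labels).auc
        assert a == pytest.approx(b, abs=1e-9)


class TestRates:
    scores = np.array([-3.0, -1.0, -2.0, 0.0])
    labels = np.array([True, True, False, False])

    def test_extremes(self):
        assert rates_at_threshold(self.scores, self.labels, -10) == (0.0, 0.0)
        assert rates_at_threshold(self.scores, self.labels, 10) == (1.0, 1.0)

    def test_mid_threshold(self):
        assert rates_at_threshold(self.scores, self.labels, -1.5) == (0.5, 0.5)

    def test_tie_counts_as_positive_call(self):
        tpr, _ = rates_at_threshold(self.scores, self.labels, -1.0)
        assert tpr == 1.0

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(1)
        scores = rng.normal(size=50)
        labels = rng.random(50) < 0.5
        labels[0], labels[1] = True, False
        prev = (0.0, 0.0)
        for thr in np.sort(scores):
            cur = rates_at_threshold(scores, labels, thr)
            assert cur[0] >= prev[0] and cur[1] >= prev[1]
            prev = cur


class TestCalibration:
    def test_perfectly_separated_returns_midpoint(self):
        scores = np.array([-5.0, -4.0, 1.0, 2.0])
        labels = np.array([True, True, False, False])
        cfg = calibrate_thresholds(scores, labels)
        assert -4.0 < cfg.loose_threshold < 1.0
        assert cfg.loose_threshold == pytest.approx((-4.0 + 1.0) / 2)

    def test_fpr_zero_on_overlapping_data(self):
        scores = np.array([-3.0, -0.5, -1.0, 0.0])
        labels = np.array([True, True, False, False])
        cfg = calibrate_thresholds(
            scores, labels, CalibrationTarget(loose_max_fpr=0.0)
        )
        tpr, fpr = rates_at_threshold(scores, labels, cfg.loose_threshold)
        assert fpr == 0.0

    def test_matches_exhaustive_sweep(self):
        rng = np.random.default_rng(42)
        scores = np.concatenate([rng.normal(-2, 1, 30), rng.normal(0, 1, 30)])
        labels = np.concatenate([np.ones(30, bool), np.zeros(30, bool)])
        cfg = calibrate_thresholds(scores, labels)
        tpr, fpr = rates_at_threshold(scores, labels, cfg.loose_threshold)
        best_j = tpr - fpr
        # brute-force sweep over a fine threshold grid
        grid = np.linspace(scores.min() - 1, scores.max() + 1, 4001)
        js = [
            rates_at_threshold(scores, labels, t)[0]
            - rates_at_threshold(scores, labels, t)[1]
            for t in grid
        ]
        assert best_j == pytest.approx(max(js), abs=1e-12)

    def test_stringent_not_above_loose(self):
        rng = np.random.default_rng(3)
        scores = rng.normal(size=40)
        labels = rng.random(40) < 0.5
        labels[0], labels[1] = True, False
        cfg = calibrate_thresholds(scores, labels)
        assert cfg.stringent_threshold <= cfg.loose_threshold

    def test_unattainable_bound_warns(self):
        scores = np.array([0.0, 0.0, 0.0, 0.0])
        labels = np.array([True, True, False, False])
        with pytest.warns(UserWarning):
            calibrate_thresholds(
                scores, labels, CalibrationTarget(loose_max_fpr=0.0,
                                                  stringent_max_fpr=0.0)
            )


class TestLabeledSetValidation:
    def test_duplicates_rejected(self):
        with pytest.raises(ValueError):
            LabeledPeptideSet([PeptideRecord("CVIM", "MTO"),
                               PeptideRecord("CVIM", "NON")])

    def test_vocabulary_enforced(self):
        with pytest.raises(ValueError):
            LabeledPeptideSet([PeptideRecord("CVIM", "maybe")])
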