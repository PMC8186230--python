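import numpy as np
import pytest

from appsig.errors import ValidationError
from appsig.evaluation import (
    DEFAULT_THRESHOLDS,
    auc_concordance,
    confusion_at_threshold,
    summarize_auc,
)


class TestConfusionAtThreshold:
    def test_boundary_thresholds_with_strict_inequality(self):
        probs = np.array([0.2, 0.4, 0.6, 0.8])
        y = np.array([0, 0, 1, 1])
        assert confusion_at_threshold(probs, y, 0.0) == (1.0, 0.0)
        assert confusion_at_threshold(probs, y, 1.0) == (0.0, 1.0)

    def test_separable_case(self):
        probs = np.array([0.9, 0.8, 0.1, 0.2])
        y = np.array([1, 1, 0, 0])
        assert confusion_at_threshold(probs, y, 0.5) == (1.0, 1.0)

    def test_single_class_rejected(self):
        with pytest.raises(ValidationError):
            confusion_at_threshold(np.array([0.5, 0.6]), np.array([1, 1]), 0.5)


class TestAUCConcordance:
    def test_perfect_separation(self):
        assert auc_concordance(np.array([0.9, 0.8, 0.1]), np.array([1, 1, 0])) == 1.0

    def test_hand_pairwise_example(self):
        # GA scores (0.8, 0.3), PA scores (0.6, 0.1): 3 of 4 pairs concordant
        scores = np.array([0.8, 0.3, 0.6, 0.1])
        y = np.array([1, 1, 0, 0])
        assert auc_concordance(scores, y) == pytest.approx(0.75)

    def test_all_ties_give_half(self):
        assert auc_concordance(np.full(6, 0.4), np.array([0, 0, 0, 1, 1, 1])) == 0.5

    def test_matches_brute_force_pair_count(self, rng):
        for _ in range(50):
            n = int(rng.integers(4, 15))
            y = np.zeros(n, dtype=int)
            y[rng.permutation(n)[: max(1, n // 3)]] = 1
            if y.sum() in (0, n):
                continue
            scores = np.round(rng.uniform(size=n), 1)  # coarse grid forces ties
            pos, neg = scores[y == 1], scores[y == 0]
            brute = np.mean(
                [(1.0 if s1 > s0 else 0.5 if s1 == s0 else 0.0) for s1 in pos for s0 in neg]
            )
            assert auc_concordance(scores, y) == pytest.approx(brute, abs=1e-12)

    def test_random_labels_center_at_half(self, rng):
        aucs = []
        for _ in range(1000):
            scores = rng.uniform(size=12)
            y = np.array([0] * 6 + [1] * 6)
            rng.shuffle(y)
            aucs.append(auc_concordance(scores, y))
        assert np.mean(aucs) == pytest.approx(0.5, abs=0.02)


class _FakeRecord:
    """Minimal stand-in for IterationRecord (synthetic test double)."""

    def __init__(self, probs, labels, aucs):
        self.signatures = [None] * len(aucs)
        self.validation_probabilities = [np.asarray(probs)] * len(aucs)
        self.validation_labels = np.asarray(labels)
        self.validation_auc = np.asarray(aucs, dtype=float)


class TestAggregateROC:
    def test_default_grid_has_19_points(self):
        from appsig.evaluation import aggregate_roc

        recs = [
            _FakeRecord([0.9, 0.1], [1, 0], [1.0]),
            _FakeRecord([0.8, 0.2], [1, 0], [1.0]),
        ]
        roc = aggregate_roc(recs)
        assert len(roc) == 19
        np.testing.assert_allclose(roc["threshold"], DEFAULT_THRESHOLDS)

    def test_identical_iterations_have_zero_se(self):
        from appsig.evaluation import aggregate_roc

        recs = [_FakeRecord([0.9, 0.4, 0.1], [1, 1, 0], [1.0]) for _ in range(3)]
        roc = aggregate_roc(recs)
        assert (roc["sensitivity_se"] == 0).all()
        assert (roc["specificity_se"] == 0).all()

    def test_hand_mean_and_sd(self):
        from appsig.evaluation import aggregate_roc

        # at threshold 0.5: sensitivities 0.8 and 1.0 -> mean 0.9, sd 0.1414
        r1 = _FakeRecord([0.9, 0.9, 0.9, 0.9, 0.1], [1, 1, 1, 1, 1], [1.0])
        r1.validation_probabilities = [np.array([0.9, 0.9, 0.9, 0.9, 0.1, 0.1])]
        r1.validation_labels = np.array([1, 1, 1, 1, 1, 0])
        r2 = _FakeRecord([0.9] * 5 + [0.1], [1] * 5 + [0], [1.0])
        roc = aggregate_roc([r1, r2], thresholds=[0.5])
        assert roc.loc[0, "sensitivity_mean"] == pytest.approx(0.9)
        assert roc.loc[0, "sensitivity_se"] == pytest.approx(np.sqrt(0.02), abs=1e-4)

    def test_roc_monotone_in_threshold(self, rng):
        from appsig.evaluation import aggregate_roc

        recs = []
        for _ in range(10):
            n = 12
            y = np.array([0] * 5 + [1] * 7)
            probs = np.clip(rng.uniform(size=n) + 0.2 * y, 0, 1)
            recs.append(_FakeRecord(probs, y, [0.5]))
        roc = aggregate_roc(recs)
        assert (np.diff(roc["sensitivity_mean"]) <= 1e-12).all()
        assert (np.diff(roc["specificity_mean"]) >= -1e-12).all()


class TestSummarizeAUC:
    def _records(self, aucs):
        return [_FakeRecord([0.9, 0.1], [1, 0], [a]) for a in aucs]

    def test_hand_mean_and_se(self):
        s = summarize_auc(self._records([0.8, 0.9, 1.0]), signature_size=1)
        assert s.mean_auc == pytest.approx(0.9)
        assert s.se_auc == pytest.approx(0.1)
        assert s.cl_lower_normal == pytest.approx(0.9 - 1.96 * 0.1)

    def test_constant_aucs_collapse_limits(self):
        s = summarize_auc(self._records([0.7] * 5), signature_size=1)
        assert s.se_auc == 0.0
        assert s.cl_lower_normal == s.mean_auc == s.cl_lower_percentile

    def test_reporting_style_matches_the_study(self):
        s = summarize_auc(self._records([0.76, 0.84, 0.92]), signature_size=1)
        assert s.report_line().startswith("AUC was 84% (SE 8, CL 68.3")

    def test_invariant_to_iteration_order(self, rng):
        aucs = list(rng.uniform(0.5, 1.0, size=20))
        s1 = summarize_auc(self._records(aucs), signature_size=1)
        s2 = summarize_auc(self._records(aucs[::-1]), signature_size=1)
        assert s1 == s2

    def test_requires_two_iterations(self):
        with pytest.raises(ValidationError):
            summarize_auc(self._records([0.9]), signature_size=1)
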