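"""ROC/PR metrics, DeLong comparison and operating-point selection."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from neoforest import metrics as m


def pair_count_auc(scores, labels):
    """Exhaustive Mann-Whitney oracle: P(pos > neg) + 0.5 P(tie)."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    wins = sum(
        1.0 if p > n else 0.5 if p == n else 0.0
        for p, n in itertools.product(pos, neg)
    )
    return wins / (len(pos) * len(neg))


class TestROCAndAUC:
    def test_perfect_and_inverted(self):
        labels = [0, 0, 1, 1]
        assert m.auc([0.1, 0.2, 0.8, 0.9], labels) == 1.0
        assert m.auc([0.9, 0.8, 0.2, 0.1], labels) == 0.0

    def test_hand_enumerated_case(self):
        assert m.auc([0.9, 0.8, 0.7, 0.6], [1, 0, 1, 0]) == pytest.approx(0.75)

    def test_one_class_rejected(self):
        with pytest.raises(ValueError):
            m.roc_curve([0.1, 0.2], [1, 1])

    def test_matches_pair_counting_with_ties(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            n = rng.integers(5, 50)
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                continue
            scores = rng.integers(0, 5, n).astype(float)  # heavy ties
            assert m.auc(scores, labels) == pytest.approx(
                pair_count_auc(scores, labels), abs=1e-12
            )

    def test_monotone_curves(self):
        rng = np.random.default_rng(4)
        roc = m.roc_curve(rng.random(100), rng.integers(0, 2, 100))
        assert (np.diff(roc.fpr) >= 0).all() and (np.diff(roc.tpr) >= 0).all()


class TestPartialAUC:
    def test_perfect_classifier_full_box(self):
        assert m.partial_auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == pytest.approx(
            0.1, abs=1e-12
        )

    def test_chance_diagonal_triangle(self):
        # constant scores: the ROC is the diagonal, area = 0.1^2 / 2
        assert m.partial_auc([0.5] * 10, [0, 1] * 5) == pytest.approx(
            0.005, abs=1e-12
        )

    def test_matches_staircase_counting_oracle(self):
        """With distinct scores the empirical ROC is a staircase, so the
        partial area can be counted negative-by-negative."""

        def staircase_pauc(scores, labels, c):
            pos = [s for s, l in zip(scores, labels) if l == 1]
            neg = sorted((s for s, l in zip(scores, labels) if l == 0),
                         reverse=True)
            area = 0.0
            for j, t in enumerate(neg):
                lo, hi = j / len(neg), (j + 1) / len(neg)
                width = min(hi, c) - lo
                if width <= 0:
                    break
                area += width * sum(p > t for p in pos) / len(pos)
            return area

        rng = np.random.default_rng(5)
        for _ in range(20):
            n = int(rng.integers(20, 60))
            labels = rng.integers(0, 2, n)
            labels[:2] = [0, 1]
            scores = rng.random(n)  # continuous: ties have probability 0
            assert m.partial_auc(scores, labels) == pytest.approx(
                staircase_pauc(scores, labels, 0.1), abs=1e-9
            )

    def test_invalid_fpr_max(self):
        with pytest.raises(ValueError):
            m.partial_auc([0.1, 0.9], [0, 1], fpr_max=0.0)

    def test_bounds_and_rank_invariance(self):
        rng = np.random.default_rng(6)
        scores = rng.random(60)
        labels = rng.integers(0, 2, 60)
        labels[:2] = [0, 1]
        value = m.partial_auc(scores, labels)
        assert 0 <= value <= 0.1
        # order-preserving transform leaves the ROC untouched
        assert m.partial_auc(np.exp(3 * scores), labels) == pytest.approx(value)

    def test_mcclish_normalisation(self):
        assert m.partial_auc(
            [0.5] * 10, [0, 1] * 5, normalized=True
        ) == pytest.approx(0.5)


class TestPRMetrics:
    def test_all_positives_ranked_first(self):
        *_, ap = m.pr_metrics([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert ap == pytest.approx(1.0)

    def test_hand_enumerated_sweep(self):
        # ranks: 0.9(+), 0.8(-), 0.7(+), 0.6(-) -> AP = mean of precision
        # at each positive: 1/1 and 2/3
        *_, ap = m.pr_metrics([0.9, 0.8, 0.7, 0.6], [1, 0, 1, 0])
        assert ap == pytest.approx(0.5 * (1.0 + 2 / 3))

    def test_random_scores_ap_near_prevalence(self):
        rng = np.random.default_rng(7)
        aps = []
        for _ in range(20):
            labels = (rng.random(400) < 0.2).astype(int)
            *_, ap = m.pr_metrics(rng.random(400), labels)
            aps.append(ap)
        assert np.mean(aps) == pytest.approx(0.2, abs=0.03)


class TestDeLong:
    def test_identical_scores_p_one(self):
        rng = np.random.default_rng(8)
        scores = rng.random(50)
        labels = rng.integers(0, 2, 50)
        labels[:2] = [0, 1]
        *_, p = m.delong_test(scores, scores, labels)
        assert p == 1.0

    def test_antisymmetric_in_arguments(self):
        rng = np.random.default_rng(9)
        labels = rng.integers(0, 2, 80)
        labels[:2] = [0, 1]
        a, b = rng.random(80), rng.random(80)
        _, _, z_ab, p_ab = m.delong_test(a, b, labels)
        _, _, z_ba, p_ba = m.delong_test(b, a, labels)
        assert z_ab == pytest.approx(-z_ba)
        assert p_ab == pytest.approx(p_ba)

    def test_reports_both_aucs(self):
        rng = np.random.default_rng(15)
        labels = rng.integers(0, 2, 60)
        labels[:2] = [0, 1]
        a = labels + rng.normal(0, 1.0, 60)
        b = rng.random(60)
        auc_a, auc_b, *_ = m.delong_test(a, b, labels)
        assert auc_a == pytest.approx(m.auc(a, labels), abs=1e-12)
        assert auc_b == pytest.approx(m.auc(b, labels), abs=1e-12)

    def test_degenerate_separation_rejected(self):
        # both classifiers perfectly separate in opposite directions:
        # the variance estimate is zero and no z-score exists
        labels = np.array([0, 0, 1, 1])
        with pytest.raises(ValueError):
            m.delong_test([0.1, 0.2, 0.8, 0.9], [0.9, 0.8, 0.2, 0.1], labels)


class TestSensSpecIntersection:
    def test_perfect_separation_gives_both_one(self):
        scores = [0.1, 0.2, 0.8, 0.9]
        labels = [0, 0, 1, 1]
        thr = m.sens_spec_intersection(scores, labels)
        cm = m.confusion_at(scores, labels, thr)
        assert cm.fn == 0 and cm.fp == 0

    def test_exhaustive_scan_oracle(self):
        rng = np.random.default_rng(10)
        scores = rng.random(60)
        labels = rng.integers(0, 2, 60)
        labels[:2] = [0, 1]
        thr = m.sens_spec_intersection(scores, labels)
        pos, neg = labels == 1, labels == 0

        def gap(t):
            pred = scores >= t
            return abs(pred[pos].mean() - (~pred)[neg].mean())

        uniq = np.unique(scores)
        candidates = np.concatenate([uniq, (uniq[:-1] + uniq[1:]) / 2])
        assert gap(thr) == pytest.approx(min(gap(t) for t in candidates))

    def test_constant_scores_single_candidate(self):
        thr = m.sens_spec_intersection([0.5] * 6, [0, 1] * 3)
        assert thr == 0.5

    def test_lower_is_positive_orientation(self):
        scores = [0.1, 0.2, 0.8, 0.9]  # rank-style: low = positive
        labels = [1, 1, 0, 0]
        thr = m.sens_spec_intersection(scores, labels, higher_is_positive=False)
        cm = m.confusion_at(scores, labels, thr, higher_is_positive=False)
        assert cm.fn == 0 and cm.fp == 0


class TestConfusionAndDerived:
    def test_threshold_extremes(self):
        scores = [0.2, 0.4, 0.6, 0.8]
        labels = [0, 1, 0, 1]
        low = m.confusion_at(scores, labels, 0.0)
        assert low.tp + low.fp == 4
        high = m.confusion_at(scores, labels, 1.0)
        assert high.tn + high.fn == 4

    def test_six_point_hand_case(self):
        scores = [0.9, 0.8, 0.7, 0.4, 0.3, 0.1]
        labels = [1, 0, 1, 1, 0, 0]
        cm = m.confusion_at(scores, labels, 0.7)  # equal counts positive
        assert (cm.tp, cm.fp, cm.fn, cm.tn) == (2, 1, 1, 2)

    def test_equal_to_threshold_counts_positive(self):
        cm = m.confusion_at([0.5], [1], 0.5)
        assert cm.tp == 1

    def test_mcc_degenerate_conventions(self):
        assert m.mcc(m.ConfusionMatrix(5, 0, 0, 0)) == 0.0
        assert m.mcc(m.ConfusionMatrix(1, 1, 1, 1)) == 0.0
        assert m.accuracy(m.ConfusionMatrix(1, 1, 1, 1)) == 0.5
        assert m.accuracy(m.ConfusionMatrix(5, 0, 0, 0)) == 1.0

    @given(st.integers(0, 50), st.integers(0, 50), st.integers(0, 50),
           st.integers(0, 50))
    @settings(max_examples=100, deadline=None)
    def test_mcc_bounded(self, tp, fp, fn, tn):
        if tp + fp + fn + tn == 0:
            return
        assert -1 <= m.mcc(m.ConfusionMatrix(tp, fp, fn, tn)) <= 1


class TestPerPatientTopK:
    def test_all_captured(self):
        capture = m.per_patient_topk(
            [0.9, 0.8, 0.1], [1, 1, 0], ["p", "p", "p"], k=2
        )
        assert capture["p"] == 1.0

    def test_k_exceeding_peptide_count(self):
        capture = m.per_patient_topk([0.2, 0.9], [1, 0], ["p", "p"], k=50)
        assert capture["p"] == 1.0

    def test_partial_capture(self):
        scores = [0.9, 0.5, 0.4, 0.3]
        labels = [1, 0, 1, 0]
        capture = m.per_patient_topk(scores, labels, ["p"] * 4, k=2)
        assert capture["p"] == 0.5

    def test_patient_without_positives_is_missing(self):
        capture = m.per_patient_topk([0.5, 0.4], [0, 0], ["p", "p"], k=1)
        assert capture["p"] is None

    def test_tie_at_rank_k_broken_by_peptide_id(self):
        scores = [0.5, 0.5]
        labels = [0, 1]
        by_id = m.per_patient_topk(scores, labels, ["p", "p"], k=1,
                                   peptide_ids=["a", "b"])
        assert by_id["p"] == 0.0  # "a" wins the tie, positive "b" misses
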