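"""From-scratch ROC machinery against brute-force and library oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vppg import (
    RocPoint,
    auc_with_se,
    closest_corner_cutoff,
    empirical_roc,
    hanley_mcneil_se,
    trapezoid_auc,
)


def brute_force_auc(pos, neg):
    """Pair enumeration of P(pos < neg) + 0.5·P(tie) — the defining statistic."""
    wins = ties = 0
    for p in pos:
        for q in neg:
            if p < q:
                wins += 1
            elif p == q:
                ties += 1
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


def random_instance(rng, allow_ties=True):
    m = rng.integers(1, 15)
    n = rng.integers(1, 15)
    if allow_ties:
        pool = rng.integers(0, 10, size=m + n).astype(float)
    else:
        pool = rng.permutation(m + n).astype(float)
    return pool[:m], pool[m:]


class TestEmpiricalRoc:
    def test_hand_counted_operating_points(self):
        # pos {10, 20}, neg {90, 95}: positive iff score < cutoff
        scores = [10.0, 20.0, 90.0, 95.0]
        labels = [True, True, False, False]
        points = {p.cutoff: p for p in empirical_roc(scores, labels)}
        # at cutoff 95 the negative scoring 90 is (falsely) test-positive
        assert points[95.0].sensitivity == 1.0
        assert points[95.0].specificity == 0.5
        # at cutoff 90 both positives and no negative are below
        assert points[90.0].sensitivity == 1.0
        assert points[90.0].specificity == 1.0
        assert trapezoid_auc(list(points.values())) == pytest.approx(1.0)

    def test_trivial_endpoints_present(self):
        points = empirical_roc([1.0, 2.0], [True, False])
        assert (points[0].sensitivity, points[0].specificity) == (0.0, 1.0)
        assert (points[-1].sensitivity, points[-1].specificity) == (1.0, 0.0)

    def test_identical_scores_give_chance_area(self):
        points = empirical_roc([5.0] * 6, [True, True, False, False, False, False])
        assert trapezoid_auc(points) == pytest.approx(0.5)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            empirical_roc([1.0, 2.0], [True, True])


class TestAuc:
    def test_perfect_separation(self):
        res = auc_with_se([1.0, 2.0, 8.0, 9.0], [True, True, False, False])
        assert res.auc == 1.0

    def test_interleaved_example_by_pair_enumeration(self):
        # pos {1, 3}, neg {2, 4}: concordant pairs (1,2),(1,4),(3,4) → 3/4
        pos, neg = [1.0, 3.0], [2.0, 4.0]
        assert brute_force_auc(pos, neg) == 0.75
        res = auc_with_se(pos + neg, [True, True, False, False])
        assert res.auc == pytest.approx(0.75)

    def test_trapezoid_equals_mann_whitney_oracle(self, rng):
        for _ in range(60):
            pos, neg = random_instance(rng)
            scores = np.concatenate([pos, neg])
            labels = np.array([True] * len(pos) + [False] * len(neg))
            area = trapezoid_auc(empirical_roc(scores, labels))
            assert area == pytest.approx(brute_force_auc(pos, neg), abs=1e-12)

    def test_agrees_with_scikit_learn(self, rng):
        from sklearn.metrics import roc_auc_score

        for _ in range(20):
            pos, neg = random_instance(rng)
            if len(set(pos) | set(neg)) < 2:
                continue
            scores = np.concatenate([pos, neg])
            labels = np.array([True] * len(pos) + [False] * len(neg))
            ours = auc_with_se(scores, labels).auc
            # low score = test positive, so feed the negated score to sklearn
            ref = roc_auc_score(labels, -scores)
            assert ours == pytest.approx(ref, abs=1e-12)

    def test_label_flip_symmetry(self, rng):
        pos, neg = random_instance(rng)
        scores = np.concatenate([pos, neg])
        labels = np.array([True] * len(pos) + [False] * len(neg))
        a = auc_with_se(scores, labels).auc
        b = auc_with_se(scores, ~labels).auc
        assert a + b == pytest.approx(1.0)

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(st.data())
    def test_invariant_under_monotone_transform(self, data):
        scores = data.draw(
            st.lists(st.integers(-50, 50), min_size=4, max_size=30).map(
                lambda xs: np.array(xs, dtype=float)
            )
        )
        labels = data.draw(
            st.lists(
                st.booleans(), min_size=len(scores), max_size=len(scores)
            ).map(np.array)
        )
        if labels.all() or not labels.any():
            return
        a = auc_with_se(scores, labels).auc
        b = auc_with_se(np.exp(scores / 25.0), labels).auc
        assert a == pytest.approx(b, abs=1e-12)

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(st.data())
    def test_dominant_positive_never_decreases_auc(self, data):
        scores = data.draw(
            st.lists(st.floats(0, 100), min_size=2, max_size=20).map(np.array)
        )
        labels = data.draw(
            st.lists(
                st.booleans(), min_size=len(scores), max_size=len(scores)
            ).map(np.array)
        )
        if labels.all() or not labels.any():
            return
        a = auc_with_se(scores, labels).auc
        extended = np.append(scores, scores.min() - 1.0)  # below every negative
        b = auc_with_se(extended, np.append(labels, True)).auc
        assert b >= a - 1e-12

    def test_hanley_mcneil_closed_form_at_study_scale(self):
        # area 0.589 with 207 positives and 641 negatives
        assert hanley_mcneil_se(0.589, 207, 641) == pytest.approx(0.0233, abs=2e-4)

    def test_delong_matches_hanley_order_of_magnitude(self, rng):
        pos = rng.normal(40, 20, 80)
        neg = rng.normal(55, 20, 120)
        scores = np.concatenate([pos, neg])
        labels = np.array([True] * 80 + [False] * 120)
        hm = auc_with_se(scores, labels, se_method="hanley-mcneil")
        dl = auc_with_se(scores, labels, se_method="delong")
        assert hm.auc == dl.auc
        assert dl.se == pytest.approx(hm.se, rel=0.25)

    def test_p_value_against_chance(self):
        res = auc_with_se(
            [1, 2, 3, 22, 4, 21, 20, 23],
            [True] * 4 + [False] * 4,
        )
        assert 0 < res.p <= 1
        assert res.z == pytest.approx((res.auc - 0.5) / res.se)


class TestClosestCorner:
    def test_dominating_point_wins(self):
        pts = [
            RocPoint(10, 1.0, 0.0),
            RocPoint(20, 0.8, 0.6),
            RocPoint(30, 0.0, 1.0),
        ]
        best = closest_corner_cutoff(pts)
        assert best.cutoff == 20
        assert best.distance == pytest.approx(np.sqrt(0.2))

    def test_single_point(self):
        pt = RocPoint(5, 0.4, 0.4)
        assert closest_corner_cutoff([pt]) is pt

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            closest_corner_cutoff([])

    def test_tie_breaks_by_sensitivity_then_cutoff(self):
        pts = [
            RocPoint(50, 0.6, 0.8),
            RocPoint(40, 0.8, 0.6),  # same distance, higher sensitivity
            RocPoint(45, 0.8, 0.6),  # same again, higher cutoff loses
        ]
        assert closest_corner_cutoff(pts).cutoff == 40

    def test_matches_exhaustive_search(self, rng):
        for _ in range(40):
            pos, neg = random_instance(rng)
            scores = np.concatenate([pos, neg])
            labels = np.array([True] * len(pos) + [False] * len(neg))
            points = empirical_roc(scores, labels)
            best = closest_corner_cutoff(points)
            assert best.distance == pytest.approx(
                min(p.distance for p in points), abs=1e-15
            )
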