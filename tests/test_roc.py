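import numpy as np
import pytest

from phscreen import DomainError, auc, roc_points, youden_optimal
from phscreen.cohort import Direction


def brute_force_auc(values, labels):
    """Oracle: concordant-pair counting with half-credit for ties."""
    pos = values[labels]
    neg = values[~labels]
    total = 0.0
    for x in pos:
        for y in neg:
            total += 1.0 if x > y else (0.5 if x == y else 0.0)
    return total / (len(pos) * len(neg))


def brute_force_youden(values, labels):
    """Oracle: best J over an exhaustive threshold grid."""
    pos = values[labels]
    neg = values[~labels]
    candidates = np.concatenate(
        [[-np.inf, np.inf], np.unique(values), np.unique(values) - 1e-9,
         np.unique(values) + 1e-9]
    )
    best = -2.0
    for t in candidates:
        sens = (pos > t).mean()
        spec = (neg <= t).mean()
        best = max(best, sens + spec - 1.0)
    return best


def _instance(rng, n_max=12, tie_range=6):
    while True:
        n = rng.integers(4, n_max + 1)
        labels = rng.random(n) < 0.5
        if labels.any() and (~labels).any():
            return rng.integers(0, tie_range, n).astype(float), labels


class TestRocPoints:
    def test_candidate_threshold_count(self):
        values = np.array([3, 5, 7, 1, 2, 4], dtype=float)
        labels = np.array([1, 1, 1, 0, 0, 0], dtype=bool)
        curve = roc_points(values, labels)
        assert len(curve.thresholds) == 7  # 5 midpoints + 2 sentinels

    def test_endpoints(self):
        values = np.array([3, 5, 7, 1, 2, 4], dtype=float)
        labels = np.array([1, 1, 1, 0, 0, 0], dtype=bool)
        curve = roc_points(values, labels)
        pts = set(zip(curve.sens.round(9), (1 - curve.spec).round(9)))
        assert (0.0, 0.0) in pts and (1.0, 1.0) in pts

    def test_staircase_monotone(self, rng):
        for _ in range(30):
            values, labels = _instance(rng)
            curve = roc_points(values, labels)
            assert (np.diff(curve.sens) <= 1e-12).all()
            assert (np.diff(1 - curve.spec) <= 1e-12).all()

    def test_perfect_separation_hits_corner(self):
        values = np.array([10, 11, 12, 1, 2, 3], dtype=float)
        labels = np.array([1, 1, 1, 0, 0, 0], dtype=bool)
        curve = roc_points(values, labels)
        assert any(s == 1.0 and sp == 1.0 for s, sp in zip(curve.sens, curve.spec))

    def test_direction_reversal_swaps_roles(self):
        values = np.array([3, 5, 7, 1, 2, 4], dtype=float)
        labels = np.array([1, 1, 1, 0, 0, 0], dtype=bool)
        fwd = roc_points(values, labels, Direction.ABOVE_IS_RISK)
        rev = roc_points(values, labels, Direction.BELOW_IS_RISK)
        assert np.allclose(np.sort(fwd.sens), np.sort(1 - rev.spec))

    def test_single_class_rejected(self):
        with pytest.raises(DomainError):
            roc_points(np.array([1.0, 2.0]), np.array([True, True]))


class TestAuc:
    def test_pair_counting_example(self):
        values = np.array([3, 5, 7, 1, 2, 4], dtype=float)
        labels = np.array([1, 1, 1, 0, 0, 0], dtype=bool)
        assert auc(values, labels).auc == pytest.approx(8 / 9)

    def test_perfect_separation_warns_and_degenerates(self):
        values = np.array([10.0, 11.0, 1.0, 2.0])
        labels = np.array([True, True, False, False])
        with pytest.warns(UserWarning):
            res = auc(values, labels)
        assert res.auc == 1.0
        assert res.ci_low == res.ci_high == 1.0

    def test_label_inversion_complements(self, rng):
        values, labels = _instance(rng)
        a1 = auc(values, labels).auc
        a2 = auc(values, ~labels).auc
        assert a1 + a2 == pytest.approx(1.0)

    def test_matches_brute_force_on_tied_instances(self, rng):
        for _ in range(500):
            values, labels = _instance(rng)
            assert auc(values, labels).auc == pytest.approx(
                brute_force_auc(values, labels), abs=1e-12
            )

    def test_ci_ordering_and_range(self, rng):
        for _ in range(25):
            values, labels = _instance(rng, n_max=20, tie_range=50)
            res = auc(values, labels)
            assert 0.0 <= res.ci_low <= res.auc <= res.ci_high <= 1.0

    def test_equals_scaled_mann_whitney(self, rng):
        from phscreen import mann_whitney_u

        for _ in range(50):
            values, labels = _instance(rng)
            u, _ = mann_whitney_u(values[labels], values[~labels])
            n1, n2 = labels.sum(), (~labels).sum()
            assert auc(values, labels).auc == pytest.approx(u / (n1 * n2))


class TestYouden:
    def test_example_tie_broken_toward_specificity(self):
        values = np.array([3, 5, 7, 1, 2, 4], dtype=float)
        labels = np.array([1, 1, 1, 0, 0, 0], dtype=bool)
        res = youden_optimal(roc_points(values, labels))
        assert res.cutoff == pytest.approx(4.5)
        assert res.youden_j == pytest.approx(2 / 3)
        assert res.specificity == 1.0

    def test_perfect_separation(self):
        values = np.array([10.0, 11.0, 1.0, 2.0])
        labels = np.array([True, True, False, False])
        res = youden_optimal(roc_points(values, labels))
        assert res.youden_j == pytest.approx(1.0)
        assert res.cutoff == pytest.approx(6.0)

    def test_identical_distributions_j_zero(self):
        values = np.array([1, 2, 3, 1, 2, 3], dtype=float)
        labels = np.array([1, 1, 1, 0, 0, 0], dtype=bool)
        res = youden_optimal(roc_points(values, labels))
        assert res.youden_j == pytest.approx(0.0)

    def test_j_identity_invariant(self, rng):
        for _ in range(50):
            values, labels = _instance(rng)
            res = youden_optimal(roc_points(values, labels))
            assert res.youden_j == pytest.approx(
                res.sensitivity + res.specificity - 1.0
            )

    def test_matches_exhaustive_search(self, rng):
        for _ in range(300):
            values, labels = _instance(rng, n_max=10)
            res = youden_optimal(roc_points(values, labels))
            assert res.youden_j == pytest.approx(
                brute_force_youden(values, labels), abs=1e-9
            )

    def test_below_is_risk_cutoff_on_original_scale(self):
        # risk is low walk distance; all positives below all negatives
        values = np.array([400.0, 450.0, 600.0, 650.0])
        labels = np.array([True, True, False, False])
        res = youden_optimal(roc_points(values, labels, Direction.BELOW_IS_RISK))
        assert res.cutoff == pytest.approx(525.0)
        assert res.youden_j == pytest.approx(1.0)

    def test_ppv_npv_at_cohort_prevalence(self):
        values = np.array([3, 5, 7, 1, 2, 4], dtype=float)
        labels = np.array([1, 1, 1, 0, 0, 0], dtype=bool)
        res = youden_optimal(roc_points(values, labels))
        # cutoff 4.5: tp=2, fn=1, tn=3, fp=0 at prevalence 1/2
        assert res.ppv == pytest.approx(1.0)
        assert res.npv == pytest.approx(3 / 4)


class TestMonotoneInvariance:
    def test_increasing_transform_preserves_auc_and_operating_point(self, rng):
        for _ in range(30):
            values, labels = _instance(rng, tie_range=20)
            transformed = np.exp(values / 5.0)  # strictly increasing
            a1 = auc(values, labels).auc
            a2 = auc(transformed, labels).auc
            assert a1 == pytest.approx(a2, abs=1e-12)
            r1 = youden_optimal(roc_points(values, labels))
            r2 = youden_optimal(roc_points(transformed, labels))
            assert r1.sensitivity == pytest.approx(r2.sensitivity)
            assert r1.specificity == pytest.approx(r2.specificity)
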