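import itertools

import numpy as np
import pytest

from phscreen import (
    ConfusionMatrix,
    DomainError,
    MissingDataError,
    PHGroup,
    attainable_scores,
    classify,
    composite_score,
    confusion_metrics,
    default_weights,
    evaluate_score_on_cohort,
    reconstruct_confusion,
)

from conftest import make_record


# record values satisfying / failing each default criterion
_MET = dict(age=60.0, six_mwd=478.0, sat6=89.0)
_UNMET = dict(age=40.0, six_mwd=600.0, sat6=97.0)


def record_for(met_flags):
    """Build a record hitting exactly the given (age, tlc/dlco, 6mwd, sat6)
    criteria."""
    age_m, ratio_m, mwd_m, sat_m = met_flags
    return make_record(
        age=_MET["age"] if age_m else _UNMET["age"],
        tlc_pct=93.0,
        dlco_pct=50.0 if ratio_m else 77.5,  # ratio 1.86 vs 1.2
        six_mwd=_MET["six_mwd"] if mwd_m else _UNMET["six_mwd"],
        sat0=98.0,
        sat6=_MET["sat6"] if sat_m else _UNMET["sat6"],
    )


class TestCompositeScore:
    def test_all_criteria_met_scores_ten(self):
        assert composite_score(record_for((1, 1, 1, 1)), default_weights()) == 10

    def test_no_criteria_met_scores_zero(self):
        assert composite_score(record_for((0, 0, 0, 0)), default_weights()) == 0

    def test_boundary_values_fail_strict_thresholds(self):
        rec = make_record(
            age=54.0,  # met (+3)
            tlc_pct=90.0,
            dlco_pct=60.0,  # ratio 1.5, unmet
            six_mwd=500.0,  # met (+2)
            sat0=98.0,
            sat6=93.0,  # exactly at cutoff -> unmet
        )
        assert composite_score(rec, default_weights()) == 5

    def test_monotone_in_each_criterion(self):
        w = default_weights()
        for flags in itertools.product([0, 1], repeat=4):
            score = composite_score(record_for(flags), w)
            for i in range(4):
                if not flags[i]:
                    worse = list(flags)
                    worse[i] = 1
                    assert composite_score(record_for(tuple(worse)), w) >= score

    def test_attainable_set(self):
        assert attainable_scores(default_weights()) == {0, 2, 3, 4, 5, 6, 7, 8, 10}
        observed = {
            composite_score(record_for(flags), default_weights())
            for flags in itertools.product([0, 1], repeat=4)
        }
        assert observed == {0, 2, 3, 4, 5, 6, 7, 8, 10}

    def test_max_score_is_ten(self):
        assert default_weights().max_score == 10


class TestClassify:
    @pytest.mark.parametrize("score,expected", [(6, True), (5, False), (10, True), (0, False)])
    def test_decision_rule_inclusive(self, score, expected):
        assert classify(score, default_weights()) is expected


class TestConfusionMetrics:
    def test_printed_composite_counts(self):
        m = confusion_metrics(ConfusionMatrix(tp=27, fn=14, tn=49, fp=3))
        assert m.ppv == pytest.approx(0.90)
        assert m.npv == pytest.approx(49 / 63)

    def test_undefined_ppv_flagged(self):
        m = confusion_metrics(ConfusionMatrix(tp=0, fp=0, fn=5, tn=5))
        assert m.ppv is None
        assert m.npv is not None

    def test_perfect_classifier(self):
        m = confusion_metrics(ConfusionMatrix(tp=10, fp=0, fn=0, tn=10))
        assert (m.sensitivity, m.specificity, m.ppv, m.npv) == (1.0, 1.0, 1.0, 1.0)

    def test_single_class_rejected(self):
        with pytest.raises(DomainError):
            confusion_metrics(ConfusionMatrix(tp=5, fp=0, fn=5, tn=0))


class TestReconstructConfusion:
    def test_printed_composite_rates(self):
        cm = reconstruct_confusion(0.66, 0.94, 41, 52)
        assert (cm.tp, cm.fn, cm.tn, cm.fp) == (27, 14, 49, 3)

    def test_printed_ratio_alone_rates(self):
        cm = reconstruct_confusion(0.65, 0.92, 41, 52)
        assert (cm.tp, cm.fn, cm.tn, cm.fp) == (27, 14, 48, 4)

    def test_perfect_rates(self):
        cm = reconstruct_confusion(1.0, 1.0, 10, 20)
        assert (cm.fn, cm.fp) == (0, 0)

    def test_round_trip_rate_error_bound(self, rng):
        for _ in range(200):
            sens, spec = rng.random(2)
            n_pos, n_neg = rng.integers(5, 100, size=2)
            cm = reconstruct_confusion(sens, spec, int(n_pos), int(n_neg))
            m = confusion_metrics(cm)
            bound = 1.0 / (2 * min(n_pos, n_neg))
            assert abs(m.sensitivity - sens) <= bound + 1e-12
            assert abs(m.specificity - spec) <= bound + 1e-12

    def test_bad_rates_rejected(self):
        with pytest.raises(DomainError):
            reconstruct_confusion(1.2, 0.5, 10, 10)


class TestEvaluateOnCohort:
    def test_fully_separated_cohort(self):
        records = [
            make_record(
                id=f"B{i}", ph_group=PHGroup.B_INCREASED,
                age=60.0, tlc_pct=93.0, dlco_pct=50.0, six_mwd=478.0,
                sat0=98.0, sat6=89.0,
            )
            for i in range(5)
        ] + [
            make_record(
                id=f"A{i}", ph_group=PHGroup.A_LOW,
                age=40.0, tlc_pct=93.0, dlco_pct=77.5, six_mwd=600.0,
                sat0=98.0, sat6=97.0,
            )
            for i in range(5)
        ]
        with pytest.warns(UserWarning):
            metrics = evaluate_score_on_cohort(records)
        assert metrics.auc_result.auc == 1.0
        assert metrics.at_cutoff.sensitivity == 1.0
        assert metrics.at_cutoff.specificity == 1.0

    def test_synthetic_default_cohort_auc_above_half(self, default_cohort):
        metrics = evaluate_score_on_cohort(default_cohort)
        assert metrics.auc_result.auc > 0.5
        cm = metrics.confusion
        assert cm.n_pos == 41 and cm.n_neg == 52

    def test_permutation_null_auc_near_half(self, default_cohort, rng):
        scores = np.asarray(
            evaluate_score_on_cohort(default_cohort).scores, dtype=float
        )
        labels = np.array([r.ph_group is PHGroup.B_INCREASED for r in default_cohort])
        from phscreen import auc as roc_auc

        aucs = []
        for _ in range(200):
            aucs.append(roc_auc(scores, rng.permutation(labels)).auc)
        assert np.mean(aucs) == pytest.approx(0.5, abs=0.02)

    def test_single_stratum_rejected(self):
        records = [
            make_record(id=f"B{i}", ph_group=PHGroup.B_INCREASED) for i in range(4)
        ]
        with pytest.raises(DomainError):
            evaluate_score_on_cohort(records)

    def test_missing_score_variable_reported(self):
        rec = make_record()
        object.__setattr__(rec, "sat6", None)
        records = [rec]
        with pytest.raises((MissingDataError, TypeError)):
            composite_score(rec, default_weights())
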