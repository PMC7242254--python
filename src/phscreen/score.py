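"""Composite PH-prediction score.

Default weights: age > 53 years and TLC/DLCO > 1.67 score three points
each; 6-minute walk distance < 507.5 m and sixth-minute saturation < 93%
score two points each (maximum 10). A total of 6 points or more flags
increased PH probability. All thresholds are strict and configurable.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .cohort import Direction, PatientRecord, PHGroup, ThresholdSpec, dichotomize
from .errors import ConfigurationError, DomainError, MissingDataError
from .risk import ConfusionMatrix
from .roc import AucResult, CutoffResult, auc as roc_auc

__all__ = [
    "ScoreWeights",
    "ScoreMetrics",
    "RateMetrics",
    "default_weights",
    "composite_score",
    "classify",
    "confusion_metrics",
    "reconstruct_confusion",
    "evaluate_score_on_cohort",
    "attainable_scores",
]


def default_weights() -> "ScoreWeights":
    return ScoreWeights(
        items=(
            (ThresholdSpec("age", 53.0, Direction.ABOVE_IS_RISK), 3),
            (ThresholdSpec("tlc_dlco", 1.67, Direction.ABOVE_IS_RISK), 3),
            (ThresholdSpec("six_mwd", 507.5, Direction.BELOW_IS_RISK), 2),
            (ThresholdSpec("sat6", 93.0, Direction.BELOW_IS_RISK), 2),
        ),
        decision_cutoff=6,
    )


@dataclass(frozen=True)
class ScoreWeights:
    """Scored criteria and the decision cutoff (score >= cutoff is
    test-positive)."""

    items: tuple[tuple[ThresholdSpec, int], ...]
    decision_cutoff: int

    def __post_init__(self) -> None:
        if not self.items:
            raise ConfigurationError("at least one scored criterion is required")
        for spec, points in self.items:
            if points <= 0 or points != int(points):
                raise ConfigurationError(
                    f"points for {spec.variable} must be a positive integer"
                )

    @property
    def max_score(self) -> int:
        return sum(points for _, points in self.items)

    def to_json(self) -> str:
        return json.dumps(
            {
                "items": [
                    {
                        "variable": spec.variable,
                        "cutoff": spec.cutoff,
                        "direction": spec.direction.value,
                        "points": points,
                    }
                    for spec, points in self.items
                ],
                "decision_cutoff": self.decision_cutoff,
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "ScoreWeights":
        raw = json.loads(text)
        items = tuple(
            (
                ThresholdSpec(
                    item["variable"], float(item["cutoff"]), Direction(item["direction"])
                ),
                int(item["points"]),
            )
            for item in raw["items"]
        )
        return cls(items=items, decision_cutoff=int(raw["decision_cutoff"]))


@dataclass(frozen=True)
class RateMetrics:
    """Operating rates; an undefined rate (empty denominator) is None."""

    sensitivity: float
    specificity: float
    ppv: float | None
    npv: float | None


@dataclass(frozen=True)
class ScoreMetrics:
    auc_result: AucResult
    at_cutoff: CutoffResult
    confusion: ConfusionMatrix
    scores: tuple[int, ...] = field(default=(), compare=False)


def composite_score(record: PatientRecord, weights: ScoreWeights) -> int:
    """Sum of points over satisfied (strict) threshold criteria."""
    total = 0
    missing = []
    for spec, points in weights.items:
        try:
            if dichotomize(record, spec):
                total += points
        except MissingDataError:
            missing.append(spec.variable)
    if missing:
        raise MissingDataError(
            f"record {record.id}: score variables missing: {', '.join(missing)}"
        )
    return total


def classify(score: int, weights: ScoreWeights) -> bool:
    """True iff the score meets the decision cutoff (inclusive)."""
    return score >= weights.decision_cutoff


def attainable_scores(weights: ScoreWeights) -> set[int]:
    """Every total reachable over the criterion combinations."""
    totals = {0}
    for _, points in weights.items:
        totals |= {t + points for t in totals}
    return totals


def confusion_metrics(cm: ConfusionMatrix) -> RateMetrics:
    """Sensitivity, specificity, PPV, NPV from integer counts.

    PPV/NPV are None (flagged undefined) when their denominator is empty
    rather than silently zero.
    """
    if cm.n_pos == 0 or cm.n_neg == 0:
        raise DomainError("confusion matrix must contain both classes")
    ppv = cm.tp / (cm.tp + cm.fp) if (cm.tp + cm.fp) > 0 else None
    npv = cm.tn / (cm.tn + cm.fn) if (cm.tn + cm.fn) > 0 else None
    return RateMetrics(
        sensitivity=cm.tp / cm.n_pos,
        specificity=cm.tn / cm.n_neg,
        ppv=ppv,
        npv=npv,
    )


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def reconstruct_confusion(
    sensitivity: float, specificity: float, n_pos: int, n_neg: int
) -> ConfusionMatrix:
    """Invert printed sensitivity/specificity to integer counts.

    tp = round(sens * n_pos), tn = round(spec * n_neg) with round-half-away
    -from-zero; the complements fill fn and fp. Raises on impossible rates.
    """
    if not (0 <= sensitivity <= 1 and 0 <= specificity <= 1):
        raise DomainError("rates must lie in [0, 1]")
    if n_pos <= 0 or n_neg <= 0:
        raise DomainError("strata sizes must be positive integers")
    tp = _round_half_away(sensitivity * n_pos)
    tn = _round_half_away(specificity * n_neg)
    fn = n_pos - tp
    fp = n_neg - tn
    if min(tp, tn, fn, fp) < 0:
        raise DomainError("reconstructed counts are inconsistent")
    return ConfusionMatrix(tp=tp, fp=fp, fn=fn, tn=tn)


def evaluate_score_on_cohort(
    cohort: Sequence[PatientRecord], weights: ScoreWeights | None = None
) -> ScoreMetrics:
    """Score every record and evaluate the decision rule on the cohort.

    AUC treats the integer score as a test value with larger-is-riskier
    orientation; the confusion matrix and operating point are taken at the
    decision cutoff.
    """
    weights = weights or default_weights()
    labels = []
    for rec in cohort:
        if rec.ph_group is None:
            raise MissingDataError(f"record {rec.id}: ph_group missing")
        labels.append(rec.ph_group is PHGroup.B_INCREASED)
    labels = np.asarray(labels, dtype=bool)
    if not (labels.any() and (~labels).any()):
        raise DomainError("cohort must contain both PH-probability strata")

    scores = np.asarray([composite_score(rec, weights) for rec in cohort])
    auc_result = roc_auc(scores, labels, Direction.ABOVE_IS_RISK)

    predicted = scores >= weights.decision_cutoff
    cm = ConfusionMatrix(
        tp=int((predicted & labels).sum()),
        fp=int((predicted & ~labels).sum()),
        fn=int((~predicted & labels).sum()),
        tn=int((~predicted & ~labels).sum()),
    )
    rates = confusion_metrics(cm)
    at_cutoff = CutoffResult(
        cutoff=float(weights.decision_cutoff),
        sensitivity=rates.sensitivity,
        specificity=rates.specificity,
        ppv=float("nan") if rates.ppv is None else rates.ppv,
        npv=float("nan") if rates.npv is None else rates.npv,
        youden_j=rates.sensitivity + rates.specificity - 1.0,
    )
    return ScoreMetrics(
        auc_result=auc_result,
        at_cutoff=at_cutoff,
        confusion=cm,
        scores=tuple(int(s) for s in scores),
    )
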