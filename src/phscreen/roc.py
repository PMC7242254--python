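"""Empirical ROC curves, AUC with DeLong confidence intervals, and
Youden-optimal cutoffs with operating-point metrics.

The positive class is the increased-PH-probability stratum throughout.
Candidate cutoffs are midpoints between adjacent distinct observed values
plus infinite sentinels; comparisons at a cutoff are strict (value > t is
test-positive after orienting so that larger means riskier).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .cohort import Direction
from .errors import DomainError

__all__ = [
    "RocCurve",
    "AucResult",
    "CutoffResult",
    "roc_points",
    "auc",
    "youden_optimal",
    "plot_roc",
]


@dataclass(frozen=True)
class RocCurve:
    """Empirical ROC staircase over the exhaustive candidate-cutoff set.

    ``thresholds`` are on the oriented scale (values negated when the
    direction is below_is_risk) in ascending order, with -inf/+inf
    sentinels; ``sens[i]``/``spec[i]`` are the operating characteristics of
    the rule "oriented value > thresholds[i]".
    """

    thresholds: np.ndarray
    sens: np.ndarray
    spec: np.ndarray
    direction: Direction
    n_pos: int
    n_neg: int
    pooled_median: float

    def original_cutoff(self, threshold: float) -> float:
        """Map an oriented threshold back to the variable's scale."""
        if self.direction is Direction.ABOVE_IS_RISK:
            return threshold
        return -threshold


@dataclass(frozen=True)
class AucResult:
    auc: float
    ci_low: float
    ci_high: float
    p_value: float
    level: float = 0.95
    se: float = float("nan")


@dataclass(frozen=True)
class CutoffResult:
    cutoff: float
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    youden_j: float


def _oriented(values, labels, direction) -> tuple[np.ndarray, np.ndarray]:
    v = np.asarray(values, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if v.shape != y.shape or v.ndim != 1:
        raise DomainError("values and labels must be 1-d arrays of equal length")
    if not (y.any() and (~y).any()):
        raise DomainError("both classes must be present")
    if not isinstance(direction, Direction):
        direction = Direction(direction)
    if direction is Direction.BELOW_IS_RISK:
        v = -v
    return v, y


def roc_points(values, labels, direction=Direction.ABOVE_IS_RISK) -> RocCurve:
    """Build the empirical ROC curve; ties collapse to one threshold."""
    if not isinstance(direction, Direction):
        direction = Direction(direction)
    v, y = _oriented(values, labels, direction)
    distinct = np.unique(v)
    mids = (distinct[:-1] + distinct[1:]) / 2.0
    thresholds = np.concatenate([[-np.inf], mids, [np.inf]])
    pos = v[y]
    neg = v[~y]
    sens = (pos[None, :] > thresholds[:, None]).mean(axis=1)
    spec = (neg[None, :] <= thresholds[:, None]).mean(axis=1)
    return RocCurve(
        thresholds=thresholds,
        sens=sens,
        spec=spec,
        direction=direction,
        n_pos=int(pos.size),
        n_neg=int(neg.size),
        pooled_median=float(np.median(v)),
    )


def _delong(pos: np.ndarray, neg: np.ndarray) -> tuple[float, float]:
    """AUC and its DeLong standard error from oriented class values."""
    psi = (pos[:, None] > neg[None, :]).astype(float)
    psi += 0.5 * (pos[:, None] == neg[None, :])
    a = float(psi.mean())
    v10 = psi.mean(axis=1)  # structural components per positive
    v01 = psi.mean(axis=0)  # per negative
    s10 = v10.var(ddof=1) if pos.size > 1 else 0.0
    s01 = v01.var(ddof=1) if neg.size > 1 else 0.0
    se = math.sqrt(s10 / pos.size + s01 / neg.size)
    return a, se


def auc(
    values,
    labels,
    direction=Direction.ABOVE_IS_RISK,
    level: float = 0.95,
) -> AucResult:
    """Trapezoidal AUC (= tie-adjusted Mann-Whitney statistic scaled by
    n_pos*n_neg) with a logit-transformed DeLong confidence interval and a
    normal-theory p-value against AUC = 0.5.
    """
    v, y = _oriented(values, labels, direction)
    a, se = _delong(v[y], v[~y])
    z = stats.norm.ppf(0.5 + level / 2.0)
    if se == 0.0:
        warnings.warn(
            "zero DeLong variance (perfect or degenerate separation); "
            "confidence interval collapses to the point estimate",
            stacklevel=2,
        )
        p = 1.0 if a == 0.5 else 0.0
        return AucResult(auc=a, ci_low=a, ci_high=a, p_value=p, level=level, se=0.0)
    # logit-scale interval keeps the bounds inside (0, 1)
    logit = math.log(a / (1.0 - a))
    se_logit = se / (a * (1.0 - a))
    lo = 1.0 / (1.0 + math.exp(-(logit - z * se_logit)))
    hi = 1.0 / (1.0 + math.exp(-(logit + z * se_logit)))
    p = float(2.0 * stats.norm.sf(abs(a - 0.5) / se))
    return AucResult(
        auc=a,
        ci_low=min(lo, a),
        ci_high=max(hi, a),
        p_value=p,
        level=level,
        se=se,
    )


def youden_optimal(curve: RocCurve) -> CutoffResult:
    """Operating point maximizing J = sensitivity + specificity - 1.

    Ties are broken toward higher specificity, then toward the threshold
    farther from the pooled median (stability). Predictive values use the
    cohort prevalence n_pos / (n_pos + n_neg).
    """
    j = curve.sens + curve.spec - 1.0
    order = np.lexsort(
        (
            -np.abs(curve.thresholds - curve.pooled_median),
            -curve.spec,
            -j,
        )
    )
    best = order[0]
    sens = float(curve.sens[best])
    spec = float(curve.spec[best])
    prev = curve.n_pos / (curve.n_pos + curve.n_neg)
    pos_rate = sens * prev + (1.0 - spec) * (1.0 - prev)
    neg_rate = (1.0 - sens) * prev + spec * (1.0 - prev)
    ppv = sens * prev / pos_rate if pos_rate > 0 else float("nan")
    npv = spec * (1.0 - prev) / neg_rate if neg_rate > 0 else float("nan")
    return CutoffResult(
        cutoff=curve.original_cutoff(float(curve.thresholds[best])),
        sensitivity=sens,
        specificity=spec,
        ppv=ppv,
        npv=npv,
        youden_j=float(j[best]),
    )


def plot_roc(curve: RocCurve, path: str, title: str = "ROC curve") -> None:
    """Write a basic ROC plot to ``path`` (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    order = np.argsort(1.0 - curve.spec)
    fpr = (1.0 - curve.spec)[order]
    tpr = curve.sens[order]
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.step(fpr, tpr, where="post")
    ax.plot([0, 1], [0, 1], linestyle="--", linewidth=0.8, color="grey")
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("Sensitivity")
    ax.set_title(title)
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
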