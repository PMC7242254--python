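"""Univariate risk estimation: hand-rolled IRLS logistic regression and
closed-form 2x2 odds ratios with Wald confidence intervals."""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import DomainError

__all__ = [
    "LogisticFit",
    "ConfusionMatrix",
    "OddsRatioResult",
    "fit_logistic_irls",
    "odds_ratio_2x2",
]


@dataclass(frozen=True)
class LogisticFit:
    beta0: float
    beta1: float
    se1: float
    or_per_unit: float
    ci_low: float
    ci_high: float
    converged: bool
    iterations: int
    p_value: float


@dataclass(frozen=True)
class ConfusionMatrix:
    """Binary-classification counts; also reused as a 2x2 exposure table
    (tp=exposed positive, fp=exposed negative, fn=unexposed positive,
    tn=unexposed negative)."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn"):
            if getattr(self, name) < 0:
                raise DomainError(f"{name} must be >= 0")

    @property
    def n_pos(self) -> int:
        return self.tp + self.fn

    @property
    def n_neg(self) -> int:
        return self.tn + self.fp


@dataclass(frozen=True)
class OddsRatioResult:
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    corrected: bool  # Haldane-Anscombe +0.5 applied


def fit_logistic_irls(
    x,
    y,
    tol: float = 1e-8,
    max_iter: int = 50,
    level: float = 0.95,
) -> LogisticFit:
    """Fit logit(P(y=1)) = beta0 + beta1*x by Newton / iteratively
    reweighted least squares.

    Converges when the score (gradient) norm drops below ``tol``. Perfect
    separation shows up as non-convergence and is flagged, never silently
    returned as a finite estimate. The odds ratio per unit of x carries a
    Wald interval from the inverse observed information.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise DomainError("x and y must be 1-d arrays of equal length")
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise DomainError("y must be binary 0/1")
    if y.min() == y.max():
        raise DomainError("both classes must be present")
    if x.min() == x.max():
        raise DomainError("x is constant; slope is unidentifiable")

    # standardize for numerical stability, transform back afterwards
    mu, sigma = x.mean(), x.std()
    xs = (x - mu) / sigma
    design = np.column_stack([np.ones_like(xs), xs])
    beta = np.zeros(2)
    converged = False
    iterations = 0
    info = np.eye(2)
    for iterations in range(1, max_iter + 1):
        eta = design @ beta
        p = 1.0 / (1.0 + np.exp(-np.clip(eta, -500, 500)))
        grad = design.T @ (y - p)
        w = p * (1.0 - p)
        info = design.T @ (design * w[:, None])
        if np.linalg.norm(grad) < tol:
            converged = True
            break
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError:
            break
        beta = beta + step
        if np.abs(beta).max() > 1e3:  # diverging: separation
            break
    # a huge standardized slope means quasi-complete separation even if the
    # score norm dipped below tol after the likelihood flattened out
    if np.abs(beta).max() > 15.0:
        converged = False

    cov = np.linalg.pinv(info)
    beta1 = beta[1] / sigma
    beta0 = beta[0] - beta[1] * mu / sigma
    se1 = math.sqrt(max(cov[1, 1], 0.0)) / sigma
    z = stats.norm.ppf(0.5 + level / 2.0)
    def _safe_exp(v: float) -> float:
        try:
            return math.exp(v)
        except OverflowError:
            return math.inf

    or_pu = _safe_exp(beta1)
    p_value = (
        float(2.0 * stats.norm.sf(abs(beta1) / se1)) if se1 > 0 else float("nan")
    )
    return LogisticFit(
        beta0=float(beta0),
        beta1=float(beta1),
        se1=float(se1),
        or_per_unit=or_pu,
        ci_low=_safe_exp(beta1 - z * se1),
        ci_high=_safe_exp(beta1 + z * se1),
        converged=converged,
        iterations=iterations,
        p_value=p_value,
    )


def odds_ratio_2x2(
    cm: ConfusionMatrix,
    correction: bool = False,
    level: float = 0.95,
) -> OddsRatioResult:
    """Odds ratio (tp*tn)/(fp*fn) with Wald CI on the log scale.

    A zero cell is a domain error unless ``correction`` enables the
    Haldane-Anscombe +0.5 adjustment, which is then flagged in the result.
    """
    cells = [cm.tp, cm.fp, cm.fn, cm.tn]
    corrected = False
    if any(c == 0 for c in cells):
        if not correction:
            raise DomainError(
                "zero cell in 2x2 table; enable the Haldane-Anscombe correction"
            )
        cells = [c + 0.5 for c in cells]
        corrected = True
    a, b, c, d = cells
    or_ = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = stats.norm.ppf(0.5 + level / 2.0)
    log_or = math.log(or_)
    p = float(2.0 * stats.norm.sf(abs(log_or) / se))
    return OddsRatioResult(
        odds_ratio=or_,
        ci_low=math.exp(log_or - z * se),
        ci_high=math.exp(log_or + z * se),
        p_value=p,
        corrected=corrected,
    )
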