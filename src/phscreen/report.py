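"""Full-report orchestration: paper-shaped CSV tables and score metrics.

Emits four CSVs (group comparison, ROC AUCs, Youden cutoffs, univariate
odds ratios) plus a JSON file with composite-score metrics and run
metadata. Display values are rounded (3 decimals for AUCs, 2 for
operating-point rates); the JSON keeps full precision.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .cohort import Direction, PatientRecord, PHGroup, ThresholdSpec, dichotomize
from .errors import DomainError
from .groupstats import compare_groups
from .io import extract_variable
from .risk import ConfusionMatrix, fit_logistic_irls, odds_ratio_2x2
from .roc import auc as roc_auc, roc_points, youden_optimal
from .score import ScoreWeights, default_weights, evaluate_score_on_cohort

__all__ = ["ReportBundle", "ANALYSIS_VARIABLES", "run_full_report"]

# analysis variables and their risk directions (larger-is-riskier unless
# physiology says otherwise)
ANALYSIS_VARIABLES: tuple[tuple[str, Direction], ...] = (
    ("age", Direction.ABOVE_IS_RISK),
    ("pack_years", Direction.ABOVE_IS_RISK),
    ("six_mwd", Direction.BELOW_IS_RISK),
    ("sat0", Direction.BELOW_IS_RISK),
    ("sat6", Direction.BELOW_IS_RISK),
    ("desaturation", Direction.ABOVE_IS_RISK),
    ("fev1_fvc", Direction.BELOW_IS_RISK),
    ("fvc_pct", Direction.BELOW_IS_RISK),
    ("tlc_pct", Direction.BELOW_IS_RISK),
    ("dlco_pct", Direction.BELOW_IS_RISK),
    ("tlc_dlco", Direction.ABOVE_IS_RISK),
    ("fvc_dlco", Direction.ABOVE_IS_RISK),
    ("vc_dlco", Direction.ABOVE_IS_RISK),
    ("ntprobnp", Direction.ABOVE_IS_RISK),
)


@dataclass(frozen=True)
class ReportBundle:
    group_comparison: pd.DataFrame
    roc_auc: pd.DataFrame
    cutoffs: pd.DataFrame
    odds_ratios: pd.DataFrame
    score_metrics: dict


def _check_strata(cohort: Sequence[PatientRecord]) -> None:
    groups = {rec.ph_group for rec in cohort}
    if PHGroup.A_LOW not in groups or PHGroup.B_INCREASED not in groups:
        raise DomainError("cohort must contain both PH-probability strata")


def run_full_report(
    cohort: Sequence[PatientRecord],
    out_dir: Optional[str | Path] = None,
    weights: Optional[ScoreWeights] = None,
    level: float = 0.95,
    seed: Optional[int] = None,
) -> ReportBundle:
    """Compute every report table on a labelled cohort.

    When ``out_dir`` is given, writes ``group_comparison.csv``,
    ``roc_auc.csv``, ``cutoffs.csv``, ``odds_ratios.csv`` and
    ``score_metrics.json`` there.
    """
    _check_strata(cohort)
    weights = weights or default_weights()

    comparison_rows = []
    auc_rows = []
    cutoff_rows = []
    or_rows = []
    for variable, direction in ANALYSIS_VARIABLES:
        values, labels = extract_variable(cohort, variable)
        if not (labels.any() and (~labels).any()):
            continue
        a_vals = values[~labels]
        b_vals = values[labels]
        summary = compare_groups(a_vals, b_vals, variable=variable)
        comparison_rows.append(
            {
                "variable": variable,
                "mean_a": round(summary.mean_a, 2),
                "sd_a": round(summary.sd_a, 2),
                "n_a": summary.n_a,
                "mean_b": round(summary.mean_b, 2),
                "sd_b": round(summary.sd_b, 2),
                "n_b": summary.n_b,
                "p_value": summary.p_value,
                "test_used": summary.test_used,
            }
        )

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            auc_result = roc_auc(values, labels, direction, level=level)
        auc_rows.append(
            {
                "variable": variable,
                "auc": round(auc_result.auc, 3),
                "ci_low": round(auc_result.ci_low, 3),
                "ci_high": round(auc_result.ci_high, 3),
                "p_value": auc_result.p_value,
            }
        )

        curve = roc_points(values, labels, direction)
        optimum = youden_optimal(curve)
        cutoff_rows.append(
            {
                "variable": variable,
                "cutoff": optimum.cutoff,
                "specificity": round(optimum.specificity, 2),
                "sensitivity": round(optimum.sensitivity, 2),
                "ppv": round(optimum.ppv, 2),
                "npv": round(optimum.npv, 2),
                "youden_j": round(optimum.youden_j, 3),
            }
        )

        or_rows.append(
            _odds_ratio_row(cohort, variable, direction, optimum.cutoff, level)
        )

    metrics = evaluate_score_on_cohort(cohort, weights)
    score_metrics = {
        "metadata": {
            "package_version": __version__,
            "seed": seed,
            "confidence_level": level,
            "weights": json.loads(weights.to_json()),
            "n_records": len(cohort),
        },
        "auc": metrics.auc_result.auc,
        "auc_ci": [metrics.auc_result.ci_low, metrics.auc_result.ci_high],
        "auc_p_value": metrics.auc_result.p_value,
        "decision_cutoff": weights.decision_cutoff,
        "sensitivity": metrics.at_cutoff.sensitivity,
        "specificity": metrics.at_cutoff.specificity,
        "ppv": metrics.at_cutoff.ppv,
        "npv": metrics.at_cutoff.npv,
        "confusion": {
            "tp": metrics.confusion.tp,
            "fp": metrics.confusion.fp,
            "fn": metrics.confusion.fn,
            "tn": metrics.confusion.tn,
        },
        "scores": list(metrics.scores),
    }

    bundle = ReportBundle(
        group_comparison=pd.DataFrame(comparison_rows),
        roc_auc=pd.DataFrame(auc_rows),
        cutoffs=pd.DataFrame(cutoff_rows),
        odds_ratios=pd.DataFrame(or_rows),
        score_metrics=score_metrics,
    )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        bundle.group_comparison.to_csv(out / "group_comparison.csv", index=False)
        bundle.roc_auc.to_csv(out / "roc_auc.csv", index=False)
        bundle.cutoffs.to_csv(out / "cutoffs.csv", index=False)
        bundle.odds_ratios.to_csv(out / "odds_ratios.csv", index=False)
        with open(out / "score_metrics.json", "w") as fh:
            json.dump(score_metrics, fh, indent=2)
    return bundle


def _odds_ratio_row(
    cohort: Sequence[PatientRecord],
    variable: str,
    direction: Direction,
    cutoff: float,
    level: float,
) -> dict:
    """Both odds-ratio flavours for one variable: per-unit (logistic) and
    dichotomized at the Youden cutoff (2x2)."""
    values, labels = extract_variable(cohort, variable)
    row: dict = {"variable": variable, "cutoff": cutoff}
    try:
        fit = fit_logistic_irls(values, labels.astype(float), level=level)
        row.update(
            or_per_unit=fit.or_per_unit,
            or_per_unit_ci_low=fit.ci_low,
            or_per_unit_ci_high=fit.ci_high,
            or_per_unit_p=fit.p_value,
            converged=fit.converged,
        )
    except DomainError:
        row.update(
            or_per_unit=np.nan,
            or_per_unit_ci_low=np.nan,
            or_per_unit_ci_high=np.nan,
            or_per_unit_p=np.nan,
            converged=False,
        )

    spec = ThresholdSpec(variable, cutoff, direction)
    flags = []
    for rec in cohort:
        try:
            flags.append(dichotomize(rec, spec))
        except Exception:
            flags.append(None)
    exposed_pos = exposed_neg = unexposed_pos = unexposed_neg = 0
    for rec, flag in zip(cohort, flags):
        if flag is None or rec.ph_group is None:
            continue
        positive = rec.ph_group is PHGroup.B_INCREASED
        if flag and positive:
            exposed_pos += 1
        elif flag:
            exposed_neg += 1
        elif positive:
            unexposed_pos += 1
        else:
            unexposed_neg += 1
    cm = ConfusionMatrix(
        tp=exposed_pos, fp=exposed_neg, fn=unexposed_pos, tn=unexposed_neg
    )
    try:
        result = odds_ratio_2x2(cm, correction=True, level=level)
        row.update(
            or_dichotomized=result.odds_ratio,
            or_dichotomized_ci_low=result.ci_low,
            or_dichotomized_ci_high=result.ci_high,
            or_dichotomized_p=result.p_value,
            haldane_corrected=result.corrected,
        )
    except DomainError:
        row.update(
            or_dichotomized=np.nan,
            or_dichotomized_ci_low=np.nan,
            or_dichotomized_ci_high=np.nan,
            or_dichotomized_p=np.nan,
            haldane_corrected=False,
        )
    return row
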