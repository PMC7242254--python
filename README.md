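# phscreen

Screening analytics for echocardiography-assessed pulmonary hypertension
(PH) in newly diagnosed interstitial lung disease (ILD). The package
re-implements, as a tested reusable pipeline:

- **Patient-record domain types** with derived pulmonary-function and
  walk-test indices (TLC/DLCO, FVC/DLCO, VC/DLCO, desaturation), strict
  threshold dichotomization, and the 2009 ESC/ERS echocardiographic
  PH-probability classifier (TRV/PASP bands plus additional signs).
- **A synthetic cohort generator** that samples two-group ILD cohorts
  (low vs. increased PH probability, default n = 52 / 41) whose marginal
  means and SDs emulate the study's printed group summaries — truncated
  normals, a moment-matched lognormal for NT-proBNP, and a Gaussian copula
  for rank correlation between TLC and DLCO.
- **Two-group comparison statistics** with the gated test-selection rule
  (Shapiro–Wilk + F test → pooled t-test, otherwise Mann–Whitney U with
  exact enumeration at small n), and 2×2 chi-square with automatic Yates
  correction.
- **ROC machinery built from scratch**: empirical staircase curves over
  the exhaustive midpoint candidate-cutoff set, trapezoidal AUC (= scaled
  tie-adjusted Mann–Whitney statistic), DeLong variance with
  logit-transformed confidence intervals, and Youden-optimal cutoffs with
  sensitivity/specificity/PPV/NPV at cohort prevalence.
- **Univariate risk estimation**: IRLS logistic regression (hand-rolled
  Newton iterations, Wald intervals, separation flagged) and closed-form
  2×2 odds ratios with optional Haldane–Anscombe correction.
- **The composite 10-point prediction score** (age > 53 and
  TLC/DLCO > 1.67 → 3 points each; 6MWD < 507.5 m and sat6 < 93% → 2
  points each; increased probability at ≥ 6 points), its cohort-level
  evaluation, and reconstruction of integer confusion matrices from
  printed operating characteristics.

## CLI

```bash
# synthetic two-group cohort CSV (93 records by default)
phscreen simulate --seed 1 --out cohort.csv

# per-patient composite scores and the >= 6-point classification
phscreen score --input cohort.csv --out scores.csv

# single-variable ROC analysis (AUC, DeLong CI, Youden cutoff, metrics)
phscreen roc --input cohort.csv --variable tlc_dlco \
    --direction above_is_risk --out roc.csv

# two-group comparison table (mean ± SD per group, p-value, test used)
phscreen compare --input cohort.csv --out comparison.csv

# everything: 4 CSV tables + score_metrics.json (metadata embedded)
phscreen report --seed 1 --out-dir report/
```

Score weights are configurable via `--weights weights.json`
(see `ScoreWeights.to_json()` for the shape); cohort generator parameters
via `phscreen simulate --config params.json`.

## Cohort CSV schema

One row per patient with columns
`id, age, sex, diagnosis, pack_years, six_mwd, sat0, sat6, fev1_fvc,
fvc_pct, vc_pct, tlc_pct, dlco_pct, ntprobnp, ph_group`.
Lung-function values are percent predicted; `sex` is `male`/`female`;
`diagnosis` is one of `sarcoidosis`, `HP`, `IPF`, `other-IIP`; `ph_group`
is `A_low` or `B_increased` (may be empty); `vc_pct` is optional. Unknown
columns are preserved. Rows violating record invariants are excluded with
logged line numbers, never imputed.

## Python API sketch

```python
import phscreen as ps

cohort = ps.generate_cohort(ps.default_params(seed=1))
metrics = ps.evaluate_score_on_cohort(cohort)          # AUC + confusion
result = ps.auc([...], [...], ps.Direction.ABOVE_IS_RISK)
optimum = ps.youden_optimal(ps.roc_points([...], [...]))
fit = ps.fit_logistic_irls(x, y)                       # IRLS logistic
```
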