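"""Synthetic two-group ILD cohort generator.

Samples patient records whose marginal means and SDs emulate the study's
printed per-group summaries, so every downstream stage (group comparison,
ROC, odds ratios, composite score) can be exercised without real data.

Marginals are truncated normals except NT-proBNP, which is lognormal
(its printed group-B SD exceeds the mean, which a near-normal nonnegative
variable cannot produce). Variables are coupled through a Gaussian copula;
by default only TLC and DLCO are rank-correlated (rho = 0.5). Sixth-minute
saturation is derived as sat0 minus desaturation rather than sampled,
because the three printed saturation rows are not jointly consistent under
independent sampling.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .cohort import Diagnosis, PatientRecord, PHGroup, Sex
from .errors import ConfigurationError, DomainError

__all__ = [
    "MarginalSpec",
    "GroupSpec",
    "CohortParams",
    "default_params",
    "fit_lognormal_moments",
    "sample_group",
    "generate_cohort",
]

# Whole-cohort categorical mix: 65M/28F; sarcoidosis 42, HP 22, IPF 21,
# other IIP 8 of 93. Not stratified by group (not reported per group).
_P_MALE = 65 / 93
_DIAGNOSES = (
    Diagnosis.SARCOIDOSIS,
    Diagnosis.HP,
    Diagnosis.IPF,
    Diagnosis.OTHER_IIP,
)
_P_DIAGNOSIS = np.array([42, 22, 21, 8], dtype=float) / 93

# vc_pct is not reported per group; synthesized as fvc_pct times a factor
# close to 1 so the VC/DLCO index exists.
_VC_FACTOR_MEAN = 1.02
_VC_FACTOR_SD = 0.03


@dataclass(frozen=True)
class MarginalSpec:
    """Marginal distribution of one cohort variable."""

    variable: str
    family: str  # truncated_normal | lognormal | constant
    mean: float
    sd: float
    lower: float = 0.0
    upper: Optional[float] = None

    def __post_init__(self) -> None:
        if self.family not in ("truncated_normal", "lognormal", "constant"):
            raise ConfigurationError(f"unknown family {self.family!r}")
        if self.sd < 0:
            raise ConfigurationError(f"{self.variable}: sd must be >= 0")
        if self.upper is not None and not self.lower < self.upper:
            raise ConfigurationError(
                f"{self.variable}: lower {self.lower} must be < upper {self.upper}"
            )


@dataclass(frozen=True)
class GroupSpec:
    specs: tuple[MarginalSpec, ...]
    n: int

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ConfigurationError("group size must be >= 0")


@dataclass(frozen=True)
class CohortParams:
    """Full generator configuration.

    ``correlation`` is a sparse list of (variable, variable, rho) pairs
    defining the Gaussian-copula coupling; the implied matrix must be
    positive semi-definite with unit diagonal.
    """

    group_a: GroupSpec
    group_b: GroupSpec
    correlation: tuple[tuple[str, str, float], ...] = ()
    seed: int = 0

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "CohortParams":
        raw = json.loads(text)

        def _group(g: dict) -> GroupSpec:
            return GroupSpec(
                specs=tuple(MarginalSpec(**s) for s in g["specs"]), n=g["n"]
            )

        return cls(
            group_a=_group(raw["group_a"]),
            group_b=_group(raw["group_b"]),
            correlation=tuple((a, b, float(r)) for a, b, r in raw.get("correlation", ())),
            seed=int(raw.get("seed", 0)),
        )


def _specs(rows: Sequence[tuple]) -> tuple[MarginalSpec, ...]:
    return tuple(MarginalSpec(*row) for row in rows)


def default_params(seed: int = 0, tlc_dlco_rho: float = 0.5) -> CohortParams:
    """Generator parameters matching the study's printed group summaries.

    Group A (low PH probability, n=52) and group B (increased probability,
    n=41). Age is truncated at 18 (the study's lower age limit), baseline
    saturation at 100 from above, everything else at zero from below.
    """
    group_a = _specs(
        [
            ("age", "truncated_normal", 43.8, 12.2, 18.0, None),
            ("pack_years", "truncated_normal", 6.9, 14.0, 0.0, None),
            ("six_mwd", "truncated_normal", 583.1, 111.6, 0.0, None),
            ("sat0", "truncated_normal", 96.6, 2.3, 0.0, 100.0),
            ("desaturation", "truncated_normal", 3.3, 3.9, 0.0, None),
            ("fev1_fvc", "truncated_normal", 78.5, 6.3, 0.0, 100.0),
            ("fvc_pct", "truncated_normal", 94.5, 22.7, 0.0, None),
            ("tlc_pct", "truncated_normal", 96.0, 19.4, 0.0, None),
            ("dlco_pct", "truncated_normal", 70.5, 20.8, 0.0, None),
            ("ntprobnp", "lognormal", 58.4, 53.9, 0.0, None),
        ]
    )
    group_b = _specs(
        [
            ("age", "truncated_normal", 57.6, 12.1, 18.0, None),
            ("pack_years", "truncated_normal", 17.8, 21.8, 0.0, None),
            ("six_mwd", "truncated_normal", 478.2, 109.0, 0.0, None),
            ("sat0", "truncated_normal", 95.8, 1.9, 0.0, 100.0),
            ("desaturation", "truncated_normal", 6.7, 5.7, 0.0, None),
            ("fev1_fvc", "truncated_normal", 75.8, 9.3, 0.0, 100.0),
            ("fvc_pct", "truncated_normal", 95.0, 21.3, 0.0, None),
            ("tlc_pct", "truncated_normal", 91.9, 21.9, 0.0, None),
            ("dlco_pct", "truncated_normal", 54.8, 22.2, 0.0, None),
            ("ntprobnp", "lognormal", 150.7, 300.7, 0.0, None),
        ]
    )
    correlation = (("tlc_pct", "dlco_pct", float(tlc_dlco_rho)),)
    return CohortParams(
        group_a=GroupSpec(group_a, 52),
        group_b=GroupSpec(group_b, 41),
        correlation=correlation,
        seed=seed,
    )


def fit_lognormal_moments(mean: float, sd: float) -> tuple[float, float]:
    """Method-of-moments lognormal parameters (log-location, log-shape).

    shape^2 = ln(1 + (sd/mean)^2); location = ln(mean) - shape^2 / 2.
    A lognormal with these parameters has population mean ``mean`` and
    population SD ``sd``.
    """
    if mean <= 0 or sd <= 0:
        raise DomainError("fit_lognormal_moments requires mean > 0 and sd > 0")
    shape_sq = math.log1p((sd / mean) ** 2)
    location = math.log(mean) - shape_sq / 2.0
    return location, math.sqrt(shape_sq)


def _correlation_matrix(
    variables: Sequence[str], pairs: Sequence[tuple[str, str, float]]
) -> np.ndarray:
    k = len(variables)
    index = {v: i for i, v in enumerate(variables)}
    r = np.eye(k)
    for va, vb, rho in pairs:
        if va not in index or vb not in index:
            continue  # pair refers to a variable this group does not sample
        if not -1.0 <= rho <= 1.0:
            raise ConfigurationError(f"correlation {va}-{vb} outside [-1, 1]")
        i, j = index[va], index[vb]
        r[i, j] = r[j, i] = rho
    eigvals = np.linalg.eigvalsh(r)
    if eigvals.min() < -1e-9:
        raise ConfigurationError("correlation matrix is not positive semi-definite")
    return r


def _marginal_ppf(spec: MarginalSpec, u: np.ndarray) -> np.ndarray:
    if spec.family == "constant" or spec.sd == 0:
        return np.full_like(u, spec.mean)
    if spec.family == "truncated_normal":
        a = (spec.lower - spec.mean) / spec.sd
        b = np.inf if spec.upper is None else (spec.upper - spec.mean) / spec.sd
        return stats.truncnorm.ppf(u, a, b, loc=spec.mean, scale=spec.sd)
    # lognormal parameterized so population mean/SD equal the spec values
    loc, shape = fit_lognormal_moments(spec.mean, spec.sd)
    return stats.lognorm.ppf(u, s=shape, scale=math.exp(loc))


def sample_group(
    specs: Sequence[MarginalSpec],
    n: int,
    correlation: Sequence[tuple[str, str, float]] = (),
    seed: int | np.random.Generator = 0,
    id_prefix: str = "P",
    ph_group: Optional[PHGroup] = None,
) -> list[PatientRecord]:
    """Draw ``n`` patient records from the given marginals.

    Sampling is a Gaussian copula: correlated standard normals are pushed
    through the normal CDF and then each variable's inverse CDF. sat6 is
    constructed as sat0 - desaturation (clipped into (0, sat0]); vc_pct as
    fvc_pct times a narrow truncated-normal factor. Identical inputs and
    seed give bit-identical output.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    variables = [s.variable for s in specs]
    required = {
        "age", "pack_years", "six_mwd", "sat0", "desaturation",
        "fev1_fvc", "fvc_pct", "tlc_pct", "dlco_pct", "ntprobnp",
    }
    missing = required - set(variables)
    if missing:
        raise ConfigurationError(f"specs missing variables: {sorted(missing)}")

    r = _correlation_matrix(variables, correlation)
    # eigen square root tolerates exact PSD-boundary matrices
    w, v = np.linalg.eigh(r)
    root = v @ np.diag(np.sqrt(np.clip(w, 0.0, None)))
    z = rng.standard_normal((n, len(variables))) @ root.T
    u = stats.norm.cdf(z)
    # keep ppf strictly inside (0, 1)
    eps = np.finfo(float).tiny
    u = np.clip(u, eps, 1.0 - 1e-16)

    columns = {
        s.variable: np.asarray(_marginal_ppf(s, u[:, i]), dtype=float)
        for i, s in enumerate(specs)
    }

    # age must clear the record invariant even for specs without the bound
    columns["age"] = np.maximum(columns["age"], 18.0)
    desat = np.maximum(columns["desaturation"], 0.0)
    sat0 = np.minimum(columns["sat0"], 100.0)
    sat6 = np.clip(sat0 - desat, 1.0, sat0)

    vc_a = (0.0 - _VC_FACTOR_MEAN) / _VC_FACTOR_SD
    vc_factor = stats.truncnorm.ppf(
        rng.uniform(size=n), vc_a, np.inf, loc=_VC_FACTOR_MEAN, scale=_VC_FACTOR_SD
    )
    vc_pct = columns["fvc_pct"] * vc_factor

    sexes = rng.uniform(size=n) < _P_MALE
    diag_idx = rng.choice(len(_DIAGNOSES), size=n, p=_P_DIAGNOSIS)

    records = []
    for i in range(n):
        records.append(
            PatientRecord(
                id=f"{id_prefix}{i + 1:04d}",
                age=float(columns["age"][i]),
                sex=Sex.MALE if sexes[i] else Sex.FEMALE,
                diagnosis=_DIAGNOSES[diag_idx[i]],
                pack_years=float(columns["pack_years"][i]),
                six_mwd=float(columns["six_mwd"][i]),
                sat0=float(sat0[i]),
                sat6=float(sat6[i]),
                fev1_fvc=float(columns["fev1_fvc"][i]),
                fvc_pct=float(columns["fvc_pct"][i]),
                vc_pct=float(vc_pct[i]),
                tlc_pct=float(columns["tlc_pct"][i]),
                dlco_pct=float(columns["dlco_pct"][i]),
                ntprobnp=float(columns["ntprobnp"][i]),
                ph_group=ph_group,
            )
        )
    return records


def generate_cohort(params: CohortParams) -> list[PatientRecord]:
    """Concatenate labelled group-A and group-B samples."""
    a = sample_group(
        params.group_a.specs,
        params.group_a.n,
        params.correlation,
        seed=params.seed,
        id_prefix="A",
        ph_group=PHGroup.A_LOW,
    )
    b = sample_group(
        params.group_b.specs,
        params.group_b.n,
        params.correlation,
        seed=params.seed + 1,
        id_prefix="B",
        ph_group=PHGroup.B_INCREASED,
    )
    return a + b
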