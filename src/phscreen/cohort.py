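"""Patient-level domain types and operations.

Holds the :class:`PatientRecord` container, derived pulmonary-function and
walk indices (TLC/DLCO etc.), threshold dichotomization, and the
echocardiographic pulmonary-hypertension probability classifier based on
tricuspid regurgitant velocity (TRV) and estimated pulmonary arterial
systolic pressure (PASP) bands.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

from .errors import ConfigurationError, DomainError, MissingDataError, ValidationError

__all__ = [
    "Sex",
    "Diagnosis",
    "PHGroup",
    "PHCategory",
    "Direction",
    "PatientRecord",
    "DerivedIndices",
    "EchoAssessment",
    "PHProbability",
    "ThresholdSpec",
    "derive_indices",
    "classify_echo_probability",
    "dichotomize",
    "resolve_variable",
    "DERIVED_VARIABLES",
]


class Sex(str, Enum):
    MALE = "male"
    FEMALE = "female"


class Diagnosis(str, Enum):
    SARCOIDOSIS = "sarcoidosis"
    HP = "HP"
    IPF = "IPF"
    OTHER_IIP = "other-IIP"


class PHGroup(str, Enum):
    """Echocardiographic probability stratum: positive class is B."""

    A_LOW = "A_low"
    B_INCREASED = "B_increased"


class PHCategory(str, Enum):
    """Ordered echo probability categories (unlikely < possible < likely)."""

    UNLIKELY = "unlikely"
    POSSIBLE = "possible"
    LIKELY = "likely"

    @property
    def rank(self) -> int:
        return {"unlikely": 0, "possible": 1, "likely": 2}[self.value]


class Direction(str, Enum):
    ABOVE_IS_RISK = "above_is_risk"
    BELOW_IS_RISK = "below_is_risk"


@dataclass(frozen=True)
class PatientRecord:
    """One subject's clinical and functional measurements.

    All lung-function values are percent predicted; ``dlco_pct`` is
    haemoglobin-corrected. ``ph_group`` may be omitted when raw echo
    measurements are carried separately.
    """

    id: str
    age: float
    sex: Sex
    diagnosis: Diagnosis
    pack_years: float
    six_mwd: float
    sat0: float
    sat6: float
    fev1_fvc: float
    fvc_pct: float
    tlc_pct: float
    dlco_pct: float
    ntprobnp: float
    vc_pct: Optional[float] = None
    ph_group: Optional[PHGroup] = None
    extra: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        if self.age < 18:
            raise ValidationError(f"record {self.id}: age {self.age} < 18")
        if not (0 < self.sat6 <= self.sat0 <= 100):
            raise ValidationError(
                f"record {self.id}: require 0 < sat6 <= sat0 <= 100, "
                f"got sat0={self.sat0}, sat6={self.sat6}"
            )
        for name in ("fev1_fvc", "fvc_pct", "tlc_pct", "dlco_pct"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"record {self.id}: {name} must be > 0")
        if self.vc_pct is not None and self.vc_pct <= 0:
            raise ValidationError(f"record {self.id}: vc_pct must be > 0")
        if self.six_mwd < 0:
            raise ValidationError(f"record {self.id}: six_mwd must be >= 0")
        if self.ntprobnp < 0:
            raise ValidationError(f"record {self.id}: ntprobnp must be >= 0")
        if self.pack_years < 0:
            raise ValidationError(f"record {self.id}: pack_years must be >= 0")


@dataclass(frozen=True)
class DerivedIndices:
    """Ratio indices and walk-test desaturation derived from a record.

    ``tlc_dlco`` is the ratio of the two percent-predicted values; a high
    value flags a diffusion deficit out of proportion to lung restriction.
    """

    tlc_dlco: float
    fvc_dlco: float
    desaturation: float
    vc_dlco: Optional[float] = None


@dataclass(frozen=True)
class EchoAssessment:
    """Raw echocardiographic inputs to the probability classifier."""

    trv: Optional[float] = None  # m/s
    pasp: Optional[float] = None  # mmHg
    additional_signs: bool = False

    def __post_init__(self) -> None:
        if self.trv is None and self.pasp is None:
            raise ValidationError("at least one of trv, pasp must be present")
        if self.trv is not None and self.trv <= 0:
            raise ValidationError("trv must be > 0")
        if self.pasp is not None and self.pasp <= 0:
            raise ValidationError("pasp must be > 0")


@dataclass(frozen=True)
class PHProbability:
    category: PHCategory


@dataclass(frozen=True)
class ThresholdSpec:
    """A named variable, a cutoff, and which side of it counts as at-risk.

    Comparisons are strict: a value exactly at the cutoff is never at-risk.
    """

    variable: str
    cutoff: float
    direction: Direction

    def __post_init__(self) -> None:
        if not math.isfinite(self.cutoff):
            raise ConfigurationError(f"cutoff for {self.variable} must be finite")
        # coerce plain strings for convenience
        if not isinstance(self.direction, Direction):
            object.__setattr__(self, "direction", Direction(self.direction))


DERIVED_VARIABLES = ("tlc_dlco", "fvc_dlco", "vc_dlco", "desaturation")

_RECORD_VARIABLES = (
    "age",
    "pack_years",
    "six_mwd",
    "sat0",
    "sat6",
    "fev1_fvc",
    "fvc_pct",
    "vc_pct",
    "tlc_pct",
    "dlco_pct",
    "ntprobnp",
)


def derive_indices(record: PatientRecord) -> DerivedIndices:
    """Compute ratio indices and desaturation from a validated record.

    ``vc_dlco`` is present iff ``vc_pct`` is present. Raises
    :class:`DomainError` if ``dlco_pct`` is not positive (the record type
    normally guarantees this, but records built with ``object.__new__`` or
    mocked inputs are still rejected here).
    """
    if record.dlco_pct is None or record.dlco_pct <= 0:
        raise DomainError("dlco_pct must be > 0 to form ratio indices")
    if record.sat6 > record.sat0:
        raise ValidationError("sat6 exceeds sat0")
    return DerivedIndices(
        tlc_dlco=record.tlc_pct / record.dlco_pct,
        fvc_dlco=record.fvc_pct / record.dlco_pct,
        vc_dlco=None if record.vc_pct is None else record.vc_pct / record.dlco_pct,
        desaturation=record.sat0 - record.sat6,
    )


def _trv_band(trv: float) -> int:
    if trv <= 2.8:
        return 0
    if trv <= 3.4:  # half-open (2.8, 3.4] covers the unprinted gap
        return 1
    return 2


def _pasp_band(pasp: float) -> int:
    if pasp <= 36:
        return 0
    if pasp <= 50:
        return 1
    return 2


def classify_echo_probability(assessment: EchoAssessment) -> PHProbability:
    """Map an echo assessment to a PH-probability category.

    Bands: TRV <=2.8 / (2.8, 3.4] / >3.4 m/s; PASP <=36 / (36, 50] / >50
    mmHg. When both measurements are present the higher band wins. In the
    lowest band, additional suggestive signs upgrade "unlikely" to
    "possible"; the middle band is "possible" and the top band "likely"
    regardless of signs.
    """
    bands = []
    if assessment.trv is not None:
        bands.append(_trv_band(assessment.trv))
    if assessment.pasp is not None:
        bands.append(_pasp_band(assessment.pasp))
    band = max(bands)
    if band == 2:
        return PHProbability(PHCategory.LIKELY)
    if band == 1:
        return PHProbability(PHCategory.POSSIBLE)
    if assessment.additional_signs:
        return PHProbability(PHCategory.POSSIBLE)
    return PHProbability(PHCategory.UNLIKELY)


def resolve_variable(record: PatientRecord, variable: str) -> float:
    """Fetch a field from the record or its derived indices.

    Raises :class:`ConfigurationError` for unknown names and
    :class:`MissingDataError` for known-but-absent values.
    """
    if variable in _RECORD_VARIABLES:
        value = getattr(record, variable)
    elif variable in DERIVED_VARIABLES:
        value = getattr(derive_indices(record), variable)
    else:
        raise ConfigurationError(f"unknown variable name: {variable!r}")
    if value is None:
        raise MissingDataError(f"record {record.id}: {variable} is missing")
    return float(value)


def dichotomize(record: PatientRecord, spec: ThresholdSpec) -> bool:
    """Strict threshold test: True iff the record is on the risk side."""
    value = resolve_variable(record, spec.variable)
    if spec.direction is Direction.ABOVE_IS_RISK:
        return value > spec.cutoff
    return value < spec.cutoff
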