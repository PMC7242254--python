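"""Cohort CSV reading/writing and column extraction.

The cohort schema uses one column per patient-record field (``id, age, sex,
diagnosis, pack_years, six_mwd, sat0, sat6, fev1_fvc, fvc_pct, vc_pct,
tlc_pct, dlco_pct, ntprobnp, ph_group``); ``vc_pct`` and ``ph_group`` may
be empty. Unknown columns are preserved on the records and written back.
Rows violating record invariants are excluded with a logged line number,
never imputed.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .cohort import (
    Diagnosis,
    PatientRecord,
    PHGroup,
    Sex,
    resolve_variable,
)
from .errors import DomainError, MissingDataError, SchemaError, ValidationError

__all__ = ["COHORT_COLUMNS", "read_cohort_csv", "write_cohort_csv", "extract_variable"]

logger = logging.getLogger(__name__)

COHORT_COLUMNS = (
    "id",
    "age",
    "sex",
    "diagnosis",
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
    "ph_group",
)

_MANDATORY = tuple(c for c in COHORT_COLUMNS if c not in ("vc_pct", "ph_group"))
_NUMERIC = (
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


def read_cohort_csv(path: str | Path) -> list[PatientRecord]:
    """Parse and validate a cohort CSV.

    Invalid rows are dropped (with their 1-based data line numbers logged);
    the exclusion count is logged once at the end.
    """
    df = pd.read_csv(path, dtype={"id": str}, float_precision="round_trip")
    if df.empty:
        raise DomainError(f"{path}: no data rows")
    missing = [c for c in _MANDATORY if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing mandatory columns: {missing}")
    extra_cols = [c for c in df.columns if c not in COHORT_COLUMNS]

    records: list[PatientRecord] = []
    excluded = 0
    for i, row in df.iterrows():
        line_no = int(i) + 2  # header is line 1
        try:
            vc = row.get("vc_pct")
            group = row.get("ph_group")
            records.append(
                PatientRecord(
                    id=str(row["id"]),
                    age=float(row["age"]),
                    sex=Sex(str(row["sex"])),
                    diagnosis=Diagnosis(str(row["diagnosis"])),
                    pack_years=float(row["pack_years"]),
                    six_mwd=float(row["six_mwd"]),
                    sat0=float(row["sat0"]),
                    sat6=float(row["sat6"]),
                    fev1_fvc=float(row["fev1_fvc"]),
                    fvc_pct=float(row["fvc_pct"]),
                    vc_pct=None if pd.isna(vc) else float(vc),
                    tlc_pct=float(row["tlc_pct"]),
                    dlco_pct=float(row["dlco_pct"]),
                    ntprobnp=float(row["ntprobnp"]),
                    ph_group=None if pd.isna(group) else PHGroup(str(group)),
                    extra={c: row[c] for c in extra_cols},
                )
            )
        except (ValidationError, ValueError) as exc:
            excluded += 1
            logger.warning("%s line %d excluded: %s", path, line_no, exc)
    if excluded:
        logger.info("%s: excluded %d invalid row(s)", path, excluded)
    if not records:
        raise DomainError(f"{path}: all rows failed validation")
    return records


def write_cohort_csv(records: Sequence[PatientRecord], path: str | Path) -> None:
    rows = []
    for rec in records:
        row = {
            "id": rec.id,
            "age": rec.age,
            "sex": rec.sex.value,
            "diagnosis": rec.diagnosis.value,
            "pack_years": rec.pack_years,
            "six_mwd": rec.six_mwd,
            "sat0": rec.sat0,
            "sat6": rec.sat6,
            "fev1_fvc": rec.fev1_fvc,
            "fvc_pct": rec.fvc_pct,
            "vc_pct": "" if rec.vc_pct is None else rec.vc_pct,
            "tlc_pct": rec.tlc_pct,
            "dlco_pct": rec.dlco_pct,
            "ntprobnp": rec.ntprobnp,
            "ph_group": "" if rec.ph_group is None else rec.ph_group.value,
        }
        row.update(rec.extra)
        rows.append(row)
    # %.17g keeps float round-trip exactness through the CSV
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.17g")


def extract_variable(
    records: Sequence[PatientRecord], variable: str
) -> tuple[np.ndarray, np.ndarray]:
    """Values and positive-class labels for one variable across a cohort.

    Records with the value or the stratum missing are skipped (their count
    is logged); positive class is the increased-probability stratum.
    """
    values, labels, skipped = [], [], 0
    for rec in records:
        if rec.ph_group is None:
            skipped += 1
            continue
        try:
            values.append(resolve_variable(rec, variable))
        except MissingDataError:
            skipped += 1
            continue
        labels.append(rec.ph_group is PHGroup.B_INCREASED)
    if skipped:
        logger.info("extract %s: skipped %d record(s)", variable, skipped)
    return np.asarray(values, dtype=float), np.asarray(labels, dtype=bool)
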