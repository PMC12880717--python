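"""Patient-level domain types for fibrosis-screening cohorts.

A cohort is one row per screened patient with type 2 diabetes and
ultrasound-diagnosed steatotic liver disease: demographics, the labs the
FIB-4 score needs (AST, ALT, platelet count), anthropometry, diabetes
history, comorbidity flags used by the factor regression, and — for
patients who actually underwent vibration-controlled transient
elastography (VCTE) — a liver stiffness measurement (LSM) in kPa.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields
from typing import Iterator, Optional, Sequence

import pandas as pd

SEX_TOKENS = ("male", "female")

#: Fields every record must carry (the triage rules need all of them).
REQUIRED_FIELDS = (
    "patient_id",
    "age",
    "sex",
    "ast",
    "alt",
    "platelet_count",
    "bmi",
    "diabetes_duration",
    "has_vascular_complications",
)

#: Optional continuous fields; absent values are stored as ``None``.
OPTIONAL_FLOAT_FIELDS = ("lsm_kpa", "waist_cm")

#: Optional boolean covariates consumed only by the factor regression.
OPTIONAL_BOOL_FIELDS = (
    "hypertension",
    "dyslipidaemia",
    "hypothyroidism",
    "ischaemic_heart_disease",
    "current_smoker",
    "family_history_liver_disease",
    "uss_grade_ge2",
    "risk_diet",
    "sedentary_lifestyle",
)

#: Canonical CSV column order shared by every module and the CLI.
COLUMNS = REQUIRED_FIELDS + OPTIONAL_FLOAT_FIELDS + OPTIONAL_BOOL_FIELDS


class CohortValidationError(ValueError):
    """Raised when one or more rows violate the record invariants.

    Carries every diagnostic, each referencing the offending row, so a
    malformed file is reported in full rather than failing on the first
    bad cell.
    """

    def __init__(self, problems: Sequence[str]):
        self.problems = list(problems)
        msg = "; ".join(self.problems[:20])
        if len(self.problems) > 20:
            msg += f"; ... ({len(self.problems)} problems total)"
        super().__init__(msg)


class SchemaError(ValueError):
    """Raised when the cohort table is missing a required column."""


def _is_pos(x) -> bool:
    return x is not None and isinstance(x, (int, float)) and math.isfinite(x) and x > 0


@dataclass
class PatientRecord:
    """One screened patient.

    Units: age in years, AST/ALT in U/L, platelets in 10^9/L, BMI in
    kg/m^2, diabetes duration in years, LSM in kPa. ``lsm_kpa`` is absent
    (``None``) when the patient was not scanned; ``has_vascular_complications``
    is true when any diabetic micro/macrovascular complication (stroke,
    ischaemic heart disease, peripheral vascular disease, neuropathy,
    nephropathy or retinopathy) is present.
    """

    patient_id: str
    age: float
    sex: str
    ast: float
    alt: float
    platelet_count: float
    bmi: float
    diabetes_duration: float
    has_vascular_complications: bool
    lsm_kpa: Optional[float] = None
    waist_cm: Optional[float] = None
    hypertension: Optional[bool] = None
    dyslipidaemia: Optional[bool] = None
    hypothyroidism: Optional[bool] = None
    ischaemic_heart_disease: Optional[bool] = None
    current_smoker: Optional[bool] = None
    family_history_liver_disease: Optional[bool] = None
    uss_grade_ge2: Optional[bool] = None
    risk_diet: Optional[bool] = None
    sedentary_lifestyle: Optional[bool] = None

    def problems(self) -> list[str]:
        """Return all invariant violations for this record (empty if valid)."""
        out: list[str] = []
        if not self.patient_id:
            out.append("patient_id is empty")
        if self.sex not in SEX_TOKENS:
            out.append(f"sex must be one of {SEX_TOKENS}, got {self.sex!r}")
        for name in ("age", "ast", "alt", "platelet_count", "bmi"):
            if not _is_pos(getattr(self, name)):
                out.append(f"{name} must be a positive finite number")
        d = self.diabetes_duration
        if d is None or not math.isfinite(d) or d < 0:
            out.append("diabetes_duration must be a finite number >= 0")
        if not isinstance(self.has_vascular_complications, bool):
            out.append("has_vascular_complications must be boolean")
        if self.lsm_kpa is not None and not _is_pos(self.lsm_kpa):
            out.append("lsm_kpa, when present, must be > 0")
        if self.waist_cm is not None and not _is_pos(self.waist_cm):
            out.append("waist_cm, when present, must be > 0")
        return out


@dataclass
class Cohort:
    """Ordered collection of :class:`PatientRecord` with unique ids."""

    records: list[PatientRecord] = field(default_factory=list)
    label: str = "cohort"

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[PatientRecord]:
        return iter(self.records)

    def __getitem__(self, i: int) -> PatientRecord:
        return self.records[i]

    def problems(self) -> list[str]:
        """All invariant violations, each prefixed with its 1-based row."""
        out: list[str] = []
        seen: set[str] = set()
        for i, rec in enumerate(self.records, start=1):
            for p in rec.problems():
                out.append(f"row {i}: {p}")
            if rec.patient_id in seen:
                out.append(f"row {i}: duplicate patient_id {rec.patient_id!r}")
            seen.add(rec.patient_id)
        return out

    def validate(self) -> "Cohort":
        """Raise :class:`CohortValidationError` unless every record is valid."""
        probs = self.problems()
        if probs:
            raise CohortValidationError(probs)
        return self

    def to_dataframe(self) -> pd.DataFrame:
        """Cohort as a DataFrame in the canonical column order.

        Booleans stay Python bools (or ``None``); absent optional values
        are ``None``. Intended for vectorised scoring/triage, not for
        direct CSV serialisation (see :mod:`fibrotriage.io`).
        """
        rows = []
        for rec in self.records:
            rows.append({c: getattr(rec, c) for c in COLUMNS})
        df = pd.DataFrame(rows, columns=list(COLUMNS))
        return df

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, label: str = "cohort") -> "Cohort":
        records = []
        for row in df.itertuples(index=False):
            d = row._asdict()
            records.append(PatientRecord(**{c: _none_if_na(d.get(c)) for c in COLUMNS if c in d}))
        return cls(records=records, label=label)

    def scanned(self) -> "Cohort":
        """Sub-cohort of patients with an LSM (VCTE actually performed)."""
        return Cohort(
            records=[r for r in self.records if r.lsm_kpa is not None],
            label=f"{self.label}/scanned",
        )


def _none_if_na(x):
    if x is None:
        return None
    if isinstance(x, float) and math.isnan(x):
        return None
    return x


# keep dataclass field names and COLUMNS in lockstep
assert tuple(f.name for f in fields(PatientRecord)) == COLUMNS
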