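"""Reading and writing the cohort CSV table.

One dialect everywhere: comma-separated, UTF-8, single header row naming
the fields of :class:`~fibrotriage.records.PatientRecord`, missing values
encoded as the empty string, booleans as ``0``/``1``, sex as
``male``/``female``. Floats are written with full ``repr`` precision so a
write/read round-trip reproduces every value exactly.
"""

from __future__ import annotations

import sys
from typing import Optional, TextIO, Union

import pandas as pd

from .records import (
    COLUMNS,
    OPTIONAL_BOOL_FIELDS,
    OPTIONAL_FLOAT_FIELDS,
    REQUIRED_FIELDS,
    Cohort,
    CohortValidationError,
    PatientRecord,
    SchemaError,
)

_TRUE = {"1", "true", "yes"}
_FALSE = {"0", "false", "no"}

PathOrFile = Union[str, TextIO]


def _parse_float(token: str, field: str, row: int) -> float:
    try:
        return float(token)
    except ValueError:
        raise CohortValidationError(
            [f"row {row}: non-numeric value {token!r} in field {field!r}"]
        ) from None


def _parse_bool(token: str, field: str, row: int) -> bool:
    t = token.strip().lower()
    if t in _TRUE:
        return True
    if t in _FALSE:
        return False
    raise CohortValidationError(
        [f"row {row}: non-boolean value {token!r} in field {field!r} (use 0/1)"]
    )


def read_cohort(
    path: PathOrFile,
    *,
    delimiter: str = ",",
    missing_token: str = "",
    label: Optional[str] = None,
) -> Cohort:
    """Read and validate a cohort table.

    Parameters
    ----------
    path
        CSV file path, ``"-"`` for stdin, or an open text handle.
    delimiter, missing_token
        Dialect overrides; defaults match :func:`write_cohort`.
    label
        Cohort label; defaults to the path.

    Raises
    ------
    SchemaError
        If a required column is absent from the header.
    CohortValidationError
        Listing every malformed row (non-numeric labs, invariant
        violations, duplicate ids) with its 1-based data-row index.
        Nothing is silently dropped or coerced.
    """
    handle = sys.stdin if path == "-" else path
    df = pd.read_csv(handle, sep=delimiter, dtype=str, keep_default_na=False)
    for col in REQUIRED_FIELDS:
        if col not in df.columns:
            raise SchemaError(f"missing required column {col!r}")

    problems: list[str] = []
    records: list[PatientRecord] = []
    for i, raw in enumerate(df.to_dict(orient="records"), start=1):
        kwargs: dict = {}
        row_ok = True
        try:
            for fieldname in COLUMNS:
                token = raw.get(fieldname, missing_token)
                token = "" if token is None else str(token).strip()
                is_missing = token == missing_token
                if fieldname == "patient_id":
                    kwargs[fieldname] = token
                elif fieldname == "sex":
                    kwargs[fieldname] = token.lower()
                elif fieldname == "has_vascular_complications":
                    kwargs[fieldname] = _parse_bool(token, fieldname, i)
                elif fieldname in OPTIONAL_BOOL_FIELDS:
                    kwargs[fieldname] = None if is_missing else _parse_bool(token, fieldname, i)
                elif fieldname in OPTIONAL_FLOAT_FIELDS:
                    kwargs[fieldname] = None if is_missing else _parse_float(token, fieldname, i)
                else:  # required numeric
                    if is_missing:
                        raise CohortValidationError(
                            [f"row {i}: required field {fieldname!r} is missing"]
                        )
                    kwargs[fieldname] = _parse_float(token, fieldname, i)
        except CohortValidationError as e:
            problems.extend(e.problems)
            row_ok = False
        if row_ok:
            rec = PatientRecord(**kwargs)
            for p in rec.problems():
                problems.append(f"row {i}: {p}")
            records.append(rec)

    seen: set[str] = set()
    for i, rec in enumerate(records, start=1):
        if rec.patient_id in seen:
            problems.append(f"row {i}: duplicate patient_id {rec.patient_id!r}")
        seen.add(rec.patient_id)

    if problems:
        raise CohortValidationError(problems)
    return Cohort(records=records, label=label or (path if isinstance(path, str) else "cohort"))


def _encode(value, fieldname: str, missing_token: str) -> str:
    if value is None:
        return missing_token
    if fieldname == "has_vascular_complications" or fieldname in OPTIONAL_BOOL_FIELDS:
        return "1" if value else "0"
    if fieldname in ("patient_id", "sex"):
        return str(value)
    return repr(float(value)) if isinstance(value, float) else str(value)


def write_cohort(
    cohort: Cohort,
    path: PathOrFile,
    *,
    delimiter: str = ",",
    missing_token: str = "",
) -> None:
    """Write a validated cohort; ``read_cohort`` round-trips it exactly.

    An empty cohort produces a header-only file.
    """
    cohort.validate()
    rows = [
        {c: _encode(getattr(rec, c), c, missing_token) for c in COLUMNS}
        for rec in cohort.records
    ]
    df = pd.DataFrame(rows, columns=list(COLUMNS))
    handle = sys.stdout if path == "-" else path
    df.to_csv(handle, sep=delimiter, index=False)
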