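"""FIB-4 scoring and LSM-based fibrosis staging.

The FIB-4 index is ``age * AST / (platelets * sqrt(ALT))`` with age in
years, AST/ALT in U/L and platelets in 10^9/L — units are fixed and never
inferred, because silent unit conversion is the classic FIB-4 failure
mode. Liver stiffness (kPa) partitions into three fibrosis stages at the
VCTE thresholds 8.0 (significant fibrosis, SF) and 12.0 (advanced chronic
liver disease, ACLD), both inclusive upward.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Union

import numpy as np

ArrayLike = Union[float, np.ndarray]

#: FIB-4 gate cutoffs of the two-step screening algorithm: scan at
#: FIB-4 >= 1.3 when age <= 65 years, at FIB-4 >= 2.0 above 65.
FIB4_LOW_CUTOFF = 1.3
FIB4_ELDERLY_CUTOFF = 2.0
AGE_CUTOFF = 65.0
#: Above this FIB-4 the risk of advanced fibrosis is considered high.
FIB4_HIGH_CUTOFF = 2.67

#: LSM staging thresholds (kPa), inclusive upward.
LSM_SF_CUTOFF = 8.0
LSM_ACLD_CUTOFF = 12.0


class FibrosisStage(str, Enum):
    """VCTE-derived fibrosis stage from liver stiffness."""

    NO_SF = "no_sf"
    SF = "sf"
    ACLD = "acld"

    @property
    def is_positive(self) -> bool:
        """SF and ACLD pool as the positive class throughout."""
        return self is not FibrosisStage.NO_SF


class Fib4Band(str, Enum):
    LOW = "low"
    INTERMEDIATE = "intermediate"
    HIGH = "high"


@dataclass(frozen=True)
class Fib4Result:
    """A FIB-4 score with its age-conditional risk band.

    ``band`` is ``high`` iff score > 2.67, ``low`` iff the score falls
    below the age-conditional scan threshold (1.3 up to age 65, 2.0
    beyond), ``intermediate`` otherwise.
    """

    score: float
    band: Fib4Band


def _check_positive(**kwargs: ArrayLike) -> None:
    for name, value in kwargs.items():
        arr = np.asarray(value, dtype=float)
        if not np.all(np.isfinite(arr)) or np.any(arr <= 0):
            raise ValueError(f"{name} must be positive and finite")


def compute_fib4(
    age: ArrayLike, ast: ArrayLike, alt: ArrayLike, platelet_count: ArrayLike
) -> ArrayLike:
    """FIB-4 = age * AST / (platelets * sqrt(ALT)).

    Accepts scalars or aligned arrays; every argument must be strictly
    positive (a non-positive argument raises ``ValueError`` naming it).
    """
    _check_positive(age=age, ast=ast, alt=alt, platelet_count=platelet_count)
    score = np.asarray(age, float) * np.asarray(ast, float) / (
        np.asarray(platelet_count, float) * np.sqrt(np.asarray(alt, float))
    )
    return float(score) if score.ndim == 0 else score


def easl_fib4_gate(age: ArrayLike, fib4: ArrayLike) -> Union[bool, np.ndarray]:
    """Age-conditional FIB-4 gate of the two-step algorithm.

    True iff (age <= 65 and FIB-4 >= 1.3) or (age > 65 and FIB-4 >= 2.0).
    """
    _check_positive(age=age)
    a = np.asarray(age, float)
    f = np.asarray(fib4, float)
    if np.any(f < 0) or not np.all(np.isfinite(f)):
        raise ValueError("fib4 must be finite and >= 0")
    gate = np.where(a <= AGE_CUTOFF, f >= FIB4_LOW_CUTOFF, f >= FIB4_ELDERLY_CUTOFF)
    return bool(gate) if gate.ndim == 0 else gate


def classify_fib4(age: float, score: float) -> Fib4Result:
    """Band a FIB-4 score given the patient's age."""
    if score > FIB4_HIGH_CUTOFF:
        band = Fib4Band.HIGH
    elif easl_fib4_gate(age, score):
        band = Fib4Band.INTERMEDIATE
    else:
        band = Fib4Band.LOW
    return Fib4Result(score=float(score), band=band)


def stage_fibrosis(lsm_kpa: float) -> FibrosisStage:
    """Map a liver stiffness measurement (kPa) to a fibrosis stage.

    lsm < 8.0 -> no significant fibrosis; 8.0 <= lsm < 12.0 -> SF;
    lsm >= 12.0 -> ACLD. Boundaries are inclusive upward.
    """
    _check_positive(lsm_kpa=lsm_kpa)
    if lsm_kpa >= LSM_ACLD_CUTOFF:
        return FibrosisStage.ACLD
    if lsm_kpa >= LSM_SF_CUTOFF:
        return FibrosisStage.SF
    return FibrosisStage.NO_SF
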