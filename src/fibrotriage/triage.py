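"""VCTE-referral rules.

Two rules are implemented behind one stateless, scikit-learn-compatible
classifier:

``easl2024``
    Refer iff the age-conditional FIB-4 gate fires (FIB-4 >= 1.3 at age
    <= 65, >= 2.0 above 65).
``new_criterion``
    Refer iff the FIB-4 gate fires AND at least one of three risk
    factors is present: diabetes duration >= 5 years, any diabetic
    micro/macrovascular complication, or BMI >= 25 kg/m^2.

The new criterion is a conjunction containing the gate, so its referral
set is always a subset of the EASL referral set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .records import Cohort, PatientRecord
from .scoring import FIB4_HIGH_CUTOFF, compute_fib4, easl_fib4_gate

RULE_EASL = "easl2024"
RULE_NEW = "new_criterion"
RULE_IDS = (RULE_EASL, RULE_NEW)

#: Factor thresholds of the new criterion.
DM_DURATION_CUTOFF = 5.0
BMI_CUTOFF = 25.0

#: Reason tokens reported with each referral decision.
REASON_GATE = "fib4_gate"
REASON_DURATION = "dm_duration"
REASON_COMPLICATIONS = "complications"
REASON_BMI = "bmi"
REASON_HIGH_RISK = "fib4_high_risk"


@dataclass(frozen=True)
class TriageDecision:
    """Outcome of one referral rule on one patient.

    ``reasons`` lists every satisfied sub-criterion, so a referral is
    always explainable; ``refer`` is True only when the rule's full
    condition holds.
    """

    rule_id: str
    refer: bool
    reasons: tuple[str, ...] = ()
    patient_id: Optional[str] = None

    def __post_init__(self):
        if self.refer and not self.reasons:
            raise ValueError("a referral must carry at least one reason")


class ReferralClassifier(BaseEstimator):
    """Rule-based VCTE-referral classifier over a cohort table.

    A deterministic decision rule, exposed with the scikit-learn
    estimator protocol so it drops into pipelines and model-selection
    tooling: ``fit`` only validates the input schema, ``predict`` returns
    a boolean referral vector.

    Parameters
    ----------
    rule : {"easl2024", "new_criterion"}
        Which referral rule to apply.
    high_risk_bypass : bool
        When True, patients with FIB-4 > 2.67 (high risk of advanced
        fibrosis) are referred directly under the new criterion even if
        no risk factor is present. Off by default: the criterion is
        defined as the FIB-4 gate plus at least one factor, with no
        high-risk exception.
    """

    def __init__(self, rule: str = RULE_NEW, high_risk_bypass: bool = False):
        self.rule = rule
        self.high_risk_bypass = high_risk_bypass

    def _required_columns(self) -> tuple[str, ...]:
        base = ("age", "ast", "alt", "platelet_count")
        if self.rule == RULE_EASL:
            return base
        return base + ("diabetes_duration", "has_vascular_complications", "bmi")

    def _validate(self, X: pd.DataFrame) -> None:
        if self.rule not in RULE_IDS:
            raise ValueError(f"unknown rule {self.rule!r}; expected one of {RULE_IDS}")
        missing = [c for c in self._required_columns() if c not in X.columns]
        if missing:
            raise ValueError(f"cohort table lacks required columns {missing}")

    def fit(self, X: pd.DataFrame, y=None) -> "ReferralClassifier":
        self._validate(X)
        self.n_features_in_ = X.shape[1]
        self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        return self

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        """Boolean referral vector, one entry per cohort row."""
        self._validate(X)
        fib4 = compute_fib4(
            X["age"].to_numpy(float),
            X["ast"].to_numpy(float),
            X["alt"].to_numpy(float),
            X["platelet_count"].to_numpy(float),
        )
        gate = easl_fib4_gate(X["age"].to_numpy(float), fib4)
        if self.rule == RULE_EASL:
            return np.asarray(gate, bool)
        factors = (
            (X["diabetes_duration"].to_numpy(float) >= DM_DURATION_CUTOFF)
            | X["has_vascular_complications"].to_numpy(bool)
            | (X["bmi"].to_numpy(float) >= BMI_CUTOFF)
        )
        refer = np.asarray(gate & factors, bool)
        if self.high_risk_bypass:
            refer = refer | (np.asarray(fib4) > FIB4_HIGH_CUTOFF)
        return refer

    def decide(self, patient: PatientRecord) -> TriageDecision:
        """Full decision for one patient, with the satisfied sub-criteria."""
        fib4 = compute_fib4(patient.age, patient.ast, patient.alt, patient.platelet_count)
        if self.rule == RULE_EASL:
            return easl_rule(patient, fib4=fib4)
        return new_criterion_rule(
            patient.age,
            fib4,
            patient.diabetes_duration,
            patient.has_vascular_complications,
            patient.bmi,
            high_risk_bypass=self.high_risk_bypass,
            patient_id=patient.patient_id,
        )


def easl_rule(patient: PatientRecord, fib4: Optional[float] = None) -> TriageDecision:
    """Apply the EASL-2024 FIB-4 gate to one patient record."""
    if fib4 is None:
        fib4 = compute_fib4(patient.age, patient.ast, patient.alt, patient.platelet_count)
    gate = easl_fib4_gate(patient.age, fib4)
    return TriageDecision(
        rule_id=RULE_EASL,
        refer=bool(gate),
        reasons=(REASON_GATE,) if gate else (),
        patient_id=patient.patient_id,
    )


def new_criterion_rule(
    age: float,
    fib4: float,
    diabetes_duration: float,
    has_vascular_complications: bool,
    bmi: float,
    *,
    high_risk_bypass: bool = False,
    patient_id: Optional[str] = None,
) -> TriageDecision:
    """The three-factor referral criterion on explicit inputs.

    Refer iff the FIB-4 gate fires and at least one of: diabetes
    duration >= 5 years, vascular complications, BMI >= 25 kg/m^2.
    ``reasons`` lists every satisfied sub-criterion whether or not the
    conjunction as a whole holds.
    """
    gate = bool(easl_fib4_gate(age, fib4))
    reasons: list[str] = []
    if gate:
        reasons.append(REASON_GATE)
    if diabetes_duration >= DM_DURATION_CUTOFF:
        reasons.append(REASON_DURATION)
    if has_vascular_complications:
        reasons.append(REASON_COMPLICATIONS)
    if bmi >= BMI_CUTOFF:
        reasons.append(REASON_BMI)
    any_factor = any(
        r in reasons for r in (REASON_DURATION, REASON_COMPLICATIONS, REASON_BMI)
    )
    refer = gate and any_factor
    if high_risk_bypass and fib4 > FIB4_HIGH_CUTOFF:
        reasons.append(REASON_HIGH_RISK)
        refer = True
    return TriageDecision(
        rule_id=RULE_NEW, refer=refer, reasons=tuple(reasons), patient_id=patient_id
    )


def apply_rule(
    patient: PatientRecord, rule_id: str, *, high_risk_bypass: bool = False
) -> TriageDecision:
    return ReferralClassifier(rule=rule_id, high_risk_bypass=high_risk_bypass).decide(patient)


@dataclass
class CohortTriage:
    """Per-patient decisions for one rule over one cohort.

    ``decisions`` is ordered like the cohort; a record whose fields the
    rule could not evaluate gets ``None`` there and a diagnostic in
    ``errors`` (1-based row index, message).
    """

    rule_id: str
    decisions: list[Optional[TriageDecision]] = field(default_factory=list)
    errors: list[tuple[int, str]] = field(default_factory=list)

    @property
    def n_referred(self) -> int:
        return sum(1 for d in self.decisions if d is not None and d.refer)


def triage_cohort(
    cohort: Union[Cohort, Sequence[PatientRecord]],
    rule_id: str,
    *,
    high_risk_bypass: bool = False,
) -> CohortTriage:
    """Apply one referral rule to every record of a cohort.

    Records missing a field the rule needs are reported in
    ``errors`` and excluded from the referral count, never silently
    referred or dropped from the decision list.
    """
    clf = ReferralClassifier(rule=rule_id, high_risk_bypass=high_risk_bypass)
    result = CohortTriage(rule_id=rule_id)
    for i, rec in enumerate(cohort, start=1):
        try:
            result.decisions.append(clf.decide(rec))
        except (TypeError, ValueError) as e:
            result.decisions.append(None)
            result.errors.append((i, f"{rec.patient_id}: {e}"))
    return result
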