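"""Diagnostic-accuracy statistics for referral rules.

A rule's referrals are crossed against VCTE truth (significant fibrosis
or advanced chronic liver disease pooled as positive) into a 2x2
confusion matrix, from which sensitivity, specificity, predictive
values, likelihood ratios, Wilson confidence intervals and the
rank-based (Mann-Whitney) AUC are derived. Accuracy is always evaluated
on the truth-bearing subset — patients who actually underwent VCTE —
while referral counts cover the whole cohort, mirroring the distinction
between patients *indicated* for a scan and patients *scanned*.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Optional, Sequence, Union

import numpy as np
from scipy import stats

from .records import Cohort
from .scoring import FibrosisStage, stage_fibrosis
from .triage import TriageDecision, triage_cohort


@dataclass(frozen=True)
class ConfusionMatrix:
    """Referral vs VCTE-diagnosed significant fibrosis.

    tp: referred with SF/ACLD; fp: referred without SF; fn: not referred
    with SF/ACLD; tn: not referred without SF.
    """

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion-matrix cells must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def n_positive(self) -> int:
        """Truth margin: patients with SF/ACLD (rule-invariant)."""
        return self.tp + self.fn

    @property
    def n_negative(self) -> int:
        return self.fp + self.tn

    @property
    def n_referred(self) -> int:
        return self.tp + self.fp

    def as_table(self) -> list[list[int]]:
        """Rows: referred / not referred; columns: SF/ACLD, no SF."""
        return [[self.tp, self.fp], [self.fn, self.tn]]


@dataclass
class DiagnosticReport:
    """Accuracy summary of one rule on one evaluated cohort.

    Proportions are in [0, 1]; ``intervals`` maps each defined
    proportion to its two-sided Wilson interval at ``conf_level``.
    Ratios with a zero denominator are ``None`` and named in
    ``undefined`` rather than fabricated.
    """

    cm: ConfusionMatrix
    sensitivity: Optional[float]
    specificity: Optional[float]
    ppv: Optional[float]
    npv: Optional[float]
    lr_pos: Optional[float]
    lr_neg: Optional[float]
    n_referred: int
    conf_level: float
    intervals: dict[str, tuple[float, float]] = field(default_factory=dict)
    undefined: tuple[str, ...] = ()

    def rounded(self) -> dict:
        """Percentages rounded half-up to 1 d.p., likelihood ratios to 2,
        matching conventional clinical reporting."""
        out: dict = {}
        for name in ("sensitivity", "specificity", "ppv", "npv"):
            v = getattr(self, name)
            out[f"{name}_pct"] = None if v is None else round_half_up(100 * v, 1)
        out["lr_pos"] = None if self.lr_pos is None else round_half_up(self.lr_pos, 2)
        out["lr_neg"] = None if self.lr_neg is None else round_half_up(self.lr_neg, 2)
        out["n_referred"] = self.n_referred
        return out


def round_half_up(x: float, ndigits: int) -> float:
    """Round with ties away from zero (the convention clinical tables use),
    not banker's rounding. Non-finite values pass through unchanged (an
    infinite Wald bound from a near-separated cell stays infinite)."""
    if not math.isfinite(x):
        return float(x)
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def _is_positive_truth(t) -> bool:
    if isinstance(t, FibrosisStage):
        return t.is_positive
    return bool(t)


def _refer_flag(d) -> bool:
    if isinstance(d, TriageDecision):
        return d.refer
    return bool(d)


def confusion(
    decisions: Sequence[Union[TriageDecision, bool]],
    truth: Sequence[Union[FibrosisStage, bool]],
) -> ConfusionMatrix:
    """Cross referral decisions against fibrosis truth.

    ``truth`` entries may be :class:`FibrosisStage` (SF and ACLD both
    count as positive) or booleans. Inputs must be aligned, non-empty
    and restricted to patients with truth available.
    """
    if len(decisions) != len(truth):
        raise ValueError(
            f"decisions ({len(decisions)}) and truth ({len(truth)}) differ in length"
        )
    if len(decisions) == 0:
        raise ValueError("cannot build a confusion matrix from no records")
    tp = fp = fn = tn = 0
    for d, t in zip(decisions, truth):
        r, pos = _refer_flag(d), _is_positive_truth(t)
        if r and pos:
            tp += 1
        elif r:
            fp += 1
        elif pos:
            fn += 1
        else:
            tn += 1
    return ConfusionMatrix(tp=tp, fp=fp, fn=fn, tn=tn)


def wilson_interval(
    successes: int, trials: int, conf_level: float = 0.95
) -> tuple[float, float]:
    """Two-sided Wilson score interval for a binomial proportion.

    Chosen over the Wald interval for its small-sample and boundary
    behaviour; always contained in [0, 1] and contains the point
    estimate.
    """
    if trials <= 0:
        raise ValueError("trials must be > 0")
    if not 0 <= successes <= trials:
        raise ValueError("successes must lie in [0, trials]")
    if not 0 < conf_level < 1:
        raise ValueError("conf_level must be in (0, 1)")
    z = stats.norm.ppf(0.5 + conf_level / 2)
    p = successes / trials
    denom = 1 + z**2 / trials
    centre = (p + z**2 / (2 * trials)) / denom
    half = (z / denom) * np.sqrt(p * (1 - p) / trials + z**2 / (4 * trials**2))
    # the bound is exactly 0 at k = 0 (and 1 at k = n); avoid roundoff there
    lo = 0.0 if successes == 0 else max(0.0, centre - half)
    hi = 1.0 if successes == trials else min(1.0, centre + half)
    return (lo, hi)


def diagnostic_metrics(cm: ConfusionMatrix, conf_level: float = 0.95) -> DiagnosticReport:
    """All accuracy statistics derivable from a 2x2 confusion matrix.

    sensitivity = tp/(tp+fn), specificity = tn/(tn+fp),
    ppv = tp/(tp+fp), npv = tn/(tn+fn),
    LR+ = sens/(1-spec), LR- = (1-sens)/spec.
    Zero-denominator ratios are flagged as undefined, never fabricated.
    """
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    undefined: list[str] = []
    intervals: dict[str, tuple[float, float]] = {}

    def ratio(num: int, den: int, name: str) -> Optional[float]:
        if den == 0:
            undefined.append(name)
            return None
        intervals[name] = wilson_interval(num, den, conf_level)
        return num / den

    sens = ratio(cm.tp, cm.n_positive, "sensitivity")
    spec = ratio(cm.tn, cm.n_negative, "specificity")
    ppv = ratio(cm.tp, cm.n_referred, "ppv")
    npv = ratio(cm.tn, cm.fn + cm.tn, "npv")

    lr_pos = lr_neg = None
    if sens is not None and spec is not None:
        if spec == 1.0:
            undefined.append("lr_pos")
        else:
            lr_pos = sens / (1 - spec)
        if spec == 0.0:
            undefined.append("lr_neg")
        else:
            lr_neg = (1 - sens) / spec
    else:
        undefined.extend(["lr_pos", "lr_neg"])

    return DiagnosticReport(
        cm=cm,
        sensitivity=sens,
        specificity=spec,
        ppv=ppv,
        npv=npv,
        lr_pos=lr_pos,
        lr_neg=lr_neg,
        n_referred=cm.n_referred,
        conf_level=conf_level,
        intervals=intervals,
        undefined=tuple(undefined),
    )


def referral_reduction(n_ref_baseline: int, n_ref_new: int) -> float:
    """Fraction of baseline referrals avoided by the new rule."""
    if n_ref_baseline <= 0:
        raise ValueError("baseline referral count must be > 0")
    if n_ref_new > n_ref_baseline:
        raise ValueError(
            "new referral count exceeds baseline; the new rule must be nested"
        )
    return (n_ref_baseline - n_ref_new) / n_ref_baseline


def empirical_auc(
    scores: Sequence[Union[float, bool]], truth: Sequence[Union[bool, FibrosisStage]]
) -> float:
    """Rank-based (Mann-Whitney) area under the ROC curve.

    Tied scores contribute half via midranks, so for a single binary
    referral flag this reduces exactly to (sensitivity + specificity)/2.
    Both classes must be present.
    """
    s = np.asarray([float(x) for x in scores], dtype=float)
    y = np.asarray([_is_positive_truth(t) for t in truth], dtype=bool)
    if s.shape[0] != y.shape[0]:
        raise ValueError("scores and truth differ in length")
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC requires both classes present")
    ranks = stats.rankdata(s)  # midranks handle ties
    return float((ranks[y].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def auc_from_confusion(cm: ConfusionMatrix) -> float:
    """(sensitivity + specificity)/2 — the AUC of a single binary rule."""
    if cm.n_positive == 0 or cm.n_negative == 0:
        raise ValueError("AUC requires both classes present")
    return (cm.tp / cm.n_positive + cm.tn / cm.n_negative) / 2


@dataclass
class RuleComparison:
    """Paired evaluation of two referral rules on one cohort.

    Referral counts cover every evaluable record; accuracy is computed
    on the truth-bearing (scanned) subset only. ``discordant_ids`` are
    the patients referred by exactly one of the two rules.
    """

    rule_a: str
    rule_b: str
    cm_a: ConfusionMatrix
    cm_b: ConfusionMatrix
    report_a: DiagnosticReport
    report_b: DiagnosticReport
    n_referred_a: int
    n_referred_b: int
    n_evaluated: int
    reduction: float
    discordant_ids: tuple[str, ...]


def compare_rules(
    cohort: Cohort,
    rule_a: str = "easl2024",
    rule_b: str = "new_criterion",
    *,
    conf_level: float = 0.95,
    high_risk_bypass: bool = False,
) -> RuleComparison:
    """Head-to-head comparison of two referral rules.

    The referral reduction is computed on whole-cohort referral counts
    (rule_a as baseline); sensitivity/specificity and friends on the
    subset of records with an LSM.
    """
    tri_a = triage_cohort(cohort, rule_a, high_risk_bypass=high_risk_bypass)
    tri_b = triage_cohort(cohort, rule_b, high_risk_bypass=high_risk_bypass)

    dec_a: list[TriageDecision] = []
    dec_b: list[TriageDecision] = []
    truth: list[FibrosisStage] = []
    discordant: list[str] = []
    for rec, da, db in zip(cohort, tri_a.decisions, tri_b.decisions):
        if da is not None and db is not None and da.refer != db.refer:
            discordant.append(rec.patient_id)
        if rec.lsm_kpa is None or da is None or db is None:
            continue
        dec_a.append(da)
        dec_b.append(db)
        truth.append(stage_fibrosis(rec.lsm_kpa))
    if not truth:
        raise ValueError("no records carry an LSM; accuracy cannot be evaluated")

    cm_a = confusion(dec_a, truth)
    cm_b = confusion(dec_b, truth)
    return RuleComparison(
        rule_a=rule_a,
        rule_b=rule_b,
        cm_a=cm_a,
        cm_b=cm_b,
        report_a=diagnostic_metrics(cm_a, conf_level),
        report_b=diagnostic_metrics(cm_b, conf_level),
        n_referred_a=tri_a.n_referred,
        n_referred_b=tri_b.n_referred,
        n_evaluated=len(truth),
        reduction=referral_reduction(tri_a.n_referred, tri_b.n_referred)
        if tri_a.n_referred > 0
        else 0.0,
        discordant_ids=tuple(discordant),
    )
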