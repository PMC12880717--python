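"""Synthetic diabetic-MASLD screening cohorts.

Generates patient tables with the covariate marginals, FIB-4
distribution, factor-fibrosis odds-ratio structure and stage-conditional
liver-stiffness distributions of a South Asian type-2-diabetes
outpatient screening population, so every pipeline stage — scoring,
triage, accuracy comparison, factor regression — can be exercised and
calibrated without any real patient data.

Generative model, per patient:

1. demographics and comorbidity flags from independent marginals
   (age normal, BMI by WHO category then uniform within it, diabetes
   duration log-normal matched to median 5 y and IQR 2-10 y, binary
   flags Bernoulli);
2. a FIB-4 band drawn from the population band frequencies, a score
   uniform within the band, and AST back-solved from uniformly drawn
   ALT and platelets so the recorded labs reproduce the score exactly;
3. patients with FIB-4 >= 1.3 are scanned; their latent SF/ACLD status
   follows a logistic risk model on the three referral factors
   (diabetes duration >= 5 y, vascular complications, BMI >= 25) with
   the intercept calibrated so the scanned SF/ACLD prevalence hits its
   target; positives split into SF vs ACLD at a fixed fraction;
4. LSM drawn from a stage-conditional truncated log-normal, so staging
   thresholds at 8 and 12 kPa recover the latent stage by construction.

Factors are independent of the FIB-4 band, so the risk-model intercept
is the single association knob linking bands, factors and fibrosis.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, field, replace
from typing import Optional

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit
from scipy.stats import truncnorm

from .records import Cohort, PatientRecord
from .scoring import FibrosisStage

#: Log odds ratios of the three referral factors for SF/ACLD.
DEFAULT_RISK_LOG_OR = {
    "dm_duration_ge5": math.log(3.8),
    "complications": math.log(19.4),
    "bmi_ge25": math.log(6.2),
}


class GenerationError(RuntimeError):
    """Raised when lab back-solving cannot satisfy its bounds."""


@dataclass
class CohortGenParams:
    """Everything governing synthetic cohort generation.

    Defaults are the study-population values: mean age 53.6 (SD 11.4)
    years, 51.5% male, BMI category frequencies (0.8%, 35.3%, 42.4%,
    21.5%), diabetes duration median 5 (IQR 2-10) years, vascular
    complications in 17.9%, FIB-4 band frequencies 64.7% / 30.9% / 4.4%
    (< 1.3, 1.3-2.67, > 2.67), SF/ACLD prevalence 62.8% among scanned
    patients with an ACLD fraction of 31/76 among positives, and factor
    odds ratios 3.8 / 19.4 / 6.2.
    """

    n: int = 363
    seed: int = 0
    label: str = "synthetic"

    # demographics
    age_mean: float = 53.6
    age_sd: float = 11.4
    age_bounds: tuple[float, float] = (18.0, 95.0)
    male_frac: float = 0.515

    # anthropometry: P(category) for BMI <18.5, 18.5-24.9, 25-29.9, >=30
    bmi_category_probs: tuple[float, ...] = (0.008, 0.353, 0.424, 0.215)
    bmi_category_bounds: tuple[tuple[float, float], ...] = (
        (16.0, 18.5),
        (18.5, 25.0),
        (25.0, 30.0),
        (30.0, 40.0),
    )
    waist_mean_female: float = 89.9
    waist_sd_female: float = 8.99
    waist_mean_male: float = 90.4
    waist_sd_male: float = 7.85

    # diabetes history
    dm_duration_median: float = 5.0
    dm_duration_iqr: tuple[float, float] = (2.0, 10.0)
    complications_prev: float = 0.179

    # comorbidity / lifestyle flags (regression covariates)
    comorbidity_prevs: dict = field(
        default_factory=lambda: {
            "hypertension": 0.529,
            "dyslipidaemia": 0.680,
            "ischaemic_heart_disease": 0.072,
            "current_smoker": 0.066,
            "family_history_liver_disease": 0.140,
            "hypothyroidism": 0.125,
            "uss_grade_ge2": 0.581,
            "risk_diet": 0.4375,
            "sedentary_lifestyle": 0.656,
        }
    )

    # fibrosis risk model (on scanned patients)
    risk_log_or: dict = field(default_factory=lambda: dict(DEFAULT_RISK_LOG_OR))
    risk_intercept: Optional[float] = None  # None -> calibrate to sf_prev_scanned
    sf_prev_scanned: float = 0.628
    acld_frac_given_sf: float = 31 / 76

    # FIB-4 structure: P(band) for < 1.3, 1.3-2.67, > 2.67 and the score
    # ranges sampled uniformly within each band
    fib4_band_probs: tuple[float, float, float] = (0.647, 0.309, 0.044)
    fib4_band_ranges: tuple[tuple[float, float], ...] = (
        (0.35, 1.3),
        (1.3, 2.67),
        (2.67, 6.5),
    )
    scan_all: bool = False  # True: every patient gets VCTE (registry-style cohort)

    # stage-conditional LSM (kPa): (log-median, log-sd, lower, upper)
    lsm_components: dict = field(
        default_factory=lambda: {
            "no_sf": (math.log(6.3), 0.25, 2.0, 8.0),
            "sf": (math.log(9.5), 0.15, 8.0, 12.0),
            "acld": (math.log(14.5), 0.25, 12.0, 50.0),
        }
    )

    # lab back-solve bounds (U/L, 10^9/L, U/L)
    alt_range: tuple[float, float] = (10.0, 200.0)
    platelet_range: tuple[float, float] = (100.0, 450.0)
    ast_range: tuple[float, float] = (10.0, 300.0)

    def validate(self) -> "CohortGenParams":
        if self.n < 0:
            raise ValueError("n must be >= 0")
        for name, probs in (
            ("bmi_category_probs", self.bmi_category_probs),
            ("fib4_band_probs", self.fib4_band_probs),
        ):
            if abs(sum(probs) - 1.0) > 1e-9 or min(probs) < 0:
                raise ValueError(f"{name} must be a probability vector summing to 1")
        for frac in (self.male_frac, self.complications_prev, self.sf_prev_scanned,
                     self.acld_frac_given_sf, *self.comorbidity_prevs.values()):
            if not 0 <= frac <= 1:
                raise ValueError("prevalences must lie in [0, 1]")
        if self.age_sd <= 0 or self.dm_duration_median <= 0:
            raise ValueError("scale parameters must be positive")
        lo, hi = self.dm_duration_iqr
        if not 0 < lo < self.dm_duration_median < hi:
            raise ValueError("dm_duration_iqr must bracket the median")
        return self

    @property
    def dm_duration_sigma(self) -> float:
        """Log-normal sigma matching the quartiles to the stated IQR."""
        lo, hi = self.dm_duration_iqr
        z75 = 0.6744897501960817  # standard-normal upper quartile
        return (math.log(hi) - math.log(lo)) / (2 * z75)

    @property
    def factor_prevalences(self) -> dict:
        """Population probabilities of the three risk factors."""
        mu, sigma = math.log(self.dm_duration_median), self.dm_duration_sigma
        p_dur = 1 - _norm_cdf((math.log(5.0) - mu) / sigma)
        p_bmi = sum(self.bmi_category_probs[2:])
        return {
            "dm_duration_ge5": p_dur,
            "complications": self.complications_prev,
            "bmi_ge25": p_bmi,
        }


def _norm_cdf(z: float) -> float:
    return 0.5 * math.erfc(-z / math.sqrt(2))


def default_params(n: int = 363, seed: int = 0) -> CohortGenParams:
    """Study-calibrated defaults (see :class:`CohortGenParams`)."""
    return CohortGenParams(n=n, seed=seed).validate()


def external_validation_params(n: int = 372, seed: int = 0) -> CohortGenParams:
    """A registry-style preset at the external-validation cohort's scale.

    Every patient carries an LSM (a VCTE-database population, not a
    screening one): mean age 59 (SD 8.6), 41.9% male, SF/ACLD
    prevalence 269/372, and a FIB-4 mix putting roughly 63% above the
    age-conditional gate. Intended for exercising rule comparison at
    this scale; its accuracy values are illustrative, not calibration
    anchors.
    """
    return replace(
        default_params(n=n, seed=seed),
        label="external-validation-shaped",
        age_mean=59.0,
        age_sd=8.6,
        male_frac=0.419,
        scan_all=True,
        sf_prev_scanned=269 / 372,
        fib4_band_probs=(0.30, 0.53, 0.17),
    ).validate()


def calibrate_risk_intercept(params: CohortGenParams) -> float:
    """Intercept making the expected scanned SF/ACLD prevalence hit target.

    The three factors are mutually independent and independent of the
    FIB-4 band, so the expectation is an eight-cell sum over the factor
    combinations; solved by bisection.
    """
    if params.risk_intercept is not None:
        return params.risk_intercept
    prevs = params.factor_prevalences
    names = list(DEFAULT_RISK_LOG_OR)
    betas = np.array([params.risk_log_or[k] for k in names])
    ps = np.array([prevs[k] for k in names])

    cells = []
    for mask in range(8):
        x = np.array([(mask >> i) & 1 for i in range(3)], dtype=float)
        weight = np.prod(np.where(x == 1, ps, 1 - ps))
        cells.append((weight, float(x @ betas)))

    def mean_prev(b0: float) -> float:
        return sum(w * expit(b0 + lp) for w, lp in cells)

    return brentq(lambda b0: mean_prev(b0) - params.sf_prev_scanned, -40.0, 40.0)


def _truncated_lognormal(
    rng: np.random.Generator, mu: float, sigma: float, lo: float, hi: float, size: int
) -> np.ndarray:
    a, b = (math.log(lo) - mu) / sigma, (math.log(hi) - mu) / sigma
    z = truncnorm.rvs(a, b, loc=mu, scale=sigma, size=size, random_state=rng)
    return np.exp(z)


def generate_cohort(params: CohortGenParams) -> Cohort:
    """Draw one synthetic cohort; deterministic given ``params.seed``."""
    params.validate()
    rng = np.random.default_rng(params.seed)
    n = params.n
    label = f"{params.label}-seed{params.seed}"
    if n == 0:
        return Cohort(records=[], label=label)

    # demographics
    male = rng.random(n) < params.male_frac
    lo, hi = params.age_bounds
    age = rng.normal(params.age_mean, params.age_sd, n)
    for _ in range(1000):
        bad = (age < lo) | (age > hi)
        if not bad.any():
            break
        age[bad] = rng.normal(params.age_mean, params.age_sd, int(bad.sum()))

    cat = rng.choice(len(params.bmi_category_probs), size=n, p=params.bmi_category_probs)
    bounds = np.array(params.bmi_category_bounds)
    bmi = rng.uniform(bounds[cat, 0], bounds[cat, 1])

    waist = np.where(
        male,
        rng.normal(params.waist_mean_male, params.waist_sd_male, n),
        rng.normal(params.waist_mean_female, params.waist_sd_female, n),
    )

    mu_d, sig_d = math.log(params.dm_duration_median), params.dm_duration_sigma
    dm_duration = np.exp(rng.normal(mu_d, sig_d, n))
    complications = rng.random(n) < params.complications_prev
    flags = {k: rng.random(n) < p for k, p in params.comorbidity_prevs.items()}

    # FIB-4 band, score, and labs consistent with the score
    band = rng.choice(3, size=n, p=params.fib4_band_probs)
    branges = np.array(params.fib4_band_ranges)
    fib4 = rng.uniform(branges[band, 0], branges[band, 1])

    alt = rng.uniform(*params.alt_range, size=n)
    plate = rng.uniform(*params.platelet_range, size=n)
    ast = fib4 * plate * np.sqrt(alt) / age
    lo_a, hi_a = params.ast_range
    for attempt in range(1000):
        bad = (ast < lo_a) | (ast > hi_a)
        if not bad.any():
            break
        m = int(bad.sum())
        alt[bad] = rng.uniform(*params.alt_range, size=m)
        plate[bad] = rng.uniform(*params.platelet_range, size=m)
        ast[bad] = fib4[bad] * plate[bad] * np.sqrt(alt[bad]) / age[bad]
    else:
        raise GenerationError(
            "AST back-solve exhausted resampling attempts; the FIB-4 band "
            "ranges are incompatible with the lab bounds"
        )

    # latent fibrosis stage and LSM for scanned patients
    scanned = np.ones(n, bool) if params.scan_all else fib4 >= 1.3
    b0 = calibrate_risk_intercept(params)
    lp = (
        b0
        + params.risk_log_or["dm_duration_ge5"] * (dm_duration >= 5.0)
        + params.risk_log_or["complications"] * complications
        + params.risk_log_or["bmi_ge25"] * (bmi >= 25.0)
    )
    positive = scanned & (rng.random(n) < expit(lp))
    acld = positive & (rng.random(n) < params.acld_frac_given_sf)

    lsm = np.full(n, np.nan)
    for stage_name, mask in (
        ("no_sf", scanned & ~positive),
        ("sf", positive & ~acld),
        ("acld", acld),
    ):
        m = int(mask.sum())
        if m:
            mu, sigma, lo_s, hi_s = params.lsm_components[stage_name]
            lsm[mask] = _truncated_lognormal(rng, mu, sigma, lo_s, hi_s, m)

    records = []
    width = max(5, len(str(n)))
    for i in range(n):
        records.append(
            PatientRecord(
                patient_id=f"p{i + 1:0{width}d}",
                age=float(age[i]),
                sex="male" if male[i] else "female",
                ast=float(ast[i]),
                alt=float(alt[i]),
                platelet_count=float(plate[i]),
                bmi=float(bmi[i]),
                diabetes_duration=float(dm_duration[i]),
                has_vascular_complications=bool(complications[i]),
                lsm_kpa=float(lsm[i]) if scanned[i] else None,
                waist_cm=float(waist[i]),
                **{k: bool(v[i]) for k, v in flags.items()},
            )
        )
    return Cohort(records=records, label=label)


def summarize_cohort(cohort: Cohort) -> dict:
    """Marginal summary shaped like a baseline-characteristics table.

    Means/SDs, medians/IQRs, category fractions, FIB-4 band counts, the
    age-split count of patients meeting the EASL gate, and the LSM/stage
    distribution of the scanned subset — directly comparable with the
    generator's calibration targets.
    """
    from .scoring import compute_fib4, easl_fib4_gate  # local to avoid cycle at import

    if len(cohort) == 0:
        raise ValueError("cannot summarise an empty cohort")
    df = cohort.to_dataframe()
    age = df["age"].to_numpy(float)
    fib4 = compute_fib4(
        age,
        df["ast"].to_numpy(float),
        df["alt"].to_numpy(float),
        df["platelet_count"].to_numpy(float),
    )
    gate = easl_fib4_gate(age, fib4)
    bmi = df["bmi"].to_numpy(float)
    dur = df["diabetes_duration"].to_numpy(float)
    n = len(cohort)

    out = {
        "n": n,
        "age_mean": float(age.mean()),
        "age_sd": float(age.std(ddof=1)) if n > 1 else 0.0,
        "age_le_65_frac": float((age <= 65).mean()),
        "male_frac": float((df["sex"] == "male").mean()),
        "bmi_category_fracs": {
            "lt_18_5": float((bmi < 18.5).mean()),
            "18_5_to_24_9": float(((bmi >= 18.5) & (bmi < 25)).mean()),
            "25_to_29_9": float(((bmi >= 25) & (bmi < 30)).mean()),
            "ge_30": float((bmi >= 30).mean()),
        },
        "bmi_ge25_frac": float((bmi >= 25).mean()),
        "dm_duration_median": float(np.median(dur)),
        "dm_duration_iqr": [float(np.percentile(dur, 25)), float(np.percentile(dur, 75))],
        "dm_duration_ge5_frac": float((dur >= 5).mean()),
        "complications_frac": float(df["has_vascular_complications"].astype(bool).mean()),
        "comorbidity_fracs": {
            k: float(df[k].dropna().astype(bool).mean()) if df[k].notna().any() else None
            for k in (
                "hypertension",
                "dyslipidaemia",
                "ischaemic_heart_disease",
                "current_smoker",
                "family_history_liver_disease",
            )
        },
        "fib4_band_fracs": {
            "lt_1_3": float((fib4 < 1.3).mean()),
            "1_3_to_2_67": float(((fib4 >= 1.3) & (fib4 <= 2.67)).mean()),
            "gt_2_67": float((fib4 > 2.67).mean()),
        },
        "easl_indicated": {
            "total": int(gate.sum()),
            "age_le_65": int((gate & (age <= 65)).sum()),
            "age_gt_65": int((gate & (age > 65)).sum()),
        },
    }

    lsm = df["lsm_kpa"].to_numpy(float)
    has = np.isfinite(lsm)
    out["scanned_n"] = int(has.sum())
    if has.any():
        scanned = lsm[has]
        out["lsm_median"] = float(np.median(scanned))
        out["lsm_iqr"] = [
            float(np.percentile(scanned, 25)),
            float(np.percentile(scanned, 75)),
        ]
        out["stage_counts"] = {
            "no_sf": int((scanned < 8).sum()),
            "sf": int(((scanned >= 8) & (scanned < 12)).sum()),
            "acld": int((scanned >= 12).sum()),
        }
    return out


def table4_fixture() -> Cohort:
    """Deterministic 121-patient scanned cohort with known rule behaviour.

    Construction forces the five joint cells of the two nested referral
    rules against fibrosis truth: 62 referred by both with SF/ACLD, 5 by
    the gate only with SF/ACLD, 21 by both without SF, 8 by the gate
    only without SF, and 25 referred by neither (9 with SF/ACLD, 16
    without) — patients over 65 whose FIB-4 sits in [1.3, 2.0), scanned
    but below both rules' thresholds. Gate-passers are 60-year-olds with
    FIB-4 exactly 1.5 (ALT 100, platelets 120, AST 30); the "gate only"
    groups carry none of the three risk factors, the "both" groups carry
    one, cycling through duration / complications / BMI. Every fourth
    positive of the largest group gets an LSM of 13 kPa so both SF and
    ACLD stages occur.
    """
    records: list[PatientRecord] = []

    def add(n: int, *, age: float, ast: float, factor: Optional[int], lsm_base: float,
            acld_every: int = 0):
        for j in range(n):
            dur, compl, bmi = 2.0, False, 23.0
            which = None if factor is None else (j % 3 if factor == -1 else factor)
            if which == 0:
                dur = 10.0
            elif which == 1:
                compl = True
            elif which == 2:
                bmi = 29.0
            lsm = 13.0 if (acld_every and j % acld_every == 0) else lsm_base
            records.append(
                PatientRecord(
                    patient_id=f"p{len(records) + 1:03d}",
                    age=age,
                    sex="male" if len(records) % 2 == 0 else "female",
                    ast=ast,
                    alt=100.0,
                    platelet_count=120.0,
                    bmi=bmi,
                    diabetes_duration=dur,
                    has_vascular_complications=compl,
                    lsm_kpa=lsm,
                )
            )

    gate_ast = 30.0  # FIB-4 = 60 * 30 / (120 * 10) = 1.5
    elder_ast = 1.5 * 120.0 * 10.0 / 70.0  # FIB-4 = 1.5 at age 70 (< 2.0 cutoff)
    add(62, age=60.0, ast=gate_ast, factor=-1, lsm_base=9.0, acld_every=4)  # both, SF
    add(5, age=60.0, ast=gate_ast, factor=None, lsm_base=10.0)  # gate only, SF
    add(21, age=60.0, ast=gate_ast, factor=-1, lsm_base=6.0)  # both, no SF
    add(8, age=60.0, ast=gate_ast, factor=None, lsm_base=6.0)  # gate only, no SF
    add(9, age=70.0, ast=elder_ast, factor=None, lsm_base=9.5)  # neither, SF
    add(16, age=70.0, ast=elder_ast, factor=None, lsm_base=6.5)  # neither, no SF

    return Cohort(records=records, label="table4-fixture").validate()


def params_to_dict(params: CohortGenParams) -> dict:
    """JSON/YAML-ready view of the generator parameters."""
    return asdict(params)


def params_from_dict(d: dict) -> CohortGenParams:
    """Build parameters from a config mapping, validating field names."""
    valid = {f.name for f in CohortGenParams.__dataclass_fields__.values()}
    unknown = set(d) - valid
    if unknown:
        raise ValueError(f"unknown generator parameters: {sorted(unknown)}")
    out = CohortGenParams(**{k: tuple(v) if isinstance(v, list) else v for k, v in d.items()})
    return out.validate()
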