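"""End-to-end screening pipeline: cohort in, comparison report out.

One call runs the full analysis: load or generate a cohort, compute
FIB-4 and stages, triage under the configured rules, evaluate accuracy
on the scanned subset, fit the factor regression, and emit a report
bundle (JSON for machines, Markdown for humans, a per-patient decision
CSV). Every number in the bundle is a deterministic function of the
configuration and seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .diagnostics import compare_rules, round_half_up
from .io import read_cohort, write_cohort
from .records import Cohort
from .regression import DesignSpec, fit_logistic_irls, univariate_screen
from .scoring import compute_fib4, easl_fib4_gate
from .simulate import CohortGenParams, generate_cohort, params_to_dict, summarize_cohort
from .triage import RULE_EASL, RULE_NEW, triage_cohort

log = logging.getLogger("fibrotriage")

#: Default regression covariates: the three referral factors as binary
#: indicators derived from the record fields.
FACTOR_COVARIATES = ("dm_duration_ge5", "complications", "bmi_ge25")


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Exactly one of ``input_path`` / ``gen_params`` must be set; ``seed``
    overrides the generator seed when simulating. The missing-data
    policy is complete-case per analysis stage: a record lacking a field
    one rule needs is excluded from that rule's counts (and reported),
    but kept wherever its fields suffice.
    """

    input_path: Optional[str] = None
    gen_params: Optional[CohortGenParams] = None
    rules: tuple[str, str] = (RULE_EASL, RULE_NEW)
    conf_level: float = 0.95
    seed: Optional[int] = None
    out_dir: Optional[str] = None
    missing_policy: str = "complete_case"
    high_risk_bypass: bool = False
    run_regression: bool = True
    regression_subset: str = "indicated"  # or "scanned"
    covariates: tuple[str, ...] = FACTOR_COVARIATES

    def validate(self) -> "RunConfig":
        if (self.input_path is None) == (self.gen_params is None):
            raise ValueError("exactly one of input_path and gen_params must be set")
        if len(self.rules) < 1:
            raise ValueError("at least one rule is required")
        if self.regression_subset not in ("indicated", "scanned"):
            raise ValueError("regression_subset must be 'indicated' or 'scanned'")
        return self


def _config_fingerprint(config: RunConfig) -> str:
    d = asdict(config)
    d.pop("out_dir", None)  # where the report lands does not change its numbers
    return hashlib.sha256(
        json.dumps(d, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def _load_cohort(config: RunConfig) -> Cohort:
    if config.input_path is not None:
        return read_cohort(config.input_path)
    params = config.gen_params
    if config.seed is not None:
        params = replace(params, seed=config.seed)
    return generate_cohort(params)


def _factor_frame(cohort: Cohort) -> pd.DataFrame:
    df = cohort.to_dataframe()
    return pd.DataFrame(
        {
            "dm_duration_ge5": (df["diabetes_duration"].astype(float) >= 5.0).astype(int),
            "complications": df["has_vascular_complications"].astype(bool).astype(int),
            "bmi_ge25": (df["bmi"].astype(float) >= 25.0).astype(int),
        },
        index=df.index,
    )


def _regression_section(cohort: Cohort, config: RunConfig) -> dict:
    """Factor regression on the truth-bearing subset.

    Outcome: SF/ACLD (LSM >= 8). Subset: scanned patients, optionally
    restricted to those the EASL gate indicates (the default, matching
    how the factors were originally identified).
    """
    df = cohort.to_dataframe()
    lsm = df["lsm_kpa"].to_numpy(float)
    has_truth = np.isfinite(lsm)
    mask = has_truth.copy()
    if config.regression_subset == "indicated":
        fib4 = compute_fib4(
            df["age"].to_numpy(float),
            df["ast"].to_numpy(float),
            df["alt"].to_numpy(float),
            df["platelet_count"].to_numpy(float),
        )
        mask &= np.asarray(easl_fib4_gate(df["age"].to_numpy(float), fib4))
    if mask.sum() < len(config.covariates) + 2:
        return {"skipped": f"only {int(mask.sum())} truth-bearing records"}

    base = _factor_frame(cohort)
    extra = [c for c in config.covariates if c not in base.columns]
    X = pd.concat([base[[c for c in config.covariates if c in base.columns]],
                   df[extra].astype(float) if extra else pd.DataFrame(index=df.index)],
                  axis=1)
    # complete-case on the used covariates
    keep = mask & X.notna().all(axis=1).to_numpy()
    n_excluded = int(mask.sum() - keep.sum())
    y = (lsm[keep] >= 8.0).astype(float)
    Xk = X.loc[keep]
    if y.min() == y.max() or any(Xk[c].nunique() <= 1 for c in Xk.columns):
        return {
            "skipped": "degenerate design (single-class outcome or constant covariate)",
            "n": int(keep.sum()),
        }
    design = DesignSpec(outcome=y, covariates=Xk)
    fit = fit_logistic_irls(design)
    section: dict = {
        "n": int(keep.sum()),
        "n_excluded_missing": n_excluded,
        "subset": config.regression_subset,
        "converged": fit.converged,
        "n_iterations": fit.n_iterations,
        "log_likelihood": fit.log_likelihood,
    }
    if fit.converged:
        uni = univariate_screen(design)
        section["table"] = [
            {
                "covariate": name,
                "univariate_p": round_half_up(float(uni.loc[name, "p_value"]), 4),
                "odds_ratio": round_half_up(float(fit.odds_ratios[name]), 2),
                "ci_low": round_half_up(float(fit.ci.loc[name, "ci_low"]), 2),
                "ci_high": round_half_up(float(fit.ci.loc[name, "ci_high"]), 2),
                "p_value": round_half_up(float(fit.p_values[name]), 4),
            }
            for name in fit.odds_ratios.index
        ]
    else:
        section["diagnostic"] = fit.diagnostic
    return section


def run_pipeline(config: RunConfig) -> dict:
    """Run the whole comparison and return the report bundle as a dict.

    When ``config.out_dir`` is set, also writes ``report.json``,
    ``report.md``, ``decisions.csv`` and (for synthetic input)
    ``cohort.csv`` there. The bundle is deterministic: identical
    (config, seed) produce byte-identical JSON.
    """
    config.validate()
    cohort = _load_cohort(config)
    cohort.validate()

    bundle: dict = {
        "meta": {
            "package": "fibrotriage",
            "version": __version__,
            "cohort_label": cohort.label,
            "n_records": len(cohort),
            "seed": config.seed
            if config.seed is not None
            else (config.gen_params.seed if config.gen_params else None),
            "config_fingerprint": _config_fingerprint(config),
        }
    }

    if len(cohort) == 0:
        bundle["screening_summary"] = {"skipped": "empty cohort"}
        bundle["triage"] = {}
        bundle["evaluation"] = {"skipped": "empty cohort"}
        bundle["regression"] = {"skipped": "empty cohort"}
        _emit(bundle, cohort, {}, config)
        return bundle

    bundle["screening_summary"] = summarize_cohort(cohort)

    triages = {}
    triage_section: dict = {}
    for rule in config.rules:
        tri = triage_cohort(cohort, rule, high_risk_bypass=config.high_risk_bypass)
        triages[rule] = tri
        triage_section[rule] = {
            "n_referred": tri.n_referred,
            "n_errors": len(tri.errors),
            "errors": [f"row {i}: {msg}" for i, msg in tri.errors[:20]],
        }
    bundle["triage"] = triage_section

    n_truth = sum(1 for r in cohort if r.lsm_kpa is not None)
    if n_truth == 0:
        log.warning("no LSM truth in cohort; accuracy evaluation skipped")
        bundle["evaluation"] = {
            "skipped": "no records carry an LSM; triage counts reported only"
        }
    elif len(config.rules) >= 2:
        comp = compare_rules(
            cohort,
            config.rules[0],
            config.rules[1],
            conf_level=config.conf_level,
            high_risk_bypass=config.high_risk_bypass,
        )
        bundle["evaluation"] = {
            "n_evaluated": comp.n_evaluated,
            "confusion": {
                comp.rule_a: {"tp": comp.cm_a.tp, "fp": comp.cm_a.fp,
                              "fn": comp.cm_a.fn, "tn": comp.cm_a.tn},
                comp.rule_b: {"tp": comp.cm_b.tp, "fp": comp.cm_b.fp,
                              "fn": comp.cm_b.fn, "tn": comp.cm_b.tn},
            },
            "metrics": {
                comp.rule_a: comp.report_a.rounded(),
                comp.rule_b: comp.report_b.rounded(),
            },
            "referrals": {
                comp.rule_a: comp.n_referred_a,
                comp.rule_b: comp.n_referred_b,
            },
            "reduction_pct": round_half_up(100 * comp.reduction, 1),
            "n_discordant": len(comp.discordant_ids),
            "discordant_ids": list(comp.discordant_ids),
        }
    else:
        bundle["evaluation"] = {"skipped": "need two rules for a comparison"}

    if config.run_regression and n_truth > 0:
        bundle["regression"] = _regression_section(cohort, config)
    else:
        bundle["regression"] = {"skipped": "no truth or disabled"}

    _emit(bundle, cohort, triages, config)
    return bundle


def _decisions_frame(cohort: Cohort, triages: dict) -> pd.DataFrame:
    rows = []
    for idx, rec in enumerate(cohort):
        fib4 = compute_fib4(rec.age, rec.ast, rec.alt, rec.platelet_count)
        row = {
            "patient_id": rec.patient_id,
            "fib4": fib4,
            "lsm_kpa": rec.lsm_kpa,
        }
        for rule, tri in triages.items():
            d = tri.decisions[idx]
            row[f"{rule}_refer"] = None if d is None else int(d.refer)
            row[f"{rule}_reasons"] = None if d is None else "|".join(d.reasons)
        rows.append(row)
    return pd.DataFrame(rows)


def bundle_to_markdown(bundle: dict) -> str:
    """Human-readable report mirroring the JSON bundle's rounded values."""
    lines = [
        "# Fibrosis screening report",
        "",
        f"Cohort: {bundle['meta']['cohort_label']} "
        f"(n = {bundle['meta']['n_records']}, seed = {bundle['meta']['seed']})",
        "",
    ]
    summ = bundle.get("screening_summary", {})
    if "skipped" not in summ and summ:
        bands = summ["fib4_band_fracs"]
        lines += [
            "## Screening summary",
            "",
            "| FIB-4 band | fraction |",
            "|---|---|",
            f"| < 1.3 | {round_half_up(100 * bands['lt_1_3'], 1)}% |",
            f"| 1.3 - 2.67 | {round_half_up(100 * bands['1_3_to_2_67'], 1)}% |",
            f"| > 2.67 | {round_half_up(100 * bands['gt_2_67'], 1)}% |",
            "",
            f"EASL-indicated: {summ['easl_indicated']['total']} "
            f"(age <= 65: {summ['easl_indicated']['age_le_65']}, "
            f"age > 65: {summ['easl_indicated']['age_gt_65']}); "
            f"scanned: {summ.get('scanned_n', 0)}",
            "",
        ]
    ev = bundle.get("evaluation", {})
    if "skipped" in ev:
        lines += ["## Evaluation", "", f"Skipped: {ev['skipped']}", ""]
    else:
        lines += ["## Rule performance (scanned subset)", ""]
        for rule, cm in ev["confusion"].items():
            m = ev["metrics"][rule]
            lines += [
                f"### {rule}",
                "",
                "| | SF/ACLD | no SF | total |",
                "|---|---|---|---|",
                f"| VCTE indicated | {cm['tp']} | {cm['fp']} | {cm['tp'] + cm['fp']} |",
                f"| VCTE not indicated | {cm['fn']} | {cm['tn']} | {cm['fn'] + cm['tn']} |",
                f"| total | {cm['tp'] + cm['fn']} | {cm['fp'] + cm['tn']} "
                f"| {sum(cm.values())} |",
                "",
                f"Sensitivity {m['sensitivity_pct']}%, specificity {m['specificity_pct']}%, "
                f"PPV {m['ppv_pct']}%, NPV {m['npv_pct']}%, "
                f"LR+ {m['lr_pos']}, LR- {m['lr_neg']}.",
                "",
            ]
        lines += [
            f"Referrals: {ev['referrals']}; reduction {ev['reduction_pct']}% "
            f"({ev['n_discordant']} discordant patients).",
            "",
        ]
    reg = bundle.get("regression", {})
    if "table" in reg:
        lines += [
            f"## Factor regression (n = {reg['n']}, subset = {reg['subset']})",
            "",
            "| covariate | univariate P | OR | 95% CI | P |",
            "|---|---|---|---|---|",
        ]
        for row in reg["table"]:
            lines.append(
                f"| {row['covariate']} | {row['univariate_p']} | {row['odds_ratio']} "
                f"| {row['ci_low']}-{row['ci_high']} | {row['p_value']} |"
            )
        lines.append("")
    elif "skipped" in reg:
        lines += ["## Factor regression", "", f"Skipped: {reg['skipped']}", ""]
    return "\n".join(lines)


def _emit(bundle: dict, cohort: Cohort, triages: dict, config: RunConfig) -> None:
    if config.out_dir is None:
        return
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "report.json").write_text(
        json.dumps(bundle, indent=2, sort_keys=True, default=str) + "\n"
    )
    (out / "report.md").write_text(bundle_to_markdown(bundle))
    if triages:
        _decisions_frame(cohort, triages).to_csv(out / "decisions.csv", index=False)
    if config.gen_params is not None:
        write_cohort(cohort, str(out / "cohort.csv"))
        (out / "generator_params.json").write_text(
            json.dumps(params_to_dict(
                config.gen_params if config.seed is None
                else replace(config.gen_params, seed=config.seed)
            ), indent=2, sort_keys=True, default=str) + "\n"
        )
    log.info("report bundle written to %s", out)
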