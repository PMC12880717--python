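# Methods

This note records the models, conventions and design choices behind
`fibrotriage`, in the spirit of a statistical-software methods appendix.
It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Screening model

Patients with type 2 diabetes and steatotic liver disease are screened
in two steps: a FIB-4 score from routine labs, then VCTE for those
above an age-conditional cutoff. FIB-4 is

    FIB-4 = age[y] · AST[U/L] / (platelets[10⁹/L] · √ALT[U/L])

Units are part of the contract; the package performs no unit inference,
because silently accepting platelets in cells/µL (or ALT in µkat/L) is
the classic way FIB-4 implementations go wrong. All arguments must be
strictly positive.

### Thresholds and boundary conventions

Every threshold is inclusive on the ≥ side:

| quantity | threshold | effect |
|---|---|---|
| FIB-4, age ≤ 65 | ≥ 1.3 | gate fires |
| FIB-4, age > 65 | ≥ 2.0 | gate fires |
| FIB-4 | > 2.67 | high-risk band |
| diabetes duration | ≥ 5 y | factor satisfied |
| BMI | ≥ 25 kg/m² | factor satisfied |
| LSM | ≥ 8.0 kPa | significant fibrosis (SF) |
| LSM | ≥ 12.0 kPa | advanced chronic liver disease (ACLD) |

The age boundary is exactly 65: the 1.3 cutoff applies *at* 65, the 2.0
cutoff strictly above. LSM staging partitions (0, ∞) into
[0, 8), [8, 12), [12, ∞). The FIB-4 risk band is age-conditional in its
low/intermediate boundary (a 70-year-old with FIB-4 1.5 is low-risk)
and fixed at 2.67 for high risk.

The three-factor criterion is a pure conjunction: gate AND (duration ≥ 5
OR complications OR BMI ≥ 25). High-FIB-4 (> 2.67) patients get no
special bypass by default, since the criterion is defined without one;
`high_risk_bypass=True` restores direct referral for them where a user
wants the conservative variant. The BMI cutoff is 25 kg/m², not the
Asian overweight cutoff of 23 — the criterion was defined with 25.

### Indicated vs scanned

Referral counts are computed over every evaluable record; accuracy
metrics only over records carrying an LSM. The two denominators are
deliberately distinct: a screening programme may scan patients the gate
does not formally indicate (e.g. over-65s with FIB-4 in [1.3, 2.0)),
and those patients carry truth that the evaluation must use. The
missing-data policy is complete-case per stage: a record lacking a
field one rule needs is excluded from that rule's counts and reported,
never silently referred or dropped globally.

## Diagnostic statistics

From the 2×2 of referral × SF/ACLD: sensitivity tp/(tp+fn), specificity
tn/(tn+fp), PPV tp/(tp+fp), NPV tn/(tn+fn), LR+ = sens/(1−spec),
LR− = (1−sens)/spec. Zero-denominator ratios are flagged as undefined,
never imputed. Because the three-factor rule's referrals are nested in
the gate's, on any common cohort sensitivity can only fall and
specificity only rise, and the truth margins (tp+fn, fp+tn) are
rule-invariant — both facts are asserted as invariants in the tests.

Intervals are Wilson score intervals (default 95 %), chosen over Wald
for small-sample and boundary behaviour; the bounds are pinned to
exactly 0 and 1 at k = 0 and k = n where the formula is exact but
floating point is not. Printed percentages round half-up to one
decimal and likelihood ratios to two, the usual clinical-table
convention (Python's banker's rounding would print 0.125 as 0.12).

AUC is the midrank Mann–Whitney statistic; for a single binary rule it
reduces exactly to (sensitivity + specificity)/2. Note that published
AUCs for binary referral rules sometimes exceed this identity, which
implies they were computed on an underlying continuous score; both
variants (`empirical_auc` on scores, `auc_from_confusion` on a rule)
are exposed so the distinction is explicit.

## Logistic regression

The factor-identification stage fits an unpenalised Bernoulli GLM with
logit link by Newton–Raphson (equivalently IRLS). Choices:

- **Initialisation** at zero coefficients with the intercept at the
  logit of outcome prevalence.
- **Step-halving** whenever a Newton step would decrease the
  log-likelihood, so the likelihood path is monotone.
- **Convergence** requires both relative log-likelihood change < 1e-8
  and max |score| < 1e-6, within 100 iterations. The converged flag is
  honest: inference (`wald_inference`, `summary`) refuses non-converged
  fits.
- **Separation** is reported, not penalised: small clinical samples
  with a strong binary predictor produce near-sparse cells, a huge
  odds ratio and a very wide (possibly infinite) Wald interval, and
  the package presents exactly that rather than applying a Firth-type
  correction the analysis did not use. A singular information matrix
  raises an error naming the collinear columns.

Wald inference: OR = exp(b), CI = exp(b ± z·se), p from b/se against
the standard normal. For one binary covariate the MLE equals the 2×2
cross-product odds ratio and the Wald CI equals Woolf's interval —
both used as closed-form test oracles, alongside coefficient-level
agreement (≤ 1e-6) with an independent maximum-likelihood
implementation.

The univariate screen mirrors standard practice: fourfold tables get an
uncorrected chi-square test, switching to Fisher's exact test when any
expected cell is below 5; continuous covariates get Student's t-test
when both outcome groups pass Shapiro–Wilk at α = 0.05, otherwise the
Mann–Whitney U-test.

## Synthetic cohort generator

The generator emulates a diabetic-MASLD screening population well
enough to exercise and calibrate every pipeline stage. Per patient:

1. **Demographics/comorbidities** from independent marginals: age
   normal (53.6, 11.4²) truncated to [18, 95]; sex Bernoulli(0.515);
   BMI by category probabilities (0.008, 0.353, 0.424, 0.215) then
   uniform within (16–18.5, 18.5–25, 25–30, 30–40); diabetes duration
   log-normal with median 5 y and σ chosen so the theoretical quartile
   ratio matches the target IQR 2–10 y (quartile matching on the log
   scale); vascular complications Bernoulli(0.179); remaining flags at
   their stated prevalences. Hypothyroidism, risk-diet and sedentary
   flags lack population marginals, so their defaults (0.125, 0.4375,
   0.656) are taken from the factor-analysis subgroup — they are inert
   except as optional regression covariates. Waist circumference is an
   inert marginal by sex.
2. **FIB-4** band from (0.647, 0.309, 0.044), score uniform within
   (0.35–1.3, 1.3–2.67, 2.67–6.5); ALT ~ U(10, 200), platelets
   ~ U(100, 450), AST solved from the FIB-4 identity and required in
   [10, 300] (resampling ALT/platelets on failure, erroring after
   bounded attempts). Recorded labs therefore reproduce the sampled
   score exactly.
3. **Fibrosis truth** for scanned patients (FIB-4 ≥ 1.3, or everyone
   under the registry-style preset): SF/ACLD ~ Bernoulli(expit(b₀ +
   ln 3.8·[dur ≥ 5] + ln 19.4·[compl] + ln 6.2·[BMI ≥ 25])), with b₀
   solved by bisection so the expected scanned prevalence is 0.628
   (factors are independent of band and age, so the expectation is an
   eight-cell sum). Positives become ACLD with probability 31/76.
4. **LSM** from stage-conditional truncated log-normals — no-SF:
   median 6.3 on (2, 8); SF: 9.5 on [8, 12); ACLD: 14.5 on [12, 50) —
   so staging recovers the latent stage by construction.

Determinism: one `numpy` Generator seeded from `params.seed` drives
everything; identical parameters give identical cohorts.

**What the generator does not model.** Factors, FIB-4 band and age are
mutually independent, which real cohorts violate (FIB-4 contains age;
long-duration diabetes brings complications). The scanned-subset LSM
distribution is a three-component mixture whose median sits slightly
above 8 kPa whenever SF prevalence exceeds 50 % — a published
scanned-cohort median below 8 alongside a > 60 % SF fraction is
arithmetically impossible, so the generator matches the stage
fractions, not the printed median, and its LSM median/IQR are
approximate. Passing tests therefore demonstrate correctness of the
pipeline's logic and calibration of the stated marginals, not fidelity
to any real population's joint distribution.

An `external_validation_params()` preset reshapes the generator to a
VCTE-registry population (n = 372, everyone scanned, prevalence
269/372, mean age 59, 41.9 % male) for exercising rule comparison at
that scale; its accuracy outputs are illustrative only.

## Evaluation fixture

`table4_fixture()` is a deterministic 121-patient scanned cohort whose
five joint cells across the two nested rules are forced by
construction: 62 / 5 / 21 / 8 referred-side records (both rules / gate
only, by truth) and 25 referred by neither (9 positive, 16 negative),
realised as over-65s with FIB-4 1.5 — scanned, but below both rules'
thresholds. It pins the exact arithmetic of confusion matrices,
metrics, likelihood ratios and the 13.5 % referral reduction, and
doubles as a schema example. One derived quantity worth noting: the
gate rule's LR+ from these cells is (67/76)/(29/45) = 1.37 — a
published value of 1.38 for the same cells is not reproducible from
them and is treated as a printing inconsistency, not a target.

## Problem sizes and statistical checks

The package's own validation uses: 1000 random small cohorts (n
60–260) for the nesting invariants; 50 random datasets (n = 200, 3–6
covariates) for solver-oracle equivalence; 200 replicates of n = 2000
for odds-ratio recovery — geometric-mean recovered ORs within 10 % of
the generating values (the geometric mean is the natural estimator on
the log-odds scale where the model is linear; the arithmetic mean of
ORs is upward-biased by Jensen's inequality, markedly so for the
OR-19.4 factor whose log-OR sampling variance is largest) — and Wald
coverage assessed on the 600 pooled intervals against [0.92, 0.98]
(per-factor coverage at 200 replicates carries ~1.5 % binomial noise);
and one n = 20 000 cohort for marginal calibration within ±0.02.

## Known limitations

- The generator's independence assumptions above; its FIB-4-band ↔
  fibrosis association runs only through the calibrated prevalence.
- Wald p-values and intervals are asymptotic; with sparse cells the
  reported intervals are wide and the point estimates finite-sample
  biased (visible as a few-percent upward drift in the recovered
  largest odds ratio).
- Only FIB-4 is implemented as the first-step score (no NFS, APRI or
  ELF), and only the binary SF/ACLD-vs-no-SF evaluation is offered;
  three-class staging metrics are out of scope.
- Cohort I/O is a single CSV dialect; device exports and EHR formats
  are deliberately unsupported.
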