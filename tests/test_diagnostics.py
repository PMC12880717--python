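"""Confusion matrices, accuracy metrics, intervals and AUC."""

import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from statsmodels.stats.proportion import proportion_confint

from fibrotriage import (
    ConfusionMatrix,
    FibrosisStage,
    auc_from_confusion,
    compare_rules,
    confusion,
    default_params,
    diagnostic_metrics,
    empirical_auc,
    generate_cohort,
    referral_reduction,
    wilson_interval,
)

EASL_CM = ConfusionMatrix(tp=67, fp=29, fn=9, tn=16)
NEW_CM = ConfusionMatrix(tp=62, fp=21, fn=14, tn=24)


def brute_force_auc(scores, truth):
    """Count concordant positive-negative pairs, ties at half weight."""
    pos = [s for s, t in zip(scores, truth) if t]
    neg = [s for s, t in zip(scores, truth) if not t]
    total = 0.0
    for p, q in itertools.product(pos, neg):
        total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


class TestConfusion:
    def test_fixture_rules_hit_expected_cells(self, fixture_cohort):
        comp = compare_rules(fixture_cohort)
        assert comp.cm_a == EASL_CM
        assert comp.cm_b == NEW_CM

    def test_all_refer_rule_empties_bottom_row(self):
        truth = [True, False, True, False, False]
        cm = confusion([True] * 5, truth)
        assert cm.fn == 0 and cm.tn == 0
        assert cm.tp == 2 and cm.fp == 3

    def test_stage_truth_pools_sf_and_acld(self):
        truth = [FibrosisStage.SF, FibrosisStage.ACLD, FibrosisStage.NO_SF]
        cm = confusion([True, True, True], truth)
        assert (cm.tp, cm.fp) == (2, 1)

    def test_length_mismatch_and_empty_rejected(self):
        with pytest.raises(ValueError, match="length"):
            confusion([True], [True, False])
        with pytest.raises(ValueError):
            confusion([], [])


class TestMetrics:
    def test_gate_rule_metrics_three_decimals(self):
        r = diagnostic_metrics(EASL_CM)
        assert r.sensitivity == pytest.approx(0.882, abs=5e-4)
        assert r.specificity == pytest.approx(0.356, abs=5e-4)
        assert r.ppv == pytest.approx(0.698, abs=5e-4)
        assert r.npv == pytest.approx(0.640, abs=5e-4)

    def test_new_criterion_likelihood_ratios_two_decimals(self):
        r = diagnostic_metrics(NEW_CM)
        assert r.lr_pos == pytest.approx(1.75, abs=5e-3)
        assert r.lr_neg == pytest.approx(0.35, abs=5e-3)
        rr = r.rounded()
        assert (rr["lr_pos"], rr["lr_neg"]) == (1.75, 0.35)

    def test_perfect_classifier(self):
        r = diagnostic_metrics(ConfusionMatrix(tp=7, fp=0, fn=0, tn=5))
        assert r.sensitivity == 1.0 and r.specificity == 1.0
        assert "lr_pos" in r.undefined  # 1 - specificity = 0

    def test_zero_specificity_flags_lr_neg(self):
        r = diagnostic_metrics(ConfusionMatrix(tp=5, fp=4, fn=1, tn=0))
        assert r.lr_neg is None and "lr_neg" in r.undefined

    def test_zero_denominator_flagged_not_fabricated(self):
        r = diagnostic_metrics(ConfusionMatrix(tp=0, fp=0, fn=3, tn=4))
        assert r.ppv is None and "ppv" in r.undefined

    @given(
        tp=st.integers(0, 50), fp=st.integers(0, 50),
        fn=st.integers(0, 50), tn=st.integers(0, 50),
    )
    def test_proportions_bounded_and_lr_consistent(self, tp, fp, fn, tn):
        cm = ConfusionMatrix(tp=tp, fp=fp, fn=fn, tn=tn)
        if cm.total == 0:
            return
        r = diagnostic_metrics(cm)
        for v in (r.sensitivity, r.specificity, r.ppv, r.npv):
            assert v is None or 0 <= v <= 1
        if r.lr_pos is not None:
            assert (r.lr_pos >= 1) == (r.sensitivity >= 1 - r.specificity)


class TestReduction:
    @pytest.mark.parametrize(
        "base, new, expected",
        [(96, 83, 0.135), (233, 197, 0.155), (17, 17, 0.0)],
    )
    def test_values(self, base, new, expected):
        assert referral_reduction(base, new) == pytest.approx(expected, abs=5e-4)

    def test_contract_violations(self):
        with pytest.raises(ValueError):
            referral_reduction(0, 0)
        with pytest.raises(ValueError):
            referral_reduction(5, 6)


class TestWilson:
    def test_zero_successes_lower_bound_zero(self):
        lo, hi = wilson_interval(0, 10)
        assert lo == 0.0 and 0 < hi < 1

    def test_symmetric_about_half(self):
        lo, hi = wilson_interval(5, 10)
        assert lo + hi == pytest.approx(1.0)

    @pytest.mark.parametrize("k, n", [(62, 76), (16, 45), (1, 30), (29, 29)])
    def test_matches_reference_implementation(self, k, n):
        lo, hi = wilson_interval(k, n)
        ref_lo, ref_hi = proportion_confint(k, n, alpha=0.05, method="wilson")
        assert lo == pytest.approx(ref_lo, abs=1e-10)
        assert hi == pytest.approx(ref_hi, abs=1e-10)

    @given(n=st.integers(1, 200), frac=st.floats(0, 1), conf=st.floats(0.5, 0.999))
    def test_contains_point_estimate_inside_unit_interval(self, n, frac, conf):
        k = round(frac * n)
        lo, hi = wilson_interval(k, n, conf)
        assert 0 <= lo <= k / n <= hi <= 1


class TestAuc:
    def test_perfect_separation_scores_one(self):
        assert empirical_auc([0.9, 0.8, 0.2, 0.1], [True, True, False, False]) == 1.0

    def test_constant_score_is_half(self):
        assert empirical_auc([3.0] * 6, [True, False, True, False, False, True]) == 0.5

    def test_binary_rule_equals_half_sens_plus_spec(self):
        # 62 TP, 21 FP, 14 FN, 24 TN as referral flags
        scores = [1.0] * 83 + [0.0] * 38
        truth = [True] * 62 + [False] * 21 + [True] * 14 + [False] * 24
        auc = empirical_auc(scores, truth)
        assert auc == pytest.approx((62 / 76 + 24 / 45) / 2, abs=1e-12)
        assert auc == pytest.approx(auc_from_confusion(NEW_CM), abs=1e-12)
        assert round(auc, 3) == 0.675

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            empirical_auc([0.1, 0.2], [True, True])

    @given(
        st.lists(
            st.tuples(st.integers(0, 5), st.booleans()), min_size=2, max_size=50
        ).filter(lambda xs: len({t for _, t in xs}) == 2)
    )
    def test_equals_brute_force_pairwise_count(self, pairs):
        scores = [float(s) for s, _ in pairs]
        truth = [t for _, t in pairs]
        assert empirical_auc(scores, truth) == pytest.approx(
            brute_force_auc(scores, truth), abs=1e-12
        )


class TestCompareRules:
    def test_fixture_reduction_and_discordance(self, fixture_cohort):
        comp = compare_rules(fixture_cohort)
        assert comp.n_referred_a == 96 and comp.n_referred_b == 83
        assert comp.reduction == pytest.approx(0.135, abs=5e-4)
        assert len(comp.discordant_ids) == 13

    def test_rule_against_itself_is_null_comparison(self, fixture_cohort):
        comp = compare_rules(fixture_cohort, "easl2024", "easl2024")
        assert comp.reduction == 0.0
        assert comp.discordant_ids == ()

    def test_no_truth_raises(self, fixture_cohort):
        import dataclasses

        blind = type(fixture_cohort)(
            records=[dataclasses.replace(r, lsm_kpa=None) for r in fixture_cohort],
            label="blind",
        )
        with pytest.raises(ValueError, match="LSM"):
            compare_rules(blind)

    def test_factor_association_raises_specificity_on_synthetic_cohort(self):
        cohort = generate_cohort(default_params(n=2000, seed=11))
        comp = compare_rules(cohort)
        assert comp.report_b.specificity > comp.report_a.specificity
        # truth margins are rule-invariant
        assert comp.cm_a.n_positive == comp.cm_b.n_positive
        assert comp.cm_a.n_negative == comp.cm_b.n_negative
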