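"""IRLS logistic regression, Wald inference and univariate screening."""

import itertools

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import stats

from fibrotriage import (
    DesignSpec,
    IRLSLogisticRegression,
    fit_logistic_irls,
    univariate_screen,
    wald_inference,
)
from fibrotriage.regression import SingularDesignError


def two_by_two_design(a, b, c, d):
    """Outcome/exposure vectors for a fourfold table.

    a: exposed with outcome, b: exposed without, c: unexposed with,
    d: unexposed without.
    """
    y = np.r_[np.ones(a), np.zeros(b), np.ones(c), np.zeros(d)]
    x = np.r_[np.ones(a + b), np.zeros(c + d)]
    return DesignSpec(outcome=y, covariates=pd.DataFrame({"exposed": x}))


def random_logistic_data(rng, n, p):
    X = rng.normal(size=(n, p))
    beta = rng.uniform(-1, 1, p)
    b0 = rng.uniform(-0.5, 0.5)
    prob = 1 / (1 + np.exp(-(b0 + X @ beta)))
    y = (rng.random(n) < prob).astype(float)
    return pd.DataFrame(X, columns=[f"c{i}" for i in range(p)]), y


class TestMle:
    def test_single_binary_covariate_equals_cross_product_odds_ratio(self):
        fit = fit_logistic_irls(two_by_two_design(62, 21, 14, 24))
        assert fit.converged
        assert fit.odds_ratios["exposed"] == pytest.approx(62 * 24 / (21 * 14), rel=1e-9)
        assert round(float(fit.odds_ratios["exposed"]), 2) == 5.06

    def test_balanced_table_gives_unit_odds_ratio(self):
        fit = fit_logistic_irls(two_by_two_design(10, 10, 10, 10))
        assert fit.odds_ratios["exposed"] == pytest.approx(1.0, abs=1e-9)

    def test_matches_reference_mle_on_random_data(self):
        rng = np.random.default_rng(314)
        for _ in range(5):
            X, y = random_logistic_data(rng, 200, int(rng.integers(3, 7)))
            est = IRLSLogisticRegression().fit(X, y)
            ref = sm.Logit(y, sm.add_constant(X.to_numpy())).fit(disp=0)
            ours = np.r_[est.intercept_, est.coef_]
            assert np.max(np.abs(ours - ref.params)) < 1e-6
            assert est.log_likelihood_ == pytest.approx(ref.llf, abs=1e-8)

    def test_score_equations_hold_at_optimum(self):
        rng = np.random.default_rng(9)
        X, y = random_logistic_data(rng, 300, 4)
        est = IRLSLogisticRegression().fit(X, y)
        assert est.converged_
        assert est.max_score_ < 1e-6

    def test_separation_reported_not_silent(self):
        # x perfectly separates y
        x = np.r_[np.linspace(1, 2, 20), np.linspace(3, 4, 20)]
        y = np.r_[np.zeros(20), np.ones(20)]
        est = IRLSLogisticRegression().fit(pd.DataFrame({"x": x}), y)
        assert not est.converged_
        assert est.diagnostic_
        with pytest.raises(ValueError, match="converge"):
            wald_inference(est)

    def test_collinear_covariates_named(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=60)
        y = (rng.random(60) < 0.5).astype(float)
        y[0], y[1] = 0.0, 1.0
        X = pd.DataFrame({"a": x, "b": 2 * x})
        with pytest.raises(SingularDesignError, match="a|b"):
            IRLSLogisticRegression().fit(X, y)

    def test_design_validation(self):
        with pytest.raises(ValueError, match="single class"):
            DesignSpec(outcome=np.ones(5), covariates=pd.DataFrame({"x": np.arange(5)}))
        with pytest.raises(ValueError, match="constant"):
            DesignSpec(
                outcome=np.r_[np.ones(3), np.zeros(3)],
                covariates=pd.DataFrame({"x": np.ones(6)}),
            )

    def test_predict_proba_matches_link(self):
        rng = np.random.default_rng(5)
        X, y = random_logistic_data(rng, 150, 3)
        est = IRLSLogisticRegression().fit(X, y)
        proba = est.predict_proba(X)
        eta = est.intercept_ + X.to_numpy() @ est.coef_
        assert np.allclose(proba[:, 1], 1 / (1 + np.exp(-eta)))
        assert np.allclose(proba.sum(axis=1), 1.0)


class TestWald:
    def test_zero_coefficient_gives_unit_or_and_symmetric_ci(self):
        fit = fit_logistic_irls(two_by_two_design(10, 10, 10, 10))
        inf = wald_inference(fit).ci.loc["exposed"]
        assert inf["odds_ratio"] == pytest.approx(1.0, abs=1e-9)
        assert inf["ci_low"] * inf["ci_high"] == pytest.approx(1.0, abs=1e-9)
        assert inf["p_value"] == pytest.approx(1.0, abs=1e-6)

    def test_matches_woolf_interval_for_fourfold_table(self):
        fit = fit_logistic_irls(two_by_two_design(62, 21, 14, 24))
        z = stats.norm.ppf(0.975)
        se = np.sqrt(1 / 62 + 1 / 21 + 1 / 14 + 1 / 24)
        expected = np.exp(np.log(62 * 24 / (21 * 14)) + np.array([-z * se, z * se]))
        assert fit.ci.loc["exposed", "ci_low"] == pytest.approx(expected[0], rel=1e-6)
        assert fit.ci.loc["exposed", "ci_high"] == pytest.approx(expected[1], rel=1e-6)

    def test_summary_frame_layout(self):
        rng = np.random.default_rng(1)
        X, y = random_logistic_data(rng, 200, 3)
        est = IRLSLogisticRegression().fit(X, y)
        summ = est.summary()
        assert list(summ.columns) == [
            "coef", "se", "odds_ratio", "ci_low", "ci_high", "p_value",
        ]
        assert (summ["ci_low"] <= summ["odds_ratio"]).all()
        assert (summ["odds_ratio"] <= summ["ci_high"]).all()


class TestUnivariateScreen:
    def test_independent_binary_covariate_scores_p_one(self):
        # outcome distribution identical in both covariate groups
        design = DesignSpec(
            outcome=np.r_[np.ones(10), np.zeros(10), np.ones(10), np.zeros(10)],
            covariates=pd.DataFrame({"g": np.r_[np.ones(20), np.zeros(20)]}),
        )
        out = univariate_screen(design)
        assert out.loc["g", "p_value"] == pytest.approx(1.0)

    def test_complications_fourfold_table_is_significant(self):
        # 1 exposed with outcome, 16 exposed without, 28/51 unexposed
        design = two_by_two_design(1, 16, 28, 51)
        out = univariate_screen(design)
        assert out.loc["exposed", "test"] == "chi_square"
        assert out.loc["exposed", "p_value"] < 0.05

    def test_sparse_table_uses_fisher(self):
        design = two_by_two_design(1, 2, 20, 30)
        out = univariate_screen(design)
        assert out.loc["exposed", "test"] == "fisher_exact"

    def test_fisher_agrees_with_permutation_enumeration(self):
        # tiny two-group binary data: enumerate every reassignment of the
        # exposure labels and count tables at least as extreme
        y = np.array([1, 1, 1, 0, 0, 0, 0, 1, 0, 1], dtype=float)
        x = np.array([1, 1, 0, 0, 0, 1, 0, 0, 1, 0], dtype=float)
        n_exposed = int(x.sum())

        def table_stat(mask):
            a = int(y[list(mask)].sum())
            return a

        observed = stats.fisher_exact(
            [[int(y[x == 1].sum()), int((1 - y)[x == 1].sum())],
             [int(y[x == 0].sum()), int((1 - y)[x == 0].sum())]]
        )[1]
        # permutation null: hypergeometric count of exposed successes
        idx = range(len(y))
        stats_seen = {}
        for combo in itertools.combinations(idx, n_exposed):
            stats_seen.setdefault(table_stat(combo), 0)
            stats_seen[table_stat(combo)] += 1
        total = sum(stats_seen.values())
        probs = {a: c / total for a, c in stats_seen.items()}
        obs_a = int(y[x == 1].sum())
        p_perm = sum(p for a, p in probs.items() if probs[a] <= probs[obs_a] + 1e-12)
        assert observed == pytest.approx(p_perm, abs=1e-9)

    def test_continuous_covariate_routes_by_normality(self):
        rng = np.random.default_rng(8)
        y = np.r_[np.ones(60), np.zeros(60)]
        normal = rng.normal(size=120) + 0.5 * y
        skewed = rng.lognormal(sigma=1.2, size=120) * (1 + y)
        design = DesignSpec(
            outcome=y, covariates=pd.DataFrame({"n": normal, "s": skewed})
        )
        out = univariate_screen(design)
        assert out.loc["n", "test"] == "t_test"
        assert out.loc["s", "test"] == "mann_whitney"
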