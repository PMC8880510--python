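"""Survival-statistics engine: oracle equivalence and calibration."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from oracles import (
    grid_search_cox_1d,
    logrank_statistic,
    permutation_logrank_p,
    permutation_logrank_p_fast,
    stepup_bh,
)
from radenrich.stats import (
    ConvergenceError,
    bh_adjust,
    chisq_independence,
    cox_fit,
    cox_lrt_p,
    km_estimate,
    logrank,
    pearson,
    ph_check,
    wilcoxon_ranksum,
)


class TestCoxFit:
    def test_matches_partial_likelihood_grid_search_on_tiny_instances(self):
        """Newton-Raphson optimum equals a 1-D grid/golden-section
        maximiser of the hand-written partial likelihood."""
        worst = 0.0
        checked = 0
        for seed in range(40):
            rng = np.random.default_rng(seed)
            n = 6
            x = rng.normal(size=n)
            time = rng.permutation(np.arange(1.0, n + 1))  # no ties
            event = rng.uniform(size=n) < 0.8
            if event.sum() < 2:
                continue
            try:
                fit = cox_fit(x, time, event)
            except ConvergenceError:
                continue  # separation: both methods diverge
            beta_oracle = grid_search_cox_1d(x, time, event)
            worst = max(worst, abs(fit.beta[0] - beta_oracle))
            checked += 1
        assert checked >= 20
        assert worst < 1e-4

    def test_null_coefficient_near_zero(self, survival_sample):
        X, t, e = survival_sample(seed=3, n=2000, beta=0.0)
        fit = cox_fit(X[:, 0], t, e)
        assert abs(fit.beta[0]) < 0.07

    def test_planted_effect_recovered(self, survival_sample):
        X, t, e = survival_sample(seed=4, n=2000, beta=0.5)
        fit = cox_fit(X[:, 0], t, e)
        assert abs(fit.beta[0] - 0.5) < 0.1

    def test_agrees_with_lifelines_with_ties(self, survival_sample):
        from lifelines import CoxPHFitter

        X, t, e = survival_sample(seed=7, n=150, beta=0.4, p_cov=3)
        t = np.round(t)  # force ties
        t[t == 0] = 0.5
        fit = cox_fit(X, t, e, ties="efron")
        df = pd.DataFrame(X, columns=["a", "b", "c"])
        df["t"], df["e"] = t, e
        ll = CoxPHFitter().fit(df, "t", "e")
        np.testing.assert_allclose(fit.beta, ll.params_.values, atol=1e-5)
        np.testing.assert_allclose(fit.se, ll.standard_errors_.values, atol=1e-5)
        assert abs(fit.loglik - ll.log_likelihood_) < 1e-6

    def test_matches_r_survival_reference(self):
        """Frozen reference fit from R survival::coxph (Efron ties) on a
        reproducible simulated dataset."""
        rng = np.random.default_rng(7)
        n = 120
        X = rng.normal(size=(n, 3))
        eta = 0.5 * X[:, 0] - 0.3 * X[:, 1]
        T = (-np.log(rng.uniform(size=n)) * np.exp(-eta)) ** (1 / 1.2) * 24
        C = rng.uniform(10, 40, n)
        time = np.round(np.minimum(T, C), 0) + 0.5
        event = (T <= C).astype(int)
        fit = cox_fit(X, time, event)
        np.testing.assert_allclose(
            fit.beta, [0.6724055, -0.3643880, -0.1761292], atol=1e-6
        )
        np.testing.assert_allclose(
            fit.se, [0.1304739, 0.1319336, 0.1542069], atol=1e-6
        )
        assert abs(fit.loglik - (-293.3468672646)) < 1e-6

    def test_hazard_ratio_ci_convention(self, survival_sample):
        X, t, e = survival_sample(seed=9, n=200, beta=0.5)
        fit = cox_fit(X[:, 0], t, e)
        assert fit.hr[0] == pytest.approx(np.exp(fit.beta[0]))
        assert fit.ci_low[0] == pytest.approx(np.exp(fit.beta[0] - 1.96 * fit.se[0]), rel=1e-3)
        assert fit.ci_low[0] > 0

    def test_input_validation(self, survival_sample):
        X, t, e = survival_sample(seed=1, n=30)
        with pytest.raises(ValueError):
            cox_fit(np.ones(30), t, e)  # constant covariate
        with pytest.raises(ValueError):
            cox_fit(X[:, 0], t, np.zeros(30))  # no events
        with pytest.raises(ValueError):
            cox_fit(X[:, 0], t, e, ties="exact")

    def test_separation_flagged(self):
        # perfectly separated risk: the likelihood is monotone in beta
        time = np.arange(1.0, 11)
        event = np.ones(10)
        x = np.arange(10.0)  # later death <=> larger x, monotone
        with pytest.raises(ConvergenceError):
            cox_fit(-x, time, event)

    def test_lrt_for_multilevel_covariate(self, survival_sample):
        X, t, e = survival_sample(seed=12, n=300, beta=0.6, p_cov=2)
        fit = cox_fit(X, t, e)
        p = cox_lrt_p(fit, X, t, e)
        assert 0 <= p < 0.05


class TestLogrank:
    def test_identical_groups_give_null_result(self):
        t = np.array([1.0, 2, 3, 4, 5] * 2)
        e = np.array([1, 0, 1, 1, 0] * 2)
        g = np.array([0] * 5 + [1] * 5)
        chi2, p = logrank(t, e, g)
        assert chi2 == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_strong_separation_significant(self):
        t = np.concatenate([np.linspace(1, 5, 20), np.linspace(30, 60, 20)])
        e = np.ones(40)
        g = np.array([0] * 20 + [1] * 20)
        _, p = logrank(t, e, g)
        assert p < 0.001

    def test_agrees_with_lifelines(self, survival_sample):
        from lifelines.statistics import logrank_test

        X, t, e = survival_sample(seed=5, n=80)
        g = X[:, 0] > 0
        chi2, p = logrank(t, e, g)
        ref = logrank_test(t[g], t[~g], e[g], e[~g])
        assert chi2 == pytest.approx(ref.test_statistic, rel=1e-10)
        assert p == pytest.approx(ref.p_value, rel=1e-10)

    def test_permutation_oracles_are_consistent(self):
        rng = np.random.default_rng(0)
        t = rng.exponential(10, 16).round(1) + 0.1
        e = rng.uniform(size=16) < 0.7
        g = rng.uniform(size=16) < 0.5
        slow = permutation_logrank_p(t, e, g, n_perm=3000, seed=1)
        fast = permutation_logrank_p_fast(t, e, g, n_perm=3000, seed=1)
        assert abs(slow - fast) < 3 * np.sqrt(slow * (1 - slow) / 3000) + 1e-6

    def test_requires_two_groups(self):
        with pytest.raises(ValueError):
            logrank([1.0, 2.0], [1, 1], [0, 0])


class TestKaplanMeier:
    def test_uncensored_grid_median(self):
        """Hand product-limit table: with deaths at 1..10 and no
        censoring, S(5) = 0.5 so the median is 5."""
        km = km_estimate(np.arange(1.0, 11), np.ones(10))
        assert km.median == pytest.approx(5.0)
        assert km.survival[0] <= 1.0
        assert np.all(np.diff(km.survival) <= 1e-12)

    def test_hand_computed_survival_steps(self):
        # deaths at 2 and 5, censored at 3: S = 3/4 then 3/4 * 1/2
        km = km_estimate([2.0, 3.0, 5.0, 7.0], [1, 0, 1, 0])
        s = dict(zip(km.times, km.survival))
        assert s[2.0] == pytest.approx(0.75)
        assert s[5.0] == pytest.approx(0.375)

    def test_all_censored_median_not_estimable(self):
        km = km_estimate([3.0, 4.0, 9.0], [0, 0, 0])
        assert not np.isfinite(km.median)
        assert km.median_str().startswith("N.E")

    def test_ne_rendering_of_unbounded_ci(self):
        rng = np.random.default_rng(2)
        t = rng.exponential(30, 25)
        e = (rng.uniform(size=25) < 0.3).astype(int)
        km = km_estimate(t, e)
        assert "(" in km.median_str() and "–" in km.median_str()


class TestBenjaminiHochberg:
    def test_hand_step_up_example(self):
        adj = bh_adjust([0.01, 0.02, 0.03, 0.04])
        np.testing.assert_allclose(adj, [0.04, 0.04, 0.04, 0.04])

    def test_single_and_equal_pvalues(self):
        assert bh_adjust([0.37])[0] == pytest.approx(0.37)
        np.testing.assert_allclose(bh_adjust([0.2, 0.2, 0.2]), [0.2, 0.2, 0.2])

    def test_matches_independent_stepup_on_random_vectors(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            p = rng.uniform(size=rng.integers(1, 40))
            np.testing.assert_allclose(bh_adjust(p), stepup_bh(p), atol=1e-12)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


class TestPHCheck:
    def test_residuals_sum_to_zero(self, survival_sample):
        X, t, e = survival_sample(seed=21, n=200, beta=0.5, p_cov=2)
        fit = cox_fit(X, t, e)
        ph = ph_check(fit, t, e, X)
        assert np.allclose(ph["residual_sums"], 0.0, atol=1e-8)
        assert len(ph["p"]) == 2 and 0 <= ph["global_p"] <= 1

    def test_null_calibration(self, survival_sample):
        rejections = 0
        n_sims = 100
        for s in range(n_sims):
            X, t, e = survival_sample(seed=1000 + s, n=150, beta=0.4, p_cov=2)
            fit = cox_fit(X, t, e)
            if ph_check(fit, t, e, X)["global_p"] < 0.05 :
                rejections += 1
        assert rejections / n_sims < 0.12  # ~alpha with MC slack

    def test_detects_time_varying_effect(self):
        detected = 0
        n_sims = 25
        for s in range(n_sims):
            rng = np.random.default_rng(300 + s)
            n = 500
            x = rng.normal(size=n)
            lam, b, t0 = 1 / 20, 0.8, 12.0
            cum0 = lam * np.exp(b * x) * t0
            ex = -np.log(rng.uniform(size=n))
            T = np.where(
                ex < cum0,
                ex / (lam * np.exp(b * x)),
                t0 + (ex - cum0) / (lam * np.exp(-b * x)),
            )
            C = rng.uniform(20, 45, n)
            t, e = np.minimum(T, C), (T <= C).astype(int)
            fit = cox_fit(x, t, e)
            if ph_check(fit, t, e, x[:, None])["global_p"] < 0.05:
                detected += 1
        assert detected / n_sims > 0.8


class TestCohortTests:
    def test_smoking_table_reproduces_published_p(self):
        # 2x2 with Yates correction: rounds to 0.91
        p = chisq_independence([[59, 55], [46, 46]])
        assert round(p, 2) == 0.91

    def test_yates_floors_balanced_table_to_p_one(self):
        p = chisq_independence([[59, 57], [46, 44]])
        assert p == pytest.approx(1.0)

    def test_larger_tables_uncorrected(self):
        table = [[10, 20, 30], [15, 15, 30]]
        p = chisq_independence(table)
        chi2, p_ref, _, _ = sps.chi2_contingency(np.array(table), correction=False)
        assert p == pytest.approx(p_ref)

    def test_zero_marginal_rejected(self):
        with pytest.raises(ValueError):
            chisq_independence([[0, 0], [5, 6]])

    def test_wilcoxon_identical_samples(self):
        assert wilcoxon_ranksum([1.0, 2, 3, 4], [1.0, 2, 3, 4]) == pytest.approx(1.0)

    def test_pearson_roundtrip(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=50)
        r, p = pearson(x, x + rng.normal(scale=0.1, size=50))
        assert r > 0.9 and p < 1e-6
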