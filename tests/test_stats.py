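"""Self-implemented statistical core against closed forms, grid-search
oracles and the reference library implementations."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats as sps
import statsmodels.api as sm
from sklearn.metrics import roc_auc_score
from statsmodels.discrete.conditional_models import ConditionalLogit
from statsmodels.stats.multitest import multipletests

from organotrope.stats import (
    bh_adjust,
    fit_conditional_logistic,
    fit_logistic,
    mann_whitney_u,
    pearson_chi_square,
    quartile_or_analysis,
    roc_auc,
    wald_or_ci,
    wilcoxon_signed_rank,
)


# ---------------------------------------------------------------------------
# unconditional logistic
# ---------------------------------------------------------------------------

class TestLogistic:
    def test_two_by_two_closed_form(self, rng):
        for _ in range(20):
            a, b, c, d = rng.integers(3, 40, size=4)
            x = np.r_[np.ones(a), np.zeros(b), np.ones(c), np.zeros(d)]
            y = np.r_[np.ones(a + b), np.zeros(c + d)]
            fit = fit_logistic(x[:, None], y)
            assert fit.converged
            assert fit.beta[1] == pytest.approx(np.log(a * d / (b * c)), abs=1e-6)

    def test_null_covariate_estimate_near_zero(self, rng):
        n = 10_000
        x = rng.standard_normal(n)
        y = (rng.random(n) < 0.3).astype(float)
        fit = fit_logistic(x[:, None], y)
        assert abs(fit.beta[1]) <= 3 * fit.se[1]

    def test_grid_search_oracle(self, rng):
        """MLE agrees with a brute-force likelihood grid search to 1e-4."""
        for _ in range(10):
            n = 40
            x = rng.standard_normal(n)
            p = 1 / (1 + np.exp(-(0.3 + 0.8 * x)))
            y = (rng.random(n) < p).astype(float)
            if y.min() == y.max():
                continue
            fit = fit_logistic(x[:, None], y)

            def nll(b0, b1):
                eta = b0 + b1 * x
                return -(y * eta - np.logaddexp(0, eta)).sum()

            b0g = np.linspace(fit.beta[0] - 0.01, fit.beta[0] + 0.01, 81)
            b1g = np.linspace(fit.beta[1] - 0.01, fit.beta[1] + 0.01, 81)
            grid = np.array([[nll(b0, b1) for b1 in b1g] for b0 in b0g])
            i, j = np.unravel_index(grid.argmin(), grid.shape)
            assert abs(b0g[i] - fit.beta[0]) <= 2.6e-4
            assert abs(b1g[j] - fit.beta[1]) <= 2.6e-4

    def test_matches_statsmodels(self, rng):
        n = 300
        X = rng.standard_normal((n, 2))
        p = 1 / (1 + np.exp(-(-0.5 + X @ [0.7, -0.4])))
        y = (rng.random(n) < p).astype(float)
        fit = fit_logistic(X, y)
        ref = sm.Logit(y, sm.add_constant(X)).fit(disp=0)
        assert np.allclose(fit.beta, ref.params, atol=1e-6)
        assert np.allclose(fit.se, ref.bse, atol=1e-5)
        assert fit.loglik == pytest.approx(ref.llf, abs=1e-6)

    def test_separation_flagged(self):
        x = np.r_[np.full(20, 2.0), np.full(20, -2.0)]
        y = np.r_[np.ones(20), np.zeros(20)]
        fit = fit_logistic(x[:, None], y)
        assert fit.separation and not fit.converged

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            fit_logistic(np.arange(5.0)[:, None], np.ones(5))


# ---------------------------------------------------------------------------
# conditional logistic
# ---------------------------------------------------------------------------

def _pairs_design(x_case, x_ctrl):
    n = len(x_case)
    x = np.r_[x_case, x_ctrl][:, None]
    y = np.r_[np.ones(n), np.zeros(n)]
    strata = np.r_[np.arange(n), np.arange(n)]
    return x, y, strata


class TestConditionalLogistic:
    def test_discordant_pair_closed_form(self):
        # binary exposure 1:1 pairs: OR = n10/n01 = 10/5 = 2
        x_case = np.r_[np.ones(10), np.zeros(5), np.ones(7), np.zeros(8)]
        x_ctrl = np.r_[np.zeros(10), np.ones(5), np.ones(7), np.zeros(8)]
        fit = fit_conditional_logistic(*_pairs_design(x_case, x_ctrl))
        assert np.exp(fit.beta[0]) == pytest.approx(2.0, abs=1e-8)
        assert fit.n_strata_informative == 15  # concordant pairs carry nothing

    def test_concordant_only_rejected(self):
        x_case = np.ones(6)
        x_ctrl = np.ones(6)
        with pytest.raises(ValueError, match="uninformative"):
            fit_conditional_logistic(*_pairs_design(x_case, x_ctrl))

    def test_stratum_without_single_case_rejected(self):
        x = np.arange(4.0)[:, None]
        with pytest.raises(ValueError):
            fit_conditional_logistic(x, [1, 1, 0, 0], [0, 0, 1, 1])

    def test_one_to_three_grid_oracle(self, rng):
        """Newton solution matches a conditional-likelihood grid search."""
        for _ in range(10):
            n_sets = 25
            x = rng.standard_normal((n_sets, 4))
            beta_true = 0.7
            w = np.exp(beta_true * x)
            case_pos = np.array(
                [rng.choice(4, p=wi / wi.sum()) for wi in w]
            )
            X, y, strata = [], [], []
            for s in range(n_sets):
                for j in range(4):
                    X.append(x[s, j])
                    y.append(1.0 if j == case_pos[s] else 0.0)
                    strata.append(s)
            X = np.array(X)[:, None]
            fit = fit_conditional_logistic(X, y, strata)

            def cll(b):
                tot = 0.0
                for s in range(n_sets):
                    eta = b * x[s]
                    tot += eta[case_pos[s]] - np.log(np.exp(eta).sum())
                return tot

            grid = np.linspace(fit.beta[0] - 0.01, fit.beta[0] + 0.01, 201)
            best = grid[np.argmax([cll(b) for b in grid])]
            assert abs(best - fit.beta[0]) <= 1e-4

    def test_paired_difference_equivalence(self, rng):
        """1:1 conditional fit equals intercept-free logistic on differences."""
        n = 60
        x_case = rng.standard_normal(n) + 0.4
        x_ctrl = rng.standard_normal(n)
        fit_c = fit_conditional_logistic(*_pairs_design(x_case, x_ctrl))
        d = (x_case - x_ctrl)[:, None]
        fit_d = fit_logistic(d, np.ones(n), add_intercept=False)
        assert abs(fit_c.beta[0] - fit_d.beta[0]) <= 1e-10
        assert fit_c.se[0] == pytest.approx(fit_d.se[0], abs=1e-8)

    def test_matches_statsmodels_conditional(self, rng):
        n = 80
        x_case = rng.standard_normal(n) + 0.5
        x_ctrl = rng.standard_normal(n)
        X, y, strata = _pairs_design(x_case, x_ctrl)
        fit = fit_conditional_logistic(X, y, strata)
        ref = ConditionalLogit(y, X, groups=strata).fit(method="newton", disp=0)
        assert fit.beta[0] == pytest.approx(ref.params[0], abs=1e-6)
        assert fit.se[0] == pytest.approx(ref.bse[0], abs=1e-5)


class TestWaldCI:
    def test_unit_se_interval(self):
        from organotrope.stats import FitResult
        fit = FitResult(["x"], np.array([0.0]), np.array([1.0]), 0.0, 1, True)
        tab = wald_or_ci(fit)
        assert tab.loc["x", "OR"] == pytest.approx(1.0)
        assert tab.loc["x", "CI_low"] == pytest.approx(np.exp(-1.959964), abs=1e-3)
        assert tab.loc["x", "CI_high"] == pytest.approx(np.exp(1.959964), abs=1e-2)

    def test_quantile_oracle_level(self, rng):
        from organotrope.stats import FitResult
        beta, se = 0.8, 0.3
        fit = FitResult(["x"], np.array([beta]), np.array([se]), 0.0, 1, True)
        for level in (0.9, 0.95, 0.99):
            tab = wald_or_ci(fit, level=level)
            z = sps.norm.ppf(0.5 + level / 2)
            assert tab.loc["x", "CI_low"] == pytest.approx(np.exp(beta - z * se))
            assert tab.loc["x", "CI_high"] == pytest.approx(np.exp(beta + z * se))

    def test_degenerate_se_collapses(self):
        from organotrope.stats import FitResult
        fit = FitResult(["x"], np.array([0.5]), np.array([0.0]), 0.0, 1, True)
        tab = wald_or_ci(fit)
        assert tab.loc["x", "CI_low"] == tab.loc["x", "CI_high"] == tab.loc["x", "OR"]


# ---------------------------------------------------------------------------
# contingency and rank tests
# ---------------------------------------------------------------------------

class TestChiSquare:
    def test_identical_columns_zero(self):
        t = np.tile([[10], [20], [5]], (1, 3))
        assert pearson_chi_square(t).statistic == pytest.approx(0.0)

    def test_formula_and_scipy_oracle(self, rng):
        for _ in range(50):
            t = rng.integers(1, 50, size=(rng.integers(2, 5), rng.integers(2, 5)))
            res = pearson_chi_square(t)
            n = t.sum()
            e = np.outer(t.sum(1), t.sum(0)) / n
            assert res.statistic == pytest.approx(((t - e) ** 2 / e).sum(), abs=1e-10)
            chi2, p, df, _ = sps.chi2_contingency(t, correction=False)
            assert res.statistic == pytest.approx(chi2, abs=1e-10)
            assert res.p_value == pytest.approx(p, abs=1e-12)
            assert res.df == df

    def test_empty_row_dropped(self):
        t = np.array([[5, 10], [0, 0], [8, 2]])
        res = pearson_chi_square(t)
        assert res.df == 1


class TestMannWhitney:
    def test_complete_separation_exact_p(self):
        res = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(0.1)  # 2/20 arrangements
        assert "exact" in res.method

    def test_identical_samples_u_half(self, rng):
        x = rng.standard_normal(8)
        res = mann_whitney_u(x, x)
        assert res.statistic == pytest.approx(len(x) ** 2 / 2)

    def test_all_tied_degenerate(self):
        res = mann_whitney_u([5, 5, 5], [5, 5])
        assert res.degenerate and res.p_value == 1.0

    def test_exact_branch_matches_scipy(self, rng):
        for _ in range(30):
            n1, n2 = rng.integers(3, 7, size=2)
            x = rng.permutation(np.arange(1.0, n1 + n2 + 1))
            res = mann_whitney_u(x[:n1], x[n1:])
            ref = sps.mannwhitneyu(x[:n1], x[n1:], alternative="two-sided",
                                   method="exact")
            assert res.statistic == pytest.approx(ref.statistic)
            assert res.p_value == pytest.approx(ref.pvalue, abs=1e-12)

    def test_tied_approximation_against_permutation(self, rng):
        x = rng.integers(0, 6, 25).astype(float)
        y = (rng.integers(0, 6, 30) + 1.0)
        res = mann_whitney_u(x, y)
        obs = res.statistic
        pooled = np.r_[x, y]
        n1 = len(x)
        mean_u = n1 * len(y) / 2
        count = 0
        n_perm = 20_000
        for _ in range(n_perm):
            rng.shuffle(pooled)
            r = sps.rankdata(pooled)
            u = r[:n1].sum() - n1 * (n1 + 1) / 2
            if abs(u - mean_u) >= abs(obs - mean_u) - 1e-9:
                count += 1
        p_perm = count / n_perm
        assert res.p_value == pytest.approx(p_perm, abs=0.02)


class TestWilcoxon:
    def test_all_positive_n6_exact(self):
        res = wilcoxon_signed_rank([1.5, 2.5, 3.5, 4.5, 5.5, 6.5])
        assert res.statistic == 21.0
        assert res.p_value == pytest.approx(2 / 64)

    def test_antisymmetric_pair_p_one(self):
        res = wilcoxon_signed_rank([3.0, -3.0])
        assert res.p_value == 1.0

    def test_zeros_dropped_and_degenerate(self):
        assert wilcoxon_signed_rank([0.0, 0.0]).degenerate
        res = wilcoxon_signed_rank([0.0, 1.0, 2.0, -0.5])
        ref = wilcoxon_signed_rank([1.0, 2.0, -0.5])
        assert res.statistic == ref.statistic and res.p_value == ref.p_value

    def test_exact_branch_matches_scipy(self, rng):
        for _ in range(30):
            n = int(rng.integers(5, 15))
            d = rng.standard_normal(n) + 0.3
            if len(np.unique(np.abs(d))) < n:
                continue
            res = wilcoxon_signed_rank(d)
            ref = sps.wilcoxon(d, alternative="two-sided", mode="exact")
            assert res.p_value == pytest.approx(ref.pvalue, abs=1e-12)

    def test_sign_flip_permutation_oracle(self, rng):
        d = np.round(rng.standard_normal(40) + 0.2, 1)
        d = d[d != 0]
        res = wilcoxon_signed_rank(d)
        ranks = sps.rankdata(np.abs(d))
        mean_w = len(d) * (len(d) + 1) / 4
        obs = abs(res.statistic - mean_w)
        count = 0
        n_perm = 20_000
        for _ in range(n_perm):
            signs = rng.choice([0.0, 1.0], len(d))
            w = (ranks * signs).sum()
            if abs(w - mean_w) >= obs - 1e-9:
                count += 1
        assert res.p_value == pytest.approx(count / n_perm, abs=0.02)


class TestBH:
    def test_hand_worked_step_up(self):
        adj = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(adj, [0.04, 0.04, 0.04, 0.04])

    def test_trivial_cases(self):
        assert np.allclose(bh_adjust([1.0, 1.0, 1.0]), 1.0)
        assert bh_adjust([0.037]) == pytest.approx([0.037])

    def test_monotone_in_raw_order(self, rng):
        p = rng.random(200)
        adj = bh_adjust(p)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-15)

    def test_matches_statsmodels(self, rng):
        p = rng.random(500)
        ref = multipletests(p, method="fdr_bh")[1]
        assert np.allclose(bh_adjust(p), ref)


class TestRocAuc:
    def test_perfect_and_constant(self):
        _, auc = roc_auc([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1])
        assert auc == 1.0
        _, auc = roc_auc(np.ones(10), np.r_[np.ones(4), np.zeros(6)])
        assert auc == 0.5

    def test_u_auc_identity_with_ties(self, rng):
        for _ in range(100):
            n1, n2 = rng.integers(3, 30, size=2)
            pos = rng.integers(0, 6, n1).astype(float)
            neg = rng.integers(0, 6, n2).astype(float)
            _, auc = roc_auc(np.r_[pos, neg], np.r_[np.ones(n1), np.zeros(n2)])
            u = mann_whitney_u(pos, neg).statistic
            assert auc == u / (n1 * n2)  # bit-exact rank identity

    def test_matches_sklearn(self, rng):
        s = rng.standard_normal(200)
        y = (rng.random(200) < 0.4).astype(int)
        _, auc = roc_auc(s, y)
        assert auc == pytest.approx(roc_auc_score(y, s), abs=1e-12)

    def test_curve_endpoints(self, rng):
        s = rng.standard_normal(50)
        y = (rng.random(50) < 0.5).astype(int)
        curve, _ = roc_auc(s, y)
        assert curve.iloc[0][["fpr", "tpr"]].tolist() == [0.0, 0.0]
        assert curve.iloc[-1][["fpr", "tpr"]].tolist() == [1.0, 1.0]

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([1.0, 2.0], [1, 1])


class TestQuartileAnalysis:
    def test_thresholds_equal_percentile_oracle(self, rng):
        ctrl = pd.Series(rng.standard_normal(120))
        case = pd.Series(rng.standard_normal(120))
        res = quartile_or_analysis(case, ctrl)
        assert np.allclose(res.thresholds, np.percentile(ctrl, [25, 50, 75]))

    def test_null_scores_or_near_one(self, rng):
        n = 400
        ctrl = pd.Series(rng.standard_normal(n))
        case = pd.Series(rng.standard_normal(n))
        res = quartile_or_analysis(case, ctrl)
        tab = wald_or_ci(res.fit)
        assert ((tab["CI_low"] <= 1.0) & (tab["CI_high"] >= 1.0)).sum() >= 2

    def test_monotone_effect_orders_quartiles(self, rng):
        wins = 0
        reps = 30
        for _ in range(reps):
            n = 150
            ctrl = pd.Series(rng.standard_normal(n))
            case = pd.Series(rng.standard_normal(n) + 1.1)  # strong shift
            res = quartile_or_analysis(case, ctrl)
            if res.fit is not None and res.estimable.get("Q4") and res.estimable.get("Q2"):
                b = dict(zip(res.fit.names, res.fit.beta))
                wins += b["Q4"] > b["Q2"]
        assert wins >= 0.95 * reps

    def test_too_few_controls_rejected(self, rng):
        with pytest.raises(ValueError):
            quartile_or_analysis(pd.Series(np.arange(5.0)), pd.Series(np.arange(5.0)))
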