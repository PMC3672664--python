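"""Statistical layer: rank tests against enumeration oracles, Holm
step-down, regression influence, and GEE correctness."""

import itertools
import math
from dataclasses import replace

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from dosidensity import stats_analysis as sa
from dosidensity import synthetic_cohort as sc
from dosidensity.synthetic_cohort import POST, PRE


class TestMannWhitney:
    def test_identical_samples_have_p_near_one(self):
        x = [1.0, 2.0, 3.0, 4.0]
        res = sa.mann_whitney(x, x)
        assert res.p_value >= 0.99

    def test_worked_example_exact_third(self):
        res = sa.mann_whitney([1.0, 2.0], [3.0, 4.0])
        assert res.method == "exact"
        assert res.p_value == pytest.approx(1.0 / 3.0)

    @pytest.mark.parametrize("n_x,n_y", [(2, 3), (3, 5), (4, 4), (5, 6), (8, 8)])
    def test_exact_matches_scipy_enumeration_without_ties(self, n_x, n_y, rng):
        """Independent oracle: scipy's exact U distribution (tie-free)."""
        for _ in range(10):
            x = rng.normal(size=n_x)
            y = rng.normal(size=n_y)
            res = sa.mann_whitney(x, y, mode="exact")
            ref = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact")
            assert res.p_value == pytest.approx(float(ref.pvalue), abs=1e-12)
            assert res.u == pytest.approx(float(ref.statistic))

    def test_tied_data_handled_with_midranks(self):
        # pooled {1, 2, 2, 3} has midranks {1, 2.5, 2.5, 4}; the observed
        # split x={1,2} gives U = 3.5 - 3 = 0.5, i.e. deviation 1.5 from the
        # null mean 2.  Rank-subset sums over the 6 assignments are
        # {3.5, 3.5, 5, 5, 5, 6.5} -> U in {0.5, 0.5, 2, 2, 2, 3.5}, so 4 of
        # 6 are at least as extreme
        res = sa.mann_whitney([1.0, 2.0], [2.0, 3.0], mode="exact")
        assert res.p_value == pytest.approx(4.0 / 6.0)

    def test_asymptotic_branch_for_large_samples(self, rng):
        x = rng.normal(0, 1, 20)
        y = rng.normal(0.5, 1, 20)
        res = sa.mann_whitney(x, y)
        assert res.method == "asymptotic"
        assert 0.0 <= res.p_value <= 1.0

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            sa.mann_whitney([], [1.0])


class TestGroupComparisons:
    def test_anova_matches_hand_computed_table(self):
        """3 groups of 3 integers; F assembled from the textbook sums of
        squares."""
        g1, g2, g3 = [1.0, 2.0, 3.0], [2.0, 3.0, 4.0], [4.0, 5.0, 6.0]
        res = sa.anova_oneway(g1, g2, g3)
        grand = np.mean(g1 + g2 + g3)
        ssb = sum(3 * (np.mean(g) - grand) ** 2 for g in (g1, g2, g3))
        ssw = sum(sum((v - np.mean(g)) ** 2 for v in g) for g in (g1, g2, g3))
        f_hand = (ssb / 2.0) / (ssw / 6.0)
        assert res.statistic == pytest.approx(f_hand, rel=1e-12)
        assert res.df == (2, 6)

    def test_anova_degenerate_constant_groups_rejected(self):
        with pytest.raises(ValueError, match="zero within-group variance"):
            sa.anova_oneway([1.0, 1.0], [2.0, 2.0])

    def test_kruskal_statistic_matches_rank_formula(self):
        """Rank-distinct data; H recomputed from the rank-sum formula."""
        g1, g2, g3 = [1.0, 7.0], [2.0, 5.0], [3.0, 11.0]
        res = sa.kruskal_wallis(g1, g2, g3)
        pooled = np.array(g1 + g2 + g3)
        ranks = sps.rankdata(pooled)
        n = pooled.size
        sums = [ranks[:2].sum(), ranks[2:4].sum(), ranks[4:].sum()]
        h_hand = 12.0 / (n * (n + 1)) * sum(s**2 / 2.0 for s in sums) - 3 * (n + 1)
        assert res.statistic == pytest.approx(h_hand, rel=1e-12)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            sa.anova_oneway([1.0, 2.0])


class TestHolm:
    def test_single_p_decided_at_raw_alpha(self):
        assert sa.holm_adjust([0.04]).reject[0]
        assert not sa.holm_adjust([0.06]).reject[0]

    def test_worked_three_p_example(self):
        res = sa.holm_adjust([0.01, 0.02, 0.04])
        np.testing.assert_allclose(res.adjusted, [0.03, 0.04, 0.04])
        assert res.reject.all()

    def test_order_invariance(self, rng):
        p = rng.uniform(0, 1, 7)
        base = sa.holm_adjust(p)
        perm = rng.permutation(7)
        shuffled = sa.holm_adjust(p[perm])
        np.testing.assert_allclose(shuffled.adjusted, base.adjusted[perm])
        np.testing.assert_array_equal(shuffled.reject, base.reject[perm])

    def test_between_bonferroni_and_unadjusted(self, rng):
        for _ in range(20):
            p = rng.uniform(0, 0.2, 6)
            holm = sa.holm_adjust(p).reject
            bonf = p < 0.05 / p.size
            raw = p < 0.05
            assert np.all(holm >= bonf)    # never more conservative than Bonf.
            assert np.all(holm <= raw)     # never more liberal than raw

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            sa.holm_adjust([0.5, 1.2])


def _dffits_loo_oracle(x, y):
    """Brute-force leave-one-out DFFITS."""
    n = x.size
    design = np.stack([np.ones(n), x], axis=1)
    beta = np.linalg.lstsq(design, y, rcond=None)[0]
    fitted = design @ beta
    h = np.diag(design @ np.linalg.inv(design.T @ design) @ design.T)
    out = np.empty(n)
    for i in range(n):
        keep = np.arange(n) != i
        beta_i = np.linalg.lstsq(design[keep], y[keep], rcond=None)[0]
        resid_i = y[keep] - design[keep] @ beta_i
        s_i = math.sqrt(resid_i @ resid_i / (n - 1 - 2))
        fitted_i = design[i] @ beta_i
        out[i] = (fitted[i] - fitted_i) / (s_i * math.sqrt(h[i]))
    return out


class TestPearsonDiagnostics:
    def test_perfect_line(self):
        x = np.array([0.0, 1.0, 2.0, 3.0])
        res = sa.pearson_with_diagnostics(x, 2 * x + 1)
        assert res.r == pytest.approx(1.0)
        np.testing.assert_allclose(res.residuals, 0.0, atol=1e-12)
        np.testing.assert_allclose(res.dffits, 0.0)
        assert res.slope == pytest.approx(2.0)
        assert res.intercept == pytest.approx(1.0)

    def test_four_point_outlier_matches_loo_oracle(self):
        # deleting the outlier leaves three exactly collinear points, so its
        # own DFFITS diverges (s_(i) = 0); the finite entries must match the
        # brute-force leave-one-out recomputation and the outlier must flag
        x = np.array([0.0, 1.0, 2.0, 3.0])
        y = np.array([0.0, 1.0, 2.0, 10.0])
        res = sa.pearson_with_diagnostics(x, y)
        oracle = _dffits_loo_oracle(x, y)
        np.testing.assert_allclose(res.dffits[:3], oracle[:3], rtol=1e-9)
        assert abs(res.dffits[3]) > res.dffits_threshold
        assert res.influential[3]
        assert not res.influential[:3].any()

    def test_random_data_matches_loo_oracle_and_statsmodels(self, rng):
        import statsmodels.api as sm

        x = rng.uniform(0, 10, 12)
        y = 1.5 * x + rng.normal(0, 2, 12)
        res = sa.pearson_with_diagnostics(x, y)
        np.testing.assert_allclose(res.dffits, _dffits_loo_oracle(x, y), rtol=1e-9)
        infl = sm.OLS(y, sm.add_constant(x)).fit().get_influence()
        np.testing.assert_allclose(res.dffits, infl.dffits[0], rtol=1e-9)

    def test_symmetry_of_r(self, rng):
        x, y = rng.normal(size=10), rng.normal(size=10)
        assert sa.pearson_with_diagnostics(x, y).r == pytest.approx(
            sa.pearson_with_diagnostics(y, x).r
        )

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            sa.pearson_with_diagnostics([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


def _cohort_table(seed=0, parameter="water", config=None):
    df = sc.generate_cohort(config or sc.CohortConfig(), seed=seed)
    return sa.prepare_change_table(df, parameter)


class TestPrepareChangeTable:
    def test_hand_built_cohort(self):
        df = pd.DataFrame(
            {
                "subject": ["A", "A", "A", "B", "B"],
                "group": [PRE] * 3 + [POST] * 2,
                "day": [0.0, 30.0, 90.0, 0.0, 85.0],
                "water": [20.0, 18.0, 17.0, 15.0, 16.5],
            }
        )
        tab = sa.prepare_change_table(df, "water")
        assert len(tab) == 3
        a30 = tab[(tab.subject == "A") & (tab.interval == 30)]["change"].iloc[0]
        assert a30 == pytest.approx(-10.0)
        b90 = tab[tab.subject == "B"]["change"].iloc[0]
        assert b90 == pytest.approx(10.0)
        assert tab[tab.subject == "B"]["interval"].iloc[0] == 90

    def test_subject_without_baseline_dropped(self):
        df = pd.DataFrame(
            {
                "subject": ["A", "A"],
                "group": [PRE, PRE],
                "day": [30.0, 90.0],
                "water": [18.0, 17.0],
            }
        )
        assert sa.prepare_change_table(df, "water").empty


class TestGEE:
    def test_one_observation_per_subject_equals_ols(self):
        rng = np.random.default_rng(3)
        tab = pd.DataFrame(
            {
                "subject": [f"S{i}" for i in range(24)],
                "group": [PRE] * 12 + [POST] * 12,
                "interval": ([30] * 6 + [60] * 6) * 2,
                "change": rng.normal(0, 5, 24),
            }
        )
        fit = sa.gee_fit(tab)
        X, names, _ = sa._build_design(tab)
        y = tab["change"].to_numpy()
        beta = np.linalg.lstsq(X, y, rcond=None)[0]
        np.testing.assert_allclose(fit.params, beta, atol=1e-10)
        resid = y - X @ beta
        sigma2 = resid @ resid / (len(y) - len(beta))
        np.testing.assert_allclose(
            fit.cov_model, sigma2 * np.linalg.inv(X.T @ X), rtol=1e-8
        )

    def test_forced_zero_alpha_reproduces_pooled_ols(self):
        tab = _cohort_table(seed=5)
        fit = sa.gee_fit(tab, force_alpha=0.0)
        X, _, _ = sa._build_design(tab)
        beta = np.linalg.lstsq(X, tab["change"].to_numpy(), rcond=None)[0]
        np.testing.assert_allclose(fit.params, beta, atol=1e-12)
        assert fit.alpha == 0.0

    def test_balanced_panel_alpha_matches_closed_form_icc(self):
        """On a balanced intercept-only panel the iterative GEE must land
        exactly on the one-shot moment (intraclass correlation) estimate
        computed from OLS residuals."""
        rng = np.random.default_rng(7)
        K = 40
        b = rng.normal(0, 2.0, K)
        y = np.concatenate([b + rng.normal(0, 1, K), b + rng.normal(0, 1, K)])
        tab = pd.DataFrame(
            {
                "subject": [f"S{i}" for i in range(K)] * 2,
                "group": PRE,
                "interval": [30] * K + [60] * K,
                "change": y,
            }
        )
        fit = sa.gee_fit(tab)
        X, _, _ = sa._build_design(tab)
        beta = np.linalg.lstsq(X, y, rcond=None)[0]
        r = y - X @ beta
        n, p = X.shape
        phi = r @ r / (n - p)
        r_pairs = r.reshape(2, K)
        icc = (r_pairs[0] * r_pairs[1]).sum() / ((K - p) * phi)
        assert fit.alpha == pytest.approx(icc, abs=1e-6)

    def test_sandwich_covariance_is_psd(self):
        for seed in range(5):
            fit = sa.gee_fit(_cohort_table(seed=seed))
            eigs = np.linalg.eigvalsh(fit.cov_robust)
            assert np.all(eigs >= -1e-10)

    def test_cross_check_against_statsmodels(self):
        import statsmodels.api as sm

        tab = _cohort_table(seed=8)
        fit = sa.gee_fit(tab)
        X, names, _ = sa._build_design(tab)
        model = sm.GEE(
            tab["change"].to_numpy(), X, groups=tab["subject"].to_numpy(),
            cov_struct=sm.cov_struct.Exchangeable(),
        )
        ref = model.fit()
        np.testing.assert_allclose(fit.params, ref.params, rtol=0.02, atol=0.3)
        se = np.sqrt(np.diag(fit.cov_robust))
        se_ref = ref.bse
        assert np.all(se / se_ref > 0.7) and np.all(se / se_ref < 1.4)

    def test_underdetermined_fit_rejected(self):
        tab = pd.DataFrame(
            {
                "subject": ["A", "B"],
                "group": [PRE, POST],
                "interval": [30, 30],
                "change": [1.0, 2.0],
            }
        )
        with pytest.raises(ValueError):
            sa.gee_fit(tab)


class TestContrasts:
    def test_baseline_contrast_is_structural_zero(self):
        fit = sa.gee_fit(_cohort_table(seed=2))
        est = sa.estimate_group_day_change(fit, PRE, "baseline")
        assert est.estimate == 0.0
        assert est.ci_lower == est.ci_upper == 0.0

    def test_unknown_interval_rejected(self):
        fit = sa.gee_fit(_cohort_table(seed=2))
        with pytest.raises(ValueError):
            sa.estimate_group_day_change(fit, PRE, 75)

    def test_ci_contains_point_estimate(self):
        fit = sa.gee_fit(_cohort_table(seed=2))
        for group in (PRE, POST):
            est = sa.estimate_group_day_change(fit, group, 90)
            assert est.ci_lower <= est.estimate <= est.ci_upper

    def test_ci_width_shrinks_with_sample_size(self):
        """Same per-subject SDs, 10x the subjects -> clearly narrower CI."""
        def config_with(n_pre, n_post):
            def scale(params, n):
                sd = {p: params.sd(p) for p in params.means}
                return sc.GroupParameters(
                    group=params.group, means=params.means,
                    ses={p: sd[p] / math.sqrt(n) for p in sd}, n=n,
                )
            return replace(
                sc.CohortConfig(),
                params_pre=scale(sc.BASELINE_PRE, n_pre),
                params_post=scale(sc.BASELINE_POST, n_post),
            )

        def width(config, seed):
            tab = sa.prepare_change_table(
                sc.generate_cohort(config, seed=seed), "water"
            )
            est = sa.estimate_group_day_change(sa.gee_fit(tab), PRE, 90)
            return est.ci_upper - est.ci_lower

        small = np.mean([width(config_with(17, 11), s) for s in range(3)])
        large = np.mean([width(config_with(170, 110), s) for s in range(3)])
        assert large < small


class TestParameterRecovery:
    def test_day90_water_contrast_recovers_generator_truth(self):
        """Mean GEE estimate over replicates matches the implied interval
        estimand: visit days are uniform on 78-104 while the trajectory
        ramps linearly to its day-90 anchor, so the day-90 cell mean is
        -11.9 x E[min(day, 90)]/90."""
        n_rep = 60
        ests = []
        for rep in range(n_rep):
            tab = _cohort_table(seed=20_000 + rep)
            fit = sa.gee_fit(tab)
            ests.append(sa.estimate_group_day_change(fit, PRE, 90).estimate)
        ests = np.array(ests)
        e_day = ((90**2 - 78**2) / 2.0 + 90.0 * 14.0) / 26.0
        implied = -11.9 * e_day / 90.0
        mc_se = ests.std(ddof=1) / math.sqrt(n_rep)
        assert abs(ests.mean() - implied) < 3.0 * mc_se + 0.15
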