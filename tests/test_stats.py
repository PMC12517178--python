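"""Statistical layer: exact enumeration oracles, FDR, regression, LMM."""
import itertools

import numpy as np
import pandas as pd
import pytest

from doc_eeg.errors import (DegenerateDataError, LengthError, ParameterError)
from doc_eeg.stats import (ContingencyTable, bh_fdr, chi_square, cohens_d,
                           fisher_exact, fit_random_intercept_lmm,
                           kruskal_wallis, mann_whitney_u,
                           multiple_regression, normality_check,
                           pearson_regression, wilcoxon_signed_rank)


class TestWilcoxon:
    def test_antisymmetric_differences_null(self):
        res = wilcoxon_signed_rank([-3, -1, 1, 3])
        assert res.p_value == pytest.approx(1.0)
        assert res.effect_size == pytest.approx(0.0)

    def test_all_positive_exact_enumeration(self):
        """Oracle: with n=10 all-positive, only 2 of 2^10 sign patterns are
        as extreme, so the exact two-sided p is 2/1024."""
        res = wilcoxon_signed_rank(np.arange(1, 11))
        assert res.p_value == pytest.approx(2 / 1024, rel=1e-9)
        assert res.effect_size == pytest.approx(1.0)

    def test_zero_differences_dropped(self):
        res = wilcoxon_signed_rank([0, 0, 1, 2, 3, 4, 5])
        assert res.n == 5

    def test_degenerate_all_zero(self):
        with pytest.raises(DegenerateDataError):
            wilcoxon_signed_rank([0.0, 0.0])

    def test_single_pair_rejected(self):
        with pytest.raises(LengthError):
            wilcoxon_signed_rank([1.0])


class TestMannWhitney:
    def test_identical_samples_zero_effect(self, rng):
        x = rng.standard_normal(30)
        res = mann_whitney_u(x, x)
        assert res.effect_size == pytest.approx(0.0)

    def test_complete_separation_exact(self):
        """Oracle: U=0 for a=(1,2) vs b=(3,4); 2 of C(4,2)=6 orderings are as
        extreme, giving exact two-sided p = 1/3."""
        res = mann_whitney_u([1, 2], [3, 4])
        assert res.statistic == 0
        assert res.p_value == pytest.approx(1 / 3, rel=1e-9)
        assert res.effect_size == pytest.approx(1.0)

    def test_empty_sample_rejected(self):
        with pytest.raises(DegenerateDataError):
            mann_whitney_u([], [1, 2])


class TestKruskal:
    def test_all_identical_degenerate(self):
        with pytest.raises(DegenerateDataError):
            kruskal_wallis([1.0, 1.0], [1.0, 1.0], [1.0, 1.0])

    def test_separated_groups_match_oracle(self):
        """H for fully separated groups of 2 with n=6: ranks (1,2),(3,4),(5,6)
        give H = 12/(n(n+1)) * sum n_i (rbar_i - rbar)^2 directly."""
        res = kruskal_wallis([1, 2], [13, 14], [25, 26])
        means = np.array([1.5, 3.5, 5.5])
        h = 12 / (6 * 7) * (2 * ((means - 3.5) ** 2)).sum()
        assert res.statistic == pytest.approx(h, rel=1e-9)
        assert res.df == 2

    def test_type_one_error_near_nominal(self, rng):
        rejections = 0
        reps = 2000
        for _ in range(reps):
            g = [rng.standard_normal(15) for _ in range(3)]
            rejections += kruskal_wallis(*g).p_value < 0.05
        assert rejections / reps == pytest.approx(0.05, abs=0.02)


class TestChiSquare:
    def test_observed_equals_expected_zero(self):
        t = ContingencyTable([[10, 20], [10, 20]])
        assert chi_square(t).statistic == pytest.approx(0.0)

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(1000):
            r, c = rng.integers(2, 4, size=2)
            counts = rng.integers(1, 20, size=(r, c))
            t = ContingencyTable(counts)
            res = chi_square(t)
            n = counts.sum()
            expected = np.outer(counts.sum(1), counts.sum(0)) / n
            oracle = ((counts - expected) ** 2 / expected).sum()
            assert res.statistic == pytest.approx(oracle, rel=1e-12)
            assert res.df == (r - 1) * (c - 1)

    def test_zero_expected_cell_named(self):
        t = ContingencyTable([[0, 5], [0, 5]])
        with pytest.raises(DegenerateDataError, match="c0"):
            chi_square(t)


class TestFisherExact:
    def test_2x2_closed_form(self):
        """P(table | margins 5/5, 5/5) for the diagonal table is
        1/C(10,5) = 1/252 per tail."""
        res = fisher_exact(ContingencyTable([[5, 0], [0, 5]]))
        assert res.p_value == pytest.approx(2 / 252, rel=1e-9)

    def test_independent_table_p_one(self):
        res = fisher_exact(ContingencyTable([[5, 5], [5, 5]]))
        assert res.p_value == pytest.approx(1.0)

    def test_rxc_enumeration_matches_2x2_hypergeometric(self):
        """The r x c enumeration must agree with scipy's 2 x 2 exact test."""
        from scipy.stats import fisher_exact as scipy_fisher
        table = np.array([[3, 7], [6, 2]])
        ours = fisher_exact(ContingencyTable(table), force_enumeration=True)
        _, scipy_p = scipy_fisher(table)
        assert ours.p_value == pytest.approx(scipy_p, rel=1e-9)

    def test_rxc_small_p_for_structured_table(self):
        t = ContingencyTable([[0, 0, 0, 11], [1, 3, 5, 5], [3, 4, 4, 4]])
        res = fisher_exact(t)
        assert res.method == "fisher_exact_enumeration"
        assert res.p_value <= 0.05


class TestBHFDR:
    def test_step_up_example(self):
        res = bh_fdr([0.01, 0.02, 0.03, 0.04])
        np.testing.assert_allclose(res.adjusted, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        res = bh_fdr([0.03])
        assert res.adjusted[0] == pytest.approx(0.03)

    def test_all_ones(self):
        res = bh_fdr([1.0, 1.0, 1.0])
        assert np.all(res.adjusted == 1.0)

    def test_permutation_invariance(self, rng):
        p = rng.uniform(size=20)
        perm = rng.permutation(20)
        a1 = bh_fdr(p).adjusted
        a2 = bh_fdr(p[perm]).adjusted
        np.testing.assert_allclose(a1[perm], a2)

    def test_adjusted_at_least_raw(self, rng):
        p = rng.uniform(size=50)
        res = bh_fdr(p)
        assert np.all(res.adjusted >= res.raw - 1e-15)


class TestPearsonRegression:
    def test_exact_line_recovered(self):
        x = np.linspace(-0.4, 0.1, 12)
        y = 3.16 - 9.86 * x
        fit, test = pearson_regression(x, y)
        assert fit.slopes["x"] == pytest.approx(-9.86)
        assert fit.intercept == pytest.approx(3.16)
        assert fit.r_squared == pytest.approx(1.0)

    def test_constant_y_degenerate(self):
        with pytest.raises(DegenerateDataError):
            pearson_regression([1, 2, 3, 4], [5, 5, 5, 5])

    def test_r_squared_is_r_squared(self, rng):
        x = rng.standard_normal(50)
        y = x + rng.standard_normal(50)
        fit, test = pearson_regression(x, y)
        assert fit.r_squared == pytest.approx(test.effect_size ** 2, rel=1e-9)


class TestMultipleRegression:
    def test_orthogonal_covariates_equal_simple_slope(self):
        n = 64
        x = np.tile([1.0, -1.0], n // 2)
        z = np.repeat([1.0, -1.0], n // 2)
        y = 2.0 * x + 0.5 * z
        fit = multiple_regression(y, pd.DataFrame({"x": x, "z": z}), "x")
        simple, _ = pearson_regression(x, y)
        assert fit.slopes["x"] == pytest.approx(simple.slopes["x"], rel=1e-9)

    def test_collinear_design_rejected(self, rng):
        x = rng.standard_normal(30)
        with pytest.raises(ParameterError):
            multiple_regression(rng.standard_normal(30),
                                pd.DataFrame({"x": x, "x2": 2 * x}), "x")

    def test_confounder_adjustment_recovers_truth(self, rng):
        """Adjusted slope covers the generating coefficient >= 90% of reps."""
        true_beta, hits, reps = 1.5, 0, 500
        for _ in range(reps):
            conf = rng.standard_normal(80)
            x = conf + rng.standard_normal(80)
            y = true_beta * x + 2.0 * conf + rng.standard_normal(80)
            fit = multiple_regression(y, pd.DataFrame({"x": x, "conf": conf}),
                                      "x")
            half = 1.96 * fit.stderr["x"]
            hits += abs(fit.slopes["x"] - true_beta) <= half
        assert hits / reps >= 0.90


class TestLMM:
    @staticmethod
    def _toy(n_subj=20, sigma_u=0.25, sigma_e=0.12, seed=0):
        from doc_eeg.synthetic import LMMTruth, generate_entropy_long_table
        truth = LMMTruth(sigma_u=sigma_u, sigma_e=sigma_e,
                         n_tbicva=n_subj // 2, n_aie=n_subj - n_subj // 2)
        return generate_entropy_long_table(truth, seed=seed)

    def test_matches_statsmodels_mixedlm(self):
        import statsmodels.formula.api as smf
        df = self._toy(40, seed=3)
        ours = fit_random_intercept_lmm(df)
        d = df.assign(g=(df.group != "AIE").astype(float),
                      s=(df.state == "anesthesia").astype(float))
        ref = smf.mixedlm("entropy ~ g * s", d, groups=d["subject"]).fit(reml=True)
        np.testing.assert_allclose(
            ours.fixed_effects["estimate"],
            [ref.params["Intercept"], ref.params["g"], ref.params["s"],
             ref.params["g:s"]], rtol=1e-5)
        assert ours.random_intercept_sd == pytest.approx(
            np.sqrt(ref.cov_re.iloc[0, 0]), rel=1e-4)
        assert ours.residual_sd == pytest.approx(np.sqrt(ref.scale), rel=1e-4)

    def test_zero_variance_collapses_to_ols(self):
        import statsmodels.api as sm
        df = self._toy(30, sigma_u=0.0, seed=11)
        ours = fit_random_intercept_lmm(df)
        g = (df.group != "AIE").astype(float).to_numpy()
        s = (df.state == "anesthesia").astype(float).to_numpy()
        X = sm.add_constant(np.column_stack([g, s, g * s]))
        ols = sm.OLS(df.entropy.to_numpy(), X).fit()
        np.testing.assert_allclose(ours.fixed_effects["estimate"], ols.params,
                                   atol=1e-6)

    def test_within_subject_differences_oracle(self):
        """With subject means removed, state and interaction estimates match
        paired OLS on the within-subject differences."""
        df = self._toy(30, seed=21)
        centred = df.copy()
        centred["entropy"] -= centred.groupby("subject")["entropy"].transform("mean")
        fit = fit_random_intercept_lmm(centred)
        wide = df.pivot_table(index=["subject", "group"], columns="state",
                              values="entropy").reset_index()
        diff = wide["anesthesia"] - wide["baseline"]
        g = (wide.group != "AIE").astype(float)
        aie_mean = diff[g == 0].mean()
        other_mean = diff[g == 1].mean()
        assert fit.effect("state")["estimate"] == pytest.approx(aie_mean, abs=1e-8)
        assert fit.effect("group:state")["estimate"] == pytest.approx(
            other_mean - aie_mean, abs=1e-8)

    def test_too_few_subjects_rejected(self):
        df = self._toy(4)
        with pytest.raises(ParameterError):
            fit_random_intercept_lmm(df)

    def test_single_observation_per_subject_flags_boundary(self, rng):
        df = pd.DataFrame({
            "subject": [f"s{i}" for i in range(20)],
            "group": ["AIE"] * 10 + ["TBI/CVA"] * 10,
            "state": ["baseline", "anesthesia"] * 10,
            "entropy": rng.standard_normal(20),
        })
        fit = fit_random_intercept_lmm(df)
        assert fit.boundary


class TestNormalityAndEffectSize:
    def test_normal_sample_usually_passes(self, rng):
        passes = sum(
            normality_check(rng.standard_normal(200)).p_value > 0.05
            for _ in range(20))
        assert passes >= 18

    def test_exponential_sample_usually_fails(self, rng):
        fails = sum(
            normality_check(rng.exponential(size=100)).p_value < 0.05
            for _ in range(20))
        assert fails >= 18

    def test_tiny_sample_rejected(self):
        with pytest.raises(LengthError):
            normality_check([1.0, 2.0, 3.0])

    def test_cohens_d_examples(self, rng):
        x = rng.standard_normal(50)
        assert cohens_d(x, x) == 0.0
        a = rng.standard_normal(2000)
        assert cohens_d(a + 1.0, a) == pytest.approx(1.0, abs=0.05)

    def test_cohens_d_matches_formula(self, rng):
        a, b = rng.standard_normal(17), rng.standard_normal(23) + 0.4
        sp = np.sqrt(((16 * a.var(ddof=1)) + (22 * b.var(ddof=1))) / 38)
        assert cohens_d(a, b) == pytest.approx((a.mean() - b.mean()) / sp,
                                               rel=1e-12)
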