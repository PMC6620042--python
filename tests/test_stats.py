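"""Inferential statistics: Spearman CI, Meng's z, t-tests, rm-ANOVA,
BCa mediation and within-subject block regression."""

import numpy as np
import pytest

from dopanet.stats import (StatsError, group_strength_test, mediation_bootstrap,
                           meng_compare, one_sample_t, paired_t, rm_anova,
                           spearman_ci, within_subject_regression)


class TestSpearman:
    def test_hand_computed_rank_correlation(self):
        # ranks differ by (0, 1, 1, 1, 1): rho = 1 - 6*4/(5*24) = 0.8
        r = spearman_ci([1, 2, 3, 4, 5], [1, 3, 2, 5, 4])
        assert r.rho == pytest.approx(0.8)
        assert r.df == 3
        assert r.ci_low <= r.rho <= r.ci_high

    def test_monotone_function_gives_unity(self):
        x = np.arange(10.0)
        assert spearman_ci(x, np.exp(x)).rho == pytest.approx(1.0)
        assert spearman_ci(x, -x).rho == pytest.approx(-1.0)

    def test_ci_uses_fisher_variance(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal(51)
        y = x + rng.standard_normal(51)
        r = spearman_ci(x, y)
        se = np.sqrt(1.06 / 48)
        z = np.arctanh(r.rho)
        assert r.ci_low == pytest.approx(np.tanh(z - 1.959964 * se), abs=1e-6)
        assert r.ci_high == pytest.approx(np.tanh(z + 1.959964 * se),
                                          abs=1e-6)
        assert 0.0 <= r.p <= 1.0

    def test_constant_vector_rejected(self):
        with pytest.raises(StatsError, match="constant"):
            spearman_ci([1, 1, 1, 1], [1, 2, 3, 4])


class TestMeng:
    def test_equal_correlations_give_zero(self):
        r = meng_compare(0.4, 0.4, 0.3, 51)
        assert r.z == pytest.approx(0.0)
        assert r.p == pytest.approx(1.0)

    def test_antisymmetric_in_the_two_correlations(self):
        r1 = meng_compare(0.45, 0.21, 0.5, 48)
        r2 = meng_compare(0.21, 0.45, 0.5, 48)
        assert r1.z == pytest.approx(-r2.z)
        assert r1.p == pytest.approx(r2.p)

    def test_degenerate_correlation_rejected(self):
        with pytest.raises(StatsError):
            meng_compare(1.0, 0.2, 0.1, 20)

    def test_rejection_agrees_with_permutation_oracle(self):
        """Exchange y1/y2 within subjects under H0 rho(x,y1)=rho(x,y2)."""
        from scipy.stats import spearmanr
        rng = np.random.default_rng(7)
        n = 400
        for b1, b2 in [(0.6, 0.1), (0.4, 0.35), (0.0, 0.0), (0.5, 0.5)]:
            x = rng.standard_normal(n)
            y1 = b1 * x + rng.standard_normal(n)
            y2 = b2 * x + rng.standard_normal(n)
            ry1 = spearmanr(x, y1).statistic
            ry2 = spearmanr(x, y2).statistic
            r12 = spearmanr(y1, y2).statistic
            observed = abs(ry1 - ry2)
            null = []
            for _ in range(400):
                swap = rng.random(n) < 0.5
                a = np.where(swap, y2, y1)
                b = np.where(swap, y1, y2)
                null.append(abs(spearmanr(x, a).statistic -
                                spearmanr(x, b).statistic))
            p_perm = (np.sum(np.asarray(null) >= observed) + 1) / 401
            p_meng = meng_compare(ry1, ry2, r12, n).p
            assert (p_meng < 0.05) == (p_perm < 0.05)


class TestTTests:
    def test_hand_computed_one_sample(self):
        r = one_sample_t([1.0, 2.0, 3.0], 0.0)
        assert r.t == pytest.approx(2 * np.sqrt(3), abs=1e-9)
        assert r.df == 2

    def test_symmetric_sample_gives_zero(self):
        r = one_sample_t([-1.0, 0.0, 1.0], 0.0)
        assert r.t == pytest.approx(0.0)
        assert r.p == pytest.approx(1.0)

    def test_df_is_n_minus_one(self, rng):
        assert one_sample_t(rng.standard_normal(51)).df == 50

    def test_paired_reduces_to_difference(self, rng):
        x = rng.standard_normal(20)
        y = rng.standard_normal(20)
        assert paired_t(x, y).t == pytest.approx(one_sample_t(x - y).t)

    def test_zero_variance_rejected(self):
        with pytest.raises(StatsError, match="variance"):
            one_sample_t([2.0, 2.0, 2.0])


class TestRMAnova:
    def test_flat_table_gives_zero_f(self):
        m = np.tile([1.0, 1.0, 1.0], (5, 1))
        assert rm_anova(m).f == pytest.approx(0.0)

    def test_degrees_of_freedom_51_by_3(self, rng):
        r = rm_anova(rng.standard_normal((51, 3)))
        assert (r.df1, r.df2) == (2, 100)

    def test_matches_sums_of_squares_oracle(self):
        m = np.array([[3.0, 4.0, 6.0],
                      [2.0, 5.0, 5.0],
                      [4.0, 4.0, 7.0],
                      [3.0, 6.0, 8.0]])
        n, k = m.shape
        grand = m.mean()
        ss_cond = n * ((m.mean(0) - grand) ** 2).sum()
        ss_subj = k * ((m.mean(1) - grand) ** 2).sum()
        ss_err = ((m - grand) ** 2).sum() - ss_cond - ss_subj
        f_oracle = (ss_cond / (k - 1)) / (ss_err / ((k - 1) * (n - 1)))
        assert rm_anova(m).f == pytest.approx(f_oracle, abs=1e-10)

    def test_agrees_with_pingouin(self, rng):
        import pandas as pd
        import pingouin as pg
        m = rng.standard_normal((12, 3)) + [0.0, 0.3, 0.6]
        long = pd.DataFrame({
            "subject": np.repeat(np.arange(12), 3),
            "cond": np.tile(np.arange(3), 12),
            "y": m.ravel(),
        })
        aov = pg.rm_anova(data=long, dv="y", within="cond",
                          subject="subject")
        r = rm_anova(m)
        assert r.f == pytest.approx(float(aov["F"].iloc[0]), rel=1e-9)
        assert r.p == pytest.approx(float(aov["p_unc"].iloc[0]), rel=1e-6)

    def test_missing_cells_rejected(self):
        m = np.ones((4, 3))
        m[1, 2] = np.nan
        with pytest.raises(StatsError, match="missing"):
            rm_anova(m)


class TestMediation:
    @staticmethod
    def linear_gaussian(n, a=0.5, b=0.4, cp=0.0, seed=0):
        rng = np.random.default_rng(seed)
        t = rng.standard_normal(n)
        m = a * t + rng.standard_normal(n)
        y = b * m + cp * t + rng.standard_normal(n)
        return t, m, y

    def test_total_equals_acme_plus_ade_per_draw(self):
        t, m, y = self.linear_gaussian(200)
        res = mediation_bootstrap(t, m, y, n_boot=500, seed=1)
        assert np.allclose(res.draws["total"],
                           res.draws["acme"] + res.draws["ade"], atol=1e-10)
        assert res.total["est"] == pytest.approx(
            res.acme["est"] + res.ade["est"], abs=1e-12)

    def test_product_of_coefficients_recovered(self):
        t, m, y = self.linear_gaussian(4000, seed=5)
        res = mediation_bootstrap(t, m, y, n_boot=299, seed=2)
        assert res.acme["est"] == pytest.approx(0.2, abs=0.05)
        assert res.ade["est"] == pytest.approx(0.0, abs=0.05)

    def test_null_mediator_path_not_rejected(self):
        t, m, y = self.linear_gaussian(1000, a=0.5, b=0.0, seed=9)
        res = mediation_bootstrap(t, m, y, n_boot=999, seed=3)
        assert res.acme["ci_low"] <= 0.0 <= res.acme["ci_high"]
        assert res.acme["p"] > 0.05

    def test_collinear_predictors_rejected(self, rng):
        t = rng.standard_normal(50)
        with pytest.raises(StatsError, match="collinear"):
            mediation_bootstrap(t, 2 * t, rng.standard_normal(50),
                                n_boot=50, seed=0)

    def test_agrees_with_statsmodels_mediation(self):
        import pandas as pd
        import statsmodels.api as sm
        from statsmodels.stats.mediation import Mediation
        t, m, y = self.linear_gaussian(300, seed=11)
        res = mediation_bootstrap(t, m, y, n_boot=999, seed=4)
        data = pd.DataFrame({"t": t, "m": m, "y": y})
        med = Mediation(sm.OLS.from_formula("y ~ t + m", data),
                        sm.OLS.from_formula("m ~ t", data),
                        "t", "m").fit(n_rep=500)
        summ = med.summary()
        assert res.acme["est"] == pytest.approx(
            float(summ.loc["ACME (average)", "Estimate"]), abs=0.02)
        assert res.ade["est"] == pytest.approx(
            float(summ.loc["ADE (average)", "Estimate"]), abs=0.02)


class TestWithinSubject:
    def test_noise_free_planted_coefficient_recovered_exactly(self, rng):
        strength = rng.standard_normal(18)
        load = np.tile([0.0, 1.0, 2.0], 6)
        prt = 1.0 - 0.1 * strength
        fit = within_subject_regression(prt, strength, load)
        assert fit.simple_w1 == pytest.approx(-0.1, abs=1e-12)
        assert fit.full_w2 == pytest.approx(-0.1, abs=1e-12)

    def test_orthogonal_strength_matches_adjusted_model(self, rng):
        load = np.tile([0.0, 1.0, 2.0], 6)
        strength = rng.standard_normal(18)
        strength -= np.polyval(np.polyfit(load, strength, 1), load)
        prt = 0.6 + 0.05 * load - 0.08 * strength + \
            0.001 * rng.standard_normal(18)
        fit = within_subject_regression(prt, strength, load)
        assert fit.simple_w1 == pytest.approx(fit.full_w2, abs=1e-3)

    def test_rank_deficient_design_rejected(self):
        load = np.tile([0.0, 1.0, 2.0], 6)
        with pytest.raises(StatsError, match="rank"):
            within_subject_regression(np.ones(18), load.copy(), load)

    def test_group_test_aggregates_strength_coefficients(self, rng):
        fits = [within_subject_regression(
            1.0 - 0.1 * s + 0.01 * rng.standard_normal(18), s,
            np.tile([0.0, 1.0, 2.0], 6))
            for s in rng.standard_normal((12, 18))]
        out = group_strength_test(fits)
        assert out["simple_strength"]["p"] < 1e-6
        assert out["simple_strength"]["mean"] == pytest.approx(-0.1,
                                                               abs=0.01)
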