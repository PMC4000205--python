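import numpy as np
import pytest
import statsmodels.api as sm

from accmeta.glmm_core import (
    _marginal_loglik_grad,
    aic,
    fit_glmm,
    lr_test,
    marginal_loglik,
    wald_test,
)
from accmeta.study_table import FactorSet, encode_design, outcomes_array
from accmeta.synthetic_data import SyntheticConfig, generate_study_table


def _direct_binomial_loglik(design, outcomes, beta):
    from scipy.special import gammaln

    y, n = (np.asarray(a, float) for a in outcomes)
    eta = design.X @ beta
    return float(np.sum(
        y * eta - n * np.logaddexp(0, eta)
        + gammaln(n + 1) - gammaln(y + 1) - gammaln(n - y + 1)
    ))


class TestMarginalLoglik:
    def test_sigma2_zero_collapses_to_plain_binomial(self, cluster_fixture):
        design, outcomes = cluster_fixture
        beta = np.array([0.8, -0.3, 0.4])
        assert marginal_loglik(design, outcomes, beta, 0.0) == pytest.approx(
            _direct_binomial_loglik(design, outcomes, beta), abs=1e-12
        )

    def test_agq_matches_bruteforce_integration(self, cluster_fixture, brute_force_oracle):
        design, outcomes = cluster_fixture
        beta = np.array([0.8, -0.3, 0.4])
        oracle = brute_force_oracle(design, outcomes, beta, 0.7)
        agq = marginal_loglik(design, outcomes, beta, 0.7, quad_order=25)
        assert agq == pytest.approx(oracle, abs=1e-8)

    def test_gap_decreases_monotonically_in_quad_order(self, cluster_fixture,
                                                       brute_force_oracle):
        design, outcomes = cluster_fixture
        beta = np.array([0.8, -0.3, 0.4])
        oracle = brute_force_oracle(design, outcomes, beta, 0.7)
        gaps = [abs(marginal_loglik(design, outcomes, beta, 0.7, quad_order=q) - oracle)
                for q in (1, 3, 7, 15)]
        assert all(g1 >= g2 - 1e-12 for g1, g2 in zip(gaps, gaps[1:]))
        assert gaps[-1] < 1e-8

    def test_single_bernoulli_row_matches_oracle(self, brute_force_oracle):
        cfg = SyntheticConfig(n_studies=2, models_per_study={1: 1.0},
                              n_eval_range=(5, 5), beta={"intercept": 0.5},
                              sigma2=0.3, seed=3)
        records = generate_study_table(cfg)[:2]
        design = encode_design(records, FactorSet.empty())
        y, n = outcomes_array(records)
        y1, n1 = np.array([1.0, y[1]]), np.array([1.0, n[1]])
        beta = np.array([0.2, 0.1])
        agq = marginal_loglik(design, (y1, n1), beta, 0.3, quad_order=25)
        oracle = brute_force_oracle(design, (y1, n1), beta, 0.3)
        assert agq == pytest.approx(oracle, abs=1e-8)

    def test_boundary_continuity(self, cluster_fixture):
        """loglik is continuous as sigma2 -> 0+."""
        design, outcomes = cluster_fixture
        beta = np.array([0.8, -0.3, 0.4])
        at_zero = marginal_loglik(design, outcomes, beta, 0.0)
        diffs = [abs(marginal_loglik(design, outcomes, beta, s2, quad_order=15) - at_zero)
                 for s2 in (1e-2, 1e-4, 1e-6)]
        # the gap vanishes linearly in sigma2 (slope = score at the boundary)
        assert diffs[0] > diffs[1] > diffs[2]
        assert diffs[2] < 1e-3
        assert diffs[1] / diffs[0] == pytest.approx(1e-2, rel=0.2)

    def test_quad_order_below_one_rejected(self, cluster_fixture):
        design, outcomes = cluster_fixture
        with pytest.raises(ValueError):
            marginal_loglik(design, outcomes, np.zeros(3), 0.5, quad_order=0)

    def test_analytic_gradient_matches_finite_differences(self, cluster_fixture):
        from accmeta.glmm_core import _binom_logconst, _marginal_loglik_arrays

        design, outcomes = cluster_fixture
        y, n = (np.asarray(a, float) for a in outcomes)
        logc = _binom_logconst(y, n)
        theta = np.array([0.7, -0.2, 0.3, np.log(0.6)])
        p = design.X.shape[1]
        _, grad, _ = _marginal_loglik_grad(
            design.X, y, n, design.cluster_index, design.n_clusters,
            theta[:p], theta[p], 7, logc,
        )
        for i in range(p + 1):
            e = np.zeros(p + 1)
            e[i] = 1e-6
            lp, _ = _marginal_loglik_arrays(
                design.X, y, n, design.cluster_index, design.n_clusters,
                (theta + e)[:p], np.exp(2 * (theta + e)[p]), 7, logc)
            lm, _ = _marginal_loglik_arrays(
                design.X, y, n, design.cluster_index, design.n_clusters,
                (theta - e)[:p], np.exp(2 * (theta - e)[p]), 7, logc)
            assert grad[i] == pytest.approx((lp - lm) / 2e-6, abs=1e-5)


class TestFitGlmm:
    def test_boundary_fit_matches_plain_logistic_mle(self):
        """Data with independent rows push sigma2 to 0 and beta to the GLM MLE."""
        cfg = SyntheticConfig(n_studies=80, beta={"intercept": 1.0,
                                                  "cv_technique[nested]": 0.5},
                              sigma2=0.0, seed=21)
        records = generate_study_table(cfg)
        design = encode_design(records, FactorSet(("cv_technique",)),
                               reference_levels={"cv_technique": "single"})
        outcomes = outcomes_array(records)
        fit = fit_glmm(design, outcomes)
        y, n = outcomes
        glm = sm.GLM(np.column_stack([y, n - y]), design.X,
                     family=sm.families.Binomial()).fit()
        assert fit.sigma2 == 0.0
        np.testing.assert_allclose(fit.beta, glm.params, atol=1e-6)
        assert fit.loglik == pytest.approx(glm.llf, abs=1e-6)

    def test_fit_invariant_to_cluster_relabeling_and_row_order(self, small_corpus):
        refs = {"cv_technique": "single"}
        fs = FactorSet(("cv_technique",))
        d1 = encode_design(small_corpus, fs, reference_levels=refs)
        fit1 = fit_glmm(d1, outcomes_array(small_corpus))
        rng = np.random.default_rng(9)
        perm = rng.permutation(len(small_corpus))
        shuffled = [small_corpus[i] for i in perm]
        d2 = encode_design(shuffled, fs, reference_levels=refs)
        fit2 = fit_glmm(d2, outcomes_array(shuffled))
        assert fit1.loglik == pytest.approx(fit2.loglik, abs=1e-6)
        np.testing.assert_allclose(fit1.beta, fit2.beta, atol=1e-4)

    def test_covariate_scaling_invariance(self, small_corpus):
        """Multiplying a numeric covariate by c divides its coefficient by c."""
        fs = FactorSet(("n_train",))
        design = encode_design(small_corpus, fs)
        outcomes = outcomes_array(small_corpus)
        fit = fit_glmm(design, outcomes)
        scaled = encode_design(small_corpus, fs)
        col = scaled.column_map["n_train"][0]
        scaled.X[:, col] *= 100.0
        fit_scaled = fit_glmm(scaled, outcomes)
        assert fit.loglik == pytest.approx(fit_scaled.loglik, abs=1e-6)
        assert fit.beta[col] == pytest.approx(100.0 * fit_scaled.beta[col], rel=1e-3)

    def test_rank_deficient_design_rejected(self, small_corpus):
        design = encode_design(small_corpus, FactorSet(("cv_technique",)))
        design.X = np.column_stack([design.X, design.X[:, -1]])
        design.columns = design.columns + ["dup"]
        with pytest.raises(np.linalg.LinAlgError):
            fit_glmm(design, outcomes_array(small_corpus))

    def test_single_cluster_rejected(self, small_corpus):
        one = [r for r in small_corpus if r.study_id == small_corpus[0].study_id]
        # intercept-only design: the forced covariate is study-level, hence constant
        design = encode_design(one, FactorSet.empty(), include_forced=False)
        with pytest.raises(ValueError, match="clusters"):
            fit_glmm(design, outcomes_array(one))

    def test_nested_deviance_monotonicity(self, small_corpus):
        outcomes = outcomes_array(small_corpus)
        refs = {"cv_technique": "single", "gene_selection": "filter"}
        full = fit_glmm(encode_design(
            small_corpus, FactorSet(("cv_technique", "gene_selection")),
            reference_levels=refs), outcomes)
        reduced = fit_glmm(encode_design(
            small_corpus, FactorSet(("cv_technique",)),
            reference_levels=refs), outcomes)
        assert full.loglik >= reduced.loglik - 1e-6


class TestLme4CrossCheck:
    def test_laplace_fit_matches_glmer(self, tmp_path):
        """Independent oracle: lme4's glmer (Laplace) on the same data.

        Checks fixed effects, the intercept variance, and the log-likelihood
        (including its constant convention) against a fully independent
        implementation of the same estimator.
        """
        import shutil
        import subprocess

        if shutil.which("Rscript") is None:
            pytest.skip("Rscript not available")
        from accmeta.study_table import write_study_table
        from accmeta.synthetic_data import SyntheticConfig, generate_study_table

        cfg = SyntheticConfig(n_studies=60,
                              beta={"intercept": 1.2, "cv_technique[nested]": 0.6},
                              sigma2=0.5, seed=55)
        records = generate_study_table(cfg)
        path = tmp_path / "corpus.csv"
        write_study_table(records, path)
        design = encode_design(records, FactorSet(("cv_technique",)),
                               reference_levels={"cv_technique": "single"})
        fit = fit_glmm(design, outcomes_array(records))

        rscript = (
            'suppressMessages(library(lme4));'
            f'd <- read.csv("{path}");'
            'd$cv_technique <- relevel(factor(d$cv_technique), ref="single");'
            'm <- glmer(cbind(n_correct, n_incorrect) ~ imbalance + cv_technique'
            ' + (1|study_id), data=d, family=binomial, nAGQ=1);'
            'cat(fixef(m), as.numeric(VarCorr(m)$study_id),'
            ' as.numeric(logLik(m)), sep="\\n")'
        )
        proc = subprocess.run(["Rscript", "-e", rscript],
                              capture_output=True, text=True, timeout=300)
        assert proc.returncode == 0, proc.stderr
        vals = [float(x) for x in proc.stdout.strip().split("\n")]
        np.testing.assert_allclose(fit.beta, vals[:3], atol=2e-3)
        assert fit.sigma2 == pytest.approx(vals[3], abs=5e-3)
        assert fit.loglik == pytest.approx(vals[4], abs=5e-3)


class TestAicAndTests:
    def test_aic_arithmetic(self, small_corpus):
        fit = fit_glmm(encode_design(small_corpus, FactorSet.empty()),
                       outcomes_array(small_corpus))
        assert fit.n_params == 3  # intercept, imbalance, sigma2
        assert aic(fit) == pytest.approx(-2 * fit.loglik + 2 * 3, abs=1e-12)
        assert fit.aic == pytest.approx(aic(fit), abs=1e-12)

    def test_lrt_identical_models(self, small_corpus):
        fit = fit_glmm(encode_design(small_corpus, FactorSet.empty()),
                       outcomes_array(small_corpus))
        res = lr_test(fit, fit)
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_lrt_chi_square_closed_form(self, small_corpus):
        outcomes = outcomes_array(small_corpus)
        refs = {"gene_selection": "filter"}
        full = fit_glmm(encode_design(small_corpus, FactorSet(("gene_selection",)),
                                      reference_levels=refs), outcomes)
        reduced = fit_glmm(encode_design(small_corpus, FactorSet.empty()), outcomes)
        res = lr_test(full, reduced)
        assert res.df == 2
        from scipy.stats import chi2
        assert res.p_value == pytest.approx(chi2.sf(res.statistic, 2), abs=1e-12)

    def test_lrt_rejects_non_nested(self, small_corpus):
        outcomes = outcomes_array(small_corpus)
        a = fit_glmm(encode_design(small_corpus, FactorSet(("cv_technique",))), outcomes)
        b = fit_glmm(encode_design(small_corpus, FactorSet(("gene_selection",))), outcomes)
        with pytest.raises(ValueError):
            lr_test(a, b)

    def test_wald_single_column_identity(self, small_corpus):
        fit = fit_glmm(encode_design(small_corpus, FactorSet(("cv_technique",))),
                       outcomes_array(small_corpus), se_method="hessian")
        col = fit.column_map["cv_technique"][0]
        res = wald_test(fit, [col])
        assert res.statistic == pytest.approx(
            (fit.beta[col] / fit.se_beta[col]) ** 2, abs=1e-10
        )
        assert res.df == 1

    def test_wald_and_lrt_agree_at_large_n(self):
        cfg = SyntheticConfig(n_studies=500, beta={"intercept": 1.0,
                                                   "cv_technique[nested]": 0.3},
                              sigma2=0.3, seed=77)
        records = generate_study_table(cfg)
        outcomes = outcomes_array(records)
        refs = {"cv_technique": "single"}
        full = fit_glmm(encode_design(records, FactorSet(("cv_technique",)),
                                      reference_levels=refs), outcomes,
                        se_method="hessian")
        reduced = fit_glmm(encode_design(records, FactorSet.empty()), outcomes)
        lrt = lr_test(full, reduced)
        wald = wald_test(full, full.column_map["cv_technique"])
        assert abs(lrt.p_value - wald.p_value) < 0.02
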