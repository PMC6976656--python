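import numpy as np
import pytest
from scipy.special import expit, logit
from scipy.stats import binom, norm

from burdenmap.glmm import (
    ModelSpec,
    build_design,
    fit,
    fit_fixed_logit,
    marginal_loglik,
    predict_linpred,
    simulate_from_fit,
)
from burdenmap.misclassification import TestAccuracy, fold
from burdenmap.survey_io import ClusterRecord


def records_for(counts, region="R1"):
    """counts: list of (y, n) pairs, all in one region."""
    return [
        ClusterRecord(f"c{i}", region, "rural", 38.0 + 0.01 * i, 9.0, 2016, n, y, 0)
        for i, (y, n) in enumerate(counts)
    ]


def brute_force_loglik(counts, eta0s, sigma, spec):
    """Independent 1-D trapezoid integration oracle for a single region."""
    z = np.linspace(-8 * sigma, 8 * sigma, 100_001)
    log_integrand = norm.logpdf(z, 0, sigma)
    for (y, n), eta0 in zip(counts, eta0s):
        mu = expit(eta0 + z)
        pi = spec.fold_floor + spec.fold_slope * mu
        log_integrand = log_integrand + binom.logpmf(y, n, pi)
    m = log_integrand.max()
    return m + np.log(np.trapezoid(np.exp(log_integrand - m), z))


class TestMarginalLoglik:
    oracle_cases = [
        # (counts, beta0, sigma, mode)
        ([(3, 10)], 0.2, 0.5, "pre_adjust"),
        ([(3, 10)], 0.2, 0.5, "embedded"),
        ([(0, 25)], -4.0, 0.3, "pre_adjust"),
        ([(1, 30), (4, 20)], -2.0, 0.8, "pre_adjust"),
        ([(1, 30), (4, 20)], -2.0, 0.8, "embedded"),
        ([(0, 25), (2, 25), (1, 40)], -3.5, 0.3, "embedded"),
        ([(5, 10), (2, 15), (9, 12)], 0.0, 1.2, "pre_adjust"),
    ]

    @pytest.mark.parametrize("counts,beta0,sigma,mode", oracle_cases)
    def test_agrees_with_brute_force_integration(self, counts, beta0, sigma, mode):
        spec = ModelSpec(mode=mode, quadrature_order=21)
        data = build_design(records_for(counts), {}, spec)
        got = marginal_loglik(np.array([beta0]), np.log(sigma), data, spec)
        want = brute_force_loglik(counts, [beta0] * len(counts), sigma, spec)
        assert got == pytest.approx(want, rel=1e-6)

    def test_sigma_zero_limit_is_plain_binomial(self):
        spec = ModelSpec(mode="pre_adjust")
        data = build_design(records_for([(3, 10), (1, 20)]), {}, spec)
        got = marginal_loglik(np.array([0.2]), -60.0, data, spec)
        want = binom.logpmf(3, 10, expit(0.2)) + binom.logpmf(1, 20, expit(0.2))
        assert got == pytest.approx(want, rel=1e-8)

    def test_embedded_with_perfect_test_equals_pre_adjust(self):
        recs = records_for([(2, 30), (5, 25)])
        pre = ModelSpec(mode="pre_adjust")
        emb = ModelSpec(mode="embedded", accuracy=TestAccuracy(1.0, 1.0))
        beta, ls = np.array([-1.5]), np.log(0.4)
        assert marginal_loglik(beta, ls, build_design(recs, {}, pre), pre) == \
            marginal_loglik(beta, ls, build_design(recs, {}, emb), emb)

    def test_quadrature_order_ladder(self, small_study, cluster_covariates):
        scenario, _, records, _ = small_study
        beta = np.array([scenario.beta0, *scenario.betas])
        lls = {}
        for q in (21, 41):
            spec = ModelSpec(covariates=scenario.covariate_names, mode="embedded",
                             quadrature_order=q)
            data = build_design(records, cluster_covariates, spec)
            lls[q] = marginal_loglik(beta, np.log(scenario.sigma), data, spec)
        assert abs(lls[21] - lls[41]) / abs(lls[41]) < 1e-6


class TestFixedLogit:
    def test_matches_statsmodels_glm(self, small_study, cluster_covariates):
        import statsmodels.api as sm

        _, _, records, _ = small_study
        y = np.array([r.n_lifetime for r in records], float)
        n = np.array([r.n_examined for r in records], float)
        v = cluster_covariates["literacy"]
        X = np.column_stack([np.ones(len(records)), v])
        spec = ModelSpec(mode="pre_adjust")
        beta, loglik, conv = fit_fixed_logit(y, n, X, spec)
        sm_fit = sm.GLM(np.column_stack([y, n - y]), X,
                        family=sm.families.Binomial()).fit()
        assert conv
        np.testing.assert_allclose(beta, sm_fit.params, atol=1e-6)
        assert loglik == pytest.approx(sm_fit.llf, rel=1e-9)


class TestFit:
    def test_closed_form_intercept_mle(self):
        spec = ModelSpec(mode="pre_adjust")
        res = fit(records_for([(25, 100)]), spec)
        assert res.sigma == 0.0  # single group: sigma fixed at the boundary
        assert res.beta[0] == pytest.approx(logit(0.25), abs=1e-6)

    def test_embedded_mle_inverts_the_fold(self):
        # with y/n inside the attainable band, fold(expit(beta0_hat)) = y/n
        spec = ModelSpec(mode="embedded")
        res = fit(records_for([(20, 1000)]), spec)
        assert fold(expit(res.beta[0]), spec.accuracy) == pytest.approx(0.02, abs=1e-6)

    def test_vcov_symmetric_psd(self, small_fit):
        result, _ = small_fit
        v = result.vcov
        np.testing.assert_allclose(v, v.T, atol=1e-12)
        assert np.all(np.linalg.eigvalsh(v) > -1e-10)
        assert result.converged
        assert len(result.region_modes) == len(result.region_ids)

    def test_matches_lme4_reference(self, small_study, cluster_covariates, tmp_path):
        """Cross-check the whole ML fit against glmer (adaptive GH, nAGQ=21)."""
        import shutil
        import subprocess

        if shutil.which("Rscript") is None:
            pytest.skip("Rscript not available")
        scenario, _, records, _ = small_study
        spec = ModelSpec(covariates=scenario.covariate_names, mode="pre_adjust")
        res = fit(records, spec, cluster_covariates)
        import csv
        with open(tmp_path / "d.csv", "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["y", "n", "region"] + list(scenario.covariate_names))
            for i, r in enumerate(records):
                w.writerow([r.n_lifetime, r.n_examined, r.region_id]
                           + [float(cluster_covariates[c][i]) for c in scenario.covariate_names])
        rscript = f"""
        suppressMessages(library(lme4))
        d <- read.csv("{tmp_path / 'd.csv'}")
        m <- glmer(cbind(y, n - y) ~ {' + '.join(scenario.covariate_names)} + (1 | region),
                   family = binomial, data = d, nAGQ = 21)
        cat(fixef(m), sqrt(unlist(VarCorr(m))), sep = "\\n")
        """
        out = subprocess.run(["Rscript", "-e", rscript], capture_output=True, text=True)
        assert out.returncode == 0, out.stderr
        ref = [float(v) for v in out.stdout.strip().splitlines()]
        np.testing.assert_allclose(res.beta, ref[:-1], atol=2e-3)
        assert res.sigma == pytest.approx(ref[-1], abs=5e-3)


class TestSimulateFromFit:
    def test_deterministic_given_seed(self, small_fit):
        result, data = small_fit
        a = simulate_from_fit(result, data, n_sims=5, seed=42)
        b = simulate_from_fit(result, data, n_sims=5, seed=42)
        np.testing.assert_array_equal(a, b)
        assert a.shape == (5, result.n_clusters)

    def test_zero_prevalence_gives_zero_counts(self):
        spec = ModelSpec(mode="pre_adjust")
        res = fit(records_for([(0, 50), (0, 40)]), spec)
        data = build_design(records_for([(0, 50), (0, 40)]), {}, spec)
        sims = simulate_from_fit(res, data, n_sims=20, seed=0, force=True)
        assert sims.max() <= 1  # MLE prevalence ~0; counts essentially never positive

    def test_replicate_mean_matches_fitted_expectation(self, small_fit):
        result, data = small_fit
        sims = simulate_from_fit(result, data, n_sims=500, seed=3)
        totals = sims.sum(axis=1)
        # observed total should match the fitted expectation within MC noise
        assert abs(totals.mean() - np.median(totals)) < 3 * totals.std() / np.sqrt(500)


class TestPredictLinpred:
    def test_intercept_only_prediction(self):
        spec = ModelSpec(mode="pre_adjust")
        res = fit(records_for([(25, 100)]), spec)
        eta, var = predict_linpred(res, {})
        assert eta[0] == pytest.approx(res.beta[0])
        assert var[0] == pytest.approx(res.vcov_beta[0, 0] + res.sigma**2)

    def test_delta_method_quadratic_form(self, small_fit):
        result, _ = small_fit
        point = {n: 0.3 for n in result.spec.covariates}
        eta, var = predict_linpred(result, point)
        x = np.array([1.0] + [0.3] * len(result.spec.covariates))
        assert eta[0] == pytest.approx(float(x @ result.beta))
        assert var[0] == pytest.approx(
            float(x @ result.vcov_beta @ x) + result.sigma**2)

    def test_unknown_covariate_rejected(self, small_fit):
        result, _ = small_fit
        with pytest.raises(KeyError):
            predict_linpred(result, {"nope": 1.0})
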