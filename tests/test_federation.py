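"""Aggregation, the ridged Newton step, fitting drivers, and the penalty sweep."""

import math

import numpy as np
import pytest
from scipy.optimize import minimize

from fedglmm.exceptions import InputError, ProtocolError
from fedglmm.federation import (
    Aggregates,
    FederationConfig,
    aggregate,
    fit_pooled,
    lambda_sweep,
    newton_step,
    run_federated_fit,
)
from fedglmm.model_core import SiteData, Theta, empty_site
from fedglmm.quadrature import gh_rule
from fedglmm.site_engine import site_loglik, site_summary
from fedglmm.simulate import generate_study, preset

from conftest import random_site, random_theta


def _summaries(sites, theta, K=2, lam=0.0):
    rule = gh_rule(K)
    return [site_summary(s, theta, rule, lam=lam) for s in sites]


class TestAggregate:
    def test_single_summary_is_identity(self, rng):
        [s] = _summaries([random_site(rng, n=8, p=3)], random_theta(rng, 3))
        agg = aggregate([s])
        assert agg.loglik == s.loglik and agg.score_tau == s.score_tau
        np.testing.assert_array_equal(agg.score_beta, s.score_beta)

    def test_duplication_scales_linearly(self, rng):
        [s] = _summaries([random_site(rng, n=8, p=3)], random_theta(rng, 3))
        agg = aggregate([s] * 4)
        assert agg.loglik == pytest.approx(4 * s.loglik, rel=1e-12)
        np.testing.assert_allclose(agg.score_beta, 4 * s.score_beta, rtol=1e-12)
        np.testing.assert_allclose(agg.hess_beta, 4 * s.hess_beta, rtol=1e-12)

    def test_matches_independent_summation(self, rng):
        theta = random_theta(rng, 3)
        summaries = _summaries([random_site(rng, n=6, p=3, site_id=f"s{i}") for i in range(10)], theta)
        agg = aggregate(summaries)
        # independent oracle: stack and reduce in one shot
        np.testing.assert_allclose(
            agg.score_beta, np.stack([s.score_beta for s in summaries]).sum(0), rtol=1e-13
        )
        np.testing.assert_allclose(
            agg.hess_beta, np.stack([s.hess_beta for s in summaries]).sum(0), rtol=1e-13
        )
        assert agg.loglik == pytest.approx(math.fsum(s.loglik for s in summaries), rel=1e-13)
        assert agg.score_tau == pytest.approx(math.fsum(s.score_tau for s in summaries), rel=1e-13)

    def test_mismatched_protocol_named(self, rng):
        theta = random_theta(rng, 3)
        a = _summaries([random_site(rng, n=6, p=3, site_id="a")], theta)[0]
        b = _summaries([random_site(rng, n=6, p=3, site_id="b")], theta, K=3)[0]
        with pytest.raises(ProtocolError, match="b"):
            aggregate([a, b])

    def test_empty_list_rejected(self):
        with pytest.raises(InputError):
            aggregate([])


class TestNewtonStep:
    def _config(self, **kw):
        return FederationConfig(method="gh", K=2, fix_tau=kw.pop("fix_tau", 1.0), **kw)

    def test_quadratic_objective_one_step(self):
        # f(beta) = -(beta - b*)' A (beta - b*) / 2: Newton lands exactly on b*
        A = np.array([[2.0, 0.3], [0.3, 1.0]])
        b_star = np.array([1.5, -0.7])
        theta = Theta(np.zeros(2), 1.0)

        def f(th):
            d = th.beta - b_star
            return -0.5 * d @ A @ d

        agg = Aggregates(loglik=f(theta), score_beta=A @ b_star, hess_beta=-A, score_tau=0.0)
        new, info = newton_step(theta, agg, self._config(), f)
        np.testing.assert_allclose(new.beta, b_star, atol=1e-12)
        assert info["ridge_delta"] == 0.0 and not info["stalled"]

    def test_rank_deficient_hessian_engages_ridge(self):
        # duplicated direction: H has a zero eigenvalue; step must stay finite
        H = -np.array([[1.0, 1.0], [1.0, 1.0]])
        s = np.array([0.5, 0.5])
        theta = Theta(np.zeros(2), 1.0)

        def f(th):  # concave along (1,1), flat along (1,-1)
            v = th.beta.sum() / 2
            return -0.5 * 2 * (v - 0.25) ** 2

        agg = Aggregates(loglik=f(theta), score_beta=s, hess_beta=H, score_tau=0.0)
        new, info = newton_step(theta, agg, self._config(), f)
        assert np.isfinite(new.beta).all()
        assert info["ridge_delta"] > 0.0
        assert f(new) >= f(theta) - 1e-12

    def test_matches_independent_optimizer(self, rng):
        sites = [random_site(rng, n=25, p=3, site_id=f"s{i}") for i in range(3)]
        config = FederationConfig(method="gh", K=2, conv_tol=1e-9, max_rounds=500)
        fit = run_federated_fit(sites, config, lam=0.0)
        rule = config.rule()

        def negll(x):
            th = Theta(x[:-1], math.exp(x[-1]))
            return -sum(site_loglik(s, th, rule) for s in sites)

        res = minimize(negll, np.zeros(4), method="BFGS", options={"gtol": 1e-9, "maxiter": 2000})
        np.testing.assert_allclose(fit.beta_hat, res.x[:-1], atol=1e-6)
        assert fit.tau_hat == pytest.approx(math.exp(res.x[-1]), abs=1e-5)


class TestFitDrivers:
    def test_federated_equals_pooled(self, rng):
        design = preset(5, n_per_site=40, seed=9)
        study = generate_study(design)
        config = FederationConfig(method="gh", K=2)
        fed = run_federated_fit(study.train_sites, config, lam=1.0)
        pooled = fit_pooled(study.train_sites, config, lam=1.0)
        np.testing.assert_allclose(fed.beta_hat, pooled.beta_hat, atol=1e-8)
        assert fed.tau_hat == pytest.approx(pooled.tau_hat, abs=1e-8)
        assert fed.loglik == pytest.approx(pooled.loglik, abs=1e-8)

    def test_all_empty_sites_converges_immediately(self):
        sites = [empty_site(2, f"e{i}") for i in range(3)]
        fit = run_federated_fit(sites, FederationConfig(method="la"), lam=0.0)
        assert fit.converged and fit.rounds == 1
        assert fit.loglik == pytest.approx(0.0, abs=1e-10)

    def test_site_order_permutation_invariance(self, rng):
        sites = [random_site(rng, n=20, p=3, site_id=f"s{i}") for i in range(4)]
        config = FederationConfig(method="gh", K=2)
        f1 = run_federated_fit(sites, config)
        f2 = run_federated_fit(sites[::-1], config)
        np.testing.assert_allclose(f1.beta_hat, f2.beta_hat, atol=1e-9)
        assert f1.tau_hat == pytest.approx(f2.tau_hat, abs=1e-9)

    def test_monotone_ascent_of_total_loglik(self, rng):
        design = preset(7, seed=21)
        study = generate_study(design)
        fit = run_federated_fit(study.train_sites, FederationConfig(method="gh", K=2))
        lls = [rec["loglik"] for rec in fit.trace]
        assert all(b >= a - 1e-9 for a, b in zip(lls, lls[1:]))

    def test_large_fixed_tau_matches_plain_logistic(self, rng):
        # one site, tau frozen huge: the random intercept is essentially free,
        # so beta should agree with a plain logistic fit within sampling error
        import statsmodels.api as sm

        n, p = 400, 4
        X = np.column_stack([np.ones(n), rng.normal(size=(n, p - 1))])
        beta_true = np.array([-0.4, 0.9, 0.0, -0.6])
        y = (rng.random(n) < 1 / (1 + np.exp(-(X @ beta_true)))).astype(float)
        site = SiteData("s", X, y)
        config = FederationConfig(method="la", fix_tau=100.0, conv_tol=1e-6)
        fit = run_federated_fit([site], config)
        glm = sm.Logit(y, X).fit(disp=0)
        se = glm.bse
        assert (np.abs(fit.beta_hat - glm.params) <= 2 * se).all()

    def test_empty_input_is_error(self):
        with pytest.raises(InputError):
            fit_pooled([], FederationConfig())

    def test_nonconvergence_reported_not_raised(self, rng):
        design = preset(5, n_per_site=40, seed=2)
        study = generate_study(design)
        fit = run_federated_fit(
            study.train_sites, FederationConfig(method="gh", K=2, max_rounds=2)
        )
        assert not fit.converged and fit.rounds == 2


class TestAgainstLme4:
    def test_laplace_fit_matches_glmer(self, tmp_path):
        # external cross-check: lme4's glmer maximizes the same Laplace
        # objective; estimates should agree to a few 1e-3
        import subprocess

        from fedglmm.io import write_sites

        design = preset(4, n_per_site=60, seed=7)
        study = generate_study(design)
        config = FederationConfig(method="la", conv_tol=1e-6, max_rounds=400)
        fit = fit_pooled(study.full_sites, config)
        csv = tmp_path / "d.csv"
        write_sites(study.full_sites, csv)
        rscript = (
            f'd <- read.csv("{csv}"); suppressMessages(library(lme4)); '
            "m <- glmer(y ~ x1+x2+x3+x4+x5+x6+x7+x8+x9+x10 + (1|site_id), "
            "data=d, family=binomial, nAGQ=1); "
            'cat(fixef(m), "\\n"); cat(as.numeric(VarCorr(m)$site_id), "\\n"); '
            'cat(logLik(m), "\\n")'
        )
        out = subprocess.run(
            ["Rscript", "-e", rscript], capture_output=True, text=True, timeout=600, check=True
        )
        lines = [l for l in out.stdout.strip().splitlines() if l.strip()]
        fixef = np.array([float(v) for v in lines[-3].split()])
        tau = float(lines[-2])
        loglik = float(lines[-1])
        np.testing.assert_allclose(fit.beta_hat, fixef, atol=5e-3)
        assert fit.tau_hat == pytest.approx(tau, abs=5e-3)
        assert fit.loglik == pytest.approx(loglik, abs=0.01)


class TestLambdaSweep:
    def test_singleton_grid_is_plain_fit(self, rng):
        design = preset(5, n_per_site=40, seed=4)
        study = generate_study(design)
        config = FederationConfig(method="gh", K=2, lambda_grid=(0.0,))
        lam_opt, fit, table = lambda_sweep(study.train_sites, study.valid_sites, config)
        assert lam_opt == 0.0 and len(table) == 1
        plain = run_federated_fit(study.train_sites, config, lam=0.0)
        np.testing.assert_allclose(fit.beta_hat, plain.beta_hat, atol=1e-12)

    def test_optimum_attains_best_validation_score(self, rng):
        design = preset(5, n_per_site=40, seed=4)
        study = generate_study(design)
        config = FederationConfig(method="gh", K=2, lambda_grid=(0.0, 2.0, 5.0))
        lam_opt, fit, table = lambda_sweep(study.train_sites, study.valid_sites, config)
        best = max(row["score"] for row in table)
        chosen = [row for row in table if row["lambda"] == lam_opt]
        assert chosen and chosen[0]["score"] == best
        assert fit.lambda_opt == lam_opt

    def test_regularization_can_help_when_overfit_prone(self):
        # p = 11 with only 30 patients/site: some lambda > 0 should match or
        # beat the unpenalized fit on held-out data
        design = preset(7, seed=6)
        study = generate_study(design)
        config = FederationConfig(method="gh", K=2, lambda_grid=tuple(float(v) for v in range(11)))
        lam_opt, _, table = lambda_sweep(study.train_sites, study.valid_sites, config)
        score = {row["lambda"]: row["score"] for row in table}
        assert max(score.values()) >= score[0.0]
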