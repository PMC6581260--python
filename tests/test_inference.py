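"""Group-level inference: t-test marginal, predictive, exceedance."""

import math

import numpy as np
import pytest
from scipy import stats as sps

import hbinfer as hb
from hbinfer.hbi import (GroupPosterior, HBIFit, HBIOptions, PriorConfig,
                         SubjectPosteriors, SummaryStats)
from hbinfer.models import ModelSpec

from conftest import gaussian_toy_model, toy_subject


def _fit_with_group(models, a, beta, sigma, nu, alpha):
    K = len(models)
    g = GroupPosterior(a=[np.atleast_1d(np.asarray(x, float)) for x in a],
                       beta=np.asarray(beta, float),
                       sigma=[np.atleast_1d(np.asarray(x, float))
                              for x in sigma],
                       nu=np.asarray(nu, float),
                       alpha=np.asarray(alpha, float))
    subs = SubjectPosteriors(theta=[np.zeros((1, m.D)) for m in models],
                             A=[np.ones((1, m.D, m.D)) for m in models],
                             log_f=np.zeros((K, 1)), r=np.full((K, 1), 1 / K))
    stats = SummaryStats(Nbar=np.ones(K), theta_bar=[np.zeros(m.D)
                                                     for m in models],
                         V_bar=[np.eye(m.D) for m in models])
    return HBIFit(models=models, group=g, subjects=subs, stats=stats,
                  model_frequency=np.full(K, 1 / K), L=0.0)


class TestHBITTest:
    def test_centered_null(self):
        toy = gaussian_toy_model()
        fit = _fit_with_group([toy], a=[0.8], beta=[3.0], sigma=[2.0],
                              nu=[2.5], alpha=[4.0])
        res = hb.hbi_ttest(fit, 0, 0, null_value=0.8)
        assert res.t == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)
        lo, hi = res.credible_interval
        assert lo < 0.8 < hi

    def test_dof_equals_one_plus_nbar(self):
        # full responsibility on one model, default v = 1/2
        spec = hb.get_model("rl")
        task = hb.generate_task("bandit2", 50, seed=2)
        data = [hb.simulate_agent(spec, [-0.5, 1.0], task, seed=i)
                for i in range(8)]
        fit = hb.run_hbi(data, [spec],
                         options=HBIOptions(seed=0, compute_pxp=False))
        res = hb.hbi_ttest(fit, 0, 0)
        assert res.dof == pytest.approx(1 + len(data), abs=1e-9)

    def test_tail_matches_gaussian_gamma_monte_carlo(self):
        # marginal of N(a, (beta*tau)^-1) x Gamma(nu, sigma) is Student;
        # check the two-sided tail against 10^6 MC draws
        a, beta, sigma, nu = 0.3, 5.0, 1.4, 3.0
        toy = gaussian_toy_model()
        fit = _fit_with_group([toy], a=[a], beta=[beta], sigma=[sigma],
                              nu=[nu], alpha=[2.0])
        res = hb.hbi_ttest(fit, 0, 0, null_value=0.0)
        rng = np.random.default_rng(10)
        n = 1_000_000
        tau = rng.gamma(nu, 1.0 / sigma, size=n)
        mu = rng.normal(a, 1.0 / np.sqrt(beta * tau))
        # two-sided: P(|mu - a| >= |0 - a|)
        mc = np.mean(np.abs(mu - a) >= abs(a))
        se = math.sqrt(mc * (1 - mc) / n)
        assert abs(res.p - mc) < 3 * se


class TestPredictive:
    def test_flat_likelihood_returns_center(self):
        flat = ModelSpec("flat", "bandit2", ("m",), ("identity",),
                         lambda th, d: 0.0, None)
        fit = _fit_with_group([flat], a=[0.9], beta=[2.0], sigma=[1.0],
                              nu=[1.5], alpha=[2.0])
        res = hb.fit_new_subject(fit, 0, toy_subject(0.0))
        assert res.theta_star[0] == pytest.approx(0.9, abs=1e-5)

    def test_matches_grid_maximization(self):
        # 1-D Bernoulli likelihood; compare to a dense grid over Eq's
        # Student-prior MAP objective
        k, n = 14, 20

        def ll(th, d):
            from scipy.special import expit
            return float(k * np.log(expit(th[0]))
                         + (n - k) * np.log(expit(-th[0])))

        bern = ModelSpec("bern", "bandit2", ("h",), ("identity",), ll, None)
        a, beta, sigma, nu = 0.1, 3.0, 1.2, 2.0
        fit = _fit_with_group([bern], a=[a], beta=[beta], sigma=[sigma],
                              nu=[nu], alpha=[2.0])
        res = hb.fit_new_subject(fit, 0, toy_subject(0.0))
        s = math.sqrt(2 * sigma / beta)
        g = np.linspace(-4, 4, 160001)
        obj = (np.array([ll([x], None) for x in g])
               + sps.t.logpdf((g - a) / s, df=2 * nu) - math.log(s))
        assert res.theta_star[0] == pytest.approx(g[np.argmax(obj)], abs=1e-4)

    def test_student_tends_to_gaussian_map(self):
        k, n = 30, 40

        def ll(th, d):
            from scipy.special import expit
            return float(k * np.log(expit(th[0]))
                         + (n - k) * np.log(expit(-th[0])))

        bern = ModelSpec("bern", "bandit2", ("h",), ("identity",), ll, None)
        # large dof: nu = 5000 -> n_k = 10^4
        a, beta, sigma, nu = 0.0, 2.0, 1.0, 5000.0
        fit = _fit_with_group([bern], a=[a], beta=[beta], sigma=[sigma],
                              nu=[nu], alpha=[2.0])
        res = hb.fit_new_subject(fit, 0, toy_subject(0.0))
        s2 = 2 * sigma / beta
        gauss = hb.fit_map_laplace(lambda h: ll(h, None), [a], [1.0 / s2],
                                   n_restarts=1, seed=0)
        assert abs(res.theta_star[0] - gauss.theta[0]) < 1e-3


class TestExceedance:
    def test_symmetric_prior(self):
        assert np.allclose(hb.exceedance_probabilities([1.0, 1.0]),
                           [0.5, 0.5])

    def test_k2_beta_closed_form_and_mc(self):
        # P(Beta(3,1) > 0.5) = 1 - 0.5^3 = 0.875 (exact path)
        phi = hb.exceedance_probabilities([3.0, 1.0])
        assert phi[0] == pytest.approx(0.875, abs=1e-12)
        # independent Dirichlet Monte-Carlo of the same quantity
        rng = np.random.default_rng(0)
        n = 200_000
        draws = rng.dirichlet([3.0, 1.0], size=n)
        mc = np.mean(draws[:, 0] > 0.5)
        se = math.sqrt(mc * (1 - mc) / n)
        assert abs(phi[0] - mc) < 3 * se

    def test_k3_normalization_and_ordering(self):
        phi = hb.exceedance_probabilities([10.0, 1.0, 1.0],
                                          n_samples=200_000, seed=1)
        assert phi.sum() == pytest.approx(1.0, abs=1e-12)
        assert phi[0] == phi.max()

    def test_invalid_alpha(self):
        with pytest.raises(ValueError):
            hb.exceedance_probabilities([1.0, -0.5])


class TestProtectedExceedance:
    def test_equal_bounds_give_half(self):
        pxp, P0 = hb.protected_exceedance([0.9, 0.1], L=-100.0, L0=-100.0)
        assert P0 == pytest.approx(0.5)
        assert np.allclose(pxp, [0.9 * 0.5 + 0.25, 0.1 * 0.5 + 0.25])

    def test_null_limit_uniform(self):
        pxp, P0 = hb.protected_exceedance([0.99, 0.01], L=-500.0, L0=-100.0)
        assert P0 == pytest.approx(1.0, abs=1e-12)
        assert np.allclose(pxp, 0.5, atol=1e-10)

    def test_large_advantage(self):
        phi = np.array([0.8, 0.2])
        pxp, P0 = hb.protected_exceedance(phi, L=20.0, L0=0.0)
        assert P0 == pytest.approx(1.0 / (1.0 + math.exp(20.0)), rel=1e-9)
        assert np.allclose(pxp, phi, atol=1e-8)

    def test_convex_combination_preserves_order(self):
        phi = np.array([0.7, 0.2, 0.1])
        pxp, P0 = hb.protected_exceedance(phi, L=1.0, L0=0.0)
        assert np.all(np.argsort(pxp) == np.argsort(phi))
        assert pxp.sum() == pytest.approx(1.0)


class TestNullHBI:
    def test_null_run_beats_alternative_only_rarely(self):
        # data generated entirely by one of two distinct models: the
        # alternative bound should exceed the null bound in nearly all
        # seeded runs
        rl = hb.get_model("rl")
        kal = hb.get_model("kalman")
        wins = 0
        n_runs = 4
        for run in range(n_runs):
            task = hb.generate_task("bandit2", 80, seed=100 + run)
            data = [hb.simulate_agent(kal, [0.0, 1.4], task, seed=10 * run + i)
                    for i in range(12)]
            opts = HBIOptions(seed=run, compute_pxp=False)
            fit = hb.run_hbi(data, [rl, kal], options=opts)
            null = hb.run_null_hbi(data, [rl, kal], options=opts)
            wins += fit.L > null.L
        assert wins >= n_runs - 1

    def test_null_pins_frequency_term(self):
        from hbinfer.hbi import _log_rho
        toy = [gaussian_toy_model(4.0, "t0"), gaussian_toy_model(4.0, "t1")]
        g = GroupPosterior(a=[np.zeros(1)] * 2, beta=np.array([2.0, 9.0]),
                           sigma=[np.ones(1)] * 2, nu=np.array([1.0, 4.0]),
                           alpha=np.array([1.0, 11.0]))
        subs = SubjectPosteriors(theta=[np.zeros((1, 1))] * 2,
                                 A=[np.ones((1, 1, 1))] * 2,
                                 log_f=np.zeros((2, 1)),
                                 r=np.full((2, 1), 0.5))
        with_m = _log_rho(subs, g, toy, null_frequencies=False)
        without = _log_rho(subs, g, toy, null_frequencies=True)
        from scipy.special import digamma
        e_log_m = digamma(g.alpha) - digamma(g.alpha.sum())
        assert np.allclose(with_m - without,
                           (e_log_m + math.log(2))[:, None], atol=1e-12)
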