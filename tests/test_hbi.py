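"""HBI algorithm steps against hand-arithmetic and conjugate oracles."""

import math

import numpy as np
import pytest
from scipy.special import digamma, gammaln

import hbinfer as hb
from hbinfer.hbi import (GroupPosterior, HBIOptions, PriorConfig,
                         SubjectPosteriors, SummaryStats, check_convergence,
                         compute_lower_bound, compute_summary_stats,
                         initialize, update_group_posterior,
                         update_responsibilities, update_subject_posteriors)
from hbinfer.models import ModelSpec

from conftest import gaussian_toy_model, toy_subject

# frozen digamma values used by the independent responsibility oracle
PSI = {2: 0.4227843350984671, 3: 0.9227843350984671, 5: 1.5061176684318005}


def _toy_models(k, prec=4.0):
    return [gaussian_toy_model(prec, f"toy{i}") for i in range(k)]


class TestSummaryStats:
    def test_hand_case(self):
        # model 0: r=(0.25, 0.75), theta=(1, 3), A^-1=(1, 1)
        models = _toy_models(2)
        subs = SubjectPosteriors(
            theta=[np.array([[1.0], [3.0]]), np.array([[0.0], [0.0]])],
            A=[np.ones((2, 1, 1)), np.ones((2, 1, 1))],
            log_f=np.zeros((2, 2)),
            r=np.array([[0.25, 0.75], [0.75, 0.25]]),
        )
        stats = compute_summary_stats(subs, models, PriorConfig())
        assert stats.Nbar[0] == pytest.approx(1.0)
        assert stats.theta_bar[0][0] == pytest.approx(2.5)
        # 0.25*(1 - 6.25 + 1) + 0.75*(9 - 6.25 + 1) = 1.75
        assert stats.V_bar[0][0, 0] == pytest.approx(1.75)

    def test_unweighted_limit_and_conservation(self):
        rng = np.random.default_rng(0)
        models = _toy_models(2)
        N = 5
        th = [rng.normal(size=(N, 1)), rng.normal(size=(N, 1))]
        A = [np.full((N, 1, 1), 2.0), np.full((N, 1, 1), 2.0)]
        r = rng.dirichlet((1, 1), size=N).T
        subs = SubjectPosteriors(theta=th, A=A, log_f=np.zeros((2, N)), r=r)
        stats = compute_summary_stats(subs, models, PriorConfig())
        assert stats.Nbar.sum() == pytest.approx(N)
        # all responsibility on model 0
        subs.r = np.vstack([np.ones(N), np.zeros(N)])
        stats = compute_summary_stats(subs, models, PriorConfig())
        assert stats.Nbar[0] == pytest.approx(N)
        assert np.allclose(stats.theta_bar[0], th[0].mean(axis=0))


class TestGroupUpdate:
    def test_hand_case(self):
        # b=1, a0=0, Nbar=2, theta_bar=3, V_bar=4:
        # a = 2*3/3 = 2 ; sigma = 0.01 + (2*4 + (2/3)*9)/2 = 7.01
        models = _toy_models(1)
        stats = SummaryStats(Nbar=np.array([2.0]),
                             theta_bar=[np.array([3.0])],
                             V_bar=[np.array([[4.0]])])
        g = update_group_posterior(stats, PriorConfig(), models)
        assert g.a[0][0] == pytest.approx(2.0)
        assert g.sigma[0][0] == pytest.approx(7.01)
        assert g.beta[0] == pytest.approx(3.0)
        assert g.nu[0] == pytest.approx(1.5)
        assert g.alpha[0] == pytest.approx(3.0)

    def test_no_data_reverts_to_prior(self):
        models = _toy_models(1)
        prior = PriorConfig()
        stats = SummaryStats(Nbar=np.array([0.0]),
                             theta_bar=[np.array([0.0])],
                             V_bar=[np.array([[1.0]])])
        g = update_group_posterior(stats, prior, models)
        assert g.a[0][0] == pytest.approx(prior.a0)
        assert g.beta[0] == pytest.approx(prior.b)
        assert g.nu[0] == pytest.approx(prior.v)
        assert g.alpha[0] == pytest.approx(prior.alpha0)
        assert g.sigma[0][0] == pytest.approx(prior.s)

    def test_degrees_of_freedom_identity(self):
        # with v = 1/2 the Student dof is 1 + Nbar
        models = _toy_models(1)
        for nbar in (0.0, 3.2, 17.0):
            stats = SummaryStats(Nbar=np.array([nbar]),
                                 theta_bar=[np.array([0.0])],
                                 V_bar=[np.array([[1.0]])])
            g = update_group_posterior(stats, PriorConfig(), models)
            assert 2 * g.nu[0] == pytest.approx(1 + nbar)

    def test_weighted_average_property(self):
        # a_k is the responsibility-weighted average of theta shrunk
        # toward a0 with weight b, from raw responsibilities
        rng = np.random.default_rng(3)
        models = _toy_models(2)
        N = 7
        th = [rng.normal(size=(N, 1)), rng.normal(size=(N, 1))]
        A = [np.full((N, 1, 1), 3.0)] * 2
        r = rng.dirichlet((1, 1), size=N).T
        subs = SubjectPosteriors(theta=th, A=A, log_f=np.zeros((2, N)), r=r)
        prior = PriorConfig(a0=0.4, b=1.7)
        stats = compute_summary_stats(subs, models, prior)
        g = update_group_posterior(stats, prior, models)
        for k in range(2):
            expect = (prior.b * 0.4 + np.sum(r[k] * th[k][:, 0])) \
                / (prior.b + r[k].sum())
            assert g.a[k][0] == pytest.approx(expect, abs=1e-12)


class TestSubjectUpdate:
    def test_flat_likelihood_returns_group_prior(self):
        flat = ModelSpec("flat", "bandit2", ("m",), ("identity",),
                         lambda th, d: 0.0, None)
        g = GroupPosterior(a=[np.array([0.7])], beta=np.array([4.0]),
                           sigma=[np.array([2.0])], nu=np.array([5.0]),
                           alpha=np.array([3.0]))
        subs = update_subject_posteriors([toy_subject(0.0)], [flat], g)
        assert subs.theta[0][0, 0] == pytest.approx(0.7, abs=1e-5)
        # A = E[T] = nu / sigma
        assert subs.A[0][0, 0, 0] == pytest.approx(5.0 / 2.0, rel=1e-3)

    def test_quadratic_likelihood_conjugate(self):
        toy = gaussian_toy_model(prec_lik=4.0)
        g = GroupPosterior(a=[np.array([0.0])], beta=np.array([2.0]),
                           sigma=[np.array([1.0])], nu=np.array([1.0]),
                           alpha=np.array([1.0]))
        # prior precision nu/sigma = 1; likelihood N(2, prec 4)
        subs = update_subject_posteriors([toy_subject(2.0)], [toy], g)
        assert subs.theta[0][0, 0] == pytest.approx(8.0 / 5.0, abs=1e-6)
        assert subs.A[0][0, 0, 0] == pytest.approx(5.0, rel=1e-3)


class TestResponsibilities:
    def test_single_model_and_symmetry(self):
        models = _toy_models(1)
        g = GroupPosterior(a=[np.zeros(1)], beta=np.array([2.0]),
                           sigma=[np.ones(1)], nu=np.array([1.0]),
                           alpha=np.array([2.0]))
        subs = SubjectPosteriors(theta=[np.zeros((3, 1))],
                                 A=[np.ones((3, 1, 1))],
                                 log_f=np.zeros((1, 3)),
                                 r=np.ones((1, 3)))
        out = update_responsibilities(subs, g, models)
        assert np.allclose(out.r, 1.0)

        models4 = _toy_models(4)
        g4 = GroupPosterior(a=[np.zeros(1)] * 4, beta=np.full(4, 2.0),
                            sigma=[np.ones(1)] * 4, nu=np.full(4, 1.5),
                            alpha=np.full(4, 2.0))
        subs4 = SubjectPosteriors(theta=[np.zeros((2, 1))] * 4,
                                  A=[np.ones((2, 1, 1))] * 4,
                                  log_f=np.full((4, 2), -7.0),
                                  r=np.full((4, 2), 0.25))
        out4 = update_responsibilities(subs4, g4, models4)
        assert np.allclose(out4.r, 0.25, atol=1e-12)

    def test_hand_case_with_frozen_digamma(self):
        # K=2, D=1, one subject; independent evaluation with tabulated
        # digamma values
        models = _toy_models(2)
        f = np.array([-10.0, -12.0])
        A = np.array([2.0, 3.0])
        nu = np.array([2.0, 3.0])
        beta = np.array([3.0, 4.0])
        alpha = np.array([2.0, 3.0])
        g = GroupPosterior(a=[np.zeros(1)] * 2, beta=beta,
                           sigma=[np.ones(1)] * 2, nu=nu, alpha=alpha)
        subs = SubjectPosteriors(
            theta=[np.zeros((1, 1))] * 2,
            A=[A[0] * np.ones((1, 1, 1)), A[1] * np.ones((1, 1, 1))],
            log_f=f[:, None], r=np.full((2, 1), 0.5))
        out = update_responsibilities(subs, g, models)

        log_rho = np.empty(2)
        for k, nu_int in enumerate((2, 3)):
            lam = 0.5 * (PSI[nu_int] - math.log(nu[k]) - 1.0 / beta[k])
            elogm = PSI[int(alpha[k])] - PSI[5]
            log_rho[k] = (f[k] + 0.5 * math.log(2 * math.pi)
                          - 0.5 * math.log(A[k]) + lam + elogm)
        expect = np.exp(log_rho - log_rho.max())
        expect /= expect.sum()
        assert np.allclose(out.r[:, 0], expect, atol=1e-10)

    def test_degenerate_subject_raises(self):
        models = _toy_models(2)
        g = GroupPosterior(a=[np.zeros(1)] * 2, beta=np.full(2, 2.0),
                           sigma=[np.ones(1)] * 2, nu=np.full(2, 1.0),
                           alpha=np.full(2, 1.0))
        subs = SubjectPosteriors(theta=[np.zeros((1, 1))] * 2,
                                 A=[np.ones((1, 1, 1))] * 2,
                                 log_f=np.full((2, 1), -np.inf),
                                 r=np.full((2, 1), 0.5))
        with pytest.raises(RuntimeError):
            update_responsibilities(subs, g, models)


class TestConvergence:
    def test_fixed_point(self):
        trace = [[np.array([1.3])], [np.array([1.3])]]
        conv, hit, d = check_convergence(trace, 2)
        assert conv and d == 0.0

    def test_boundary_is_strict(self):
        # theta-hat moving 1.0 -> 1.1 gives d-hat = 0.01 exactly: not
        # converged under the strict inequality
        trace = [[np.array([1.0])], [np.array([1.1])]]
        conv, hit, d = check_convergence(trace, 2)
        assert d == pytest.approx(0.01)
        assert not conv

    def test_max_iteration_flag(self):
        trace = [[np.array([0.0])], [np.array([5.0])]]
        conv, hit, d = check_convergence(trace, 50)
        assert not conv and hit


class TestRunHBI:
    def test_conjugate_toy_bound_matches_independent_assembly(self):
        # K=1 Gaussian toy where the Laplace step is exact: the lower
        # bound must equal a term-by-term analytic assembly of
        # E_q[log p] - E_q[log q]
        P_L = 4.0
        toy = gaussian_toy_model(P_L)
        data = [toy_subject(x) for x in (0.8, 1.6, 2.1)]
        prior = PriorConfig()
        fit = hb.run_hbi(data, [toy], prior,
                         HBIOptions(seed=0, compute_pxp=False,
                                    init_restarts=1))
        dL = np.diff(fit.trace["L"])
        assert np.all(dL > -1e-8)  # VB monotonicity (exact-Laplace regime)

        g, s = fit.group, fit.subjects
        a, beta = g.a[0][0], g.beta[0]
        sig, nu = g.sigma[0][0], g.nu[0]
        L = 0.0
        for n, d in enumerate(data):
            th, A = s.theta[0][n, 0], s.A[0][n, 0, 0]
            x = d.outcomes[0]
            L += (-0.5 * math.log(2 * math.pi / P_L)
                  - 0.5 * P_L * ((x - th) ** 2 + 1 / A))
            L += (-0.5 * math.log(2 * math.pi)
                  + 0.5 * (digamma(nu) - math.log(sig))
                  - 0.5 * (nu / sig) * ((th - a) ** 2 + 1 / A) - 0.5 / beta)
            L += 0.5 * (1 + math.log(2 * math.pi)) - 0.5 * math.log(A)
        b, v, s0 = prior.b, prior.v, prior.s
        L += (-0.5 * math.log(2 * math.pi)
              + 0.5 * (math.log(b) + digamma(nu) - math.log(sig))
              - 0.5 * b * ((nu / sig) * a ** 2 + 1 / beta))
        L += (v * math.log(s0) - gammaln(v)
              + (v - 1) * (digamma(nu) - math.log(sig)) - s0 * nu / sig)
        L += (0.5 * math.log(2 * math.pi) + 0.5
              - 0.5 * (math.log(beta) + digamma(nu) - math.log(sig)))
        L += nu - math.log(sig) + gammaln(nu) + (1 - nu) * digamma(nu)
        assert fit.L == pytest.approx(L, abs=1e-6)

    def test_duplicate_models_split_evenly(self):
        spec = hb.get_model("rl")
        task = hb.generate_task("bandit2", 40, seed=3)
        data = [hb.simulate_agent(spec, [-0.5, 1.0], task, seed=i)
                for i in range(6)]
        twin = hb.get_model("rl")
        fit = hb.run_hbi(data, [spec, twin],
                         options=HBIOptions(seed=1, compute_pxp=False))
        assert np.allclose(fit.subjects.r, 0.5, atol=0.02)
        assert np.allclose(fit.model_frequency, 0.5, atol=0.02)

    def test_responsibility_and_frequency_normalization(self):
        toy = _toy_models(2)
        data = [toy_subject(x) for x in (0.0, 0.5, 2.0, -1.0)]
        fit = hb.run_hbi(data, toy,
                         options=HBIOptions(seed=0, compute_pxp=False,
                                            init_restarts=1))
        assert np.allclose(fit.subjects.r.sum(axis=0), 1.0, atol=1e-9)
        assert fit.stats.Nbar.sum() == pytest.approx(len(data))
        assert fit.model_frequency.sum() == pytest.approx(1.0)

    def test_initialization_invariant_to_subject_order(self):
        spec = hb.get_model("rl")
        task = hb.generate_task("bandit2", 30, seed=4)
        data = [hb.simulate_agent(spec, [-0.5, 1.0], task, seed=i)
                for i in range(4)]
        opts = HBIOptions(seed=0, init_restarts=0)
        s1 = initialize(data, [spec], PriorConfig(), opts)
        s2 = initialize(data[::-1], [spec], PriorConfig(), opts)
        assert np.allclose(s1.theta[0], s2.theta[0][::-1], atol=1e-8)

    def test_parameter_recovery_within_hierarchical_errors(self):
        # simulated RL groups: the fitted group mean should lie within
        # 3 hierarchical errors of the generating mean in nearly all runs
        true_mean = (-0.8473, 1.0986)
        groups = [hb.GroupSpec("rl", 20, [(true_mean[0], 0.5),
                                          (true_mean[1], 0.5)])]
        ok = 0
        n_runs = 6
        for run in range(n_runs):
            cfg = hb.ScenarioConfig("recovery", groups, T=200,
                                    n_replications=1, master_seed=run)
            data, _ = hb.generate_group_dataset(cfg, 0)
            fit = hb.run_hbi(data, [hb.get_model("rl")],
                             options=HBIOptions(seed=run, compute_pxp=False))
            hits = []
            for i in range(2):
                tt = hb.hbi_ttest(fit, 0, i, null_value=true_mean[i])
                hits.append(abs(tt.t) < 3.0)
            ok += all(hits)
        assert ok >= n_runs - 1
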