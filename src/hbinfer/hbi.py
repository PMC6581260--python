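"""The hierarchical Bayesian inference (HBI) algorithm.

HBI fits a model space {M_1..M_K} to N subjects concurrently, treating
both the parameters h_kn and the model identity z_n of every subject as
random effects.  The generative model is a mixture over models whose
mixing proportions m follow a Dirichlet prior, with a Gaussian-Gamma
prior on each model's group mean mu_k and diagonal group precision
T_k = diag(tau_k):

    z_n  ~ Multinomial(m),      m ~ Dir(alpha0)
    h_kn ~ N(mu_k, T_k^-1)
    x_n  ~ p(x_n | h_kn, M_k)   if z_kn = 1
    mu_k ~ N(a0, (b T_k)^-1),   tau_ki ~ Gamma(v, s)

Inference is mean-field variational Bayes with the factorization
q(H, Z) q(mu, tau, m); the conditional subject posterior q(h_kn) is a
Laplace (quadratic) approximation.  Each iteration performs four steps:
(1) responsibility-weighted summary statistics, (2) conjugate update of
the group posterior q(mu_k, tau_k) and Dir(alpha), (3) Laplace refit of
every subject under the updated group prior, (4) responsibility update
via the digamma-corrected subject-level evidence.  Convergence is
declared when the normalized change d-hat of the summary statistics
drops below 0.01 (at most 50 iterations).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np
from scipy.special import digamma, gammaln, logsumexp

from .laplace import fit_map_laplace
from .models import ModelSpec, SubjectData

__all__ = [
    "PriorConfig",
    "GroupPosterior",
    "SubjectPosteriors",
    "SummaryStats",
    "HBIOptions",
    "HBIFit",
    "initialize",
    "compute_summary_stats",
    "update_group_posterior",
    "update_subject_posteriors",
    "update_responsibilities",
    "check_convergence",
    "compute_lower_bound",
    "run_hbi",
]

_LOG2PI = math.log(2.0 * math.pi)


# ---------------------------------------------------------------------------
# configuration and state containers
# ---------------------------------------------------------------------------

@dataclass
class PriorConfig:
    """Hyper-priors of the HBI generative model.

    ``b`` acts as the effective number of prior samples for the group
    means and ``v`` as half the effective number of prior samples for the
    group precisions; ``s`` seeds the Gamma inverse scale and is kept
    small so the posterior deviances are data-driven.  ``a0`` may be a
    scalar (broadcast over dimensions and models) or a per-model vector.
    """

    a0: float | Sequence = 0.0
    b: float = 1.0
    v: float = 0.5
    s: float = 0.01
    alpha0: float = 1.0

    def __post_init__(self):
        if self.b <= 0 or self.v <= 0 or self.s <= 0 or self.alpha0 <= 0:
            raise ValueError("b, v, s and alpha0 must be strictly positive")

    def a0_for(self, D: int, k: int = 0) -> np.ndarray:
        a0 = self.a0
        if np.isscalar(a0):
            return np.full(D, float(a0))
        a0 = list(a0)
        if np.isscalar(a0[0]):
            return np.asarray(a0, dtype=float)
        return np.asarray(a0[k], dtype=float)


@dataclass
class GroupPosterior:
    """Per-model q(mu_k, tau_k) = N(mu_k | a_k, diag(beta_k tau_k)^-1)
    G(tau_k | nu_k, sigma_k) plus the Dirichlet concentrations alpha_k."""

    a: List[np.ndarray]
    beta: np.ndarray
    sigma: List[np.ndarray]
    nu: np.ndarray
    alpha: np.ndarray

    @property
    def K(self) -> int:
        return len(self.a)


@dataclass
class SubjectPosteriors:
    """Laplace posteriors and responsibilities for every subject x model."""

    theta: List[np.ndarray]    # per model: (N, D_k)
    A: List[np.ndarray]        # per model: (N, D_k, D_k)
    log_f: np.ndarray          # (K, N)
    r: np.ndarray              # (K, N), columns sum to one

    @property
    def K(self) -> int:
        return len(self.theta)

    @property
    def N(self) -> int:
        return int(self.log_f.shape[1])


@dataclass
class SummaryStats:
    Nbar: np.ndarray             # (K,)
    theta_bar: List[np.ndarray]  # per model (D_k,)
    V_bar: List[np.ndarray]      # per model (D_k, D_k)


@dataclass
class HBIOptions:
    seed: int = 0
    max_iter: int = 50
    tol: float = 0.01
    init_prior_variance: float = 6.25
    init_restarts: int = 2
    warm_restarts: int = 0
    nbar_floor: float = 1e-6
    vbar_floor: float = 1e-10
    compute_pxp: bool = True
    xp_samples: int = 1_000_000
    verbose: bool = False


@dataclass
class HBIFit:
    """Full result of an HBI run."""

    models: List[ModelSpec]
    group: GroupPosterior
    subjects: SubjectPosteriors
    stats: SummaryStats
    model_frequency: np.ndarray
    L: float
    xp: Optional[np.ndarray] = None
    pxp: Optional[np.ndarray] = None
    P0: Optional[float] = None
    L0: Optional[float] = None
    converged: bool = False
    hit_max_iter: bool = False
    n_iter: int = 0
    trace: dict = field(default_factory=dict)
    prior: Optional[PriorConfig] = None
    options: Optional[HBIOptions] = None


# ---------------------------------------------------------------------------
# seeding helper
# ---------------------------------------------------------------------------

def _fit_seed(master: int, k: int, n: int, iteration: int) -> int:
    ss = np.random.SeedSequence((int(master) & 0x7FFFFFFF, k, n, iteration))
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


# ---------------------------------------------------------------------------
# algorithm steps
# ---------------------------------------------------------------------------

def initialize(data: Sequence[SubjectData], models: Sequence[ModelSpec],
               prior: PriorConfig, options: Optional[HBIOptions] = None
               ) -> SubjectPosteriors:
    """Fit every model to every subject under a weakly-informative
    Gaussian prior and start with uniform responsibilities."""
    options = options or HBIOptions()
    K, N = len(models), len(data)
    if K < 1 or N < 1:
        raise ValueError("need at least one model and one subject")
    prec0 = 1.0 / options.init_prior_variance
    theta, A = [], []
    log_f = np.zeros((K, N))
    for k, spec in enumerate(models):
        D = spec.D
        a0 = prior.a0_for(D, k)
        th_k = np.zeros((N, D))
        A_k = np.zeros((N, D, D))
        n_failed = 0
        for n, d in enumerate(data):
            res = fit_map_laplace(
                lambda h, _d=d, _s=spec: _s.loglik(h, _d),
                prior_mean=a0,
                prior_precision=np.full(D, prec0),
                n_restarts=options.init_restarts,
                seed=_fit_seed(options.seed, k, n, 0),
            )
            th_k[n] = res.theta
            A_k[n] = res.A
            log_f[k, n] = res.log_f
            n_failed += 0 if res.converged else 1
        if n_failed == N:
            raise RuntimeError(
                f"model '{spec.name}' failed to fit on every subject")
        theta.append(th_k)
        A.append(A_k)
    r = np.full((K, N), 1.0 / K)
    return SubjectPosteriors(theta=theta, A=A, log_f=log_f, r=r)


def compute_summary_stats(subjects: SubjectPosteriors,
                          models: Sequence[ModelSpec],
                          prior: PriorConfig,
                          nbar_floor: float = 1e-6,
                          vbar_floor: float = 1e-10) -> SummaryStats:
    """Responsibility-weighted counts, means and deviances per model."""
    K, N = subjects.K, subjects.N
    if not np.allclose(subjects.r.sum(axis=0), 1.0, atol=1e-6):
        raise ValueError("responsibilities must be normalized per subject")
    Nbar = subjects.r.sum(axis=1)
    theta_bar, V_bar = [], []
    for k in range(K):
        D = models[k].D
        th = subjects.theta[k]
        r = subjects.r[k]
        if Nbar[k] < nbar_floor:
            # no responsibility left: revert to the prior location
            theta_bar.append(prior.a0_for(D, k))
            V_bar.append(np.eye(D))
            continue
        tb = (r[:, None] * th).sum(axis=0) / Nbar[k]
        Ainv = np.linalg.inv(subjects.A[k])
        outer = np.einsum("n,ni,nj->ij", r, th, th)
        V = (outer / Nbar[k] - np.outer(tb, tb)
             + np.einsum("n,nij->ij", r, Ainv) / Nbar[k])
        V = 0.5 * (V + V.T)
        w, Q = np.linalg.eigh(V)
        if np.any(w < vbar_floor):
            V = (Q * np.maximum(w, vbar_floor)) @ Q.T
        theta_bar.append(tb)
        V_bar.append(V)
    return SummaryStats(Nbar=Nbar, theta_bar=theta_bar, V_bar=V_bar)


def update_group_posterior(stats: SummaryStats, prior: PriorConfig,
                           models: Sequence[ModelSpec]) -> GroupPosterior:
    """Conjugate Gaussian-Gamma / Dirichlet update from summary stats."""
    K = len(stats.Nbar)
    a, sigma = [], []
    beta = np.empty(K)
    nu = np.empty(K)
    alpha = np.empty(K)
    for k in range(K):
        D = models[k].D
        a0 = prior.a0_for(D, k)
        Nk = float(stats.Nbar[k])
        tb = stats.theta_bar[k]
        Vb = stats.V_bar[k]
        a_k = (Nk * tb + prior.b * a0) / (Nk + prior.b)
        dm = tb - a0
        sig = prior.s + 0.5 * np.diag(
            Nk * Vb + (prior.b * Nk / (prior.b + Nk)) * np.outer(dm, dm))
        a.append(a_k)
        sigma.append(sig)
        beta[k] = prior.b + Nk
        nu[k] = prior.v + 0.5 * Nk
        alpha[k] = prior.alpha0 + Nk
    return GroupPosterior(a=a, beta=beta, sigma=sigma, nu=nu, alpha=alpha)


def update_subject_posteriors(data: Sequence[SubjectData],
                              models: Sequence[ModelSpec],
                              group: GroupPosterior,
                              subjects: Optional[SubjectPosteriors] = None,
                              options: Optional[HBIOptions] = None,
                              iteration: int = 1) -> SubjectPosteriors:
    """Laplace refit of every subject x model under the current group
    posterior prior N(a_k, (E[T_k])^-1) with E[T_k] = nu_k diag(sigma_k)^-1.

    Warm-starts from the previous modes when available; responsibilities
    are carried over untouched.
    """
    options = options or HBIOptions()
    K, N = group.K, len(data)
    theta, A = [], []
    log_f = np.zeros((K, N))
    for k, spec in enumerate(models):
        D = spec.D
        prec = group.nu[k] / group.sigma[k]  # E[T_k] diagonal
        th_k = np.zeros((N, D))
        A_k = np.zeros((N, D, D))
        for n, d in enumerate(data):
            x0 = subjects.theta[k][n] if subjects is not None else None
            res = fit_map_laplace(
                lambda h, _d=d, _s=spec: _s.loglik(h, _d),
                prior_mean=group.a[k],
                prior_precision=prec,
                n_restarts=options.warm_restarts if x0 is not None
                else options.init_restarts,
                x0=x0,
                seed=_fit_seed(options.seed, k, n, iteration),
            )
            th_k[n] = res.theta
            A_k[n] = res.A
            log_f[k, n] = res.log_f
        theta.append(th_k)
        A.append(A_k)
    r = subjects.r.copy() if subjects is not None else np.full((K, N), 1.0 / K)
    return SubjectPosteriors(theta=theta, A=A, log_f=log_f, r=r)


def _log_rho(subjects: SubjectPosteriors, group: GroupPosterior,
             models: Sequence[ModelSpec], null_frequencies: bool = False
             ) -> np.ndarray:
    """log rho_kn: digamma-corrected Laplace evidence plus E[log m_k]."""
    K, N = subjects.K, subjects.N
    out = np.empty((K, N))
    if null_frequencies:
        e_log_m = np.full(K, -math.log(K))
    else:
        e_log_m = digamma(group.alpha) - digamma(group.alpha.sum())
    for k in range(K):
        D = models[k].D
        lam = 0.5 * D * (digamma(group.nu[k]) - math.log(group.nu[k])
                         - 1.0 / group.beta[k])
        sign, logdet = np.linalg.slogdet(subjects.A[k])
        out[k] = (subjects.log_f[k] + 0.5 * D * _LOG2PI - 0.5 * logdet
                  + lam + e_log_m[k])
    return out


def update_responsibilities(subjects: SubjectPosteriors,
                            group: GroupPosterior,
                            models: Sequence[ModelSpec],
                            null_frequencies: bool = False
                            ) -> SubjectPosteriors:
    """Softmax of log rho_kn over models, per subject (log-sum-exp)."""
    lr = _log_rho(subjects, group, models, null_frequencies)
    if np.any(np.all(np.isneginf(lr), axis=0)):
        raise RuntimeError("degenerate subject: -inf evidence for all models")
    r = np.exp(lr - logsumexp(lr, axis=0, keepdims=True))
    r /= r.sum(axis=0, keepdims=True)
    return SubjectPosteriors(theta=subjects.theta, A=subjects.A,
                             log_f=subjects.log_f, r=r)


def _theta_hat(stats: SummaryStats) -> List[np.ndarray]:
    out = []
    for tb, Vb in zip(stats.theta_bar, stats.V_bar):
        out.append(tb / np.sqrt(np.maximum(np.diag(Vb), 1e-12)))
    return out


def check_convergence(trace_theta_hat: List[List[np.ndarray]],
                      iteration: int, tol: float = 0.01,
                      max_iter: int = 50):
    """Return (converged, hit_max_iter, d_hat) from the theta-hat trace.

    d-hat averages, over models and dimensions, the squared change of the
    normalized summary statistic between consecutive iterations;
    convergence requires strictly d-hat < tol.
    """
    if len(trace_theta_hat) < 2:
        return False, iteration >= max_iter, math.inf
    prev, cur = trace_theta_hat[-2], trace_theta_hat[-1]
    K = len(cur)
    d_hat = 0.0
    for p, c in zip(prev, cur):
        d_hat += float(np.sum((c - p) ** 2)) / p.size
    d_hat /= K
    if d_hat < tol:
        return True, False, d_hat
    return False, iteration >= max_iter, d_hat


# ---------------------------------------------------------------------------
# variational lower bound
# ---------------------------------------------------------------------------

def _kl_gamma(nu, sigma, v, s):
    """KL( Gamma(nu, rate sigma) || Gamma(v, rate s) ), elementwise."""
    return ((nu - v) * digamma(nu) - gammaln(nu) + gammaln(v)
            + v * (np.log(sigma) - np.log(s)) + nu * (s - sigma) / sigma)


def _kl_gauss_gamma(group: GroupPosterior, prior: PriorConfig,
                    models: Sequence[ModelSpec]) -> float:
    """Sum over models of KL[q(mu_k, tau_k) || p(mu_k, tau_k)]."""
    total = 0.0
    for k in range(group.K):
        D = models[k].D
        a0 = prior.a0_for(D, k)
        nu, beta = group.nu[k], group.beta[k]
        sig = group.sigma[k]
        d = group.a[k] - a0
        kl_mu = 0.5 * (
            D * (math.log(beta / prior.b) - 1.0 + prior.b / beta)
            + prior.b * float(np.sum((nu / sig) * d * d)))
        kl_tau = float(np.sum(_kl_gamma(nu, sig, prior.v, prior.s)))
        total += kl_mu + kl_tau
    return total


def _kl_dirichlet(alpha: np.ndarray, alpha0: float) -> float:
    K = alpha.size
    a0 = np.full(K, alpha0)
    asum, a0sum = alpha.sum(), a0.sum()
    return float(
        gammaln(asum) - gammaln(a0sum)
        - np.sum(gammaln(alpha)) + np.sum(gammaln(a0))
        + np.sum((alpha - a0) * (digamma(alpha) - digamma(asum))))


def compute_lower_bound(subjects: SubjectPosteriors, group: GroupPosterior,
                        prior: PriorConfig, models: Sequence[ModelSpec],
                        null_frequencies: bool = False) -> float:
    """Variational lower bound L of the log marginal likelihood.

    Assembled as sum_n log sum_k rho_kn minus the group-level KL terms;
    under the null (alpha0 -> infinity) the Dirichlet term vanishes and
    E[log m_k] is pinned at log(1/K).
    """
    lr = _log_rho(subjects, group, models, null_frequencies)
    L = float(np.sum(logsumexp(lr, axis=0)))
    L -= _kl_gauss_gamma(group, prior, models)
    if not null_frequencies:
        L -= _kl_dirichlet(group.alpha, prior.alpha0)
    if not np.isfinite(L):
        raise RuntimeError("non-finite lower bound")
    return L


# ---------------------------------------------------------------------------
# main loop
# ---------------------------------------------------------------------------

def run_hbi(data: Sequence[SubjectData], models: Sequence[ModelSpec],
            prior: Optional[PriorConfig] = None,
            options: Optional[HBIOptions] = None,
            null_frequencies: bool = False) -> HBIFit:
    """Run the full HBI loop and attach model-selection statistics.

    With ``null_frequencies=True`` the algorithm runs under the prior null
    hypothesis of equal model frequencies (used to compute the protected
    exceedance probability); see :func:`hbinfer.inference.run_null_hbi`.
    """
    prior = prior or PriorConfig()
    options = options or HBIOptions()
    N = len(data)

    subjects = initialize(data, models, prior, options)
    theta_hat_trace: List[List[np.ndarray]] = []
    d_trace, L_trace = [], []
    converged = hit_max = False
    group = None
    stats = None
    it = 0
    for it in range(1, options.max_iter + 1):
        stats = compute_summary_stats(subjects, models, prior,
                                      options.nbar_floor, options.vbar_floor)
        group = update_group_posterior(stats, prior, models)
        subjects = update_subject_posteriors(data, models, group, subjects,
                                             options, iteration=it)
        subjects = update_responsibilities(subjects, group, models,
                                           null_frequencies)
        L = compute_lower_bound(subjects, group, prior, models,
                                null_frequencies)
        theta_hat_trace.append(_theta_hat(stats))
        converged, hit_max, d_hat = check_convergence(
            theta_hat_trace, it, options.tol, options.max_iter)
        d_trace.append(d_hat)
        L_trace.append(L)
        if options.verbose:
            print(f"  iter {it:2d}  d^={d_hat:9.3g}  L={L:.3f}")
        if converged or hit_max:
            break

    # final summary statistics under the final responsibilities
    stats = compute_summary_stats(subjects, models, prior,
                                  options.nbar_floor, options.vbar_floor)
    freq = stats.Nbar / N

    fit = HBIFit(models=list(models), group=group, subjects=subjects,
                 stats=stats, model_frequency=freq, L=L_trace[-1],
                 converged=converged, hit_max_iter=hit_max, n_iter=it,
                 trace={"d_hat": d_trace, "L": L_trace},
                 prior=prior, options=options)

    if not null_frequencies and options.compute_pxp and len(models) > 1:
        from .inference import attach_model_selection
        attach_model_selection(fit, data)
    return fit
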