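"""Baseline inference procedures: NHI and HPE.

NHI (non-hierarchical inference) fits every subject independently under a
fixed, weakly-informative Gaussian prior (mean 0, variance 6.25 per
dimension on the unconstrained scale) and approximates each subject-level
model evidence by the Laplace formula.  The N x K evidence matrix is then
submitted to random-effects Bayesian model selection (variational
Dirichlet-multinomial updates), yielding expected model frequencies,
exceedance and protected exceedance probabilities.

HPE (hierarchical parameter estimation) is empirical-Bayes expectation
maximization for a single model over all subjects: the E-step computes
Laplace subject posteriors under the current group prior N(mu, V), the
M-step re-estimates mu and the diagonal V from the subject posteriors.
Model identity is a fixed effect, so models are compared by summed
subject evidence penalized iBIC-style for the group hyperparameters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.special import digamma, logsumexp

from .laplace import LaplaceResult, fit_map_laplace, log_evidence_laplace
from .models import ModelSpec, SubjectData

__all__ = [
    "NHIResult",
    "BMSResult",
    "HPEResult",
    "run_nhi",
    "bms_random_effects",
    "run_hpe",
    "fixed_effects_comparison",
]

_LOG2PI = math.log(2.0 * math.pi)

NHI_PRIOR_MEAN = 0.0
NHI_PRIOR_VARIANCE = 6.25


@dataclass
class BMSResult:
    alpha: np.ndarray
    frequencies: np.ndarray
    xp: np.ndarray
    pxp: np.ndarray
    P0: float
    converged: bool
    n_iter: int
    u: Optional[np.ndarray] = None  # (N, K) posterior model attribution


@dataclass
class NHIResult:
    models: List[ModelSpec]
    theta: List[np.ndarray]        # per model (N, D_k)
    A: List[np.ndarray]
    log_evidence: np.ndarray       # (N, K)
    bms: Optional[BMSResult] = None


@dataclass
class HPEResult:
    model: ModelSpec
    mu: np.ndarray                 # group mean
    V: np.ndarray                  # group variance (diagonal, as vector)
    theta: np.ndarray              # (N, D)
    A: np.ndarray                  # (N, D, D)
    log_f: np.ndarray              # (N,)
    log_group_evidence: float
    n_iter: int
    converged: bool
    n_obs: int
    n_group_params: int
    trace_mu: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# NHI
# ---------------------------------------------------------------------------

def run_nhi(data: Sequence[SubjectData], models: Sequence[ModelSpec],
            prior_mean: float = NHI_PRIOR_MEAN,
            prior_variance: float = NHI_PRIOR_VARIANCE,
            n_restarts: int = 2, seed: int = 0,
            run_bms: bool = True, alpha0: float = 1.0) -> NHIResult:
    """Independent Laplace fits per subject and model under a fixed prior."""
    if prior_variance <= 0:
        raise ValueError("prior variance must be positive")
    K, N = len(models), len(data)
    theta, A = [], []
    log_ev = np.zeros((N, K))
    for k, spec in enumerate(models):
        D = spec.D
        th_k = np.zeros((N, D))
        A_k = np.zeros((N, D, D))
        for n, d in enumerate(data):
            res = fit_map_laplace(
                lambda h, _d=d, _s=spec: _s.loglik(h, _d),
                prior_mean=np.full(D, prior_mean),
                prior_precision=np.full(D, 1.0 / prior_variance),
                n_restarts=n_restarts,
                seed=(seed * 97 + 31 * k + n) % (2 ** 31),
            )
            th_k[n] = res.theta
            A_k[n] = res.A
            log_ev[n, k] = log_evidence_laplace(res)
        theta.append(th_k)
        A.append(A_k)
    out = NHIResult(models=list(models), theta=theta, A=A, log_evidence=log_ev)
    if run_bms and K > 1:
        out.bms = bms_random_effects(log_ev, alpha0=alpha0, seed=seed)
    return out


def bms_random_effects(log_evidence: np.ndarray, alpha0: float = 1.0,
                       max_iter: int = 200, tol: float = 1e-8,
                       n_samples: int = 1_000_000, seed: int = 0) -> BMSResult:
    """Random-effects Bayesian model selection over subject evidences.

    Variational updates of the Dirichlet-multinomial model over model
    identity: u_nk prop. exp(log_ev_nk + psi(alpha_k) - psi(sum alpha)),
    alpha_k = alpha0 + sum_n u_nk.  The protected exceedance probability
    uses the free-energy comparison against the uniform-frequency null of
    the same model.
    """
    log_ev = np.asarray(log_evidence, dtype=float)
    if not np.all(np.isfinite(log_ev)):
        raise ValueError("log evidence matrix must be finite")
    N, K = log_ev.shape
    alpha = np.full(K, float(alpha0))
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        w = log_ev + (digamma(alpha) - digamma(alpha.sum()))
        u = np.exp(w - logsumexp(w, axis=1, keepdims=True))
        new_alpha = alpha0 + u.sum(axis=0)
        if np.max(np.abs(new_alpha - alpha)) < tol:
            alpha = new_alpha
            converged = True
            break
        alpha = new_alpha
    # final attribution under the converged concentrations
    w = log_ev + (digamma(alpha) - digamma(alpha.sum()))
    u = np.exp(w - logsumexp(w, axis=1, keepdims=True))

    from .inference import exceedance_probabilities, protected_exceedance
    xp = exceedance_probabilities(alpha, n_samples=n_samples, seed=seed)
    # free energy of the fitted model vs. the uniform-frequency null
    e_log_m = digamma(alpha) - digamma(alpha.sum())
    F1 = float(np.sum(logsumexp(log_ev + e_log_m, axis=1)))
    F1 -= _kl_dirichlet_vec(alpha, alpha0)
    F0 = float(np.sum(logsumexp(log_ev - math.log(K), axis=1)))
    pxp, P0 = protected_exceedance(xp, F1, F0)
    freq = alpha / alpha.sum()
    return BMSResult(alpha=alpha, frequencies=freq, xp=xp, pxp=pxp, P0=P0,
                     converged=converged, n_iter=it, u=u)


def _kl_dirichlet_vec(alpha: np.ndarray, alpha0: float) -> float:
    from scipy.special import gammaln
    K = alpha.size
    a0 = np.full(K, alpha0)
    return float(
        gammaln(alpha.sum()) - gammaln(a0.sum())
        - np.sum(gammaln(alpha)) + np.sum(gammaln(a0))
        + np.sum((alpha - a0) * (digamma(alpha) - digamma(alpha.sum()))))


# ---------------------------------------------------------------------------
# HPE
# ---------------------------------------------------------------------------

def run_hpe(data: Sequence[SubjectData], model: ModelSpec,
            init_mean: float = 0.0, init_variance: float = 6.25,
            max_iter: int = 50, tol: float = 1e-4,
            var_floor: float = 1e-6, n_restarts: int = 2, seed: int = 0,
            fixed_dims: Optional[Dict[int, Tuple[float, float]]] = None
            ) -> HPEResult:
    """Empirical-Bayes EM for one model across all subjects.

    ``fixed_dims`` maps parameter indices to (mean, variance) pairs held
    fixed throughout (the "null fit" used for group-level hypothesis
    testing); fixed dimensions do not count as free group hyperparameters
    in the iBIC penalty.
    """
    N = len(data)
    D = model.D
    fixed_dims = fixed_dims or {}
    mu = np.full(D, float(init_mean))
    V = np.full(D, float(init_variance))
    for i, (m_i, v_i) in fixed_dims.items():
        mu[i] = m_i
        V[i] = v_i

    theta = np.zeros((N, D))
    A = np.zeros((N, D, D))
    log_f = np.zeros(N)
    warm = [None] * N
    converged = False
    trace_mu = []
    it = 0
    for it in range(1, max_iter + 1):
        # E-step: Laplace subject posteriors under N(mu, diag(V))
        for n, d in enumerate(data):
            res = fit_map_laplace(
                lambda h, _d=d: model.loglik(h, _d),
                prior_mean=mu,
                prior_precision=1.0 / V,
                n_restarts=0 if warm[n] is not None else n_restarts,
                x0=warm[n],
                seed=(seed * 89 + 17 * it + n) % (2 ** 31),
            )
            theta[n] = res.theta
            A[n] = res.A
            log_f[n] = res.log_f
            warm[n] = res.theta
        # M-step
        new_mu = theta.mean(axis=0)
        Ainv_diag = np.array([np.diag(np.linalg.inv(A[n])) for n in range(N)])
        new_V = (np.mean(theta ** 2 + Ainv_diag, axis=0) - new_mu ** 2)
        new_V = np.maximum(new_V, var_floor)
        for i, (m_i, v_i) in fixed_dims.items():
            new_mu[i] = m_i
            new_V[i] = v_i
        rel = max(
            float(np.max(np.abs(new_mu - mu) / np.maximum(1.0, np.abs(mu)))),
            float(np.max(np.abs(new_V - V) / np.maximum(1.0, np.abs(V)))),
        )
        mu, V = new_mu, new_V
        trace_mu.append(mu.copy())
        if rel < tol:
            converged = True
            break

    n_obs = int(sum(d.T for d in data))
    n_free = 2 * (D - len(fixed_dims))
    subject_ev = np.array(
        [log_evidence_laplace(LaplaceResult(theta[n], A[n], log_f[n], True))
         for n in range(N)])
    log_ev = float(subject_ev.sum()) - 0.5 * n_free * math.log(max(n_obs, 1))
    return HPEResult(model=model, mu=mu, V=V, theta=theta, A=A, log_f=log_f,
                     log_group_evidence=log_ev, n_iter=it, converged=converged,
                     n_obs=n_obs, n_group_params=n_free, trace_mu=trace_mu)


def fixed_effects_comparison(hpe_results: Sequence[HPEResult],
                             tie_tol: float = 1e-6):
    """Select the model with the largest penalized group evidence.

    Returns (evidences, selected_index, is_tie); all fits must cover the
    same subjects.
    """
    n_obs = {r.n_obs for r in hpe_results}
    n_subj = {r.theta.shape[0] for r in hpe_results}
    if len(n_obs) > 1 or len(n_subj) > 1:
        raise ValueError("HPE fits must cover identical subject sets")
    ev = np.array([r.log_group_evidence for r in hpe_results])
    order = np.argsort(ev)[::-1]
    selected = int(order[0])
    is_tie = bool(ev.size > 1 and abs(ev[order[0]] - ev[order[1]]) < tie_tol)
    return ev, selected, is_tie
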