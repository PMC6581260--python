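"""Subject-level MAP optimization and Laplace approximation.

Every inference procedure in this package (non-hierarchical fits, the
EM-based hierarchical estimator and the variational HBI algorithm)
approximates a subject-level posterior

    l(h) = p(x | h, M) * N(h | prior_mean, prior_precision^-1)

by a Gaussian centered at the mode: ``theta = argmax log l``,
``A = -Hessian[log l](theta)`` and ``log_f = log l(theta)``.  The Laplace
log evidence is then ``log_f + (D/2) log 2pi - 1/2 log |A|``.

Optimization is quasi-Newton (L-BFGS-B) with numerical gradients and a
configurable multi-start: the prior mean plus ``n_restarts`` starting
points drawn from the prior.  Choice-model likelihoods (e.g. learning
models with softmax decision rules) can be multimodal, so at least one
random restart is recommended for cold starts; warm starts from a previous
solution typically need none.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np
from scipy.optimize import minimize

__all__ = ["LaplaceResult", "fit_map_laplace", "log_evidence_laplace"]

_LOG2PI = math.log(2.0 * math.pi)


@dataclass
class LaplaceResult:
    """Quadratic approximation of a subject-level posterior."""

    theta: np.ndarray          # posterior mode
    A: np.ndarray              # precision (negative Hessian at the mode)
    log_f: float               # log posterior density value at the mode
    converged: bool
    n_restarts_used: int = 0
    hessian_repaired: bool = False


def _neg_hessian_fd(f: Callable, x: np.ndarray, step: float = 1e-4) -> np.ndarray:
    """Central finite-difference Hessian of ``-f`` at ``x``."""
    D = x.size
    H = np.empty((D, D))
    f0 = f(x)
    steps = step * np.maximum(1.0, np.abs(x))
    # diagonal
    fp = np.empty(D)
    fm = np.empty(D)
    for i in range(D):
        e = np.zeros(D)
        e[i] = steps[i]
        fp[i] = f(x + e)
        fm[i] = f(x - e)
        H[i, i] = (fp[i] - 2.0 * f0 + fm[i]) / steps[i] ** 2
    for i in range(D):
        for j in range(i + 1, D):
            e_i = np.zeros(D)
            e_j = np.zeros(D)
            e_i[i] = steps[i]
            e_j[j] = steps[j]
            fpp = f(x + e_i + e_j)
            fmm = f(x - e_i - e_j)
            H[i, j] = H[j, i] = (
                fpp - fp[i] - fp[j] + 2.0 * f0 - fm[i] - fm[j] + fmm
            ) / (2.0 * steps[i] * steps[j])
    return -H


def _repair_pd(A: np.ndarray, floor: float = 1e-6):
    """Symmetrize and floor eigenvalues so that A is positive definite."""
    A = 0.5 * (A + A.T)
    w, V = np.linalg.eigh(A)
    if np.all(w > floor):
        return A, False
    w = np.maximum(w, floor)
    return (V * w) @ V.T, True


def fit_map_laplace(
    log_target: Callable[[np.ndarray], float],
    prior_mean: Sequence[float],
    prior_precision: Sequence[float],
    n_restarts: int = 2,
    x0: Optional[np.ndarray] = None,
    seed: int = 0,
    gtol: float = 1e-6,
    hess_floor: float = 1e-6,
) -> LaplaceResult:
    """Maximize ``log_target(h) + log N(h | prior_mean, prior_precision^-1)``.

    Parameters
    ----------
    log_target
        Log-likelihood term (may be identically zero for prior-only fits).
    prior_mean, prior_precision
        Gaussian prior on the unconstrained scale; the precision is
        diagonal, given as a vector (or a diagonal matrix).
    n_restarts
        Number of random starting points drawn from the prior, in
        addition to the prior mean and (if given) the warm start ``x0``.
    x0
        Optional warm start, tried first.
    """
    mu = np.atleast_1d(np.asarray(prior_mean, dtype=float))
    prec = np.asarray(prior_precision, dtype=float)
    if prec.ndim == 2:
        prec = np.diag(prec)
    prec = np.atleast_1d(prec)
    if np.any(prec <= 0):
        raise ValueError("prior precision must be positive")
    D = mu.size
    half_logdet_prec = 0.5 * float(np.sum(np.log(prec)))

    def log_post(h):
        dh = h - mu
        lp = -0.5 * D * _LOG2PI + half_logdet_prec - 0.5 * float(dh @ (prec * dh))
        return float(log_target(h)) + lp

    def neg(h):
        v = log_post(h)
        return 1e12 if not np.isfinite(v) else -v

    rng = np.random.default_rng(seed)
    starts = []
    if x0 is not None:
        starts.append(np.asarray(x0, dtype=float))
    starts.append(mu.copy())
    for _ in range(n_restarts):
        starts.append(mu + rng.standard_normal(D) / np.sqrt(prec))

    best = None
    any_ok = False
    for s in starts:
        res = minimize(neg, s, method="L-BFGS-B",
                       options={"gtol": gtol, "maxiter": 500})
        if best is None or res.fun < best.fun:
            best = res
        any_ok = any_ok or bool(res.success)

    theta = np.asarray(best.x, dtype=float)
    A = _neg_hessian_fd(log_post, theta)
    A, repaired = _repair_pd(A, hess_floor)
    return LaplaceResult(
        theta=theta,
        A=A,
        log_f=float(log_post(theta)),
        converged=any_ok,
        n_restarts_used=len(starts),
        hessian_repaired=repaired,
    )


def log_evidence_laplace(result: LaplaceResult, D: Optional[int] = None) -> float:
    """Laplace approximation to the log marginal likelihood.

    ``log_f + (D/2) log 2pi - 1/2 log |A|`` with ``A`` the posterior
    precision at the mode.
    """
    if D is None:
        D = result.theta.size
    sign, logdet = np.linalg.slogdet(result.A)
    if sign <= 0:
        raise ValueError("posterior precision must be positive definite")
    return float(result.log_f + 0.5 * D * _LOG2PI - 0.5 * logdet)
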