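"""Population-level statistics derived from an HBI fit.

The marginal posterior of the i-th group mean of model k is a Student
distribution

    p(mu_ki | X) = St( (mu_ki - a_ki) / (s_ki / sqrt(n_k)) | n_k ),

with n_k = 2 nu_k degrees of freedom and empirical deviance
s_ki^2 = 2 sigma_ki / beta_k; s_ki / sqrt(n_k) is the *hierarchical
error*, the standard-error analogue whose degrees of freedom are driven
by the responsibility-weighted subject count rather than N.  The HBI
t-test reads significance off this marginal.  Model selection uses
exceedance probabilities of the Dirichlet posterior over model
frequencies, protected against the chance hypothesis via the lower-bound
comparison with a null run in which frequencies are pinned uniform.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps
from scipy.optimize import minimize

from .hbi import HBIFit, HBIOptions, PriorConfig, run_hbi
from .models import ModelSpec, SubjectData

__all__ = [
    "TTestResult",
    "PredictiveResult",
    "hbi_ttest",
    "fit_new_subject",
    "exceedance_probabilities",
    "protected_exceedance",
    "run_null_hbi",
    "attach_model_selection",
]


@dataclass
class TTestResult:
    model: str
    param: str
    a: float                   # posterior group mean a_ki
    s: float                   # empirical deviance s_ki
    hierarchical_error: float  # s_ki / sqrt(n_k)
    dof: float                 # n_k = 2 nu_k
    t: float
    p: float
    credible_interval: tuple
    level: float


@dataclass
class PredictiveResult:
    theta_star: np.ndarray
    center: np.ndarray         # a_k
    scale: np.ndarray          # diag(s_k)
    dof: float                 # n_k
    converged: bool


def hbi_ttest(fit: HBIFit, model: int | str, param: int | str,
              null_value: float = 0.0, level: float = 0.95,
              one_sided: bool = False) -> TTestResult:
    """Student test of a group-mean parameter against ``null_value``."""
    k = _model_index(fit, model)
    spec = fit.models[k]
    i = (spec.param_names.index(param) if isinstance(param, str) else int(param))
    a = float(fit.group.a[k][i])
    nk = 2.0 * float(fit.group.nu[k])
    s2 = 2.0 * float(fit.group.sigma[k][i]) / float(fit.group.beta[k])
    s = math.sqrt(s2)
    he = s / math.sqrt(nk)
    t = (a - null_value) / he
    if one_sided:
        p = float(sps.t.sf(t, df=nk))
    else:
        p = float(2.0 * sps.t.sf(abs(t), df=nk))
    q = sps.t.ppf(0.5 + level / 2.0, df=nk)
    ci = (a - q * he, a + q * he)
    return TTestResult(model=spec.name, param=spec.param_names[i], a=a, s=s,
                       hierarchical_error=he, dof=nk, t=t, p=p,
                       credible_interval=ci, level=level)


def _model_index(fit: HBIFit, model) -> int:
    if isinstance(model, str):
        for k, m in enumerate(fit.models):
            if m.name == model:
                return k
        raise KeyError(f"model '{model}' not in fit")
    return int(model)


def fit_new_subject(fit: HBIFit, model: int | str, new_data: SubjectData
                    ) -> PredictiveResult:
    """MAP parameters of an unseen subject under the predictive prior.

    The predictive over a new subject's parameters is Student with center
    a_k, scale diag(s_k) and n_k degrees of freedom (using the b = 2v
    convention, which holds with the defaults b = 1, v = 1/2); the MAP
    maximizes the data likelihood times this heavy-tailed prior.
    """
    k = _model_index(fit, model)
    spec = fit.models[k]
    a = fit.group.a[k]
    nk = 2.0 * float(fit.group.nu[k])
    s = np.sqrt(2.0 * fit.group.sigma[k] / float(fit.group.beta[k]))

    def neg(h):
        z = (h - a) / s
        lp = float(np.sum(sps.t.logpdf(z, df=nk) - np.log(s)))
        v = spec.loglik(h, new_data) + lp
        return 1e12 if not np.isfinite(v) else -v

    best = None
    for x0 in (a, a + 0.1, a - 0.1):
        res = minimize(neg, x0, method="L-BFGS-B", options={"maxiter": 500})
        if best is None or res.fun < best.fun:
            best = res
    return PredictiveResult(theta_star=np.asarray(best.x, float), center=a,
                            scale=s, dof=nk, converged=bool(best.success))


def exceedance_probabilities(alpha: Sequence[float],
                             n_samples: int = 1_000_000,
                             seed: int = 0) -> np.ndarray:
    """phi_k = Prob(m_k > m_j for all j != k) under Dir(alpha).

    Exact (regularized incomplete beta) for K = 2; Dirichlet Monte-Carlo
    otherwise.
    """
    alpha = np.asarray(alpha, dtype=float)
    if np.any(alpha <= 0):
        raise ValueError("Dirichlet concentrations must be positive")
    K = alpha.size
    if K == 1:
        return np.array([1.0])
    if K == 2:
        p1 = float(sps.beta.sf(0.5, alpha[0], alpha[1]))
        return np.array([p1, 1.0 - p1])
    rng = np.random.default_rng(seed)
    phi = np.zeros(K)
    done = 0
    while done < n_samples:
        m = min(200_000, n_samples - done)
        draws = rng.dirichlet(alpha, size=m)
        idx, cnt = np.unique(np.argmax(draws, axis=1), return_counts=True)
        phi[idx] += cnt
        done += m
    return phi / n_samples


def protected_exceedance(phi: Sequence[float], L: float, L0: float):
    """Shrink exceedance probabilities toward uniform by the chance
    posterior P0 = 1 / (1 + exp(L - L0))."""
    phi = np.asarray(phi, dtype=float)
    K = phi.size
    # overflow-safe logistic
    d = np.clip(L - L0, -700.0, 700.0)
    P0 = float(1.0 / (1.0 + math.exp(d)))
    pxp = phi * (1.0 - P0) + P0 / K
    return pxp, P0


def run_null_hbi(data: Sequence[SubjectData], models: Sequence[ModelSpec],
                 prior: Optional[PriorConfig] = None,
                 options: Optional[HBIOptions] = None) -> HBIFit:
    """HBI under the prior null hypothesis of equal model frequencies
    (alpha0 -> infinity, realized by pinning E[log m_k] = log(1/K))."""
    if options is not None:
        options = _no_pxp(options)
    return run_hbi(data, models, prior, options, null_frequencies=True)


def _no_pxp(options: HBIOptions) -> HBIOptions:
    import copy
    options = copy.copy(options)
    options.compute_pxp = False
    return options


def attach_model_selection(fit: HBIFit, data: Sequence[SubjectData]) -> HBIFit:
    """Compute xp, pxp and P0 for an existing fit (runs the null HBI)."""
    options = fit.options or HBIOptions()
    fit.xp = exceedance_probabilities(fit.group.alpha,
                                      n_samples=options.xp_samples,
                                      seed=options.seed)
    null_fit = run_null_hbi(data, fit.models, fit.prior, options)
    fit.L0 = null_fit.L
    fit.pxp, fit.P0 = protected_exceedance(fit.xp, fit.L, fit.L0)
    return fit
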