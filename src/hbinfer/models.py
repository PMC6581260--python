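"""Cognitive model library: learning models, tasks and agent simulators.

All models are discrete-choice models with a softmax decision rule.  Each
model is described by a :class:`ModelSpec` whose log-likelihood is
parameterized on the *unconstrained* ("normally distributed") scale: the
raw parameter vector lives in R^D and is mapped inside the likelihood to
the constrained scale through per-parameter transforms (sigmoid for rates
and weights, exponential for positive parameters such as the inverse
temperature, identity for unbounded biases).  Gaussian group-level priors
therefore act on the scale where normality is assumed.

Tasks
-----
``bandit2``   two-armed bandit; latent reward probabilities follow a
              reflected Gaussian random walk and are binarized per trial.
``gonogo``    go/no-go task with interleaved appetitive/aversive stimuli;
              outcome value is independent of the stimulus label.
``twostep``   two-stage Markov decision task with fixed 0.7/0.3
              common/rare transitions and drifting second-stage rewards.

Models
------
``rl``                Rescorla-Wagner Q-learning (alpha, beta).
``dual_rl``           separate learning rates for positive/negative
                      prediction errors (alpha+, alpha-, beta).
``kalman``            Kalman-filter learner with decaying learning rate
                      driven by observation noise (omega, beta).
``actor_critic``      TD critic plus actor preference update (alpha, beta).
``last_outcome``      softmax on the most recent outcome (beta); the
                      non-learning "outlier" strategy.
``rl_persev`` / ``dual_rl_persev``
                      bandit models with a perseveration bonus p on the
                      previously chosen action.
``rl_gonogo`` / ``dual_rl_gonogo`` / ``biased_rl``
                      go/no-go variants; ``biased_rl`` adds a Pavlovian
                      bias +b (appetitive) / -b (aversive) to the "go"
                      utility.
``mf_twostep`` / ``mb_twostep`` / ``hybrid_twostep``
                      model-free SARSA, model-based planner, and their
                      w-weighted hybrid (which nests the other two).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from scipy.special import expit, logit

from ._accel import maybe_jit
from .exceptions import ConfigurationError

__all__ = [
    "SubjectData",
    "TaskData",
    "ModelSpec",
    "transform_parameters",
    "inverse_transform_parameters",
    "evaluate_loglik",
    "simulate_agent",
    "generate_task",
    "get_model",
    "list_models",
]


# ---------------------------------------------------------------------------
# data containers
# ---------------------------------------------------------------------------

@dataclass
class SubjectData:
    """One subject's trial sequence.

    ``choices`` are 0-based action indices (stage-1 actions for the
    two-step task).  ``stimuli`` labels the go/no-go cue valence
    (0 aversive, 1 appetitive).  ``states`` holds the second-stage state
    and ``choices2`` the second-stage action of the two-step task.
    """

    choices: np.ndarray
    outcomes: np.ndarray
    stimuli: Optional[np.ndarray] = None
    states: Optional[np.ndarray] = None
    choices2: Optional[np.ndarray] = None

    def __post_init__(self):
        self.choices = np.asarray(self.choices, dtype=np.int64)
        self.outcomes = np.asarray(self.outcomes, dtype=np.float64)
        if self.choices.shape != self.outcomes.shape:
            raise ValueError("choices and outcomes must share length T")
        for name in ("stimuli", "states", "choices2"):
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v, dtype=np.int64)
                if v.shape != self.choices.shape:
                    raise ValueError(f"{name} must share length T with choices")
                setattr(self, name, v)

    @property
    def T(self) -> int:
        return int(self.choices.shape[0])


@dataclass
class TaskData:
    """A realized task environment.

    ``outcome_prob`` holds the latent reward probability per trial and
    option ((T, 2) for bandit2/gonogo, (T, 2, 2) per second-stage
    state x action for twostep); ``outcomes`` the pre-drawn binarized
    rewards of the same shape.
    """

    kind: str
    T: int
    outcome_prob: np.ndarray
    outcomes: np.ndarray
    stimuli: Optional[np.ndarray] = None
    transition_matrix: Optional[np.ndarray] = None
    seed: Optional[int] = None

    def __post_init__(self):
        self.outcome_prob = np.asarray(self.outcome_prob, dtype=np.float64)
        self.outcomes = np.asarray(self.outcomes, dtype=np.float64)
        if self.T <= 0:
            raise ValueError("T must be positive")
        if np.any(self.outcome_prob < 0) or np.any(self.outcome_prob > 1):
            raise ValueError("outcome_prob entries must lie in [0, 1]")


# ---------------------------------------------------------------------------
# parameter transforms
# ---------------------------------------------------------------------------

_FORWARD = {
    "identity": lambda x: x,
    "sigmoid": expit,
    # clipped to keep downstream arithmetic overflow-free; irrelevant for
    # any realistic parameter value
    "exponential": lambda x: np.exp(np.minimum(x, 80.0)),
}
_INVERSE = {
    "identity": lambda y: y,
    "sigmoid": logit,
    "exponential": np.log,
}


def transform_parameters(raw: Sequence[float], spec: "ModelSpec") -> np.ndarray:
    """Map an unconstrained parameter vector to the constrained scale."""
    raw = np.asarray(raw, dtype=np.float64)
    if raw.shape != (spec.D,):
        raise ValueError(
            f"expected {spec.D} parameters for model '{spec.name}', got shape {raw.shape}"
        )
    return np.array(
        [_FORWARD[t](x) for t, x in zip(spec.transforms, raw)], dtype=np.float64
    )


def inverse_transform_parameters(constrained: Sequence[float], spec: "ModelSpec") -> np.ndarray:
    """Map constrained parameters back to the unconstrained scale."""
    constrained = np.asarray(constrained, dtype=np.float64)
    if constrained.shape != (spec.D,):
        raise ValueError(
            f"expected {spec.D} parameters for model '{spec.name}', got shape {constrained.shape}"
        )
    return np.array(
        [_INVERSE[t](x) for t, x in zip(spec.transforms, constrained)], dtype=np.float64
    )


# ---------------------------------------------------------------------------
# likelihood / simulation kernels
#
# Each kernel runs the model dynamics once.  In evaluation mode (sim=False)
# choices/outcomes are inputs and the summed log choice probability is
# returned; in simulation mode choices are sampled from the softmax using
# the pre-drawn uniforms ``u`` and outcomes realized from ``table``.
# ---------------------------------------------------------------------------

@maybe_jit
def _log_sig(x):
    # numerically stable log(sigmoid(x))
    if x < -35.0:
        return x
    if x >= 0.0:
        return -math.log1p(math.exp(-x))
    return x - math.log1p(math.exp(x))


@maybe_jit
def _run_qlearn(alpha_p, alpha_m, beta, persev, q0,
                choices, outcomes, sim, table, u):
    qa = q0
    qb = q0
    prev = -1
    ll = 0.0
    for t in range(choices.shape[0]):
        x0 = beta * qa
        x1 = beta * qb
        if prev == 0:
            x0 += persev
        elif prev == 1:
            x1 += persev
        d = x0 - x1  # logit of P(choice = 0)
        if sim:
            p0 = math.exp(_log_sig(d))
            c = 0 if u[t] < p0 else 1
            choices[t] = c
            r = table[t, c]
            outcomes[t] = r
        else:
            c = choices[t]
            r = outcomes[t]
        ll += _log_sig(d) if c == 0 else _log_sig(-d)
        q = qa if c == 0 else qb
        delta = r - q
        a = alpha_p if delta > 0.0 else alpha_m
        if c == 0:
            qa += a * delta
        else:
            qb += a * delta
        prev = c
    return ll


@maybe_jit
def _run_kalman(omega, beta, m0, v0, choices, outcomes, sim, table, u):
    if omega < 1e-12:  # guard underflow of exp(raw) at extreme raw values
        omega = 1e-12
    ma = m0
    mb = m0
    va = v0
    vb = v0
    ll = 0.0
    for t in range(choices.shape[0]):
        d = beta * (ma - mb)
        if sim:
            p0 = math.exp(_log_sig(d))
            c = 0 if u[t] < p0 else 1
            choices[t] = c
            r = table[t, c]
            outcomes[t] = r
        else:
            c = choices[t]
            r = outcomes[t]
        ll += _log_sig(d) if c == 0 else _log_sig(-d)
        if c == 0:
            k = va / (va + omega)
            ma += k * (r - ma)
            va *= 1.0 - k
        else:
            k = vb / (vb + omega)
            mb += k * (r - mb)
            vb *= 1.0 - k
    return ll


@maybe_jit
def _run_actor_critic(alpha, beta, v0, choices, outcomes, sim, table, u):
    V = v0
    pa = 0.0
    pb = 0.0
    ll = 0.0
    for t in range(choices.shape[0]):
        d = beta * (pa - pb)
        if sim:
            p0 = math.exp(_log_sig(d))
            c = 0 if u[t] < p0 else 1
            choices[t] = c
            r = table[t, c]
            outcomes[t] = r
        else:
            c = choices[t]
            r = outcomes[t]
        ll += _log_sig(d) if c == 0 else _log_sig(-d)
        delta = r - V
        V += alpha * delta
        if c == 0:
            pa += alpha * delta
        else:
            pb += alpha * delta
    return ll


@maybe_jit
def _run_gonogo(alpha_p, alpha_m, beta, bias, q0,
                choices, outcomes, stimuli, sim, table, u):
    # q[s, a]: 2 stimuli x (0 = no-go, 1 = go)
    q = np.full((2, 2), q0)
    ll = 0.0
    for t in range(choices.shape[0]):
        s = stimuli[t]
        x_ng = beta * q[s, 0]
        x_go = beta * q[s, 1]
        if s == 1:
            x_go += bias
        else:
            x_go -= bias
        d = x_ng - x_go  # logit of P(no-go)
        if sim:
            p0 = math.exp(_log_sig(d))
            c = 0 if u[t] < p0 else 1
            choices[t] = c
            r = table[t, c]
            outcomes[t] = r
        else:
            c = choices[t]
            r = outcomes[t]
        ll += _log_sig(d) if c == 0 else _log_sig(-d)
        delta = r - q[s, c]
        a = alpha_p if delta > 0.0 else alpha_m
        q[s, c] += a * delta
    return ll


@maybe_jit
def _run_twostep(alpha, beta, w, q0,
                 choices, outcomes, states, choices2,
                 sim, table, u1, u2, us):
    # SARSA(lambda=1) model-free values, model-based planning over the
    # known 0.7/0.3 transition structure, hybrid stage-1 mixture weight w.
    q1 = np.full(2, q0)
    q2 = np.full((2, 2), q0)
    ll = 0.0
    for t in range(choices.shape[0]):
        m0 = q2[0, 0] if q2[0, 0] >= q2[0, 1] else q2[0, 1]
        m1 = q2[1, 0] if q2[1, 0] >= q2[1, 1] else q2[1, 1]
        qmb0 = 0.7 * m0 + 0.3 * m1
        qmb1 = 0.3 * m0 + 0.7 * m1
        v0 = w * qmb0 + (1.0 - w) * q1[0]
        v1 = w * qmb1 + (1.0 - w) * q1[1]
        d1 = beta * (v0 - v1)
        if sim:
            p0 = math.exp(_log_sig(d1))
            a1 = 0 if u1[t] < p0 else 1
            choices[t] = a1
            common = us[t] < 0.7
            s = a1 if common else 1 - a1
            states[t] = s
        else:
            a1 = choices[t]
            s = states[t]
        ll += _log_sig(d1) if a1 == 0 else _log_sig(-d1)
        d2 = beta * (q2[s, 0] - q2[s, 1])
        if sim:
            p0 = math.exp(_log_sig(d2))
            a2 = 0 if u2[t] < p0 else 1
            choices2[t] = a2
            r = table[t, s, a2]
            outcomes[t] = r
        else:
            a2 = choices2[t]
            r = outcomes[t]
        ll += _log_sig(d2) if a2 == 0 else _log_sig(-d2)
        delta1 = q2[s, a2] - q1[a1]
        delta2 = r - q2[s, a2]
        q1[a1] += alpha * delta1
        q2[s, a2] += alpha * delta2
        q1[a1] += alpha * delta2  # lambda = 1 eligibility
    return ll


_EMPTY_I = np.zeros(0, dtype=np.int64)
_EMPTY_F = np.zeros(0, dtype=np.float64)
_EMPTY_T2 = np.zeros((0, 2), dtype=np.float64)
_EMPTY_T22 = np.zeros((0, 2, 2), dtype=np.float64)


# ---------------------------------------------------------------------------
# constrained-scale likelihood entry points
# ---------------------------------------------------------------------------

def qlearn_loglik(alpha_p, alpha_m, beta, persev, data: SubjectData, q0=0.5):
    """Q-learning family log-likelihood on the constrained scale."""
    return float(_run_qlearn(float(alpha_p), float(alpha_m), float(beta),
                             float(persev), float(q0),
                             data.choices, data.outcomes, False, _EMPTY_T2,
                             _EMPTY_F))


def kalman_loglik(omega, beta, data: SubjectData, m0=0.0, v0=1.0):
    """Kalman-filter learner log-likelihood on the constrained scale."""
    return float(_run_kalman(float(omega), float(beta), float(m0), float(v0),
                             data.choices, data.outcomes, False, _EMPTY_T2,
                             _EMPTY_F))


def actor_critic_loglik(alpha, beta, data: SubjectData, v0=0.5):
    return float(_run_actor_critic(float(alpha), float(beta), float(v0),
                                   data.choices, data.outcomes, False,
                                   _EMPTY_T2, _EMPTY_F))


def gonogo_loglik(alpha_p, alpha_m, beta, bias, data: SubjectData, q0=0.5):
    if data.stimuli is None:
        raise ConfigurationError("go/no-go models need stimulus labels")
    return float(_run_gonogo(float(alpha_p), float(alpha_m), float(beta),
                             float(bias), float(q0),
                             data.choices, data.outcomes, data.stimuli,
                             False, _EMPTY_T2, _EMPTY_F))


def twostep_loglik(alpha, beta, w, data: SubjectData, q0=0.5):
    if data.states is None or data.choices2 is None:
        raise ConfigurationError("two-step models need states and choices2")
    return float(_run_twostep(float(alpha), float(beta), float(w), float(q0),
                              data.choices, data.outcomes, data.states,
                              data.choices2, False, _EMPTY_T22,
                              _EMPTY_F, _EMPTY_F, _EMPTY_F))


# ---------------------------------------------------------------------------
# model specifications
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelSpec:
    """A candidate model: dimension, transforms, likelihood and simulator."""

    name: str
    task_kind: str
    param_names: tuple
    transforms: tuple
    _loglik_c: Callable = field(repr=False, compare=False)
    _sim_c: Callable = field(repr=False, compare=False)

    @property
    def D(self) -> int:
        return len(self.param_names)

    def loglik(self, raw: Sequence[float], data: SubjectData) -> float:
        """Log-likelihood of ``data`` at the unconstrained parameters."""
        return evaluate_loglik(self, raw, data)

    def simulate(self, raw: Sequence[float], task: TaskData, seed: int) -> SubjectData:
        return simulate_agent(self, raw, task, seed)


def evaluate_loglik(spec: ModelSpec, raw_params, data: SubjectData) -> float:
    raw = np.asarray(raw_params, dtype=np.float64)
    if raw.shape != (spec.D,):
        raise ValueError(
            f"model '{spec.name}' has {spec.D} parameters, got shape {raw.shape}"
        )
    if not np.all(np.isfinite(raw)):
        raise ValueError("non-finite parameter values")
    if data.T == 0:
        return 0.0
    theta = transform_parameters(raw, spec)
    return spec._loglik_c(theta, data)


def simulate_agent(spec: ModelSpec, raw_params, task: TaskData, seed: int) -> SubjectData:
    """Sample a synthetic subject from the model playing ``task``."""
    raw = np.asarray(raw_params, dtype=np.float64)
    if raw.shape != (spec.D,):
        raise ValueError(
            f"model '{spec.name}' has {spec.D} parameters, got shape {raw.shape}"
        )
    if not np.all(np.isfinite(raw)):
        raise ValueError("non-finite parameter values")
    if task.kind != spec.task_kind:
        raise ConfigurationError(
            f"model '{spec.name}' plays task '{spec.task_kind}', got '{task.kind}'"
        )
    theta = transform_parameters(raw, spec)
    rng = np.random.default_rng(seed)
    return spec._sim_c(theta, task, rng)


def _make_bandit_spec(name, param_names, transforms, ll, sim):
    return ModelSpec(name, "bandit2", tuple(param_names), tuple(transforms), ll, sim)


def _sim_generic(run, unpack):
    """Build a simulator closure from a kernel and a parameter unpacker."""

    def sim(theta, task: TaskData, rng) -> SubjectData:
        T = task.T
        choices = np.zeros(T, dtype=np.int64)
        outcomes = np.zeros(T, dtype=np.float64)
        u = rng.random(T)
        run(*unpack(theta), choices, outcomes, True, task.outcomes, u)
        return SubjectData(choices=choices, outcomes=outcomes)

    return sim


def get_model(name: str, q0: float = 0.5, kalman_m0: float = 0.0,
              kalman_v0: float = 1.0) -> ModelSpec:
    """Return the named :class:`ModelSpec`.

    ``q0`` sets the initial value of learned action values (midpoint of the
    {0, 1} outcome range by default); the Kalman filter instead starts each
    option at mean ``kalman_m0`` with prior variance ``kalman_v0``.
    """
    if name == "rl":
        return _make_bandit_spec(
            "rl", ("alpha", "beta"), ("sigmoid", "exponential"),
            lambda th, d: qlearn_loglik(th[0], th[0], th[1], 0.0, d, q0),
            _sim_generic(_run_qlearn, lambda th: (th[0], th[0], th[1], 0.0, q0)))
    if name == "dual_rl":
        return _make_bandit_spec(
            "dual_rl", ("alpha_pos", "alpha_neg", "beta"),
            ("sigmoid", "sigmoid", "exponential"),
            lambda th, d: qlearn_loglik(th[0], th[1], th[2], 0.0, d, q0),
            _sim_generic(_run_qlearn, lambda th: (th[0], th[1], th[2], 0.0, q0)))
    if name == "rl_persev":
        return _make_bandit_spec(
            "rl_persev", ("alpha", "beta", "persev"),
            ("sigmoid", "exponential", "identity"),
            lambda th, d: qlearn_loglik(th[0], th[0], th[1], th[2], d, q0),
            _sim_generic(_run_qlearn, lambda th: (th[0], th[0], th[1], th[2], q0)))
    if name == "dual_rl_persev":
        return _make_bandit_spec(
            "dual_rl_persev", ("alpha_pos", "alpha_neg", "beta", "persev"),
            ("sigmoid", "sigmoid", "exponential", "identity"),
            lambda th, d: qlearn_loglik(th[0], th[1], th[2], th[3], d, q0),
            _sim_generic(_run_qlearn, lambda th: (th[0], th[1], th[2], th[3], q0)))
    if name == "last_outcome":
        return _make_bandit_spec(
            "last_outcome", ("beta",), ("exponential",),
            lambda th, d: qlearn_loglik(1.0, 1.0, th[0], 0.0, d, q0),
            _sim_generic(_run_qlearn, lambda th: (1.0, 1.0, th[0], 0.0, q0)))
    if name == "kalman":
        return _make_bandit_spec(
            "kalman", ("omega", "beta"), ("exponential", "exponential"),
            lambda th, d: kalman_loglik(th[0], th[1], d, kalman_m0, kalman_v0),
            _sim_generic(_run_kalman,
                         lambda th: (th[0], th[1], kalman_m0, kalman_v0)))
    if name == "actor_critic":
        return _make_bandit_spec(
            "actor_critic", ("alpha", "beta"), ("sigmoid", "exponential"),
            lambda th, d: actor_critic_loglik(th[0], th[1], d, q0),
            _sim_generic(_run_actor_critic, lambda th: (th[0], th[1], q0)))

    if name in ("rl_gonogo", "dual_rl_gonogo", "biased_rl"):
        if name == "rl_gonogo":
            params, trans = ("alpha", "beta"), ("sigmoid", "exponential")
            unpack = lambda th: (th[0], th[0], th[1], 0.0, q0)
        elif name == "dual_rl_gonogo":
            params = ("alpha_pos", "alpha_neg", "beta")
            trans = ("sigmoid", "sigmoid", "exponential")
            unpack = lambda th: (th[0], th[1], th[2], 0.0, q0)
        else:
            params, trans = ("alpha", "beta", "bias"), (
                "sigmoid", "exponential", "identity")
            unpack = lambda th: (th[0], th[0], th[1], th[2], q0)

        def ll(th, d, _unpack=unpack):
            ap, am, beta, bias, q0_ = _unpack(th)
            return gonogo_loglik(ap, am, beta, bias, d, q0_)

        def sim(th, task, rng, _unpack=unpack):
            if task.stimuli is None:
                raise ConfigurationError("go/no-go task must carry stimuli")
            T = task.T
            choices = np.zeros(T, dtype=np.int64)
            outcomes = np.zeros(T, dtype=np.float64)
            u = rng.random(T)
            ap, am, beta, bias, q0_ = _unpack(th)
            _run_gonogo(ap, am, beta, bias, q0_, choices, outcomes,
                        task.stimuli, True, task.outcomes, u)
            return SubjectData(choices=choices, outcomes=outcomes,
                               stimuli=task.stimuli.copy())

        return ModelSpec(name, "gonogo", tuple(params), tuple(trans), ll, sim)

    if name in ("mf_twostep", "mb_twostep", "hybrid_twostep"):
        if name == "mf_twostep":
            params, trans = ("alpha", "beta"), ("sigmoid", "exponential")
            unpack = lambda th: (th[0], th[1], 0.0)
        elif name == "mb_twostep":
            params, trans = ("alpha", "beta"), ("sigmoid", "exponential")
            unpack = lambda th: (th[0], th[1], 1.0)
        else:
            params = ("alpha", "beta", "w")
            trans = ("sigmoid", "exponential", "sigmoid")
            unpack = lambda th: (th[0], th[1], th[2])

        def ll2(th, d, _unpack=unpack):
            a, b, w = _unpack(th)
            return twostep_loglik(a, b, w, d, q0)

        def sim2(th, task, rng, _unpack=unpack):
            T = task.T
            choices = np.zeros(T, dtype=np.int64)
            outcomes = np.zeros(T, dtype=np.float64)
            states = np.zeros(T, dtype=np.int64)
            choices2 = np.zeros(T, dtype=np.int64)
            u1 = rng.random(T)
            u2 = rng.random(T)
            us = rng.random(T)
            a, b, w = _unpack(th)
            _run_twostep(a, b, w, q0, choices, outcomes, states, choices2,
                         True, task.outcomes, u1, u2, us)
            return SubjectData(choices=choices, outcomes=outcomes,
                               states=states, choices2=choices2)

        return ModelSpec(name, "twostep", tuple(params), tuple(trans), ll2, sim2)

    raise ConfigurationError(f"unknown model '{name}'")


def list_models() -> list:
    return ["rl", "dual_rl", "kalman", "actor_critic", "last_outcome",
            "rl_persev", "dual_rl_persev",
            "rl_gonogo", "dual_rl_gonogo", "biased_rl",
            "mf_twostep", "mb_twostep", "hybrid_twostep"]


# ---------------------------------------------------------------------------
# task generation
# ---------------------------------------------------------------------------

def _reflected_walk(rng, T, n, walk_sd, lo, hi):
    p = np.empty((T, n))
    x = rng.uniform(lo, hi, size=n)
    for t in range(T):
        x = x + rng.normal(0.0, walk_sd, size=n)
        # reflect into [lo, hi]
        for _ in range(10):
            x = np.where(x > hi, 2 * hi - x, x)
            x = np.where(x < lo, 2 * lo - x, x)
            if np.all((x >= lo) & (x <= hi)):
                break
        p[t] = x
    return p


def generate_task(kind: str, T: int, seed: int, walk_sd: float = 0.1,
                  bounds=(0.2, 0.8)) -> TaskData:
    """Generate a task with binarized Gaussian random-walk reward schedules.

    Latent reward probabilities per option follow independent Gaussian
    random walks (step sd ``walk_sd``) reflected at ``bounds``; per-trial
    binary outcomes are pre-drawn Bernoulli(prob) for every option.
    """
    if T <= 0:
        raise ValueError("T must be positive")
    if walk_sd <= 0:
        raise ValueError("walk_sd must be positive")
    lo, hi = bounds
    if not (0.0 <= lo < hi <= 1.0):
        raise ValueError("bounds must satisfy 0 <= lo < hi <= 1")
    rng = np.random.default_rng(seed)

    if kind in ("bandit2", "gonogo"):
        prob = _reflected_walk(rng, T, 2, walk_sd, lo, hi)
        outs = (rng.random((T, 2)) < prob).astype(np.float64)
        stim = rng.integers(0, 2, size=T) if kind == "gonogo" else None
        return TaskData(kind=kind, T=T, outcome_prob=prob, outcomes=outs,
                        stimuli=stim, seed=seed)
    if kind == "twostep":
        prob = _reflected_walk(rng, T, 4, walk_sd, lo, hi).reshape(T, 2, 2)
        outs = (rng.random((T, 2, 2)) < prob).astype(np.float64)
        trans = np.array([[0.7, 0.3], [0.3, 0.7]])
        return TaskData(kind=kind, T=T, outcome_prob=prob, outcomes=outs,
                        transition_matrix=trans, seed=seed)
    raise ConfigurationError(f"unknown task kind '{kind}'")
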