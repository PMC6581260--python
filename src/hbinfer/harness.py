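"""Synthetic-group generation, scenario runner and evaluation metrics.

A scenario describes a mixed population of agents: how many subjects each
generating model contributes, the per-parameter generating distributions
on the unconstrained scale, the task and trial count, optional outliers,
and which inference methods to run.  ``run_scenario`` generates the
replications, fits each requested method (HBI, NHI, HPE) and scores model
selection, per-subject model attribution and parameter recovery.

Default generating conditions: two-armed bandit with T = 100 trials,
reward-probability random walk of step sd 0.1 bounded in [0.2, 0.8];
model parameters drawn from normal distributions on the unconstrained
scale (see ``DEFAULT_GENERATING_DISTS``).  The plain-RL learning rate is
generated below both dual-alpha learning rates so that pooling subjects
across models biases non-weighted group estimates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

from .baselines import fixed_effects_comparison, run_hpe, run_nhi
from .distributions import MomentMatchedDistribution
from .exceptions import ConfigurationError
from .hbi import HBIOptions, PriorConfig, run_hbi
from .inference import hbi_ttest
from .models import (ModelSpec, SubjectData, generate_task, get_model,
                     simulate_agent, transform_parameters)

__all__ = [
    "GroupSpec",
    "ScenarioConfig",
    "DEFAULT_GENERATING_DISTS",
    "make_scenario",
    "generate_group_dataset",
    "run_scenario",
    "summarize_scenario",
    "compute_estimation_error",
    "attribution_roc",
    "true_parameter_ttest_fpr",
    "hbi_ttest_study",
]


# unconstrained-scale (mean, sd) per parameter; constrained-scale means in
# comments
DEFAULT_GENERATING_DISTS: Dict[str, List[Tuple[float, float]]] = {
    "rl": [(-2.1972, 0.5), (1.0986, 0.5)],            # alpha~0.10, beta~3
    "dual_rl": [(1.3863, 0.5), (-0.4055, 0.5), (1.0986, 0.5)],  # 0.80/0.40
    "kalman": [(0.0, 0.5), (1.0986, 0.5)],            # omega~1, beta~3
    "actor_critic": [(-0.8473, 0.5), (1.0986, 0.5)],  # alpha~0.30
    "last_outcome": [(1.0986, 0.5)],
    "rl_persev": [(-2.1972, 0.5), (1.0986, 0.5), (0.0, 0.5)],
    "dual_rl_persev": [(1.3863, 0.5), (-0.4055, 0.5), (1.0986, 0.5),
                       (0.0, 0.5)],
    "rl_gonogo": [(-1.3863, 0.5), (1.0986, 0.5)],
    "dual_rl_gonogo": [(1.3863, 0.5), (-0.4055, 0.5), (1.0986, 0.5)],
    "biased_rl": [(-1.3863, 0.5), (1.0986, 0.5), (0.0, 1.0)],  # bias var 1
    "mf_twostep": [(0.0, 0.5), (1.0986, 0.5)],
    "mb_twostep": [(0.0, 0.5), (1.0986, 0.5)],
    "hybrid_twostep": [(0.0, 0.5), (1.0986, 0.5), (0.0, 0.5)],
}

# Fig-7-style parameter-space outliers: near-zero decision noise, and
# optionally a near-zero learning rate (unconstrained-scale means)
_SMALL_BETA = (math.log(0.05), 0.25)
_SMALL_ALPHA = (math.log(0.02 / 0.98), 0.25)


@dataclass
class GroupSpec:
    """One generating subpopulation: model name, subject count and the
    per-parameter generating distribution on the unconstrained scale.

    Each distribution entry is either ``(mean, sd)`` for a normal or
    ``{"moments": (mean, var, skew, kurt)}`` for a moment-matched skewed
    family.
    """

    model: str
    count: int
    dist: Optional[list] = None

    def __post_init__(self):
        if self.count < 0:
            raise ConfigurationError("subject counts must be >= 0")
        if self.dist is None:
            self.dist = [tuple(p) for p in DEFAULT_GENERATING_DISTS[self.model]]


@dataclass
class ScenarioConfig:
    name: str
    groups: List[GroupSpec]
    task_kind: str = "bandit2"
    T: int = 100
    walk_sd: float = 0.1
    bounds: tuple = (0.2, 0.8)
    n_replications: int = 20
    methods: tuple = ("hbi",)
    model_space: Optional[List[str]] = None
    outliers: Optional[dict] = None
    master_seed: int = 0

    def __post_init__(self):
        if self.n_replications < 1:
            raise ConfigurationError("n_replications must be >= 1")
        if self.model_space is None:
            self.model_space = [g.model for g in self.groups]


def make_scenario(name: str, counts: Optional[Sequence[int]] = None,
                  n_replications: int = 20, seed: int = 0, T: int = 100,
                  methods=("hbi",), **overrides) -> ScenarioConfig:
    """Named scenarios mirroring the simulation studies.

    ``same_complexity``: RL vs Kalman filter (default 10/30).
    ``nested``:          RL vs dual-alpha RL (default 10/30).
    ``four_models``:     RL, dual-alpha, Kalman, actor-critic (30 dominant).
    ``twostep``:         hybrid vs MB vs MF agents (30/10/10).
    ``gonogo_bias``:     biased-RL go/no-go agents (bias effect size via
                         ``effect``), optionally with a dual-alpha
                         go/no-go subgroup (``two_model=True``).
    """
    if name == "same_complexity":
        counts = counts or (10, 30)
        # mid-range learning rate (~0.3): in this scenario RL is not
        # constrained to lie below other models' rates
        rl_dist = [(-0.8473, 0.5), (1.0986, 0.5)]
        groups = [GroupSpec("rl", counts[0], rl_dist),
                  GroupSpec("kalman", counts[1])]
        return ScenarioConfig(name, groups, n_replications=n_replications,
                              master_seed=seed, T=T, methods=methods,
                              **overrides)
    if name == "nested":
        counts = counts or (10, 30)
        groups = [GroupSpec("rl", counts[0]), GroupSpec("dual_rl", counts[1])]
        return ScenarioConfig(name, groups, n_replications=n_replications,
                              master_seed=seed, T=T, methods=methods,
                              **overrides)
    if name == "four_models":
        counts = counts or (10, 10, 30, 10)
        names = ["rl", "dual_rl", "kalman", "actor_critic"]
        groups = [GroupSpec(m, c) for m, c in zip(names, counts)]
        return ScenarioConfig(name, groups, n_replications=n_replications,
                              master_seed=seed, T=T, methods=methods,
                              **overrides)
    if name == "twostep":
        counts = counts or (30, 10, 10)
        names = ["hybrid_twostep", "mb_twostep", "mf_twostep"]
        groups = [GroupSpec(m, c) for m, c in zip(names, counts)]
        return ScenarioConfig(name, groups, task_kind="twostep",
                              n_replications=n_replications,
                              master_seed=seed, T=T, methods=methods,
                              **overrides)
    if name == "gonogo_bias":
        effect = overrides.pop("effect", 0.0)
        two_model = overrides.pop("two_model", False)
        counts = counts or ((20, 20) if two_model else (20,))
        dist = [tuple(p) for p in DEFAULT_GENERATING_DISTS["biased_rl"]]
        dist[2] = (effect, 1.0)
        groups = [GroupSpec("biased_rl", counts[0], dist)]
        if two_model:
            groups.append(GroupSpec("dual_rl_gonogo", counts[1]))
        return ScenarioConfig(name, groups, task_kind="gonogo",
                              n_replications=n_replications,
                              master_seed=seed, T=T, methods=methods,
                              **overrides)
    raise ConfigurationError(f"unknown scenario '{name}'")


# ---------------------------------------------------------------------------
# dataset generation
# ---------------------------------------------------------------------------

def _draw_params(dist, rng) -> np.ndarray:
    out = np.empty(len(dist))
    for i, spec in enumerate(dist):
        if isinstance(spec, dict) and "moments" in spec:
            m, v, sk, ku = spec["moments"]
            out[i] = MomentMatchedDistribution(m, v, sk, ku).rvs(1, rng)[0]
        else:
            mean, sd = spec
            if sd <= 0:
                raise ConfigurationError("generating sd must be positive")
            out[i] = rng.normal(mean, sd)
    return out


def generate_group_dataset(config: ScenarioConfig, replication_index: int):
    """Simulate one replication of a scenario.

    Returns ``(data, truth)``: the list of per-subject trial sequences and
    a truth record with generating model indices, names and unconstrained
    parameters.  Deterministic in (config.master_seed, replication_index).
    """
    base = np.random.SeedSequence(
        (config.master_seed & 0x7FFFFFFF, replication_index))
    n_total = sum(g.count for g in config.groups)
    n_out = (config.outliers or {}).get("count", 0) \
        if config.outliers and config.outliers.get("type") != "evidence_duplication" else 0
    children = base.spawn(3 * (n_total + n_out))

    data: List[SubjectData] = []
    model_idx: List[int] = []
    model_name: List[str] = []
    raw_params: List[np.ndarray] = []
    ci = 0
    for gi, g in enumerate(config.groups):
        spec = get_model(g.model)
        for _ in range(g.count):
            prng = np.random.default_rng(children[ci])
            task_seed = int(children[ci + 1].generate_state(1)[0] & 0x7FFFFFFF)
            sim_seed = int(children[ci + 2].generate_state(1)[0] & 0x7FFFFFFF)
            ci += 3
            raw = _draw_params(g.dist, prng)
            task = generate_task(config.task_kind, config.T, task_seed,
                                 config.walk_sd, config.bounds)
            data.append(simulate_agent(spec, raw, task, sim_seed))
            model_idx.append(gi)
            model_name.append(g.model)
            raw_params.append(raw)

    if config.outliers:
        otype = config.outliers["type"]
        count = int(config.outliers.get("count", 1))
        if otype == "evidence_duplication":
            subj = int(config.outliers.get("subject", 0))
            for _ in range(count):
                data.append(data[subj])
                model_idx.append(model_idx[subj])
                model_name.append(model_name[subj])
                raw_params.append(raw_params[subj])
        elif otype in ("small_beta", "small_alpha_small_beta"):
            g = config.groups[0]
            spec = get_model(g.model)
            beta_pos = spec.param_names.index("beta")
            for _ in range(count):
                prng = np.random.default_rng(children[ci])
                task_seed = int(children[ci + 1].generate_state(1)[0] & 0x7FFFFFFF)
                sim_seed = int(children[ci + 2].generate_state(1)[0] & 0x7FFFFFFF)
                ci += 3
                dist = [tuple(p) for p in g.dist]
                dist[beta_pos] = _SMALL_BETA
                if otype == "small_alpha_small_beta":
                    dist[0] = _SMALL_ALPHA
                raw = _draw_params(dist, prng)
                task = generate_task(config.task_kind, config.T, task_seed,
                                     config.walk_sd, config.bounds)
                data.append(simulate_agent(spec, raw, task, sim_seed))
                model_idx.append(0)
                model_name.append(g.model)
                raw_params.append(raw)
        else:
            raise ConfigurationError(f"unknown outlier type '{otype}'")

    truth = {
        "model_index": np.asarray(model_idx),
        "model_name": model_name,
        "raw_params": raw_params,
        "replication": replication_index,
    }
    return data, truth


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def compute_estimation_error(estimates, truth, space: str = "unconstrained",
                             spec: Optional[ModelSpec] = None) -> np.ndarray:
    """Element-wise absolute estimation error, by default on the
    unconstrained ("normally distributed") scale."""
    est = np.atleast_2d(np.asarray(estimates, float))
    tru = np.atleast_2d(np.asarray(truth, float))
    if est.shape != tru.shape:
        raise ValueError("estimates and truth must be aligned")
    if space == "constrained":
        if spec is None:
            raise ValueError("constrained-space errors need a ModelSpec")
        est = np.vstack([transform_parameters(e, spec) for e in est])
        tru = np.vstack([transform_parameters(t, spec) for t in tru])
    elif space != "unconstrained":
        raise ValueError(f"unknown space '{space}'")
    return np.abs(est - tru)


def attribution_roc(responsibilities, truth_labels):
    """ROC curve and trapezoid AUC of per-subject model attribution."""
    from sklearn.metrics import roc_curve
    y = np.asarray(truth_labels, int)
    r = np.asarray(responsibilities, float)
    if len(np.unique(y)) < 2:
        raise ValueError("AUC undefined for single-class truth")
    fpr, tpr, thr = roc_curve(y, r)
    auc = float(np.trapezoid(tpr, fpr))
    return (fpr, tpr, thr), auc


# ---------------------------------------------------------------------------
# scenario runner
# ---------------------------------------------------------------------------

def _score_attribution(resp_kn: np.ndarray, truth_idx: np.ndarray):
    assigned = np.argmax(resp_kn, axis=0)
    return float(np.mean(assigned == truth_idx)), assigned


def _estimation_error_rows(theta_per_model, truth, model_space):
    errs = []
    for n, (gi, raw) in enumerate(zip(truth["model_index"],
                                      truth["raw_params"])):
        name = truth["model_name"][n]
        if name not in model_space:
            continue
        k = model_space.index(name)
        est = theta_per_model[k][n]
        errs.append(np.mean(np.abs(est - raw)))
    return float(np.mean(errs)) if errs else np.nan


def run_scenario(config: ScenarioConfig,
                 hbi_options: Optional[HBIOptions] = None,
                 prior: Optional[PriorConfig] = None,
                 keep_fits: bool = False) -> pd.DataFrame:
    """Run all replications x methods of a scenario and score them.

    Returns a tidy table with one row per replication x method:
    selected model (and whether it matches the most frequent generating
    model), protected exceedance probability of the selection where the
    method provides one, estimated model frequencies, per-subject
    attribution accuracy, and mean absolute parameter estimation error on
    the unconstrained scale.
    """
    prior = prior or PriorConfig()
    model_space = list(config.model_space)
    specs = [get_model(m) for m in model_space]
    counts = {m: 0 for m in model_space}
    for g in config.groups:
        if g.model in counts:
            counts[g.model] += g.count
    true_major = int(np.argmax([counts[m] for m in model_space]))

    rows = []
    fits = []
    for rep in range(config.n_replications):
        data, truth = generate_group_dataset(config, rep)
        truth_k = np.array([model_space.index(nm) if nm in model_space else -1
                            for nm in truth["model_name"]])
        rep_fits = {}
        for method in config.methods:
            row = {"replication": rep, "method": method,
                   "n_subjects": len(data)}
            if method == "hbi":
                opts = hbi_options or HBIOptions()
                opts = _reseed(opts, config.master_seed, rep)
                fit = run_hbi(data, specs, prior, opts)
                sel = int(np.argmax(fit.pxp if fit.pxp is not None
                                    else fit.model_frequency))
                row["pxp_selected"] = (float(fit.pxp[sel])
                                       if fit.pxp is not None else np.nan)
                acc, _ = _score_attribution(fit.subjects.r, truth_k)
                row["attribution_accuracy"] = acc
                for k, m in enumerate(model_space):
                    row[f"freq_{m}"] = float(fit.model_frequency[k])
                row["mean_abs_error"] = _estimation_error_rows(
                    fit.subjects.theta, truth, model_space)
                rep_fits["hbi"] = fit
            elif method == "nhi":
                res = run_nhi(data, specs, seed=config.master_seed + 1000 + rep)
                sel = int(np.argmax(res.bms.pxp))
                row["pxp_selected"] = float(res.bms.pxp[sel])
                acc, _ = _score_attribution(res.bms.u.T, truth_k)
                row["attribution_accuracy"] = acc
                for k, m in enumerate(model_space):
                    row[f"freq_{m}"] = float(res.bms.frequencies[k])
                row["mean_abs_error"] = _estimation_error_rows(
                    res.theta, truth, model_space)
                rep_fits["nhi"] = res
            elif method == "hpe":
                hres = [run_hpe(data, s, seed=config.master_seed + 2000 + rep)
                        for s in specs]
                ev, sel, tie = fixed_effects_comparison(hres)
                row["pxp_selected"] = np.nan
                row["attribution_accuracy"] = np.nan
                rel = ev - ev.max()
                w = np.exp(rel) / np.exp(rel).sum()
                for k, m in enumerate(model_space):
                    row[f"freq_{m}"] = float(w[k])
                row["mean_abs_error"] = _estimation_error_rows(
                    [h.theta for h in hres], truth, model_space)
                rep_fits["hpe"] = hres
            else:
                raise ConfigurationError(f"unknown method '{method}'")
            row["selected_model"] = sel
            row["selected_name"] = model_space[sel]
            row["correct_selection"] = bool(sel == true_major)
            rows.append(row)
        if keep_fits:
            fits.append(rep_fits)

    df = pd.DataFrame(rows)
    df.attrs["scenario"] = config.name
    df.attrs["true_majority_model"] = model_space[true_major]
    if keep_fits:
        df.attrs["fits"] = fits
    return df


def _reseed(opts: HBIOptions, master: int, rep: int) -> HBIOptions:
    import copy
    opts = copy.copy(opts)
    opts.seed = int((master * 100003 + rep) % (2 ** 31))
    return opts


def summarize_scenario(df: pd.DataFrame) -> pd.DataFrame:
    """Mean and SEM of the numeric metrics per method."""
    num = df.select_dtypes(float).columns
    g = df.groupby("method")[list(num)]
    mean = g.mean().add_suffix("_mean")
    sem = g.sem().add_suffix("_sem")
    out = pd.concat([mean, sem], axis=1)
    out["selection_accuracy"] = df.groupby("method")["correct_selection"].mean()
    return out


# ---------------------------------------------------------------------------
# group-level test studies
# ---------------------------------------------------------------------------

def true_parameter_ttest_fpr(n_groups: int, group_size: int,
                             dist: MomentMatchedDistribution, seed: int = 0,
                             alpha: float = 0.05) -> float:
    """False-positive rate of a classical one-sample t-test applied to
    TRUE generated parameters (no model fitting involved)."""
    rng = np.random.default_rng(seed)
    draws = dist.rvs((n_groups, group_size), rng)
    p = sps.ttest_1samp(draws, popmean=0.0, axis=1).pvalue
    return float(np.mean(p < alpha))


def hbi_ttest_study(effect: float, n_reps: int, n_subjects: int = 20,
                    two_model: bool = False, T: int = 100, seed: int = 0,
                    bias_moments: Optional[tuple] = None,
                    hbi_options: Optional[HBIOptions] = None) -> np.ndarray:
    """P-values of the HBI t-test on the go/no-go Pavlovian bias.

    Generates ``n_reps`` groups of biased-RL agents whose bias parameter
    has group mean ``effect`` (variance 1, normal unless ``bias_moments``
    specifies a skewed moment family), fits HBI and tests the bias
    against zero.  Used for power (effect > 0), null calibration
    (effect = 0) and the skewed-null studies.
    """
    counts = (n_subjects, n_subjects) if two_model else (n_subjects,)
    cfg = make_scenario("gonogo_bias", counts=counts, n_replications=n_reps,
                        seed=seed, T=T, effect=effect, two_model=two_model)
    if bias_moments is not None:
        cfg.groups[0].dist[2] = {"moments": tuple(bias_moments)}
    specs = [get_model(m) for m in cfg.model_space]
    pvals = np.empty(n_reps)
    for rep in range(n_reps):
        data, _ = generate_group_dataset(cfg, rep)
        opts = _reseed(hbi_options or HBIOptions(compute_pxp=False),
                       seed, rep)
        opts.compute_pxp = False
        fit = run_hbi(data, specs, options=opts)
        pvals[rep] = hbi_ttest(fit, "biased_rl", "bias", 0.0).p
    return pvals
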