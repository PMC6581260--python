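"""Reading and writing subject data, fits and scenario configurations.

Subject data are exchanged as one-row-per-trial CSV (columns ``trial``,
``choice``, ``outcome`` and, where applicable, ``stimulus``, ``state1``,
``state2``, ``choice2``) or an equivalent JSON object; scenario
configurations as YAML; fit results as JSON.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd
import yaml

from .harness import GroupSpec, ScenarioConfig
from .hbi import HBIFit
from .models import SubjectData

__all__ = [
    "subject_to_frame",
    "subject_from_frame",
    "write_subject_csv",
    "read_subject_csv",
    "write_subject_json",
    "read_subject_json",
    "scenario_to_yaml",
    "scenario_from_yaml",
    "fit_to_json",
]

PathLike = Union[str, Path]


def subject_to_frame(data: SubjectData) -> pd.DataFrame:
    df = pd.DataFrame({
        "trial": np.arange(data.T),
        "choice": data.choices,
        "outcome": data.outcomes,
    })
    if data.stimuli is not None:
        df["stimulus"] = data.stimuli
    if data.states is not None:
        df["state1"] = np.zeros(data.T, dtype=int)
        df["state2"] = data.states
    if data.choices2 is not None:
        df["choice2"] = data.choices2
    return df


def subject_from_frame(df: pd.DataFrame) -> SubjectData:
    kw = {"choices": df["choice"].to_numpy(),
          "outcomes": df["outcome"].to_numpy()}
    if "stimulus" in df:
        kw["stimuli"] = df["stimulus"].to_numpy()
    if "state2" in df:
        kw["states"] = df["state2"].to_numpy()
    if "choice2" in df:
        kw["choices2"] = df["choice2"].to_numpy()
    return SubjectData(**kw)


def write_subject_csv(data: SubjectData, path: PathLike) -> None:
    subject_to_frame(data).to_csv(path, index=False)


def read_subject_csv(path: PathLike) -> SubjectData:
    return subject_from_frame(pd.read_csv(path))


def write_subject_json(data: SubjectData, path: PathLike) -> None:
    obj = {c: subject_to_frame(data)[c].tolist()
           for c in subject_to_frame(data).columns}
    Path(path).write_text(json.dumps(obj))


def read_subject_json(path: PathLike) -> SubjectData:
    obj = json.loads(Path(path).read_text())
    return subject_from_frame(pd.DataFrame(obj))


def scenario_to_yaml(config: ScenarioConfig, path: PathLike) -> None:
    obj = dataclasses.asdict(config)
    obj["bounds"] = list(config.bounds)
    obj["methods"] = list(config.methods)
    for g in obj["groups"]:
        g["dist"] = [list(p) if not isinstance(p, dict) else p
                     for p in g["dist"]]
    Path(path).write_text(yaml.safe_dump(obj, sort_keys=False))


def scenario_from_yaml(path: PathLike) -> ScenarioConfig:
    obj = yaml.safe_load(Path(path).read_text())
    groups = [GroupSpec(g["model"], g["count"],
                        [tuple(p) if not isinstance(p, dict) else p
                         for p in g["dist"]])
              for g in obj.pop("groups")]
    obj["bounds"] = tuple(obj.get("bounds", (0.2, 0.8)))
    obj["methods"] = tuple(obj.get("methods", ("hbi",)))
    return ScenarioConfig(groups=groups, **obj)


def _np_default(o):
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    raise TypeError(f"not JSON serializable: {type(o)}")


def fit_to_json(fit: HBIFit, path: PathLike) -> None:
    """Serialize the group/subject posteriors and trace of an HBI fit."""
    obj = {
        "models": [m.name for m in fit.models],
        "group": {
            "a": [a.tolist() for a in fit.group.a],
            "beta": fit.group.beta.tolist(),
            "sigma": [s.tolist() for s in fit.group.sigma],
            "nu": fit.group.nu.tolist(),
            "alpha": fit.group.alpha.tolist(),
        },
        "subjects": {
            "theta": [t.tolist() for t in fit.subjects.theta],
            "A": [a.tolist() for a in fit.subjects.A],
            "log_f": fit.subjects.log_f.tolist(),
            "responsibility": fit.subjects.r.tolist(),
        },
        "model_frequency": fit.model_frequency.tolist(),
        "L": fit.L,
        "xp": None if fit.xp is None else fit.xp.tolist(),
        "pxp": None if fit.pxp is None else fit.pxp.tolist(),
        "P0": fit.P0,
        "L0": fit.L0,
        "converged": fit.converged,
        "n_iter": fit.n_iter,
        "trace": fit.trace,
    }
    Path(path).write_text(json.dumps(obj, default=_np_default))
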