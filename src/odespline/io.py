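"""Readers/writers for the package's delimited-text formats.

Time courses travel as long-format TSV with columns
``experiment, time, state, observed[, clean]`` (gzip-transparent through
pandas); parameter vectors as two-column ``parameter\\tvalue`` TSV,
order-insensitive and alias-aware.  Run configurations are YAML mapped
onto a strict pydantic model (unknown keys rejected).
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field

from .models import G1S_PARAM_ALIASES, OdeModel, get_model
from .synthetic import Experiment, TimeCourseSet

__all__ = [
    "read_timecourses",
    "write_timecourses",
    "read_params",
    "write_params",
    "RunConfig",
    "load_config",
    "nominal_params_path",
]

_TC_COLUMNS = ["experiment", "time", "state", "observed"]


def write_timecourses(path, dataset: TimeCourseSet, include_clean: bool = True):
    rows = []
    for e, exp in enumerate(dataset.experiments):
        names = dataset.state_names or tuple(
            f"x{i+1}" for i in range(exp.observed.shape[1])
        )
        for j, t in enumerate(exp.times):
            for i, s in enumerate(names):
                row = {
                    "experiment": e,
                    "time": t,
                    "state": s,
                    "observed": exp.observed[j, i],
                }
                if include_clean:
                    row["clean"] = exp.clean[j, i]
                rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_timecourses(path, model_name: str = "", noise_level: float = np.nan):
    """Parse a long-format TSV into a TimeCourseSet.

    Times are sorted ascending within each experiment; duplicate
    (experiment, time, state) rows and experiments missing a state column
    raise explicit schema errors.
    """
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in _TC_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    if df[_TC_COLUMNS[:3]].duplicated().any():
        dup = df[df[_TC_COLUMNS[:3]].duplicated()].iloc[0]
        raise ValueError(
            f"{path}: duplicate row for experiment={dup['experiment']} "
            f"time={dup['time']} state={dup['state']}"
        )
    has_clean = "clean" in df.columns
    # pivoting sorts columns lexically; restore the model's state order when
    # known, else the order of first appearance in the file
    try:
        order = list(get_model(model_name).state_names)
    except KeyError:
        order = list(dict.fromkeys(df["state"]))
    if set(df["state"]) - set(order):
        extra = sorted(set(df["state"]) - set(order))
        raise ValueError(f"{path}: unknown state name(s) {extra}")
    experiments = []
    state_names: tuple = ()
    for e, grp in df.groupby("experiment", sort=True):
        obs = grp.pivot(index="time", columns="state", values="observed")
        obs = obs.reindex(columns=[s for s in order if s in obs.columns])
        if obs.isna().any().any():
            bad = obs.columns[obs.isna().any()].tolist()
            raise ValueError(
                f"{path}: experiment {e} has missing values for state(s) {bad}"
            )
        names = tuple(obs.columns)
        if state_names and names != state_names:
            raise ValueError(
                f"{path}: experiment {e} states {names} differ from {state_names}"
            )
        state_names = names
        obs = obs.sort_index()
        times = obs.index.to_numpy(dtype=float)
        if np.any(np.diff(times) <= 0):
            raise ValueError(f"{path}: experiment {e} has non-increasing times")
        observed = obs.to_numpy(dtype=float)
        if has_clean:
            clean = (
                grp.pivot(index="time", columns="state", values="clean")
                .reindex(columns=list(names))
                .sort_index()
                .to_numpy(dtype=float)
            )
        else:
            clean = observed.copy()
        experiments.append(
            Experiment(
                initial_state=clean[0].copy(),
                times=times,
                clean=clean,
                observed=observed,
            )
        )
    return TimeCourseSet(
        model_name=model_name,
        experiments=tuple(experiments),
        noise_level=noise_level,
        state_names=state_names,
    )


def write_params(path, names, values, bounds=None):
    df = pd.DataFrame({"parameter": list(names), "value": np.asarray(values)})
    if bounds is not None:
        lo, hi = bounds
        df["lower"] = np.asarray(lo)
        df["upper"] = np.asarray(hi)
    df.to_csv(path, sep="\t", index=False)


def read_params(path, model: OdeModel) -> np.ndarray:
    """Read a two-column parameter TSV, matched by name against a model.

    Matching is order-insensitive; legacy aliases (e.g. the k39/k96
    labels of the G1/S activation/deactivation rates) are translated.
    Unknown or duplicate names raise; missing parameters fall back to the
    model's nominal values.
    """
    df = pd.read_csv(path, sep="\t")
    if "parameter" not in df.columns or "value" not in df.columns:
        raise ValueError(f"{path}: expected columns 'parameter' and 'value'")
    names = [G1S_PARAM_ALIASES.get(str(n), str(n)) for n in df["parameter"]]
    if len(set(names)) != len(names):
        dup = sorted({n for n in names if names.count(n) > 1})
        raise ValueError(f"{path}: duplicate parameter name(s) {dup}")
    theta = np.asarray(model.nominal_params, dtype=float).copy()
    for name, value in zip(names, df["value"]):
        theta[model.param_index(name)] = float(value)
    return theta


def nominal_params_path(model_name: str) -> Path:
    """Path of the packaged nominal-parameter table for a benchmark."""
    path = Path(__file__).parent / "data" / f"{model_name}_nominal_params.tsv"
    if not path.exists():
        raise FileNotFoundError(f"no packaged parameter table for {model_name!r}")
    return path


class SmoothingSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    lam: Optional[float] = Field(default=None, description="None = noise lookup")
    deriv_order: int = 2
    n_basis: Optional[int] = None
    degree: int = 3


class EstimatorSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    kind: str = "lp"  # lp | nlp
    method: str = "gauss-newton"  # nlp only: gauss-newton | sres
    free_params: Optional[list] = None
    refine: int = 10
    options: dict = Field(default_factory=dict)


class RunConfig(BaseModel):
    """Validated run description; unknown keys are rejected everywhere."""

    model_config = ConfigDict(extra="forbid")
    model: str
    data: Optional[str] = None  # path; None = generate synthetically
    noise_level: float = 0.0
    n_experiments: int = 4
    n_points: int = 40
    seed: int = 0
    smoothing: SmoothingSection = Field(default_factory=SmoothingSection)
    estimator: EstimatorSection = Field(default_factory=EstimatorSection)
    output: Optional[str] = None

    def load_dataset(self) -> TimeCourseSet:
        from .synthetic import make_benchmark_dataset

        if self.data:
            return read_timecourses(self.data, self.model, self.noise_level)
        return make_benchmark_dataset(
            self.model, self.noise_level, self.n_experiments, self.n_points,
            self.seed,
        )


def load_config(path) -> RunConfig:
    with open(path) as fh:
        return RunConfig(**(yaml.safe_load(fh) or {}))
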