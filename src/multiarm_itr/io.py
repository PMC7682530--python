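"""CSV + YAML-sidecar serialization for trial datasets and donor cohorts.

The CSV holds one row per subject; the sidecar declares column types,
categorical level lists, the arm and outcome columns, the randomization
probabilities, and the generator seed, so a dataset round-trips with its
schema intact.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import TrialDataset
from .donors import DonorCohort, DonorGeneratorConfig

__all__ = ["save_trial", "load_trial", "save_cohort", "load_cohort"]


def _column_schema(X: pd.DataFrame) -> dict:
    schema = {}
    for c in X.columns:
        if isinstance(X[c].dtype, pd.CategoricalDtype):
            schema[c] = {"type": "categorical",
                         "levels": [_plain(v) for v in X[c].cat.categories]}
        else:
            schema[c] = {"type": "continuous"}
    return schema


def _plain(v):
    return v.item() if isinstance(v, np.generic) else v


def _apply_schema(df: pd.DataFrame, schema: dict) -> pd.DataFrame:
    out = df.copy()
    for c, spec in schema.items():
        if spec["type"] == "categorical":
            out[c] = pd.Categorical(out[c], categories=spec["levels"])
        else:
            out[c] = out[c].astype(float)
    return out


def _sidecar_path(path) -> Path:
    return Path(path).with_suffix(".yaml")


def save_trial(data: TrialDataset, path, seed: int | None = None) -> None:
    df = data.X.copy()
    df["arm"] = data.A
    df["outcome"] = data.Y
    df.to_csv(path, index=False)
    meta = {
        "kind": "trial",
        "columns": _column_schema(data.X),
        "arm_column": "arm",
        "outcome_column": "outcome",
        "n_arms": int(data.K),
        "propensity": [float(p) for p in data.propensity[0]],
        "seed": seed,
    }
    with open(_sidecar_path(path), "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=False)


def load_trial(path) -> TrialDataset:
    with open(_sidecar_path(path)) as fh:
        meta = yaml.safe_load(fh)
    if meta.get("kind") != "trial":
        raise ValueError(f"{path} is not a trial dataset")
    df = pd.read_csv(path)
    X = _apply_schema(df[list(meta["columns"])], meta["columns"])
    n, K = len(df), int(meta["n_arms"])
    prop = np.tile(np.asarray(meta["propensity"], float), (n, 1))
    return TrialDataset(X=X, A=df[meta["arm_column"]].to_numpy(int),
                        Y=df[meta["outcome_column"]].to_numpy(float),
                        K=K, propensity=prop)


def save_cohort(cohort: DonorCohort, path) -> None:
    df = cohort.baseline.copy()
    df["arm"] = cohort.arm
    df["attendances"] = cohort.attendances
    df["G"] = cohort.G
    df["R_tilde"] = cohort.R_tilde
    df.to_csv(path, index=False)
    meta = {
        "kind": "donor_cohort",
        "columns": _column_schema(cohort.baseline),
        "arm_column": "arm",
        "arm_labels": {1: "12wk", 2: "10wk", 3: "8wk"},
        "outcome_columns": {"benefit": "G", "deferral_count": "R_tilde",
                            "attendances": "attendances"},
        "propensity": [1 / 3, 1 / 3, 1 / 3],
        "generator_config": {k: _plain_cfg(v) for k, v in vars(cohort.config).items()},
        "seed": cohort.seed,
    }
    with open(_sidecar_path(path), "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=False)


def _plain_cfg(v):
    if isinstance(v, tuple):
        return [float(x) for x in v]
    return _plain(v)


def load_cohort(path) -> DonorCohort:
    with open(_sidecar_path(path)) as fh:
        meta = yaml.safe_load(fh)
    if meta.get("kind") != "donor_cohort":
        raise ValueError(f"{path} is not a donor cohort")
    df = pd.read_csv(path)
    X = _apply_schema(df[list(meta["columns"])], meta["columns"])
    cfg_raw = meta.get("generator_config", {})
    cfg = DonorGeneratorConfig(**{
        k: tuple(v) if isinstance(v, list) else v for k, v in cfg_raw.items()})
    return DonorCohort(
        baseline=X,
        arm=df[meta["arm_column"]].to_numpy(int),
        attendances=df["attendances"].to_numpy(int),
        G=df["G"].to_numpy(float),
        R_tilde=df["R_tilde"].to_numpy(int),
        config=cfg,
        seed=meta.get("seed"),
    )
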