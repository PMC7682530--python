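"""Six benchmark data-generating settings for multi-arm ITR estimation.

Each setting draws five independent covariates, assigns one of three arms
uniformly at random, and generates a Gaussian outcome

    Y = m(X) + 0.5 * Delta_A(X) + eps,   eps ~ Normal(0, 1),

with main effect ``m(X) = 1 + 0.5 X4 + 0.3 X5`` and arm-specific interaction
functions ``Delta_1, Delta_2, Delta_3`` (``Delta_3 = 0`` throughout).  The true
optimal arm is ``argmax_a Delta_a(X)`` with ties broken toward the smallest arm
index.  The settings span tree-type (1, 6), linear (2), nonlinear (3, 4) and
mixed-discrete-covariate (5) interaction structures; in setting 6 one arm is
optimal for every subject.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd

from .core import Rule, TrialDataset, argmax_arms

__all__ = ["SimSetting", "SETTINGS", "gen_setting", "true_optimal_arm",
           "fixed_test_set", "oracle_value"]

K_ARMS = 3
NOISE_SD = 1.0


def _main_effect(X: pd.DataFrame) -> np.ndarray:
    return 1.0 + 0.5 * X["X4"].to_numpy(float) + 0.3 * X["X5"].to_numpy(float)


@dataclass(frozen=True)
class SimSetting:
    """One benchmark data-generating configuration."""

    setting_id: int
    deltas: tuple[Callable[[pd.DataFrame], np.ndarray], ...]
    covariates: str  # "continuous" or "mixed"
    description: str

    n_arms: int = K_ARMS
    noise_sd: float = NOISE_SD

    def delta_matrix(self, X: pd.DataFrame) -> np.ndarray:
        """``n x K`` matrix of interaction effects ``Delta_a(X)``."""
        return np.column_stack([d(X) for d in self.deltas])

    def mean_outcome(self, X: pd.DataFrame, A: np.ndarray) -> np.ndarray:
        dm = self.delta_matrix(X)
        return _main_effect(X) + 0.5 * dm[np.arange(len(X)), np.asarray(A) - 1]


def _col(X, name):
    return X[name].to_numpy(float)


_ZERO = lambda X: np.zeros(len(X))

SETTINGS: dict[int, SimSetting] = {
    1: SimSetting(
        1,
        (
            lambda X: 4.0 * (_col(X, "X1") > 0.5) - 2.0,
            lambda X: 2.0 * (_col(X, "X2") >= 0.5) * (_col(X, "X3") < 0.25) - 1.0,
            _ZERO,
        ),
        "continuous",
        "tree-type interactions",
    ),
    2: SimSetting(
        2,
        (
            lambda X: 3.0 * _col(X, "X1") - 2.0 * _col(X, "X2"),
            lambda X: 5.0 * _col(X, "X3") - _col(X, "X4") + _col(X, "X5") - 1.0,
            _ZERO,
        ),
        "continuous",
        "linear interactions",
    ),
    3: SimSetting(
        3,
        (
            lambda X: 3.0 * _col(X, "X1") ** 2 - np.exp(_col(X, "X2")),
            lambda X: _col(X, "X3") * _col(X, "X4"),
            _ZERO,
        ),
        "continuous",
        "nonlinear with a between-covariate product",
    ),
    4: SimSetting(
        4,
        (
            lambda X: 3.0 * _col(X, "X1") ** 2 - np.exp(_col(X, "X2")),
            lambda X: _col(X, "X3") ** 3,
            _ZERO,
        ),
        "continuous",
        "nonlinear interactions",
    ),
    5: SimSetting(
        5,
        (
            lambda X: 2.0 * (np.isin(X["X1"].to_numpy(int), [1, 2])) * _col(X, "X2") - 1.0,
            lambda X: 5.0 * (X["X1"].to_numpy(int) == 5) * _col(X, "X3") - 2.0,
            _ZERO,
        ),
        "mixed",
        "mixed discrete covariates",
    ),
    6: SimSetting(
        6,
        (
            lambda X: (_col(X, "X1") > 0.5) + 2.0,
            lambda X: 2.0 * (_col(X, "X2") >= 0.5) * (_col(X, "X3") < 0.25) - 3.0,
            _ZERO,
        ),
        "continuous",
        "one arm optimal for every subject",
    ),
}


def _draw_covariates(setting: SimSetting, n: int, rng: np.random.Generator) -> pd.DataFrame:
    if setting.covariates == "continuous":
        cols = {f"X{j}": rng.uniform(-1.0, 1.0, n) for j in range(1, 6)}
        return pd.DataFrame(cols)
    # mixed: X1 discrete uniform {1..5} (categorical), X2 ~ Bernoulli(0.5),
    # X3..X5 ~ U(-1, 1)
    X1 = rng.integers(1, 6, n)
    return pd.DataFrame(
        {
            "X1": pd.Categorical(X1, categories=[1, 2, 3, 4, 5]),
            "X2": rng.integers(0, 2, n).astype(float),
            "X3": rng.uniform(-1.0, 1.0, n),
            "X4": rng.uniform(-1.0, 1.0, n),
            "X5": rng.uniform(-1.0, 1.0, n),
        }
    )


def _get_setting(setting_id: int) -> SimSetting:
    if setting_id not in SETTINGS:
        raise ValueError(f"unknown setting_id {setting_id!r}; must be one of 1..6")
    return SETTINGS[setting_id]


def true_optimal_arm(setting_id: int, X: pd.DataFrame) -> np.ndarray:
    """Argmax of the interaction effects, ties toward the smallest arm index."""
    setting = _get_setting(setting_id)
    return argmax_arms(setting.delta_matrix(X))


def gen_setting(setting_id: int, n: int, seed: int) -> tuple[TrialDataset, np.ndarray]:
    """Generate a trial dataset under one of the six benchmark settings.

    Returns the dataset and the per-subject true optimal arm.  Identical seeds
    yield identical datasets.
    """
    setting = _get_setting(setting_id)
    if n < setting.n_arms:
        raise ValueError(f"n must be at least the number of arms ({setting.n_arms})")
    rng = np.random.default_rng(seed)
    X = _draw_covariates(setting, n, rng)
    A = rng.integers(1, setting.n_arms + 1, n)
    Y = setting.mean_outcome(X, A) + rng.normal(0.0, setting.noise_sd, n)
    data = TrialDataset(X=X, A=A, Y=Y, K=setting.n_arms)
    return data, true_optimal_arm(setting_id, X)


_TEST_SEED_OFFSET = 711_000  # dedicated stream so test sets never collide with training draws


def fixed_test_set(setting_id: int, n_test: int = 10_000, seed: int = 0
                   ) -> tuple[TrialDataset, np.ndarray]:
    """The evaluation test set for a setting: drawn once from a dedicated seed
    and reused across replicates."""
    return gen_setting(setting_id, n_test, seed=_TEST_SEED_OFFSET + 17 * setting_id + seed)


def oracle_value(setting_id: int, rule: Rule, n_mc: int = 100_000, seed: int = 0
                 ) -> tuple[float, float]:
    """Monte-Carlo oracle of the population value ``E[m(X) + 0.5 Delta_{D(X)}(X)]``.

    Returns ``(value, standard_error)``.  Used as an independent diagnostic
    alongside the IPW estimator: it evaluates the rule against the known truth
    rather than against a finite trial sample.
    """
    setting = _get_setting(setting_id)
    rng = np.random.default_rng(seed)
    X = _draw_covariates(setting, n_mc, rng)
    arms = rule.decide(X)
    vals = _main_effect(X) + 0.5 * setting.delta_matrix(X)[np.arange(n_mc), arms - 1]
    return float(vals.mean()), float(vals.std(ddof=1) / np.sqrt(n_mc))
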