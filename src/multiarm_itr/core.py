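"""Core abstractions: trial data containers, treatment rules, and evaluation metrics.

A treatment rule (ITR) is a map ``D`` from a subject's baseline covariates to one
of ``K`` arms labelled ``1..K``.  Every learner in this package produces a
:class:`Rule`; every evaluation quantity consumes one.  The value of a rule,

    V(D) = E[ I(A = D(X)) / P(A|X) * Y ],

is the expected outcome had the whole population been treated according to ``D``,
and is estimated here by inverse-probability weighting on a trial sample with
known randomization probabilities.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "TrialDataset",
    "Rule",
    "FixedRule",
    "FunctionRule",
    "UndefinedITREffectError",
    "argmax_arms",
    "ipw_value",
    "misclassification",
    "itr_effect",
    "utility",
    "deferral_target_transform",
    "assignment_proportions",
    "fixed_rule",
]


class UndefinedITREffectError(ValueError):
    """Raised when an ITR effect is undefined (empty concordant or discordant group)."""


@dataclass
class TrialDataset:
    """Per-subject trial data ``(X, A, Y)`` with known randomization probabilities.

    Parameters
    ----------
    X : pandas.DataFrame
        ``n x p`` covariate table.  Categorical covariates must carry a pandas
        ``category`` dtype (their declared levels); all other columns are
        treated as continuous.
    A : array of int
        Arm label per subject, in ``{1..K}``.
    Y : array of float
        Scalar outcome per subject (larger is better).
    K : int
        Number of arms.
    propensity : array, optional
        ``n x K`` known probabilities ``P(A = a | X)``.  Defaults to the
        uniform ``1/K`` of a balanced randomized trial.
    """

    X: pd.DataFrame
    A: np.ndarray
    Y: np.ndarray
    K: int
    propensity: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=int)
        self.Y = np.asarray(self.Y, dtype=float)
        n = len(self.X)
        if not (len(self.A) == len(self.Y) == n):
            raise ValueError("X, A and Y must have equal length")
        if self.X.isna().any().any() or np.isnan(self.Y).any():
            raise ValueError("missing entries are not allowed")
        if self.A.min() < 1 or self.A.max() > self.K:
            raise ValueError(f"arm labels must lie in 1..{self.K}")
        if len(np.unique(self.A)) < self.K:
            raise ValueError("every arm must be observed at least once")
        if self.propensity is None:
            self.propensity = np.full((n, self.K), 1.0 / self.K)
        else:
            self.propensity = np.asarray(self.propensity, dtype=float)
            if self.propensity.shape != (n, self.K):
                raise ValueError("propensity must be n x K")
            if (self.propensity <= 0).any():
                raise ValueError("positivity violated: propensities must be > 0")
            if not np.allclose(self.propensity.sum(axis=1), 1.0):
                raise ValueError("per-subject propensities must sum to 1")

    @property
    def n(self) -> int:
        return len(self.X)

    @property
    def p(self) -> int:
        return self.X.shape[1]

    def observed_propensity(self) -> np.ndarray:
        """``P(A_i | X_i)`` for the arm each subject actually received."""
        return self.propensity[np.arange(self.n), self.A - 1]

    def subset(self, idx: np.ndarray) -> "TrialDataset":
        return TrialDataset(
            X=self.X.iloc[idx].reset_index(drop=True),
            A=self.A[idx],
            Y=self.Y[idx],
            K=self.K,
            propensity=self.propensity[idx],
        )


def argmax_arms(scores: np.ndarray) -> np.ndarray:
    """Row-wise argmax over per-arm scores, returning arm labels ``1..K``.

    Ties are broken toward the smallest arm index (for the donor application,
    arms are coded so that arm 1 is the longest inter-donation interval, making
    this also the safest choice).
    """
    scores = np.asarray(scores, dtype=float)
    return scores.argmax(axis=1) + 1  # np.argmax takes the first maximum


@dataclass
class Rule:
    """A deterministic map from covariates to an arm in ``{1..K}``."""

    decide_fn: Callable[[pd.DataFrame], np.ndarray] = field(repr=False)
    K: int = 3
    provenance: str = "unspecified"

    def decide(self, X: pd.DataFrame) -> np.ndarray:
        arms = np.asarray(self.decide_fn(X), dtype=int)
        if len(arms) != len(X):
            raise ValueError("rule returned wrong number of decisions")
        if arms.min() < 1 or arms.max() > self.K:
            raise ValueError("rule produced an arm outside 1..K")
        return arms

    def __call__(self, X: pd.DataFrame) -> np.ndarray:
        return self.decide(X)


class FixedRule(Rule):
    """Non-personalized rule recommending the same arm for everyone."""

    def __init__(self, arm: int, K: int = 3):
        if not 1 <= arm <= K:
            raise ValueError(f"arm must lie in 1..{K}")
        super().__init__(
            decide_fn=lambda X: np.full(len(X), arm, dtype=int),
            K=K,
            provenance=f"fixed(arm={arm})",
        )
        self.arm = arm


class FunctionRule(Rule):
    """Rule wrapping an arbitrary covariate-to-arm function."""

    def __init__(self, fn: Callable[[pd.DataFrame], np.ndarray], K: int = 3,
                 provenance: str = "function"):
        super().__init__(decide_fn=fn, K=K, provenance=provenance)


def fixed_rule(arm: int, K: int = 3) -> FixedRule:
    """The constant rule that assigns arm ``arm`` to every subject."""
    return FixedRule(arm, K=K)


def ipw_value(data: TrialDataset, rule: Rule, normalized: bool = False) -> float:
    """Inverse-probability-weighted estimate of the value ``V(D)``.

    The default is the plug-in estimator

        (1/n) sum_i I(A_i = D(X_i)) Y_i / P(A_i | X_i).

    With ``normalized=True`` the Hajek variant divides by the sum of the
    weights of concordant subjects instead of ``n``.
    """
    if (data.propensity <= 0).any():
        raise ValueError("positivity violated: zero propensity encountered")
    pscore = data.observed_propensity()
    concordant = data.A == rule.decide(data.X)
    # exact (correctly rounded) summation: the estimator is then independent of
    # subject ordering down to the last bit
    num = math.fsum(data.Y[concordant] / pscore[concordant])
    if normalized:
        denom = math.fsum(1.0 / pscore[concordant])
        if denom == 0:
            return 0.0
        return num / denom
    return num / data.n


def misclassification(predicted: Sequence[int], truth: Sequence[int]) -> float:
    """Fraction of subjects whose predicted arm differs from the reference arm."""
    predicted = np.asarray(predicted)
    truth = np.asarray(truth)
    if predicted.shape != truth.shape:
        raise ValueError("predicted and truth must have equal length")
    return float(np.mean(predicted != truth))


def itr_effect(data: TrialDataset, rule: Rule, outcome: np.ndarray | None = None) -> float:
    """ITR effect: mean outcome among subjects whose observed arm agrees with the
    rule minus the mean among those whose arm disagrees.

    For a fixed (constant-arm) rule this contrasts one arm against the pooled
    others.  Raises :class:`UndefinedITREffectError` when either group is empty,
    which is distinct from a numeric zero.
    """
    y = data.Y if outcome is None else np.asarray(outcome, dtype=float)
    if len(y) != data.n:
        raise ValueError("outcome length must match the dataset")
    concordant = data.A == rule.decide(data.X)
    if concordant.all() or not concordant.any():
        raise UndefinedITREffectError(
            "ITR effect undefined: concordant or discordant group is empty"
        )
    return float(y[concordant].mean() - y[~concordant].mean())


def utility(G, R_tilde, b: float):
    """Benefit–risk utility ``U = G - b * R_tilde``.

    ``G`` is the benefit (units of blood collected), ``R_tilde`` the number of
    low-hemoglobin deferrals, and ``b >= 0`` the trade-off parameter: the
    benefit loss considered equivalent to one extra deferral.
    """
    if b < 0:
        raise ValueError("trade-off parameter b must be nonnegative")
    G = np.asarray(G, dtype=float)
    R_tilde = np.asarray(R_tilde, dtype=float)
    if (R_tilde < 0).any():
        raise ValueError("deferral count must be nonnegative")
    out = G - b * R_tilde
    return float(out) if out.ndim == 0 else out


def deferral_target_transform(R):
    """Map a deferral rate ``R`` in [0,1] to ``arcsin(sqrt(1 - R))``.

    The arcsine square-root transform stabilizes the variance of a proportion;
    applying it to ``1 - R`` yields a quantity that is strictly decreasing in
    ``R``, so maximizing the transform minimizes the deferral rate.
    """
    R = np.asarray(R, dtype=float)
    if (R < 0).any() or (R > 1).any():
        raise ValueError("deferral rate must lie in [0, 1]")
    out = np.arcsin(np.sqrt(1.0 - R))
    return float(out) if out.ndim == 0 else out


def assignment_proportions(rule: Rule, X: pd.DataFrame, K: int | None = None) -> np.ndarray:
    """Proportion of subjects assigned to each arm by ``rule`` (sums to 1)."""
    if len(X) == 0:
        raise ValueError("X must be nonempty")
    K = K or rule.K
    arms = rule.decide(X)
    return np.bincount(arms - 1, minlength=K) / len(X)
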