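"""Direct learning (D-learning) with linear decision functions.

For each unordered arm pair {a, i} (a < i), subjects on those two arms are
encoded ``A_ai = +1`` for arm a and ``-1`` for arm i, and the pairwise optimal
decision function is estimated by weighted least squares,

    f_ai in argmin_f sum_j (2 Y_j A_ai,j - f(X_j))^2 / P(A_j | X_j),

with ``f(x) = x^T beta`` (intercept included).  The sign of ``f_ai`` prefers
arm a over arm i.  The multi-arm rule aggregates pairwise functions by

    D(x) = argmax_a sum_{i != a} f_ai(x),

using the exact anti-symmetry ``f_ia = -f_ai``.  Under uniform randomization
the weights are a constant 1/K and cancel, but they are carried explicitly so
non-uniform designs work unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.linear_model import LassoCV

from .core import Rule, TrialDataset, argmax_arms
from .design import CovariateEncoder

__all__ = ["PairwiseFunctions", "fit_pair", "fit_dlearning", "multiarm_rule"]


def _encode_with_intercept(encoder: CovariateEncoder, X: pd.DataFrame) -> np.ndarray:
    blocks = encoder.blocks(X)
    M = np.hstack([blocks[c] for c in X.columns if blocks[c].shape[1]])
    return np.hstack([np.ones((len(X), 1)), M])


@dataclass
class PairwiseFunctions:
    """Linear pairwise decision functions f_ai for all pairs a < i."""

    encoder: CovariateEncoder
    coef: dict[tuple[int, int], np.ndarray]   # keyed by (a, i) with a < i
    K: int

    def f(self, a: int, i: int, X: pd.DataFrame) -> np.ndarray:
        """Evaluate f_ai(x); anti-symmetry f_ia = -f_ai is exact by construction."""
        if a == i:
            raise ValueError("pair must involve two distinct arms")
        lo, hi = min(a, i), max(a, i)
        if (lo, hi) not in self.coef:
            raise ValueError(f"pair ({a},{i}) was not fitted")
        vals = _encode_with_intercept(self.encoder, X) @ self.coef[(lo, hi)]
        return vals if a == lo else -vals

    def coef_table(self) -> pd.DataFrame:
        """Pairwise coefficient vectors, one row per column of the design."""
        names = ["(intercept)"]
        for c in self.encoder.columns_:
            names.extend(self.encoder.block_names(c))
        return pd.DataFrame(
            {f"f_{a}{i}": beta for (a, i), beta in sorted(self.coef.items())},
            index=names)

    def scores(self, X: pd.DataFrame) -> np.ndarray:
        """n x K matrix of aggregated scores sum_{i != a} f_ai(x)."""
        S = np.zeros((len(X), self.K))
        for a in range(1, self.K + 1):
            for i in range(1, self.K + 1):
                if i != a:
                    S[:, a - 1] += self.f(a, i, X)
        return S


def fit_pair(data: TrialDataset, a: int, i: int,
             encoder: CovariateEncoder | None = None,
             penalty: str = "none", cv_folds: int = 5, seed: int = 0) -> np.ndarray:
    """Weighted least squares for one pairwise decision function f_ai (a < i).

    Returns the coefficient vector (intercept first).  With ``penalty='l1'``
    the lasso path is tuned by cross-validation.
    """
    if not (1 <= a < i <= data.K):
        raise ValueError("require 1 <= a < i <= K")
    mask = (data.A == a) | (data.A == i)
    if not (data.A == a).any() or not (data.A == i).any():
        raise ValueError(f"arms {a} and {i} must both be present")
    enc = encoder or CovariateEncoder().fit(data.X)
    M = _encode_with_intercept(enc, data.X.iloc[np.where(mask)[0]].reset_index(drop=True))
    Aai = np.where(data.A[mask] == a, 1.0, -1.0)
    resp = 2.0 * data.Y[mask] * Aai
    w = 1.0 / data.observed_propensity()[mask]
    if penalty == "none":
        sw = np.sqrt(w)
        beta, *_ = np.linalg.lstsq(M * sw[:, None], resp * sw, rcond=None)
        return beta
    if penalty == "l1":
        model = LassoCV(cv=cv_folds, random_state=seed, fit_intercept=False)
        model.fit(M, resp, sample_weight=w)
        return model.coef_
    raise ValueError(f"unknown penalty {penalty!r}")


def fit_dlearning(data: TrialDataset, penalty: str = "none", cv_folds: int = 5,
                  seed: int = 0) -> tuple[Rule, PairwiseFunctions]:
    """Fit all K(K-1)/2 pairwise functions and return the aggregated rule."""
    enc = CovariateEncoder().fit(data.X)
    coef = {
        (a, i): fit_pair(data, a, i, encoder=enc, penalty=penalty,
                         cv_folds=cv_folds, seed=seed)
        for a in range(1, data.K + 1)
        for i in range(a + 1, data.K + 1)
    }
    pw = PairwiseFunctions(encoder=enc, coef=coef, K=data.K)
    return multiarm_rule(pw), pw


def multiarm_rule(pairwise: PairwiseFunctions) -> Rule:
    """The argmax-of-aggregated-pairwise-scores rule (ties to smallest arm index)."""
    expected = pairwise.K * (pairwise.K - 1) // 2
    if len(pairwise.coef) != expected:
        raise ValueError(f"need all {expected} pairwise fits")

    def decide(X: pd.DataFrame) -> np.ndarray:
        return argmax_arms(pairwise.scores(X))

    return Rule(decide_fn=decide, K=pairwise.K, provenance="D-learning(linear)")
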