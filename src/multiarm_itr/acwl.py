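"""Adaptive contrast weighted learning (ACWL).

Per-arm conditional means are estimated with flexible regressions and corrected
per subject by the doubly-robust augmented inverse-probability-weighted (AIPW)
construction,

    mu_hat_a(X_i) = mu_tilde_a(X_i) + I(A_i = a) / pi_a(X_i) * (Y_i - mu_tilde_a(X_i)),

so each subject carries K pseudo-estimates of what they would experience under
each arm.  Ordering these yields per-subject order statistics
``mu_(1) <= ... <= mu_(K)``, ordering labels ``l_a``, the optimal label
``l_K``, and the adaptive contrasts ``C1 = mu_(K) - mu_(K-1)`` (least
conservative) and ``C2 = mu_(K) - mu_(1)`` (most conservative).  The rule is a
weighted classification tree that predicts ``l_K`` with per-subject weight
``C1`` or ``C2`` (``C2`` is the default), pruned by cost-complexity
cross-validation with a 1-SE rule.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import HistGradientBoostingRegressor
from sklearn.linear_model import LinearRegression
from sklearn.model_selection import KFold
from sklearn.tree import DecisionTreeClassifier, export_text

from .core import Rule, TrialDataset
from .design import CovariateEncoder

__all__ = ["ArmMeanModel", "ContrastSet", "fit_arm_means", "build_contrasts",
           "fit_weighted_tree_rule", "fit_acwl", "contrast_diagnostics"]


def _encode_numeric(encoder: CovariateEncoder, X: pd.DataFrame) -> np.ndarray:
    blocks = encoder.blocks(X)
    return np.hstack([blocks[c] for c in X.columns if blocks[c].shape[1]])


def _make_regressor(spec: str, seed: int):
    if spec == "gbt":
        # flexible default: ACWL's selling point is robustness to the outcome
        # model's functional form
        return HistGradientBoostingRegressor(
            max_iter=500, max_depth=3, learning_rate=0.05, random_state=seed,
            early_stopping=False,
        )
    if spec == "linear":
        return LinearRegression()
    raise ValueError(f"unknown regressor_spec {spec!r}")


@dataclass
class ArmMeanModel:
    """Per-arm outcome regressions plus AIPW per-subject pseudo-estimates."""

    encoder: CovariateEncoder
    models: dict[int, object]
    mu_tilde: np.ndarray   # n x K regression predictions on the training data
    mu_hat: np.ndarray     # n x K AIPW pseudo-estimates
    K: int

    def predict_mu(self, X: pd.DataFrame) -> np.ndarray:
        M = _encode_numeric(self.encoder, X)
        return np.column_stack([self.models[a].predict(M) for a in range(1, self.K + 1)])


def fit_arm_means(data: TrialDataset, regressor_spec: str = "gbt", seed: int = 0
                  ) -> ArmMeanModel:
    """Fit per-arm outcome regressions and form AIPW pseudo-estimates.

    The augmentation term ``I(A_i = a)/pi_a * (Y_i - mu_tilde_a(X_i))`` is zero
    for arms the subject did not receive, and vanishes when the regression fits
    the subject exactly.
    """
    encoder = CovariateEncoder().fit(data.X)
    M = _encode_numeric(encoder, data.X)
    models: dict[int, object] = {}
    mu_tilde = np.zeros((data.n, data.K))
    for a in range(1, data.K + 1):
        in_arm = data.A == a
        if not in_arm.any():
            raise ValueError(f"arm {a} has no subjects")
        reg = _make_regressor(regressor_spec, seed + a)
        reg.fit(M[in_arm], data.Y[in_arm])
        models[a] = reg
        mu_tilde[:, a - 1] = reg.predict(M)
    # AIPW augmentation
    mu_hat = mu_tilde.copy()
    rows = np.arange(data.n)
    pi = data.propensity[rows, data.A - 1]
    mu_hat[rows, data.A - 1] += (data.Y - mu_tilde[rows, data.A - 1]) / pi
    return ArmMeanModel(encoder=encoder, models=models, mu_tilde=mu_tilde,
                        mu_hat=mu_hat, K=data.K)


@dataclass
class ContrastSet:
    """Per-subject arm-effect ordering and adaptive contrasts."""

    ordering: np.ndarray   # n x K; column a-1 holds l_a (arm with a-th smallest mean)
    l_K: np.ndarray        # per-subject estimated optimal arm
    C1: np.ndarray         # mu_(K) - mu_(K-1) >= 0
    C2: np.ndarray         # mu_(K) - mu_(1) >= C1


def build_contrasts(mu: np.ndarray) -> ContrastSet:
    """Order per-subject arm means and form the contrasts C1 and C2.

    Ties in the ordering are broken by arm index (stable sort), so the optimal
    label ``l_K`` of a tied top pair is the larger-index arm only if it is
    strictly better — equal means keep the original arm order with the last
    position taken by the highest-index tied arm.
    """
    mu = np.asarray(mu, float)
    if mu.ndim != 2 or mu.shape[1] < 2:
        raise ValueError("need an n x K matrix of arm means with K >= 2")
    if not np.isfinite(mu).all():
        bad = np.where(~np.isfinite(mu).all(axis=1))[0]
        raise ValueError(f"non-finite arm-mean estimate for subject(s) {bad[:5]}")
    order = np.argsort(mu, axis=1, kind="stable")  # ascending; ties keep arm order
    srt = np.take_along_axis(mu, order, axis=1)
    return ContrastSet(
        ordering=order + 1,
        l_K=order[:, -1] + 1,
        C1=srt[:, -1] - srt[:, -2],
        C2=srt[:, -1] - srt[:, 0],
    )


def fit_weighted_tree_rule(X: pd.DataFrame, labels: np.ndarray, weights: np.ndarray,
                           K: int, cv_folds: int = 5, seed: int = 0,
                           min_leaf_frac: float = 1 / 400) -> Rule:
    """Weighted classification tree minimizing ``sum_i C(X_i) I(D(X_i) != l_K(X_i))``.

    The cost-complexity pruning parameter is chosen by weighted K-fold CV with
    the 1-SE rule; the minimum leaf size scales with n (n/400, at least 5).
    """
    weights = np.asarray(weights, float)
    if (weights < 0).any():
        raise ValueError("weights must be nonnegative")
    labels = np.asarray(labels, int)
    if weights.sum() == 0:
        warnings.warn("all classification weights are zero; returning majority-label rule")
        maj = int(np.bincount(labels).argmax())
        return Rule(decide_fn=lambda Xn: np.full(len(Xn), maj, dtype=int), K=K,
                    provenance="ACWL(majority)")
    if len(np.unique(labels)) < 2:
        only = int(labels[0])
        return Rule(decide_fn=lambda Xn: np.full(len(Xn), only, dtype=int), K=K,
                    provenance=f"ACWL(constant={only})")

    encoder = CovariateEncoder().fit(X)
    M = _encode_numeric(encoder, X)
    min_leaf = max(5, int(round(len(X) * min_leaf_frac)))
    base = DecisionTreeClassifier(min_samples_leaf=min_leaf, random_state=seed)
    path = base.cost_complexity_pruning_path(M, labels, sample_weight=weights)
    alphas = np.unique(np.clip(path.ccp_alphas, 0.0, None))
    if len(alphas) > 15:  # thin a long pruning path
        alphas = alphas[np.linspace(0, len(alphas) - 1, 15).astype(int)]

    kf = KFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    losses = np.zeros((cv_folds, len(alphas)))
    for f, (tr, te) in enumerate(kf.split(M)):
        for j, a in enumerate(alphas):
            t = DecisionTreeClassifier(min_samples_leaf=min_leaf, ccp_alpha=a,
                                       random_state=seed)
            t.fit(M[tr], labels[tr], sample_weight=weights[tr])
            miss = t.predict(M[te]) != labels[te]
            losses[f, j] = np.sum(weights[te] * miss) / max(weights[te].sum(), 1e-12)
    mean_loss = losses.mean(axis=0)
    se = losses.std(axis=0, ddof=1) / np.sqrt(cv_folds)
    best = int(np.argmin(mean_loss))
    # 1-SE rule: the most pruned tree within one SE of the minimum
    ok = mean_loss <= mean_loss[best] + se[best]
    alpha = float(alphas[np.max(np.where(ok))])

    tree = DecisionTreeClassifier(min_samples_leaf=min_leaf, ccp_alpha=alpha,
                                  random_state=seed)
    tree.fit(M, labels, sample_weight=weights)

    def decide(Xn: pd.DataFrame) -> np.ndarray:
        return tree.predict(_encode_numeric(encoder, Xn)).astype(int)

    rule = Rule(decide_fn=decide, K=K, provenance=f"ACWL(alpha={alpha:.4g})")
    rule.tree_ = tree
    rule.tree_text_ = export_text(tree)
    return rule


def contrast_diagnostics(cs: ContrastSet) -> pd.DataFrame:
    """Distributional summary of the adaptive contrasts and best-arm labels."""
    qs = [0.05, 0.25, 0.5, 0.75, 0.95]
    rows = {f"C1_q{int(100 * q)}": np.quantile(cs.C1, q) for q in qs}
    rows |= {f"C2_q{int(100 * q)}": np.quantile(cs.C2, q) for q in qs}
    counts = np.bincount(cs.l_K, minlength=cs.ordering.shape[1] + 1)[1:]
    for a, c in enumerate(counts, start=1):
        rows[f"share_lK_arm{a}"] = c / len(cs.l_K)
    return pd.DataFrame([rows])


def fit_acwl(data: TrialDataset, contrast: str = "C2", regressor_spec: str = "gbt",
             cv_folds: int = 5, seed: int = 0) -> tuple[Rule, ContrastSet]:
    """Full ACWL pipeline: AIPW arm means, contrasts, weighted tree rule."""
    if contrast not in ("C1", "C2"):
        raise ValueError("contrast must be 'C1' or 'C2'")
    model = fit_arm_means(data, regressor_spec=regressor_spec, seed=seed)
    cs = build_contrasts(model.mu_hat)
    w = cs.C2 if contrast == "C2" else cs.C1
    rule = fit_weighted_tree_rule(data.X, cs.l_K, w, data.K,
                                  cv_folds=cv_folds, seed=seed)
    rule.provenance = f"ACWL-{contrast}[{rule.provenance}]"
    return rule, cs
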