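"""Penalized least squares on the basis ``(1, X, A, XA)`` with grouped selection.

Two variants of factor-level selection are provided:

* ``GL`` — group lasso: each covariate's main-effect dummies, the arm dummies,
  and each covariate-by-arm interaction block are penalized as groups, so a
  factor is either wholly in or wholly out of the model.
* ``HGL`` — hierarchical group lasso: the glinternet-style overlapped-group
  formulation, in which each interaction group is augmented with copies of its
  two parent main-effect blocks.  A selected interaction therefore always
  carries nonzero parent main effects (strong hierarchy), while interactions
  with weak marginal signal can still be discovered because part of the parent
  main effect can be absorbed into the interaction group.

The optimizer is FISTA (accelerated proximal gradient) with a group
soft-threshold prox, gram-matrix gradients, warm starts along a log-spaced
lambda path, and a minimum-CV-MSE lambda choice.  The fitted rule is
``argmax_a`` of the predicted conditional means.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import Rule, TrialDataset, argmax_arms
from .design import CovariateEncoder, GroupedDesign, build_design, design_for_arm

logger = logging.getLogger(__name__)

__all__ = ["PenalizedFit", "fit_penalized", "fit_pls", "rule_from_fit",
           "selection_frequency"]


# ---------------------------------------------------------------------------
# group-lasso optimizer (FISTA with gram gradients)
# ---------------------------------------------------------------------------

def _group_prox(theta: np.ndarray, groups: list[np.ndarray], thresholds: np.ndarray
                ) -> np.ndarray:
    out = theta.copy()
    for g, t in zip(groups, thresholds):
        nrm = np.linalg.norm(theta[g])
        out[g] = 0.0 if nrm <= t else theta[g] * (1.0 - t / nrm)
    return out


def _fista_path(Z: np.ndarray, y: np.ndarray, groups: list[np.ndarray],
                weights: np.ndarray, lams: np.ndarray,
                tol: float = 1e-7, max_iter: int = 5000) -> np.ndarray:
    """Solve min 1/(2n)||y - Z theta||^2 + lam * sum_g w_g ||theta_g|| along a path.

    Returns an array of shape ``(len(lams), n_cols)``.  Warm-started from the
    previous lambda (the path should be ordered from large to small).
    """
    n, p = Z.shape
    G = Z.T @ Z / n
    c = Z.T @ y / n
    # Lipschitz constant of the gradient = largest eigenvalue of G
    L = float(np.linalg.eigvalsh(G)[-1]) if p else 1.0
    L = max(L, 1e-12)
    step = 1.0 / L

    def objective(x, lam):
        return 0.5 * (x @ G @ x) - c @ x + lam * sum(
            w * np.linalg.norm(x[g]) for g, w in zip(groups, weights))

    thetas = np.zeros((len(lams), p))
    theta = np.zeros(p)
    for li, lam in enumerate(lams):
        x = theta.copy()
        zk = theta.copy()
        tk = 1.0
        thr = step * lam * weights
        obj_prev = objective(x, lam)
        flat = 0
        for _ in range(max_iter):
            grad = G @ zk - c
            x_new = _group_prox(zk - step * grad, groups, thr)
            obj = objective(x_new, lam)
            if obj > obj_prev:
                # adaptive restart keeps the momentum sequence from stalling
                zk = x_new.copy()
                tk = 1.0
            else:
                tk_new = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * tk * tk))
                zk = x_new + ((tk - 1.0) / tk_new) * (x_new - x)
                tk = tk_new
            x = x_new
            # criterion must hold on several consecutive iterations: FISTA can
            # plateau transiently far from the optimum
            flat = flat + 1 if abs(obj_prev - obj) <= tol * (abs(obj_prev) + 1e-12) else 0
            obj_prev = obj
            if flat >= 5:
                break
        theta = x
        thetas[li] = x
    return thetas


# ---------------------------------------------------------------------------
# problem assembly
# ---------------------------------------------------------------------------

@dataclass
class _Problem:
    """Standardized penalized-regression problem (intercept removed by centering)."""

    Z: np.ndarray                 # centered/scaled penalized columns
    col_map: np.ndarray           # latent column -> original design column
    groups: list[np.ndarray]      # latent-column index arrays
    group_names: list[str]
    weights: np.ndarray
    means: np.ndarray
    sds: np.ndarray

    def to_original_beta(self, theta: np.ndarray, y_mean: float, n_design_cols: int
                         ) -> np.ndarray:
        beta = np.zeros(n_design_cols)
        scaled = theta / self.sds
        np.add.at(beta, self.col_map, scaled)
        beta[0] = y_mean - float(self.means / self.sds @ theta)
        return beta


def _assemble(design: GroupedDesign, variant: str) -> _Problem:
    M = design.matrix
    penalized = [g for g in design.groups if g.kind != "intercept"]

    latent_cols: list[int] = []
    groups: list[np.ndarray] = []
    names: list[str] = []
    if variant == "GL":
        for g in penalized:
            idx = range(len(latent_cols), len(latent_cols) + len(g.cols))
            latent_cols.extend(g.cols)
            groups.append(np.fromiter(idx, int))
            names.append(g.name)
    elif variant == "HGL":
        # main/arm groups as-is, plus overlapped interaction groups that carry
        # copies of both parents' columns (glinternet penalty)
        for g in penalized:
            if g.kind == "interaction":
                continue
            idx = range(len(latent_cols), len(latent_cols) + len(g.cols))
            latent_cols.extend(g.cols)
            groups.append(np.fromiter(idx, int))
            names.append(g.name)
        for g in design.interaction_groups():
            cols = []
            for parent in g.parents:
                cols.extend(design.group_by_name(parent).cols)
            cols.extend(g.cols)
            idx = range(len(latent_cols), len(latent_cols) + len(cols))
            latent_cols.extend(cols)
            groups.append(np.fromiter(idx, int))
            names.append(g.name)
    else:
        raise ValueError(f"unknown variant {variant!r}; use 'GL' or 'HGL'")

    col_map = np.asarray(latent_cols, int)
    Z = M[:, col_map].astype(float)
    means = Z.mean(axis=0)
    sds = Z.std(axis=0)
    degenerate = sds <= 1e-12
    keep_groups, keep_names = [], []
    keep_mask = ~degenerate
    for g, nm in zip(groups, names):
        if keep_mask[g].any():
            keep_groups.append(g)
            keep_names.append(nm)
        else:
            warnings.warn(f"group '{nm}' is constant after standardization; dropped")
    sds = np.where(degenerate, 1.0, sds)
    Z = (Z - means) / sds
    Z[:, degenerate] = 0.0
    weights = np.array([np.sqrt(keep_mask[g].sum()) for g in keep_groups])
    return _Problem(Z=Z, col_map=col_map, groups=keep_groups, group_names=keep_names,
                    weights=weights, means=means, sds=sds)


def _lambda_grid(prob: _Problem, y: np.ndarray, n_lambdas: int, decades: float
                 ) -> np.ndarray:
    yc = y - y.mean()
    n = len(y)
    lam_max = max(
        np.linalg.norm(prob.Z[:, g].T @ yc / n) / w
        for g, w in zip(prob.groups, prob.weights)
    )
    lam_max = max(lam_max, 1e-12)
    return np.logspace(np.log10(lam_max), np.log10(lam_max) - decades, n_lambdas)


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------

@dataclass
class PenalizedFit:
    """A fitted GL/HGL penalized least-squares model."""

    design: GroupedDesign
    variant: str
    beta: np.ndarray                       # on the original design scale, incl. intercept
    lam: float
    cv_lambdas: np.ndarray
    cv_mse: np.ndarray
    selected_groups: dict[str, bool]       # latent group name -> nonzero
    latent_theta: np.ndarray = field(repr=False, default=None)

    def predict_arm_means(self, X: pd.DataFrame) -> np.ndarray:
        """``n x K`` predicted conditional means, one column per arm."""
        return np.column_stack([
            design_for_arm(self.design, X, a) @ self.beta
            for a in range(1, self.design.K + 1)
        ])

    def selected_interactions(self) -> dict[str, bool]:
        """Per-covariate indicator that its arm-interaction group is selected."""
        out = {}
        for g in self.design.interaction_groups():
            cov = g.name.split(":", 1)[1]
            out[cov] = self.selected_groups.get(g.name, False)
        return out

    def summary(self) -> dict:
        """JSON-serializable fit summary: selected groups, lambda, CV curve."""
        return {
            "variant": self.variant,
            "lambda": self.lam,
            "cv_lambdas": [float(v) for v in self.cv_lambdas],
            "cv_mse": [float(v) for v in self.cv_mse],
            "selected_groups": {k: bool(v) for k, v in self.selected_groups.items()},
            "selected_interactions": self.selected_interactions(),
        }

    def satisfies_strong_hierarchy(self, tol: float = 1e-10) -> bool:
        """Check that every nonzero interaction block has nonzero parent effects."""
        for g in self.design.interaction_groups():
            if np.linalg.norm(self.beta[list(g.cols)]) > tol:
                for parent in g.parents:
                    pcols = list(self.design.group_by_name(parent).cols)
                    if np.linalg.norm(self.beta[pcols]) <= tol:
                        return False
        return True


def fit_penalized(design: GroupedDesign, y: np.ndarray, variant: str = "GL",
                  lam_grid: np.ndarray | None = None, n_lambdas: int = 50,
                  lambda_decades: float = 4.0, cv_folds: int = 5, seed: int = 0,
                  tol: float = 1e-7, max_iter: int = 5000) -> PenalizedFit:
    """Fit GL or HGL penalized least squares with lambda chosen by K-fold CV.

    The intercept is unpenalized (handled by centering); all other groups carry
    a sqrt(group size) penalty weight.  The CV criterion is mean squared
    prediction error; the minimizing lambda is refitted on the full data.
    """
    y = np.asarray(y, float)
    if len(y) != design.matrix.shape[0]:
        raise ValueError("design and y are not conformable")
    prob = _assemble(design, variant)
    if lam_grid is None:
        lam_grid = _lambda_grid(prob, y, n_lambdas, lambda_decades)
    lam_grid = np.asarray(lam_grid, float)

    cv_mse = np.zeros((cv_folds, len(lam_grid)))
    rng = np.random.default_rng(seed)
    folds = rng.permutation(len(y)) % cv_folds
    for f in range(cv_folds):
        tr, te = folds != f, folds == f
        Ztr, ytr = prob.Z[tr], y[tr]
        mz, my = Ztr.mean(axis=0), ytr.mean()
        thetas = _fista_path(Ztr - mz, ytr - my, prob.groups, prob.weights,
                             lam_grid, tol=tol, max_iter=max_iter)
        preds = my + (prob.Z[te] - mz) @ thetas.T
        cv_mse[f] = np.mean((y[te, None] - preds) ** 2, axis=0)
    mean_mse = cv_mse.mean(axis=0)
    best = int(np.argmin(mean_mse))
    lam = float(lam_grid[best])

    theta = _fista_path(prob.Z - prob.Z.mean(axis=0), y - y.mean(),
                        prob.groups, prob.weights,
                        lam_grid[: best + 1], tol=tol, max_iter=max_iter)[-1]
    beta = prob.to_original_beta(theta, float(y.mean()), design.n_cols)
    selected = {
        nm: bool(np.linalg.norm(theta[g]) > 0)
        for nm, g in zip(prob.group_names, prob.groups)
    }
    return PenalizedFit(design=design, variant=variant, beta=beta, lam=lam,
                        cv_lambdas=lam_grid, cv_mse=mean_mse,
                        selected_groups=selected, latent_theta=theta)


def rule_from_fit(fit: PenalizedFit, provenance_extra: str = "") -> Rule:
    """The argmax-of-predicted-means rule induced by a penalized fit."""
    K = fit.design.K

    def decide(X: pd.DataFrame) -> np.ndarray:
        return argmax_arms(fit.predict_arm_means(X))

    return Rule(decide_fn=decide, K=K,
                provenance=f"l1-PLS-{fit.variant}(lam={fit.lam:.4g}){provenance_extra}")


def fit_pls(data: TrialDataset, variant: str = "GL", cv_folds: int = 5,
            seed: int = 0, **kwargs) -> tuple[Rule, PenalizedFit]:
    """Convenience wrapper: build the grouped design, fit, and return the rule."""
    design = build_design(data.X, data.A, data.K)
    fit = fit_penalized(design, data.Y, variant=variant, cv_folds=cv_folds,
                        seed=seed, **kwargs)
    return rule_from_fit(fit), fit


def selection_frequency(fits: list[PenalizedFit]) -> pd.Series:
    """Percentage of fits in which each covariate's arm-interaction group is nonzero."""
    if len(fits) < 2:
        raise ValueError("selection frequencies need at least two fits")
    counts: dict[str, int] = {}
    for f in fits:
        for cov, sel in f.selected_interactions().items():
            counts[cov] = counts.get(cov, 0) + int(sel)
    return pd.Series({c: 100.0 * k / len(fits) for c, k in counts.items()},
                     name="selection_pct")
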