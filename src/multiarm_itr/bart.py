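"""Bayesian additive regression trees (BART) and the posterior-argmax rule.

The outcome model is a sum of ``m`` regression trees with Gaussian noise,

    Y = sum_{j=1}^m g(x; T_j, M_j) + eps,   eps ~ N(0, sigma^2),

fitted by Bayesian backfitting MCMC: each sweep updates every tree's structure
by a Metropolis-Hastings grow/prune/change proposal against its partial
residual, redraws all leaf means from their conjugate normal conditionals, and
redraws ``sigma^2`` from its inverse-gamma conditional.  Priors follow the
standard defaults: a depth-penalizing tree prior ``p(split at depth d) =
base * (1 + d)^(-power)``, leaf means ``N(0, sigma_mu^2)`` with ``sigma_mu =
(ymax - ymin)_scaled / (2 k sqrt(m))`` after the outcome is internally mapped
to ``[-0.5, 0.5]``, and ``sigma^2 ~ nu lambda / chi^2_nu`` with ``lambda``
calibrated so that ``P(sigma < sd(y)) = q``.

For treatment-rule estimation the arm enters the design as dummy variables so
trees may split on any arm contrast; the ITR assigns each subject to the arm
with the largest posterior mean of ``E(Y | X = x, A = a)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core import Rule, TrialDataset, UndefinedITREffectError, argmax_arms
from .design import CovariateEncoder

__all__ = ["BARTModel", "PosteriorDraws", "fit_bart", "bart_rule",
           "posterior_itr_effect", "posterior_value", "optimized_itr_reference"]


class _Node:
    __slots__ = ("nid", "var", "cut", "left", "right", "depth")

    def __init__(self, nid: int, depth: int):
        self.nid = nid
        self.depth = depth
        self.var = -1          # -1 marks a leaf
        self.cut = 0.0
        self.left: "_Node | None" = None
        self.right: "_Node | None" = None

    @property
    def is_leaf(self) -> bool:
        return self.var < 0


class _Tree:
    """One regression tree plus cached leaf assignments for train and test rows."""

    def __init__(self, n_train: int, n_test: int):
        self.root = _Node(0, 0)
        self.nodes: dict[int, _Node] = {0: self.root}
        self.next_id = 1
        self.val = np.zeros(8)               # leaf values indexed by node id
        self.leaf_of_train = np.zeros(n_train, dtype=np.int64)
        self.leaf_of_test = np.zeros(n_test, dtype=np.int64)

    def _ensure_capacity(self, nid: int) -> None:
        if nid >= len(self.val):
            new = np.zeros(max(2 * len(self.val), nid + 1))
            new[: len(self.val)] = self.val
            self.val = new

    def leaves(self) -> list[_Node]:
        return [nd for nd in self.nodes.values() if nd.is_leaf]

    def prunable(self) -> list[_Node]:
        """Internal nodes whose two children are both leaves."""
        return [nd for nd in self.nodes.values()
                if not nd.is_leaf and nd.left.is_leaf and nd.right.is_leaf]

    def fit_train(self) -> np.ndarray:
        return self.val[self.leaf_of_train]

    def fit_test(self) -> np.ndarray:
        return self.val[self.leaf_of_test]


def _marginal_loglik(n, s, sigma2, sigmu2):
    """Log integrated likelihood of residuals in one leaf (up to shared constants).

    ``n`` is the row count and ``s`` the residual sum; the leaf mean has prior
    N(0, sigma_mu^2).
    """
    denom = sigma2 + n * sigmu2
    return 0.5 * np.log(sigma2 / denom) + sigmu2 * s * s / (2.0 * sigma2 * denom)


class BARTModel:
    """Sum-of-trees sampler with posterior predictive draws at test points.

    Parameters mirror the conventional defaults: 200 trees, tree prior
    ``base=0.95, power=2``, leaf-scale ``k=2``, error-variance prior
    ``nu=3, q=0.90``, 100 burn-in sweeps and 1000 kept draws.
    """

    P_GROW, P_PRUNE, P_CHANGE = 0.25, 0.25, 0.5

    def __init__(self, n_trees: int = 200, n_burn: int = 100, n_draws: int = 1000,
                 k: float = 2.0, base: float = 0.95, power: float = 2.0,
                 nu: float = 3.0, q: float = 0.90, n_cutpoints: int = 100,
                 min_leaf: int = 5, seed: int = 0):
        self.n_trees = n_trees
        self.n_burn = n_burn
        self.n_draws = n_draws
        self.k = k
        self.base = base
        self.power = power
        self.nu = nu
        self.q = q
        self.n_cutpoints = n_cutpoints
        self.min_leaf = min_leaf
        self.seed = seed

    # -- prior helpers ------------------------------------------------------
    def _p_split(self, depth: int) -> float:
        return self.base * (1.0 + depth) ** (-self.power)

    # -- fitting ------------------------------------------------------------
    def fit(self, X: np.ndarray, y: np.ndarray, X_test: np.ndarray) -> "BARTModel":
        X = np.asarray(X, float)
        y = np.asarray(y, float)
        X_test = np.asarray(X_test, float)
        if not np.isfinite(y).all():
            raise ValueError("non-finite outcomes are not allowed")
        rng = np.random.default_rng(self.seed)
        n, p = X.shape
        n_test = X_test.shape[0]

        # internal standardization of y to [-0.5, 0.5]
        y_min, y_max = y.min(), y.max()
        self._shift, self._scale = y_min, max(y_max - y_min, 1e-12)
        ys = (y - self._shift) / self._scale - 0.5

        sigmu2 = (1.0 / (2.0 * self.k * np.sqrt(self.n_trees))) ** 2
        sd_ys = max(ys.std(ddof=1), 1e-8)
        lam = sd_ys**2 * stats.chi2.ppf(1.0 - self.q, self.nu) / self.nu
        sigma2 = sd_ys**2

        # cutpoint grids: uniform quantile grid per variable (binary -> 0.5)
        cuts = []
        for j in range(p):
            u = np.unique(X[:, j])
            if len(u) <= 2:
                grid = (u[:-1] + u[1:]) / 2.0 if len(u) == 2 else u
            else:
                qs = np.quantile(X[:, j], np.linspace(0, 1, self.n_cutpoints + 2)[1:-1])
                grid = np.unique(qs)
            cuts.append(grid)

        trees = [_Tree(n, n_test) for _ in range(self.n_trees)]
        total_fit = np.zeros(n)

        S = self.n_draws
        self.test_draws_ = np.empty((S, n_test))
        self.sigma_draws_ = np.empty(S)

        for it in range(self.n_burn + S):
            for tree in trees:
                fit_j = tree.fit_train()
                resid = ys - total_fit + fit_j   # partial residual for this tree
                self._update_tree(tree, X, X_test, resid, sigma2, sigmu2, cuts, rng)
                new_fit = self._draw_leaf_values(tree, resid, sigma2, sigmu2, rng)
                total_fit += new_fit - fit_j
            e = ys - total_fit
            sigma2 = (self.nu * lam + e @ e) / rng.chisquare(self.nu + n)
            if it >= self.n_burn:
                s = it - self.n_burn
                self.test_draws_[s] = sum(t.fit_test() for t in trees)
                self.sigma_draws_[s] = np.sqrt(sigma2) * self._scale
        # back-transform test draws to the original outcome scale
        self.test_draws_ = (self.test_draws_ + 0.5) * self._scale + self._shift
        return self

    # -- MCMC moves ---------------------------------------------------------
    def _update_tree(self, tree, X, X_test, resid, sigma2, sigmu2, cuts, rng):
        leaves = tree.leaves()
        if len(tree.nodes) == 1:
            move = "grow"
            p_fwd = 1.0
        else:
            u = rng.random()
            move = "grow" if u < self.P_GROW else ("prune" if u < 0.5 else "change")
            p_fwd = self.P_GROW if move == "grow" else self.P_PRUNE

        if move == "grow":
            leaf = leaves[rng.integers(len(leaves))]
            var = int(rng.integers(X.shape[1]))
            grid = cuts[var]
            if len(grid) == 0:
                return
            cut = float(grid[rng.integers(len(grid))])
            rows = np.where(tree.leaf_of_train == leaf.nid)[0]
            go_left = X[rows, var] <= cut
            n_l = int(go_left.sum())
            n_r = len(rows) - n_l
            if n_l < self.min_leaf or n_r < self.min_leaf:
                return
            r = resid[rows]
            s_l = float(r[go_left].sum())
            s_all = float(r.sum())
            loglik = (_marginal_loglik(n_l, s_l, sigma2, sigmu2)
                      + _marginal_loglik(n_r, s_all - s_l, sigma2, sigmu2)
                      - _marginal_loglik(len(rows), s_all, sigma2, sigmu2))
            d = leaf.depth
            ps, ps_child = self._p_split(d), self._p_split(d + 1)
            log_prior = np.log(ps) + 2.0 * np.log(1.0 - ps_child) - np.log(1.0 - ps)
            n_prunable_new = self._count_prunable_after_grow(tree, leaf)
            log_prop = (np.log(self.P_PRUNE)
                        - np.log(n_prunable_new)
                        - np.log(p_fwd) + np.log(len(leaves)))
            if np.log(rng.random()) < loglik + log_prior + log_prop:
                self._apply_grow(tree, leaf, var, cut, rows, go_left, X_test)

        elif move == "prune":
            cand = tree.prunable()
            node = cand[rng.integers(len(cand))]
            lid, rid = node.left.nid, node.right.nid
            rows = np.where((tree.leaf_of_train == lid) | (tree.leaf_of_train == rid))[0]
            in_left = tree.leaf_of_train[rows] == lid
            r = resid[rows]
            s_l = float(r[in_left].sum())
            s_all = float(r.sum())
            n_l = int(in_left.sum())
            loglik = (_marginal_loglik(len(rows), s_all, sigma2, sigmu2)
                      - _marginal_loglik(n_l, s_l, sigma2, sigmu2)
                      - _marginal_loglik(len(rows) - n_l, s_all - s_l, sigma2, sigmu2))
            d = node.depth
            ps, ps_child = self._p_split(d), self._p_split(d + 1)
            log_prior = -(np.log(ps) + 2.0 * np.log(1.0 - ps_child) - np.log(1.0 - ps))
            n_leaves_new = len(leaves) - 1
            p_grow_new = 1.0 if len(tree.nodes) == 3 else self.P_GROW
            log_prop = (np.log(p_grow_new) - np.log(n_leaves_new)
                        - np.log(self.P_PRUNE) + np.log(len(cand)))
            if np.log(rng.random()) < loglik + log_prior + log_prop:
                self._apply_prune(tree, node, rows)

        else:  # change: redraw the split rule of a prunable internal node
            cand = tree.prunable()
            node = cand[rng.integers(len(cand))]
            var = int(rng.integers(X.shape[1]))
            grid = cuts[var]
            if len(grid) == 0:
                return
            cut = float(grid[rng.integers(len(grid))])
            lid, rid = node.left.nid, node.right.nid
            rows = np.where((tree.leaf_of_train == lid) | (tree.leaf_of_train == rid))[0]
            new_left = X[rows, var] <= cut
            n_l = int(new_left.sum())
            if n_l < self.min_leaf or len(rows) - n_l < self.min_leaf:
                return
            r = resid[rows]
            old_left = tree.leaf_of_train[rows] == lid
            s_all = float(r.sum())
            s_l_new, s_l_old = float(r[new_left].sum()), float(r[old_left].sum())
            n_l_old = int(old_left.sum())
            loglik = (_marginal_loglik(n_l, s_l_new, sigma2, sigmu2)
                      + _marginal_loglik(len(rows) - n_l, s_all - s_l_new, sigma2, sigmu2)
                      - _marginal_loglik(n_l_old, s_l_old, sigma2, sigmu2)
                      - _marginal_loglik(len(rows) - n_l_old, s_all - s_l_old,
                                         sigma2, sigmu2))
            if np.log(rng.random()) < loglik:
                node.var, node.cut = var, cut
                tree.leaf_of_train[rows] = np.where(new_left, lid, rid)
                t_rows = np.where((tree.leaf_of_test == lid) | (tree.leaf_of_test == rid))[0]
                if len(t_rows):
                    tree.leaf_of_test[t_rows] = np.where(
                        X_test[t_rows, var] <= cut, lid, rid)

    @staticmethod
    def _count_prunable_after_grow(tree: _Tree, leaf: _Node) -> int:
        # the grown node becomes prunable; its parent (if prunable) stops being so
        return 1 + sum(
            1 for nd in tree.prunable()
            if nd.left is not leaf and nd.right is not leaf
        )

    def _apply_grow(self, tree, leaf, var, cut, rows, go_left, X_test):
        leaf.var, leaf.cut = var, cut
        l = _Node(tree.next_id, leaf.depth + 1)
        r = _Node(tree.next_id + 1, leaf.depth + 1)
        tree.next_id += 2
        leaf.left, leaf.right = l, r
        tree.nodes[l.nid] = l
        tree.nodes[r.nid] = r
        tree._ensure_capacity(r.nid)
        tree.leaf_of_train[rows] = np.where(go_left, l.nid, r.nid)
        t_rows = np.where(tree.leaf_of_test == leaf.nid)[0]
        if len(t_rows):
            tree.leaf_of_test[t_rows] = np.where(
                X_test[t_rows, var] <= cut, l.nid, r.nid)

    @staticmethod
    def _apply_prune(tree, node, rows):
        del tree.nodes[node.left.nid], tree.nodes[node.right.nid]
        lid, rid = node.left.nid, node.right.nid
        node.left = node.right = None
        node.var = -1
        tree.leaf_of_train[rows] = node.nid
        t_rows = (tree.leaf_of_test == lid) | (tree.leaf_of_test == rid)
        tree.leaf_of_test[t_rows] = node.nid

    def _draw_leaf_values(self, tree, resid, sigma2, sigmu2, rng) -> np.ndarray:
        ids, inv = np.unique(tree.leaf_of_train, return_inverse=True)
        counts = np.bincount(inv)
        sums = np.bincount(inv, weights=resid)
        post_var = sigma2 * sigmu2 / (sigma2 + counts * sigmu2)
        post_mean = sigmu2 * sums / (sigma2 + counts * sigmu2)
        draws = post_mean + np.sqrt(post_var) * rng.standard_normal(len(ids))
        tree._ensure_capacity(int(ids.max()))
        tree.val[ids] = draws
        return tree.val[tree.leaf_of_train]


# ---------------------------------------------------------------------------
# ITR layer on top of the sampler
# ---------------------------------------------------------------------------

@dataclass
class PosteriorDraws:
    """Posterior predictive draws of ``E(Y | X = x, A = a)`` per subject and arm."""

    draws: np.ndarray          # S x n x K, original outcome scale
    K: int
    encoder: CovariateEncoder = field(repr=False, default=None)
    settings: dict = field(default_factory=dict)

    @property
    def n_draws(self) -> int:
        return self.draws.shape[0]

    def posterior_means(self) -> np.ndarray:
        """n x K posterior-mean surface, the basis of the BART ITR."""
        return self.draws.mean(axis=0)


def _design_matrix(encoder: CovariateEncoder, X: pd.DataFrame, A: np.ndarray, K: int
                   ) -> np.ndarray:
    blocks = encoder.blocks(X)
    M = np.hstack([blocks[c] for c in X.columns if blocks[c].shape[1]])
    armD = np.column_stack([(np.asarray(A) == a).astype(float) for a in range(2, K + 1)])
    return np.hstack([M, armD])


def fit_bart(data: TrialDataset, X_eval: pd.DataFrame | None = None,
             n_trees: int = 200, n_burn: int = 100, n_draws: int = 1000,
             k: float = 2.0, base: float = 0.95, power: float = 2.0,
             nu: float = 3.0, q: float = 0.90, seed: int = 0) -> PosteriorDraws:
    """Fit BART to ``E(Y | X, A)`` and draw the K counterfactual surfaces.

    ``X_eval`` defaults to the training covariates; predictions are returned
    for every evaluation subject under each of the K arm settings.
    """
    X_eval = data.X if X_eval is None else X_eval
    encoder = CovariateEncoder().fit(data.X)
    Xtr = _design_matrix(encoder, data.X, data.A, data.K)
    n_eval = len(X_eval)
    Xte = np.vstack([
        _design_matrix(encoder, X_eval, np.full(n_eval, a), data.K)
        for a in range(1, data.K + 1)
    ])
    model = BARTModel(n_trees=n_trees, n_burn=n_burn, n_draws=n_draws, k=k,
                      base=base, power=power, nu=nu, q=q, seed=seed)
    model.fit(Xtr, data.Y, Xte)
    draws = model.test_draws_.reshape(n_draws, data.K, n_eval).transpose(0, 2, 1)
    return PosteriorDraws(draws=draws, K=data.K, encoder=encoder,
                          settings=dict(n_trees=n_trees, n_burn=n_burn,
                                        n_draws=n_draws, k=k, base=base,
                                        power=power, nu=nu, q=q, seed=seed))


def bart_rule(draws: PosteriorDraws) -> np.ndarray:
    """Per-subject argmax of posterior means (arm labels 1..K, ties to smallest)."""
    return argmax_arms(draws.posterior_means())


def posterior_itr_effect(draws: PosteriorDraws, observed_arms: np.ndarray,
                         rule_arms: np.ndarray) -> tuple[float, tuple[float, float], np.ndarray]:
    """Posterior of the model-based ITR effect of a rule.

    Per posterior draw the effect contrasts the mean predicted outcome at the
    observed arm between rule-concordant and rule-discordant subjects.  Returns
    ``(posterior mean, (2.5%, 97.5%) equal-tail interval, per-draw effects)``.
    """
    observed_arms = np.asarray(observed_arms, int)
    rule_arms = np.asarray(rule_arms, int)
    conc = observed_arms == rule_arms
    if conc.all() or not conc.any():
        raise UndefinedITREffectError(
            "posterior ITR effect undefined: empty concordant or discordant group")
    n = draws.draws.shape[1]
    pred_obs = draws.draws[:, np.arange(n), observed_arms - 1]  # S x n
    eff = pred_obs[:, conc].mean(axis=1) - pred_obs[:, ~conc].mean(axis=1)
    lo, hi = np.percentile(eff, [2.5, 97.5])
    return float(eff.mean()), (float(lo), float(hi)), eff


def posterior_value(draws: PosteriorDraws, rule_arms: np.ndarray) -> np.ndarray:
    """Per-draw mean predicted outcome if everyone followed ``rule_arms``."""
    n = draws.draws.shape[1]
    return draws.draws[:, np.arange(n), np.asarray(rule_arms, int) - 1].mean(axis=1)


def optimized_itr_reference(draws: PosteriorDraws) -> dict:
    """Best-case reference: per MCMC draw, assign each subject to that draw's
    argmax arm.  Non-achievable in practice (the rule varies across draws), but
    its per-draw value dominates any fixed rule's per-draw value exactly.
    """
    per_draw_arms = draws.draws.argmax(axis=2) + 1          # S x n
    per_draw_value = draws.draws.max(axis=2).mean(axis=1)   # S
    return {
        "per_draw_arms": per_draw_arms,
        "per_draw_value": per_draw_value,
        "non_achievable_reference": True,
    }


def fit_bart_itr(data: TrialDataset, X_eval: pd.DataFrame | None = None,
                 seed: int = 0, **bart_kwargs) -> tuple[Rule, PosteriorDraws]:
    """Convenience wrapper returning a Rule that re-predicts on new covariates.

    The returned rule caches the evaluation-set decisions; deciding for a
    different covariate table refits predictions through the stored posterior
    is not possible (trees are not retained), so the rule is only defined for
    the evaluation table it was built with.
    """
    X_eval = data.X if X_eval is None else X_eval
    draws = fit_bart(data, X_eval=X_eval, seed=seed, **bart_kwargs)
    arms = bart_rule(draws)

    def decide(Xn: pd.DataFrame) -> np.ndarray:
        if len(Xn) == len(X_eval) and (Xn is X_eval or Xn.equals(X_eval)):
            return arms
        raise ValueError("BART rule is defined only for its evaluation covariate table")

    rule = Rule(decide_fn=decide, K=data.K, provenance="BART(posterior-argmax)")
    rule.cached_arms_ = arms
    return rule, draws
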