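"""Design-matrix construction on the basis ``(1, X, A, XA)`` with group structure.

Categorical covariates are dummy-coded at the factor level (first level as
reference), the arm enters through ``K - 1`` dummy variables, and every
covariate contributes an arm-interaction block of ``(levels - 1) * (K - 1)``
columns (or ``K - 1`` for a continuous covariate).  Each covariate's main
effect, the arm dummies, and each covariate-by-arm block form the groups used
by factor-level (group-lasso) selection; the hierarchy map links each
interaction group to its two parents (the covariate's main-effect group and
the arm group).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["CovariateEncoder", "Group", "GroupedDesign", "build_design"]


@dataclass(frozen=True)
class Group:
    name: str
    cols: tuple[int, ...]
    kind: str  # "intercept" | "main" | "arm" | "interaction"
    parents: tuple[str, ...] = ()  # for interactions: (main group name, arm group name)


class CovariateEncoder:
    """Dummy-codes a covariate table with declared categorical levels.

    The level lists are frozen at fit time; an unseen category at predict time
    is rejected with the offending column named.
    """

    def __init__(self) -> None:
        self.columns_: list[str] | None = None
        self.levels_: dict[str, list] = {}

    def fit(self, X: pd.DataFrame) -> "CovariateEncoder":
        self.columns_ = list(X.columns)
        self.levels_ = {}
        for c in X.columns:
            if isinstance(X[c].dtype, pd.CategoricalDtype) or X[c].dtype == object:
                self.levels_[c] = list(pd.unique(pd.Series(X[c]).astype("category").cat.categories))
        return self

    def blocks(self, X: pd.DataFrame) -> dict[str, np.ndarray]:
        """Per-covariate encoded blocks (n x n_cols_j arrays)."""
        if self.columns_ is None:
            raise RuntimeError("encoder not fitted")
        if list(X.columns) != self.columns_:
            raise ValueError("covariate schema mismatch with the training data")
        out: dict[str, np.ndarray] = {}
        for c in self.columns_:
            if c in self.levels_:
                levels = self.levels_[c]
                vals = pd.Series(X[c]).astype(object)
                unseen = set(vals.unique()) - set(levels)
                if unseen:
                    raise ValueError(f"unseen category {unseen!r} in column '{c}'")
                # reference = first level; one dummy per remaining level
                out[c] = np.column_stack(
                    [(vals == lv).to_numpy(float) for lv in levels[1:]]
                ) if len(levels) > 1 else np.zeros((len(X), 0))
            else:
                out[c] = X[c].to_numpy(float).reshape(-1, 1)
        return out

    def block_names(self, c: str) -> list[str]:
        if c in self.levels_:
            return [f"{c}[{lv}]" for lv in self.levels_[c][1:]]
        return [c]


@dataclass
class GroupedDesign:
    """A grouped design matrix with its encoder and hierarchy map."""

    matrix: np.ndarray
    col_names: list[str]
    groups: list[Group]
    encoder: CovariateEncoder
    K: int
    arm_reference: int = 1
    hierarchy: dict[str, tuple[str, str]] = field(default_factory=dict)

    @property
    def n_cols(self) -> int:
        return self.matrix.shape[1]

    def group_by_name(self, name: str) -> Group:
        for g in self.groups:
            if g.name == name:
                return g
        raise KeyError(name)

    def interaction_groups(self) -> list[Group]:
        return [g for g in self.groups if g.kind == "interaction"]


def _arm_dummies(A: np.ndarray, K: int, reference: int) -> tuple[np.ndarray, list[str]]:
    arms = [a for a in range(1, K + 1) if a != reference]
    M = np.column_stack([(np.asarray(A) == a).astype(float) for a in arms])
    return M, [f"A[{a}]" for a in arms]


def build_design(X: pd.DataFrame, A: np.ndarray, K: int,
                 encoder: CovariateEncoder | None = None,
                 arm_reference: int = 1) -> GroupedDesign:
    """Build the grouped ``(1, X, A, XA)`` design for ``n`` subjects."""
    if K < 2:
        raise ValueError("K must be at least 2")
    if encoder is None:
        encoder = CovariateEncoder().fit(X)
    blocks = encoder.blocks(X)
    armM, arm_names = _arm_dummies(A, K, arm_reference)

    cols: list[np.ndarray] = [np.ones((len(X), 1))]
    names: list[str] = ["(intercept)"]
    groups: list[Group] = [Group("(intercept)", (0,), "intercept")]
    idx = 1
    for c in X.columns:
        B = blocks[c]
        if B.shape[1] == 0:
            continue
        cols.append(B)
        names.extend(encoder.block_names(c))
        groups.append(Group(f"main:{c}", tuple(range(idx, idx + B.shape[1])), "main"))
        idx += B.shape[1]
    cols.append(armM)
    names.extend(arm_names)
    groups.append(Group("arm", tuple(range(idx, idx + armM.shape[1])), "arm"))
    idx += armM.shape[1]
    hierarchy: dict[str, tuple[str, str]] = {}
    for c in X.columns:
        B = blocks[c]
        if B.shape[1] == 0:
            continue
        inter = np.einsum("ij,ik->ijk", B, armM).reshape(len(X), -1)
        cols.append(inter)
        names.extend(
            f"{bn}:{an}" for bn in encoder.block_names(c) for an in arm_names
        )
        gname = f"int:{c}"
        groups.append(Group(gname, tuple(range(idx, idx + inter.shape[1])),
                            "interaction", parents=(f"main:{c}", "arm")))
        hierarchy[gname] = (f"main:{c}", "arm")
        idx += inter.shape[1]

    return GroupedDesign(
        matrix=np.hstack(cols),
        col_names=names,
        groups=groups,
        encoder=encoder,
        K=K,
        arm_reference=arm_reference,
        hierarchy=hierarchy,
    )


def design_for_arm(design: GroupedDesign, X: pd.DataFrame, arm: int) -> np.ndarray:
    """Design rows for covariates ``X`` with every subject set to ``arm``."""
    sub = build_design(X, np.full(len(X), arm), design.K,
                       encoder=design.encoder, arm_reference=design.arm_reference)
    return sub.matrix
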