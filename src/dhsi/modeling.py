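"""Distilling the ranked index into a portable regression model.

Ranking ties every episode's score to the sample it was ranked in.  To
obtain an index computable on any new sample, the normalized score is
regressed on the 29 binary parameters (ordinary least squares), then
improved by adding pairwise interaction terms discovered with a regression
tree: at each node the splitter is the parameter with the largest absolute
difference in mean score between its two groups, growth stopping when a
terminal node would fall below ``min_node_size`` episodes or when the
split raises the tree's overall R-squared by no more than ``delta_r2``.
Splitter pairs that co-occur on a root-to-leaf path become candidate
interaction products; exactly collinear columns are dropped before the
refit.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .scoring import ALL_PARAMETERS

logger = logging.getLogger(__name__)

__all__ = [
    "DHSIModel",
    "TreeNode",
    "InteractionTree",
    "fit_initial_model",
    "grow_interaction_tree",
    "derive_interactions",
    "fit_improved_model",
    "predict_dhsi",
    "predict_frame",
]

COLLINEARITY_TOL = 1e-8


@dataclass
class DHSIModel:
    """Fitted linear model mapping a parameter vector to a 0-100 score."""

    intercept: float
    main_effects: dict[str, float]
    interactions: list[tuple[tuple[str, str], float]]
    dropped_terms: list
    fit_stats: dict[str, float]
    clamp_count: int = 0
    provenance: dict = field(default_factory=dict)

    def to_json(self, path=None) -> str:
        payload = {
            "intercept": self.intercept,
            "main_effects": self.main_effects,
            "interactions": [
                {"pair": list(pair), "coefficient": c} for pair, c in self.interactions
            ],
            "dropped_terms": [
                list(t) if isinstance(t, (tuple, list)) else t
                for t in self.dropped_terms
            ],
            "fit_stats": self.fit_stats,
            "provenance": self.provenance,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, path) -> "DHSIModel":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            intercept=payload["intercept"],
            main_effects=payload["main_effects"],
            interactions=[
                (tuple(item["pair"]), item["coefficient"])
                for item in payload["interactions"]
            ],
            dropped_terms=[
                tuple(t) if isinstance(t, list) else t
                for t in payload["dropped_terms"]
            ],
            fit_stats=payload["fit_stats"],
            provenance=payload.get("provenance", {}),
        )


def _design_matrix(
    X: pd.DataFrame, interactions: Sequence[tuple[str, str]]
) -> pd.DataFrame:
    design = X[list(ALL_PARAMETERS)].astype(float).copy()
    for a, b in interactions:
        design[f"{a}:{b}"] = design[a] * design[b]
    return design


def _independent_columns(design: pd.DataFrame) -> tuple[list[str], list[str]]:
    """Greedy selection of columns linearly independent of the intercept
    and of the columns kept so far (tolerance on singular values)."""
    n = len(design)
    kept_mat = [np.ones(n)]
    kept, dropped = [], []
    for col in design.columns:
        candidate = np.column_stack(kept_mat + [design[col].to_numpy()])
        s = np.linalg.svd(candidate, compute_uv=False)
        if s[-1] > COLLINEARITY_TOL * max(s[0], 1.0):
            kept.append(col)
            kept_mat.append(design[col].to_numpy())
        else:
            dropped.append(col)
    return kept, dropped


def _residual_stats(resid: np.ndarray, n_params: int) -> dict[str, float]:
    n = len(resid)
    dof = max(n - n_params, 1)
    return {
        "residual_standard_error": float(np.sqrt(np.sum(resid**2) / dof)),
        "resid_min": float(np.min(resid)),
        "resid_q1": float(np.percentile(resid, 25)),
        "resid_median": float(np.median(resid)),
        "resid_q3": float(np.percentile(resid, 75)),
        "resid_max": float(np.max(resid)),
    }


def _fit_ols(
    X: pd.DataFrame,
    y: np.ndarray,
    interactions: Sequence[tuple[str, str]],
) -> DHSIModel:
    y = np.asarray(y, dtype=float)
    design = _design_matrix(X, interactions)

    if np.var(y) == 0.0:
        # Degenerate response: slopes zero, R^2 defined as 0 by convention.
        resid = np.zeros_like(y)
        stats = {"r_squared": 0.0, "adjusted_r_squared": 0.0,
                 "f_statistic": float("nan"), **_residual_stats(resid, 1)}
        return DHSIModel(
            intercept=float(y[0]) if len(y) else 0.0,
            main_effects={p: 0.0 for p in ALL_PARAMETERS},
            interactions=[(tuple(pair), 0.0) for pair in interactions],
            dropped_terms=[],
            fit_stats=stats,
        )

    kept, dropped = _independent_columns(design)
    if dropped:
        logger.warning("dropping collinear design columns: %s", dropped)
    exog = sm.add_constant(design[kept], has_constant="add")
    res = sm.OLS(y, exog).fit()

    coefs = dict(zip(exog.columns, res.params))
    main = {p: float(coefs.get(p, 0.0)) for p in ALL_PARAMETERS}
    inter = []
    for a, b in interactions:
        name = f"{a}:{b}"
        if name in coefs:
            inter.append(((a, b), float(coefs[name])))

    dropped_terms: list = []
    for name in dropped:
        dropped_terms.append(tuple(name.split(":")) if ":" in name else name)

    stats = {
        "r_squared": float(res.rsquared),
        "adjusted_r_squared": float(res.rsquared_adj),
        "f_statistic": float(res.fvalue),
        **_residual_stats(np.asarray(res.resid), len(kept) + 1),
    }
    return DHSIModel(
        intercept=float(coefs["const"]),
        main_effects=main,
        interactions=inter,
        dropped_terms=dropped_terms,
        fit_stats=stats,
    )


def fit_initial_model(X: pd.DataFrame, y) -> DHSIModel:
    """OLS of the normalized ranking score on the 29 main effects."""
    return _fit_ols(X, y, interactions=[])


# ---------------------------------------------------------------------------
# Regression-tree interaction discovery
# ---------------------------------------------------------------------------


@dataclass
class TreeNode:
    size: int
    mean: float
    sse: float
    split_param: Optional[str] = None
    left: Optional["TreeNode"] = None   # split parameter absent (0)
    right: Optional["TreeNode"] = None  # split parameter present (1)
    r_squared_at_creation: float = 0.0

    @property
    def is_leaf(self) -> bool:
        return self.split_param is None


@dataclass
class InteractionTree:
    root: TreeNode
    min_node_size: int
    delta_r2: float
    r_squared_path: list[float] = field(default_factory=list)

    @property
    def r_squared(self) -> float:
        return self.r_squared_path[-1] if self.r_squared_path else 0.0

    def leaves(self) -> list[TreeNode]:
        out, stack = [], [self.root]
        while stack:
            node = stack.pop()
            if node.is_leaf:
                out.append(node)
            else:
                stack.extend([node.left, node.right])
        return out


def _node_sse(y: np.ndarray) -> float:
    return float(np.sum((y - y.mean()) ** 2)) if len(y) else 0.0


def _best_split(
    X: pd.DataFrame, y: np.ndarray, mask: np.ndarray, min_node_size: int
):
    """Admissible splitter maximizing |mean(y|x=1) - mean(y|x=0)| within the
    node; ties broken by larger SSE reduction, then by parameter order."""
    best = None
    y_node = y[mask]
    sse_node = _node_sse(y_node)
    for p in X.columns:
        xj = X[p].to_numpy()[mask]
        n1 = int(xj.sum())
        n0 = len(xj) - n1
        if n1 < min_node_size or n0 < min_node_size:
            continue
        m1 = y_node[xj == 1].mean()
        m0 = y_node[xj == 0].mean()
        diff = abs(m1 - m0)
        sse_red = sse_node - _node_sse(y_node[xj == 0]) - _node_sse(y_node[xj == 1])
        if best is None or diff > best[0] + 1e-12 or (
            abs(diff - best[0]) <= 1e-12 and sse_red > best[1] + 1e-12
        ):
            best = (diff, sse_red, p)
    return best


def grow_interaction_tree(
    X: pd.DataFrame,
    y,
    min_node_size: int = 50,
    delta_r2: float = 0.01,
) -> InteractionTree:
    """Recursive binary splitting on the binary parameters.

    The tree-level R-squared is ``1 - SSE(leaves)/SST(root)``; a node's
    best split is accepted only when it raises this overall R-squared by
    strictly more than ``delta_r2`` and leaves both children with at least
    ``min_node_size`` episodes.  Deterministic given (X, y).
    """
    y = np.asarray(y, dtype=float)
    params = [p for p in ALL_PARAMETERS if p in X.columns]
    Xp = X[params]
    sst = _node_sse(y)

    root = TreeNode(size=len(y), mean=float(y.mean()) if len(y) else 0.0,
                    sse=sst, r_squared_at_creation=0.0)
    tree = InteractionTree(root=root, min_node_size=min_node_size,
                           delta_r2=delta_r2, r_squared_path=[0.0])
    if sst == 0.0 or len(y) < 2 * min_node_size:
        return tree

    current_sse = [sst]  # mutable running SSE over all leaves

    def recurse(node: TreeNode, mask: np.ndarray) -> None:
        best = _best_split(Xp, y, mask, min_node_size)
        if best is None:
            return
        _, sse_red, p = best
        delta = sse_red / sst
        if delta <= delta_r2:
            return
        xj = Xp[p].to_numpy().astype(bool)
        mask0 = mask & ~xj
        mask1 = mask & xj
        current_sse[0] -= sse_red
        r2 = 1.0 - current_sse[0] / sst
        node.split_param = p
        node.left = TreeNode(size=int(mask0.sum()), mean=float(y[mask0].mean()),
                             sse=_node_sse(y[mask0]), r_squared_at_creation=r2)
        node.right = TreeNode(size=int(mask1.sum()), mean=float(y[mask1].mean()),
                              sse=_node_sse(y[mask1]), r_squared_at_creation=r2)
        tree.r_squared_path.append(r2)
        recurse(node.left, mask0)
        recurse(node.right, mask1)

    recurse(root, np.ones(len(y), dtype=bool))
    return tree


def derive_interactions(
    tree: InteractionTree, mode: str = "ancestor"
) -> list[tuple[str, str]]:
    """Candidate interaction pairs from co-occurring splitters.

    ``mode="ancestor"`` (default) pairs every ancestor splitter with every
    descendant splitter on a root-to-leaf path; ``mode="parent"`` restricts
    to immediate parent-child pairs.  Pairs are order-normalized and
    deduplicated, preserving discovery order; a parameter paired with
    itself is skipped (the product would duplicate the main effect).
    """
    if mode not in ("ancestor", "parent"):
        raise ValueError(f"unknown mode {mode!r}")
    seen: dict[tuple[str, str], None] = {}

    def walk(node: TreeNode, ancestors: list[str]) -> None:
        if node.is_leaf:
            return
        p = node.split_param
        pool = ancestors if mode == "ancestor" else ancestors[-1:]
        for a in pool:
            if a == p:
                continue
            pair = tuple(sorted((a, p), key=lambda q: ALL_PARAMETERS.index(q)))
            seen.setdefault(pair, None)
        walk(node.left, ancestors + [p])
        walk(node.right, ancestors + [p])

    walk(tree.root, [])
    return list(seen)


def fit_improved_model(
    X: pd.DataFrame, y, interactions: Sequence[tuple[str, str]]
) -> DHSIModel:
    """Refit with interaction product columns, dropping exact collinearity."""
    for a, b in interactions:
        for p in (a, b):
            if p not in ALL_PARAMETERS:
                raise ValueError(f"interaction references unknown parameter {p!r}")
    return _fit_ols(X, y, interactions=list(interactions))


def _features_from_vector(v) -> Mapping[str, int]:
    if isinstance(v, Mapping):
        flags = v
    elif isinstance(v, pd.Series):
        flags = v.to_dict()
    else:
        seq = list(v)
        if len(seq) != len(ALL_PARAMETERS):
            raise ValueError(
                f"expected {len(ALL_PARAMETERS)} flags, got {len(seq)}"
            )
        flags = dict(zip(ALL_PARAMETERS, seq))
    return flags


def predict_dhsi(model: DHSIModel, v) -> float:
    """Score a single parameter vector; results clamped to [0, 100].

    Clamping events are counted on ``model.clamp_count``.
    """
    flags = _features_from_vector(v)
    score = model.intercept
    for p in ALL_PARAMETERS:
        score += model.main_effects.get(p, 0.0) * float(flags[p])
    for (a, b), coef in model.interactions:
        score += coef * float(flags[a]) * float(flags[b])
    if score < 0.0 or score > 100.0:
        model.clamp_count += 1
    return float(min(max(score, 0.0), 100.0))


def predict_frame(model: DHSIModel, X: pd.DataFrame) -> np.ndarray:
    """Vectorized prediction over a parameter matrix, clamped to [0, 100]."""
    score = np.full(len(X), model.intercept, dtype=float)
    for p in ALL_PARAMETERS:
        score += model.main_effects.get(p, 0.0) * X[p].to_numpy(dtype=float)
    for (a, b), coef in model.interactions:
        score += coef * X[a].to_numpy(dtype=float) * X[b].to_numpy(dtype=float)
    model.clamp_count += int(np.sum((score < 0) | (score > 100)))
    return np.clip(score, 0.0, 100.0)
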