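"""Multivariate conditional-inference tree on the n x K pseudo-value outcome.

Split variables are chosen by permutation tests of generalized correlation
statistics between each covariate and the K-dimensional pseudo-value response:

    T_j = sum_{i in node} g_j(X_ij) (theta_i(t_1), ..., theta_i(t_K))^T ,

with g_j the identity for continuous covariates, integer scores for ordered
factors, and category indicators for unordered factors.  Each element of T_j is
centered and scaled by its exact conditional (permutation-null) mean and
standard deviation; the summary statistic is the maximum absolute standardized
element, so each test refers to the single time point with the strongest
association and is unaffected by the (possibly non-monotone) shape of the
pseudo-value trajectories.  P-values come from Monte-Carlo permutations that
shuffle whole individuals (rows of the pseudo-value matrix), preserving the
within-individual dependence.  The cutpoint maximizes the same standardized
two-sample statistic over all admissible binary partitions.

Permutation-null moments are the exact conditional (Strasser-Weber) ones: for
a linear statistic sum_i g_i * theta_ik permuted over individuals,

    E    = (sum_i g_i) * mean_k(theta),
    Var  = sum_i (g_i - mean(g))^2 * sum_i (theta_ik - mean_k)^2 / (m - 1).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .pseudo import InvalidInputError, PseudoValueMatrix

__all__ = [
    "SplitRule",
    "TreeNode",
    "TreeConfig",
    "correlation_statistic",
    "permutation_pvalue",
    "select_split_variable",
    "find_best_split",
    "grow_tree",
    "apply_tree",
    "tree_to_dict",
    "tree_from_dict",
]

_EPS = 1e-12


@dataclass(frozen=True)
class SplitRule:
    """Binary decision rule of one tree node.

    ``threshold`` rules send ``x <= xi`` left; ``subset`` rules send category
    members of ``left_categories`` left.  ``categories`` stores the training
    category order for ordered factors (needed to score new data).
    """

    variable: str
    var_index: int
    kind: str  # "threshold" | "subset"
    threshold: float | None = None
    left_categories: tuple = ()
    categories: tuple = ()

    def route_left(self, values: np.ndarray) -> np.ndarray:
        if self.kind == "threshold":
            if self.categories:  # ordered factor: map to integer scores
                lut = {c: i for i, c in enumerate(self.categories)}
                try:
                    codes = np.array([lut[v] for v in values], dtype=float)
                except KeyError as exc:
                    raise InvalidInputError(
                        f"unseen level {exc.args[0]!r} for ordered factor {self.variable!r}"
                    ) from None
                return codes <= self.threshold
            return np.asarray(values, dtype=float) <= self.threshold
        known = set(self.left_categories) | set(self.categories)
        unseen = {v for v in values} - known
        if unseen:
            raise InvalidInputError(
                f"unseen level(s) {sorted(map(str, unseen))} for factor {self.variable!r}"
            )
        left = set(self.left_categories)
        return np.array([v in left for v in values])


@dataclass
class TreeNode:
    node_id: int
    members: np.ndarray  # individual indices
    depth: int
    split: SplitRule | None = None
    children: tuple | None = None  # (left, right)
    p_value: float | None = None

    @property
    def is_terminal(self) -> bool:
        return self.split is None

    def terminal_nodes(self):
        if self.is_terminal:
            return [self]
        return self.children[0].terminal_nodes() + self.children[1].terminal_nodes()

    def all_nodes(self):
        if self.is_terminal:
            return [self]
        return [self] + self.children[0].all_nodes() + self.children[1].all_nodes()


@dataclass
class TreeConfig:
    """Stopping and testing parameters for tree growth.

    ``min_node_size`` is counted in individuals; with K grid points it
    corresponds to ``min_node_size * K`` augmented observations (default 5,
    i.e. five times the number of time points in rows).
    """

    max_depth: int = 2
    alpha: float = 0.05
    min_node_size: int = 5
    n_perm: int = 9999
    seed: int | None = None
    max_factor_categories: int = 10

    def __post_init__(self) -> None:
        if self.max_depth < 0:
            raise InvalidInputError("max_depth must be >= 0")
        if not (0 < self.alpha <= 1):
            raise InvalidInputError("alpha must lie in (0, 1]")
        if self.min_node_size < 1:
            raise InvalidInputError("min_node_size must be >= 1")


# ---------------------------------------------------------------------------
# covariate transformations


def transform_covariate(values, scale: str):
    """Influence transform g_j: (m x p~ matrix, categories tuple)."""
    if scale == "continuous":
        return np.asarray(values, dtype=float).reshape(-1, 1), ()
    cats = tuple(sorted(pd.unique(np.asarray(values))))
    if scale == "ordered":
        lut = {c: i for i, c in enumerate(cats)}
        codes = np.array([lut[v] for v in values], dtype=float)
        return codes.reshape(-1, 1), cats
    # unordered factor: one indicator column per observed category
    g = np.column_stack([(np.asarray(values) == c).astype(float) for c in cats])
    return g, cats


def _null_moments(g: np.ndarray, theta: np.ndarray):
    """Exact permutation mean and sd of each element of g^T theta."""
    m = theta.shape[0]
    theta_bar = theta.mean(axis=0)
    s_theta = ((theta - theta_bar) ** 2).sum(axis=0)  # (K,)
    g_sum = g.sum(axis=0)  # (q,)
    s_g = ((g - g.mean(axis=0)) ** 2).sum(axis=0)  # (q,)
    mean = np.outer(g_sum, theta_bar)
    var = np.outer(s_g, s_theta) / max(m - 1, 1)
    return mean, np.sqrt(var)


def correlation_statistic(theta: np.ndarray, covariate, scale: str = "continuous"):
    """Standardized generalized correlation statistic of one covariate.

    Returns the (p~ x K) matrix of standardized elements (NaN where the
    permutation variance is zero) and the maximum absolute standardized value
    (-inf if every element is degenerate, e.g. a constant covariate).
    """
    theta = np.asarray(theta, dtype=float)
    if theta.ndim != 2 or theta.shape[0] < 2:
        raise InvalidInputError("need at least two individuals")
    g, _ = transform_covariate(covariate, scale)
    if g.shape[0] != theta.shape[0]:
        raise InvalidInputError("covariate length does not match outcome rows")
    T = g.T @ theta
    mean, sd = _null_moments(g, theta)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (T - mean) / sd
    z[sd <= _EPS] = np.nan
    finite = np.isfinite(z)
    max_abs = np.abs(z[finite]).max() if finite.any() else -np.inf
    return z, float(max_abs)


def _stacked_blocks(theta, covariate_blocks):
    """Stack transformed covariates; return G, per-covariate column slices."""
    mats, slices, start = [], [], 0
    for g in covariate_blocks:
        mats.append(g)
        slices.append(slice(start, start + g.shape[1]))
        start += g.shape[1]
    G = np.hstack(mats) if mats else np.empty((theta.shape[0], 0))
    return G, slices


def _batch_max_abs(G, theta, mean, sd, slices, perm_idx):
    """Max-abs standardized statistics for a batch of permutations.

    perm_idx: (B, m) integer matrix of row permutations of theta.
    Returns (B, n_cov) matrix of per-covariate max-abs values.
    """
    theta_perm = theta[perm_idx]  # (B, m, K)
    T = np.matmul(G.T[None, :, :], theta_perm)  # (B, q, K)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.abs((T - mean[None]) / sd[None])
    z = np.where(sd[None] > _EPS, z, -np.inf)
    out = np.empty((perm_idx.shape[0], len(slices)))
    for j, sl in enumerate(slices):
        block = z[:, sl, :]
        out[:, j] = block.reshape(block.shape[0], -1).max(axis=1)
    return out


def permutation_pvalue(
    theta: np.ndarray,
    covariate,
    scale: str = "continuous",
    n_perm: int = 9999,
    rng: np.random.Generator | None = None,
) -> float:
    """Monte-Carlo permutation p-value of the max-abs correlation statistic.

    Permutations shuffle whole individuals (rows of theta), never single
    entries; p = (1 + #{permuted >= observed}) / (1 + n_perm).
    """
    rng = np.random.default_rng(rng)
    theta = np.asarray(theta, dtype=float)
    g, _ = transform_covariate(covariate, scale)
    _, obs = correlation_statistic(theta, covariate, scale)
    if not np.isfinite(obs):
        return 1.0
    mean, sd = _null_moments(g, theta)
    m = theta.shape[0]
    count = 0
    for lo in range(0, n_perm, 256):
        B = min(256, n_perm - lo)
        idx = rng.permuted(np.tile(np.arange(m), (B, 1)), axis=1)
        mx = _batch_max_abs(g, theta, mean, sd, [slice(0, g.shape[1])], idx)[:, 0]
        count += int((mx >= obs - _EPS).sum())
    return (1 + count) / (1 + n_perm)


def select_split_variable(theta, covariate_blocks, names, n_perm, rng, alpha):
    """Choose the covariate with minimal permutation p-value.

    A single shared permutation stream is used for all covariates.  Returns
    (index, p_value) or (None, min_p) when no p-value falls below ``alpha``.
    Ties are broken by larger observed statistic, then smaller index.
    """
    m = theta.shape[0]
    usable, obs_stats = [], []
    for j, g in enumerate(covariate_blocks):
        mean, sd = _null_moments(g, theta)
        if np.all(sd <= _EPS):
            obs_stats.append(-np.inf)
            continue
        T = g.T @ theta
        with np.errstate(invalid="ignore", divide="ignore"):
            z = np.abs((T - mean) / sd)
        z = np.where(sd > _EPS, z, -np.inf)
        obs_stats.append(z.max())
        usable.append(j)
    if not usable:
        return None, 1.0
    sub_blocks = [covariate_blocks[j] for j in usable]
    G, slices = _stacked_blocks(theta, sub_blocks)
    mean, sd = _null_moments(G, theta)
    obs = np.array([obs_stats[j] for j in usable])
    counts = np.zeros(len(usable), dtype=int)
    for lo in range(0, n_perm, 256):
        B = min(256, n_perm - lo)
        idx = rng.permuted(np.tile(np.arange(m), (B, 1)), axis=1)
        mx = _batch_max_abs(G, theta, mean, sd, slices, idx)
        counts += (mx >= obs[None] - _EPS).sum(axis=0)
    pvals = (1 + counts) / (1 + n_perm)
    # minimal p, ties by larger observed statistic, then smaller index
    order = sorted(range(len(usable)), key=lambda a: (pvals[a], -obs[a], usable[a]))
    best = order[0]
    if pvals[best] > alpha:
        return None, float(pvals.min())
    return usable[best], float(pvals[best])


def find_best_split(theta, covariate, scale, min_size, max_factor_categories=10):
    """Cutpoint maximizing the standardized two-sample statistic.

    Both daughters must contain at least ``min_size`` individuals; returns
    (left_mask, details) or None when no admissible partition exists.  For a
    partition with right-daughter size n_r in a node of size m the permutation
    moments are mu_k = n_r * mean_k(theta) and
    sigma^2_k = n_r (m - n_r) / (m - 1) * mean_i (theta_ik - mean_k)^2.
    """
    theta = np.asarray(theta, dtype=float)
    m, K = theta.shape
    theta_bar = theta.mean(axis=0)
    v = ((theta - theta_bar) ** 2).mean(axis=0)  # (K,)
    valid_k = v > _EPS
    if not valid_k.any() or m < 2 * min_size:
        return None
    tot = theta.sum(axis=0)

    def score(n_right, right_sums):
        # right_sums: (C, K); n_right: (C,)
        with np.errstate(invalid="ignore", divide="ignore"):
            var = np.outer(n_right * (m - n_right) / (m - 1), v)
            z = np.abs((right_sums - np.outer(n_right, theta_bar)) / np.sqrt(var))
        z[:, ~valid_k] = -np.inf
        z[var <= _EPS] = -np.inf
        return z.max(axis=1)

    if scale in ("continuous", "ordered"):
        g, cats = transform_covariate(covariate, scale)
        x = g[:, 0]
        order = np.argsort(x, kind="stable")
        xs = x[order]
        cum = np.cumsum(theta[order], axis=0)
        # cut after position q (1-based count in left daughter), at value changes
        qs = np.nonzero(np.diff(xs) > 0)[0] + 1
        qs = qs[(qs >= min_size) & (m - qs >= min_size)]
        if qs.size == 0:
            return None
        right_sums = tot[None] - cum[qs - 1]
        sc = score((m - qs).astype(float), right_sums)
        if not np.isfinite(sc).any():
            return None
        best = int(np.argmax(sc))
        q = qs[best]
        threshold = 0.5 * (xs[q - 1] + xs[q])
        left_mask = x <= threshold
        return left_mask, {
            "kind": "threshold",
            "threshold": float(threshold),
            "categories": cats,
            "score": float(sc[best]),
        }

    # unordered factor: enumerate all binary partitions of the categories
    cats = tuple(sorted(pd.unique(np.asarray(covariate))))
    c = len(cats)
    if c > max_factor_categories:
        raise InvalidInputError(
            f"unordered factor with {c} > {max_factor_categories} categories; "
            "exhaustive partition enumeration refused"
        )
    if c < 2:
        return None
    codes = np.array([cats.index(vv) for vv in covariate])
    cat_sums = np.zeros((c, K))
    np.add.at(cat_sums, codes, theta)
    cat_counts = np.bincount(codes, minlength=c)
    subsets, n_left_list, left_sum_list = [], [], []
    for r in range(1, c):
        for comb in combinations(range(1, c), r - 1):
            left = (0,) + comb  # always contains the first category: no mirrors
            subsets.append(left)
            n_left_list.append(cat_counts[list(left)].sum())
            left_sum_list.append(cat_sums[list(left)].sum(axis=0))
    n_left = np.array(n_left_list, dtype=float)
    admissible = (n_left >= min_size) & (m - n_left >= min_size)
    if not admissible.any():
        return None
    left_sums = np.array(left_sum_list)
    sc = score(m - n_left, tot[None] - left_sums)
    sc[~admissible] = -np.inf
    if not np.isfinite(sc).any():
        return None
    best = int(np.argmax(sc))
    left_set = tuple(cats[i] for i in subsets[best])
    left_mask = np.isin(np.asarray(covariate), np.asarray(left_set))
    return left_mask, {
        "kind": "subset",
        "left_categories": left_set,
        "categories": cats,
        "score": float(sc[best]),
    }


def grow_tree(
    covariates: pd.DataFrame,
    scales: dict,
    pv: PseudoValueMatrix,
    config: TreeConfig,
    rng: np.random.Generator | None = None,
) -> TreeNode:
    """Grow a depth-limited conditional-inference tree (preorder node ids).

    Growth stops at depth ``config.max_depth``, when every permutation test
    exceeds ``config.alpha``, or when no partition leaves both daughters with
    ``config.min_node_size`` individuals.  ``max_depth = 0`` yields a single
    terminal root.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    theta_all = pv.values
    names = list(covariates.columns)
    cols = [covariates[c].to_numpy() for c in names]
    col_scales = [scales.get(c, "continuous") for c in names]
    counter = {"next_id": 1}

    def build(members: np.ndarray, depth: int) -> TreeNode:
        node = TreeNode(node_id=counter["next_id"], members=members, depth=depth)
        counter["next_id"] += 1
        if depth >= config.max_depth or len(members) < max(2 * config.min_node_size, 2):
            return node
        theta = theta_all[members]
        blocks = []
        for j in range(len(names)):
            g, _ = transform_covariate(cols[j][members], col_scales[j])
            blocks.append(g)
        j_star, p_val = select_split_variable(
            theta, blocks, names, config.n_perm, rng, config.alpha
        )
        node.p_value = p_val
        if j_star is None:
            return node
        res = find_best_split(
            theta,
            cols[j_star][members],
            col_scales[j_star],
            config.min_node_size,
            config.max_factor_categories,
        )
        if res is None:
            return node
        left_mask, info = res
        rule = SplitRule(
            variable=names[j_star],
            var_index=j_star,
            kind=info["kind"],
            threshold=info.get("threshold"),
            left_categories=tuple(info.get("left_categories", ())),
            categories=tuple(info.get("categories", ())),
        )
        node.split = rule
        left = build(members[left_mask], depth + 1)
        right = build(members[~left_mask], depth + 1)
        node.children = (left, right)
        return node

    return build(np.arange(pv.n), 0)


def apply_tree(root: TreeNode, covariates: pd.DataFrame) -> np.ndarray:
    """Terminal node id for each row of ``covariates``."""
    out = np.empty(len(covariates), dtype=int)

    def descend(node: TreeNode, idx: np.ndarray) -> None:
        if node.is_terminal:
            out[idx] = node.node_id
            return
        vals = covariates[node.split.variable].to_numpy()[idx]
        left = node.split.route_left(vals)
        descend(node.children[0], idx[left])
        descend(node.children[1], idx[~left])

    descend(root, np.arange(len(covariates)))
    return out


# ---------------------------------------------------------------------------
# serialization


def tree_to_dict(node: TreeNode) -> dict:
    d = {
        "node_id": node.node_id,
        "depth": node.depth,
        "n_members": int(len(node.members)),
        "members": np.asarray(node.members).tolist(),
        "p_value": node.p_value,
    }
    if node.split is not None:
        s = node.split
        d["split"] = {
            "variable": s.variable,
            "var_index": s.var_index,
            "kind": s.kind,
            "threshold": s.threshold,
            "left_categories": list(s.left_categories),
            "categories": list(s.categories),
        }
        d["children"] = [tree_to_dict(c) for c in node.children]
    return d


def tree_from_dict(d: dict) -> TreeNode:
    node = TreeNode(
        node_id=d["node_id"],
        members=np.asarray(d["members"], dtype=int),
        depth=d["depth"],
        p_value=d.get("p_value"),
    )
    if "split" in d:
        s = d["split"]
        node.split = SplitRule(
            variable=s["variable"],
            var_index=s["var_index"],
            kind=s["kind"],
            threshold=s["threshold"],
            left_categories=tuple(s["left_categories"]),
            categories=tuple(s["categories"]),
        )
        node.children = tuple(tree_from_dict(c) for c in d["children"])
    return node


def tree_to_json(node: TreeNode, **kwargs) -> str:
    return json.dumps(tree_to_dict(node), **kwargs)


def tree_from_json(text: str) -> TreeNode:
    return tree_from_dict(json.loads(text))
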