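"""Pseudo-value regression trees: tree growth, cascaded boosting, prediction.

A fitted model is a conditional-inference tree whose every node carries a
component-wise boosting fit.  Offsets cascade down the tree: the root starts
from the link-transformed Kaplan-Meier curve (the per-time mean of the
pseudo-values), and each daughter node starts from the time-dependent average
of its parent's fitted values, so information selected in higher-level nodes
stabilizes the smaller models below.  One global tuning parameter m_stop(1)
(the root iteration count, chosen by cross-validation) is allocated to the
nodes proportionally to node size:

    m_stop(N) = round( n_N / n * m_stop(1) ).

Survival probabilities are obtained by routing an individual to its terminal
node and applying the inverse complementary log-log link to the node's
additive predictor.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import __version__ as _pkg_version
from .boost import BoostConfig, BoostFit, boost_arrays, cloglog_response, root_offset
from .ctree import TreeConfig, TreeNode, apply_tree, grow_tree, tree_from_dict, tree_to_dict
from .pseudo import (
    InvalidInputError,
    PseudoValueMatrix,
    SurvivalDataset,
    TimeGrid,
    choose_time_grid,
    expand_factors,
    jackknife_pseudo_values,
)

__all__ = [
    "PRTModel",
    "CVResult",
    "node_mstop",
    "fit_prt",
    "predict_survival",
    "cross_validate_mstop",
    "save_model",
    "load_model",
]

logger = logging.getLogger(__name__)

MODEL_SCHEMA_VERSION = 1


def node_mstop(m_stop1: int, n_node: int, n: int) -> int:
    """Node-wise iteration budget: round(n_node / n * m_stop1).

    Rounding is to the nearest integer, half away from zero; a node may
    receive 0 iterations (offset-only fit).  The root receives m_stop1.
    """
    if n_node > n or n_node <= 0 or n <= 0 or m_stop1 < 0:
        raise InvalidInputError("require 0 < n_node <= n and m_stop1 >= 0")
    return int(np.floor(n_node / n * m_stop1 + 0.5))


@dataclass
class PRTModel:
    """Fitted pseudo-value regression tree."""

    grid: TimeGrid
    tree: TreeNode
    fits: dict  # node_id -> BoostFit
    mstops: dict  # node_id -> int
    columns: list  # expanded covariate columns used by the boosting fits
    scales: dict  # raw covariate scale tags (for factor expansion of new data)
    raw_columns: list
    meta: dict

    def terminal_fit(self, node_id: int) -> BoostFit:
        return self.fits[node_id]


def _node_rows(members: np.ndarray, K: int) -> np.ndarray:
    """Row indices of the given individuals in an n x K long-format layout."""
    return (members[:, None] * K + np.arange(K)[None, :]).ravel()


def fit_prt(
    dataset: SurvivalDataset,
    grid: TimeGrid,
    tree_config: TreeConfig,
    boost_config: BoostConfig,
    m_stop1: int,
    pv: PseudoValueMatrix | None = None,
    tree: TreeNode | None = None,
) -> PRTModel:
    """Fit a PRT model: pseudo-values, tree, then cascaded node-wise boosting.

    ``pv`` and ``tree`` may be supplied to reuse precomputed stages (the
    cross-validation routine shares one tree across candidate m_stop values).
    The fit is deterministic given the tree-config seed.
    """
    if pv is None:
        pv = jackknife_pseudo_values(dataset, grid)
    if tree is None:
        tree = grow_tree(dataset.covariates, dataset.scales, pv, tree_config)
    K = grid.K
    n = dataset.n
    Xdf = expand_factors(dataset.covariates, dataset.scales)
    columns = list(Xdf.columns)
    X = Xdf.to_numpy(dtype=float)
    theta_wide = pv.values

    fits: dict = {}
    mstops: dict = {}

    def fit_node(node: TreeNode, offset: np.ndarray) -> None:
        members = np.asarray(node.members)
        m = node_mstop(m_stop1, len(members), n)
        theta = theta_wide[members].reshape(-1)
        kidx = np.tile(np.arange(K), len(members))
        Xn = np.repeat(X[members], K, axis=0)
        cfg = BoostConfig(
            nu=boost_config.nu,
            m_stop=m,
            time_df=boost_config.time_df,
            penalty_order=boost_config.penalty_order,
            center=boost_config.center,
        )
        fit = boost_arrays(theta, kidx, Xn, columns, offset, grid.points, cfg)
        fits[node.node_id] = fit
        mstops[node.node_id] = m
        if node.is_terminal:
            return
        fitted_wide = fit.fitted.reshape(len(members), K)
        for child in node.children:
            pos = np.searchsorted(members, np.asarray(child.members))
            child_offset = fitted_wide[pos].mean(axis=0)
            fit_node(child, child_offset)

    fit_node(tree, root_offset(theta_wide))
    meta = {
        "n": n,
        "max_depth": tree_config.max_depth,
        "alpha": tree_config.alpha,
        "min_node_size": tree_config.min_node_size,
        "n_perm": tree_config.n_perm,
        "nu": boost_config.nu,
        "m_stop1": m_stop1,
        "seed": tree_config.seed,
        "version": _pkg_version,
    }
    return PRTModel(
        grid=grid,
        tree=tree,
        fits=fits,
        mstops=mstops,
        columns=columns,
        scales=dict(dataset.scales),
        raw_columns=list(dataset.covariates.columns),
        meta=meta,
    )


def predict_survival(model: PRTModel, covariates: pd.DataFrame, times=None) -> np.ndarray:
    """Estimated survival probabilities S(t | X) on (a subset of) the grid.

    Individuals are routed to a terminal node by the split rules; the node's
    additive predictor is mapped through the inverse cloglog link.  Requested
    times must lie on the training grid.  Rows of the result are nonincreasing
    in time for every individual.
    """
    if list(covariates.columns) != list(model.raw_columns):
        missing = set(model.raw_columns) - set(covariates.columns)
        if missing:
            raise InvalidInputError(f"missing covariate column(s): {sorted(missing)}")
        covariates = covariates[model.raw_columns]
    if times is None:
        times = model.grid.points
    times = np.asarray(times, dtype=float)
    kidx_t = np.searchsorted(model.grid.points, times)
    if np.any(kidx_t >= model.grid.K) or not np.allclose(model.grid.points[kidx_t], times):
        raise InvalidInputError("requested times must lie on the training grid")

    Xdf = expand_factors(covariates, model.scales)
    for col in model.columns:
        if col not in Xdf.columns:  # level absent in new data: dummy column of zeros
            Xdf[col] = 0.0
    extra = set(Xdf.columns) - set(model.columns)
    if extra:
        raise InvalidInputError(f"unseen factor level(s) produce unknown column(s): {sorted(extra)}")
    X = Xdf[model.columns].to_numpy(dtype=float)

    node_ids = apply_tree(model.tree, covariates)
    out = np.empty((len(covariates), len(times)))
    for nid in np.unique(node_ids):
        rows = np.nonzero(node_ids == nid)[0]
        fit = model.fits[nid]
        Xr = np.repeat(X[rows], len(times), axis=0)
        kk = np.tile(kidx_t, len(rows))
        f = fit.linear_predictor(Xr, kk)
        out[rows] = cloglog_response(f).reshape(len(rows), len(times))
    return out


@dataclass
class CVResult:
    """Cross-validation trace for the root iteration count m_stop(1)."""

    candidates: list
    mean_losses: list
    selected: int

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"m_stop1": self.candidates, "mean_loss": self.mean_losses})


DEFAULT_MSTOP_GRID = (0, 50, 100, 250, 500, 1000, 2500)


def _stratified_folds(event: np.ndarray, folds: int, rng: np.random.Generator):
    """Fold label per individual, stratified by the event indicator."""
    n = len(event)
    labels = np.empty(n, dtype=int)
    for value in (0, 1):
        idx = np.nonzero(event == value)[0]
        idx = rng.permutation(idx)
        labels[idx] = np.arange(len(idx)) % folds
    return labels


def _subset(dataset: SurvivalDataset, idx: np.ndarray) -> SurvivalDataset:
    return SurvivalDataset(
        ids=np.asarray(dataset.ids)[idx],
        time=dataset.time[idx],
        event=dataset.event[idx],
        covariates=dataset.covariates.iloc[idx].reset_index(drop=True),
        scales=dict(dataset.scales),
    )


def cross_validate_mstop(
    dataset: SurvivalDataset,
    grid: TimeGrid | None,
    candidates=DEFAULT_MSTOP_GRID,
    tree_config: TreeConfig | None = None,
    boost_config: BoostConfig | None = None,
    folds: int = 5,
    seed: int | None = None,
    quantile_levels=(0.1, 0.3, 0.5, 0.7, 0.9),
) -> CVResult:
    """Five-fold (by default) cross-validation of the root iteration count.

    Per fold, pseudo-values are recomputed on the training fold and a new tree
    is grown; each candidate is fitted through the full cascade and evaluated
    with the squared cloglog loss against pseudo-values computed *within* the
    test fold (guarding against over-optimism).  Folds are assigned per
    individual (all K observations together) and stratified by event status.
    The pooled mean loss over all test observations selects the candidate;
    ties go to the smallest candidate.
    """
    candidates = sorted(int(c) for c in candidates)
    if not candidates:
        raise InvalidInputError("candidate list is empty")
    if folds < 2:
        raise InvalidInputError("need at least two folds")
    tree_config = tree_config or TreeConfig()
    boost_config = boost_config or BoostConfig()
    rng = np.random.default_rng(seed)
    labels = _stratified_folds(dataset.event, folds, rng)

    sums = np.zeros(len(candidates))
    count = 0
    for fold in range(folds):
        train_idx = np.nonzero(labels != fold)[0]
        test_idx = np.nonzero(labels == fold)[0]
        train = _subset(dataset, train_idx)
        test = _subset(dataset, test_idx)
        fold_grid = grid or choose_time_grid(train.time, quantile_levels)
        pv_train = jackknife_pseudo_values(train, fold_grid)
        fold_tree_cfg = TreeConfig(
            max_depth=tree_config.max_depth,
            alpha=tree_config.alpha,
            min_node_size=tree_config.min_node_size,
            n_perm=tree_config.n_perm,
            seed=int(rng.integers(2**31 - 1)),
            max_factor_categories=tree_config.max_factor_categories,
        )
        tree = grow_tree(train.covariates, train.scales, pv_train, fold_tree_cfg)
        pv_test = jackknife_pseudo_values(test, fold_grid)
        for ci, m1 in enumerate(candidates):
            model = fit_prt(
                train, fold_grid, fold_tree_cfg, boost_config, m1, pv=pv_train, tree=tree
            )
            pred = predict_survival(model, test.covariates)
            sums[ci] += ((pv_test.values - pred) ** 2).sum()
        count += pv_test.values.size
    mean_losses = sums / count
    selected = candidates[int(np.argmin(mean_losses))]
    return CVResult(candidates=list(candidates), mean_losses=mean_losses.tolist(), selected=selected)


# ---------------------------------------------------------------------------
# model file (versioned structured text)


def model_to_dict(model: PRTModel) -> dict:
    return {
        "schema_version": MODEL_SCHEMA_VERSION,
        "grid": model.grid.points.tolist(),
        "tree": tree_to_dict(model.tree),
        "fits": {str(k): v.to_dict() for k, v in model.fits.items()},
        "mstops": {str(k): int(v) for k, v in model.mstops.items()},
        "columns": list(model.columns),
        "scales": dict(model.scales),
        "raw_columns": list(model.raw_columns),
        "meta": model.meta,
    }


def model_from_dict(d: dict) -> PRTModel:
    if d.get("schema_version") != MODEL_SCHEMA_VERSION:
        raise InvalidInputError(f"unsupported model schema version {d.get('schema_version')}")
    return PRTModel(
        grid=TimeGrid(points=np.asarray(d["grid"], dtype=float)),
        tree=tree_from_dict(d["tree"]),
        fits={int(k): BoostFit.from_dict(v) for k, v in d["fits"].items()},
        mstops={int(k): int(v) for k, v in d["mstops"].items()},
        columns=list(d["columns"]),
        scales=dict(d["scales"]),
        raw_columns=list(d["raw_columns"]),
        meta=dict(d["meta"]),
    )


def save_model(model: PRTModel, path) -> None:
    with open(path, "w") as fh:
        json.dump(model_to_dict(model), fh)


def load_model(path) -> PRTModel:
    with open(path) as fh:
        return model_from_dict(json.load(fh))
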