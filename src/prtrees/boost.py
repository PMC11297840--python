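"""Component-wise gradient boosting under the complementary log-log squared loss.

Each node of a pseudo-value regression tree is fitted by stagewise functional
gradient descent of the empirical risk

    R(f) = sum_rows ( theta - h(f) )^2 ,   h(f) = 1 - exp(-exp(-f)),

over an additive predictor

    f = f0(t) + gamma_0 + sum_j gamma_j x_j + alpha(t),

where f0 is a fixed time-dependent offset inherited from the parent node.  At
every iteration all base-learners (an intercept, one no-intercept simple linear
model per covariate, and a monotone time smoother) are fitted to the current
negative gradient; only the best-fitting one is updated by a small step nu.
Early stopping (m_stop) yields shrinkage and data-driven covariate selection.
The time learner is constrained to be nondecreasing, which keeps the baseline
risk monotone and the predicted survival curves nonincreasing in time.

The monotone time learner is a penalized least-squares fit of the K grid-level
values (second-order difference roughness penalty, penalty weight chosen to
match a target effective degrees of freedom) subject to nonnegative first
differences.  Because time takes only the K grid values during both training
and prediction, this on-grid representation is exactly as expressive as a
constrained spline basis while avoiding knot placement with few distinct times.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from .pseudo import InvalidInputError

__all__ = [
    "BoostConfig",
    "BoostFit",
    "cloglog_response",
    "cloglog_link",
    "loss",
    "negative_gradient",
    "fit_linear_baselearner",
    "fit_monotone_time_baselearner",
    "boost_node",
    "compute_offset",
    "root_offset",
]

logger = logging.getLogger(__name__)

_EXP_CLAMP = 700.0
_PROB_CLIP = 1e-6


def cloglog_response(f):
    """Inverse complementary log-log link h(f) = 1 - exp(-exp(-f)).

    Strictly decreasing in f, mapping the real line onto (0, 1).  Exponentials
    are clamped to avoid overflow for extreme predictors.
    """
    inner = np.exp(np.clip(-np.asarray(f, dtype=float), -_EXP_CLAMP, _EXP_CLAMP))
    return 1.0 - np.exp(-inner)


def cloglog_link(s):
    """Link g(S) = -log(-log(1 - S)); inverse of :func:`cloglog_response`.

    Probabilities are clipped into [1e-6, 1 - 1e-6] to guard the double log.
    """
    s = np.clip(np.asarray(s, dtype=float), _PROB_CLIP, 1.0 - _PROB_CLIP)
    return -np.log(-np.log(1.0 - s))


def loss(theta, f):
    """Squared-error loss on the probability scale: (theta - h(f))^2."""
    return (np.asarray(theta, dtype=float) - cloglog_response(f)) ** 2


def negative_gradient(theta, f):
    """Negative derivative of the loss w.r.t. the predictor.

    Equals 2 * h'(f) * (theta - h(f)) with h'(f) = -exp(-exp(-f)) exp(-f) < 0;
    guarded exponentials make it vanish (instead of overflowing) for |f| large.
    """
    f = np.asarray(f, dtype=float)
    inner = np.exp(np.clip(-f, -_EXP_CLAMP, _EXP_CLAMP))
    dh = -np.exp(-inner) * inner  # h'(f)
    return 2.0 * dh * (np.asarray(theta, dtype=float) - (1.0 - np.exp(-inner)))


def fit_linear_baselearner(x, u):
    """No-intercept least-squares fit of u on x: slope, fitted values, rss."""
    x = np.asarray(x, dtype=float)
    u = np.asarray(u, dtype=float)
    sx2 = x @ x
    if sx2 <= 0:
        raise InvalidInputError("constant (zero-variance) covariate is unusable")
    slope = (x @ u) / sx2
    fitted = slope * x
    rss = u @ u - slope * slope * sx2
    return float(slope), fitted, float(max(rss, 0.0))


# ---------------------------------------------------------------------------
# monotone time base-learner


def _difference_penalty(K: int, order: int) -> np.ndarray:
    D = np.eye(K)
    for _ in range(order):
        D = np.diff(D, axis=0)
    return D.T @ D


def _penalty_weight(W: np.ndarray, P: np.ndarray, df_target: float) -> float:
    """Penalty weight lambda with tr[(W + lambda P)^-1 W] ~= df_target."""
    K = len(W)
    if df_target >= K or np.allclose(P, 0):
        return 0.0

    def df(lam):
        return np.trace(np.linalg.solve(np.diag(W) + lam * P, np.diag(W)))

    lo, hi = 1e-10, 1e12
    if df(hi) > df_target:  # cannot go below the penalty null space dimension
        return hi
    for _ in range(80):
        mid = np.sqrt(lo * hi)
        if df(mid) > df_target:
            lo = mid
        else:
            hi = mid
    return float(np.sqrt(lo * hi))


class _MonotoneTimeSolver:
    """Exact monotone penalized least squares on K grid levels.

    Minimizes sum_rows (u - a_{k(row)})^2 + lam * a' P a subject to
    a_1 <= ... <= a_K.  The optimum is found by enumerating the 2^(K-1) merge
    patterns of adjacent equality constraints: for the true active set the
    equality-constrained solution is the (feasible) global optimum, so the
    feasible pattern solution with minimal objective is exact.
    """

    def __init__(self, weights: np.ndarray, lam: float, P: np.ndarray):
        self.W = np.asarray(weights, dtype=float)
        K = len(self.W)
        self.K = K
        Q = np.diag(self.W) + lam * P
        self.Q = Q
        maps = []
        for r in range(K, 0, -1):
            for cuts in combinations(range(1, K), r - 1):
                bounds = (0,) + cuts + (K,)
                Z = np.zeros((K, r))
                for gi in range(r):
                    Z[bounds[gi] : bounds[gi + 1], gi] = 1.0
                ZQZ = Z.T @ Q @ Z
                maps.append(Z @ np.linalg.solve(ZQZ, Z.T))
        self.maps = np.stack(maps)  # (2^(K-1), K, K)

    def solve(self, b: np.ndarray) -> np.ndarray:
        """Minimizer for target vector b = W * groupmeans(u)."""
        A = self.maps @ b  # (n_pat, K)
        feasible = np.all(np.diff(A, axis=1) >= -1e-9, axis=1)
        obj = np.einsum("pi,ij,pj->p", A, self.Q, A) - 2.0 * A @ b
        obj[~feasible] = np.inf
        a = A[int(np.argmin(obj))]
        return np.maximum.accumulate(a)  # clean up -1e-9 level wiggle


def fit_monotone_time_baselearner(t, u, grid_points, df_target: float = 4.0, penalty_order: int = 2):
    """Monotone penalized fit of u on the grid-valued time column.

    Returns (fitted curve at the K grid points, fitted row values, rss).  The
    fit depends on t only through the grid point; with K = 1 the learner is
    collinear with the intercept and must be excluded by the caller.
    """
    grid_points = np.asarray(grid_points, dtype=float)
    K = len(grid_points)
    if K < 2:
        raise InvalidInputError("time learner needs at least two grid points")
    t = np.asarray(t, dtype=float)
    u = np.asarray(u, dtype=float)
    kidx = np.searchsorted(grid_points, t)
    if not np.allclose(grid_points[kidx], t):
        raise InvalidInputError("time column contains off-grid values")
    W = np.bincount(kidx, minlength=K).astype(float)
    P = _difference_penalty(K, penalty_order) if K > penalty_order else np.zeros((K, K))
    lam = _penalty_weight(np.maximum(W, _PROB_CLIP), P, df_target)
    solver = _MonotoneTimeSolver(np.maximum(W, 1e-12), lam, P)
    b = np.bincount(kidx, weights=u, minlength=K)
    a = solver.solve(b)
    fitted = a[kidx]
    rss = float(u @ u - 2.0 * a @ b + (W * a * a).sum())
    return a, fitted, max(rss, 0.0)


# ---------------------------------------------------------------------------
# node-wise boosting


@dataclass
class BoostConfig:
    """Step length, iteration budget and time-learner smoothness."""

    nu: float = 0.01
    m_stop: int = 100
    time_df: float = 4.0
    penalty_order: int = 2
    center: bool = True

    def __post_init__(self) -> None:
        if not (0 < self.nu <= 1):
            raise InvalidInputError("nu must lie in (0, 1]")
        if self.m_stop < 0:
            raise InvalidInputError("m_stop must be >= 0")


@dataclass
class BoostFit:
    """Aggregated boosting fit of one tree node.

    ``offset`` (length K, link scale) is the inherited starting value,
    ``gamma0`` the accumulated intercept (with centering constants absorbed),
    ``slopes`` the per-covariate linear coefficients on the original covariate
    scale, and ``alpha`` the accumulated monotone time curve at the grid
    points.  ``selection`` logs the chosen learner per iteration ("intercept",
    a covariate name, or "time").
    """

    offset: np.ndarray
    gamma0: float
    slopes: np.ndarray
    columns: list
    alpha: np.ndarray
    selection: list = field(default_factory=list)
    fitted: np.ndarray | None = None  # training rows, link scale

    def linear_predictor(self, X: np.ndarray, kidx: np.ndarray) -> np.ndarray:
        """f = offset(t) + gamma_0 + X gamma + alpha(t) for rows (X, kidx)."""
        return self.offset[kidx] + self.gamma0 + X @ self.slopes + self.alpha[kidx]

    def to_dict(self) -> dict:
        return {
            "offset": self.offset.tolist(),
            "gamma0": self.gamma0,
            "slopes": self.slopes.tolist(),
            "columns": list(self.columns),
            "alpha": self.alpha.tolist(),
            "selection": list(self.selection),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BoostFit":
        return cls(
            offset=np.asarray(d["offset"], dtype=float),
            gamma0=float(d["gamma0"]),
            slopes=np.asarray(d["slopes"], dtype=float),
            columns=list(d["columns"]),
            alpha=np.asarray(d["alpha"], dtype=float),
            selection=list(d["selection"]),
        )


def _table_arrays(table, grid_points):
    """Extract (theta, kidx, X, columns) from an augmented long-format table."""
    reserved = {"id", "time", "pseudo", "x0"}
    columns = [c for c in table.columns if c not in reserved]
    theta = table["pseudo"].to_numpy(dtype=float)
    kidx = np.searchsorted(grid_points, table["time"].to_numpy(dtype=float))
    X = table[columns].to_numpy(dtype=float) if columns else np.empty((len(table), 0))
    return theta, kidx, X, columns


def boost_node(table, offset: np.ndarray, grid_points, config: BoostConfig) -> BoostFit:
    """Run component-wise gradient boosting on one node's augmented table.

    ``offset`` is the length-K starting value on the link scale.  Covariates
    with zero variance inside the node (for example binary split variables of
    ancestor nodes) are excluded from the set of candidate learners.
    """
    if len(table) == 0:
        raise InvalidInputError("empty node table")
    grid_points = np.asarray(grid_points, dtype=float)
    theta, kidx, X, columns = _table_arrays(table, grid_points)
    return boost_arrays(theta, kidx, X, columns, offset, grid_points, config)


def boost_arrays(theta, kidx, X, columns, offset, grid_points, config: BoostConfig) -> BoostFit:
    """Array-level boosting core (see :func:`boost_node`)."""
    grid_points = np.asarray(grid_points, dtype=float)
    K = len(grid_points)
    offset = np.asarray(offset, dtype=float)
    if offset.shape != (K,) or not np.all(np.isfinite(offset)):
        raise InvalidInputError("offset must be a finite length-K vector")
    if len(theta) == 0:
        raise InvalidInputError("empty node table")
    nrows = len(theta)
    p = X.shape[1]

    col_means = X.mean(axis=0) if config.center else np.zeros(p)
    Xc = X - col_means
    sx2 = np.einsum("ij,ij->j", Xc, Xc)
    usable = sx2 > 1e-12

    use_time = K >= 2
    if use_time:
        W = np.bincount(kidx, minlength=K).astype(float)
        P = (
            _difference_penalty(K, config.penalty_order)
            if K > config.penalty_order
            else np.zeros((K, K))
        )
        lam = _penalty_weight(np.maximum(W, _PROB_CLIP), P, config.time_df)
        solver = _MonotoneTimeSolver(W, lam, P)

    f = offset[kidx].copy()
    c0 = 0.0
    gammas = np.zeros(p)
    alpha = np.zeros(K)
    selection: list = []

    if p and not usable.any() and not use_time:
        warnings.warn("all covariate learners unusable; returning offset-only fit")

    n_learners = 1 + p + 1  # intercept, covariates, time
    rss = np.full(n_learners, np.inf)
    for _ in range(config.m_stop):
        u = negative_gradient(theta, f)
        su2 = u @ u
        slope0 = u.mean()
        rss[0] = su2 - nrows * slope0 * slope0
        if p:
            slopes_all = np.zeros(p)
            np.divide(Xc.T @ u, sx2, out=slopes_all, where=usable)
            rss[1 : 1 + p] = np.where(usable, su2 - slopes_all**2 * sx2, np.inf)
        if use_time:
            b = np.bincount(kidx, weights=u, minlength=K)
            a = solver.solve(b)
            rss[-1] = su2 - 2.0 * a @ b + (W * a * a).sum()
        winner = int(np.argmin(rss))
        if not np.isfinite(rss[winner]):
            break
        if winner == 0:
            f += config.nu * slope0
            c0 += config.nu * slope0
            selection.append("intercept")
        elif winner <= p:
            j = winner - 1
            f += config.nu * slopes_all[j] * Xc[:, j]
            gammas[j] += config.nu * slopes_all[j]
            selection.append(columns[j])
        else:
            f += config.nu * a[kidx]
            alpha += config.nu * a
            selection.append("time")

    gamma0 = c0 - gammas @ col_means
    return BoostFit(
        offset=offset,
        gamma0=float(gamma0),
        slopes=gammas,
        columns=columns,
        alpha=alpha,
        selection=selection,
        fitted=f,
    )


def compute_offset(parent_fitted: np.ndarray, parent_kidx: np.ndarray, member_rows: np.ndarray, K: int) -> np.ndarray:
    """Per-time mean of the parent's fitted values over the node's observations.

    ``member_rows`` indexes the rows of the parent's augmented table that
    belong to the daughter node.
    """
    vals = parent_fitted[member_rows]
    ks = parent_kidx[member_rows]
    sums = np.bincount(ks, weights=vals, minlength=K)
    counts = np.bincount(ks, minlength=K)
    if np.any(counts == 0):
        raise InvalidInputError("node has no observation at some grid time")
    return sums / counts


def root_offset(pv_values: np.ndarray) -> np.ndarray:
    """Root-node offset: link-transformed per-time mean of the pseudo-values.

    By the jackknife average identity the per-time mean equals the full-sample
    Kaplan-Meier estimate, so the root offset is g(S_KM(t_k)) on the link
    scale (clipped before the double log).
    """
    return cloglog_link(pv_values.mean(axis=0))
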