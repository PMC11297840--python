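"""Evaluation metrics and the classical GEE pseudo-value regression baseline.

Accuracy of estimated survival probabilities is measured against known truths
by MSE/RMSE and bias, and against observed right-censored data by the inverse
probability-of-censoring-weighted (IPCW) Brier score and a truncated,
IPCW-weighted concordance index.  The baseline model is the standard marginal
pseudo-value regression

    g(S(t_k | X_i)) = alpha_k + gamma' X_i ,

with the complementary log-log link and an independence working covariance,
solved as a generalized estimating equation by damped Gauss-Newton.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .boost import cloglog_link, cloglog_response
from .pseudo import InvalidInputError, SurvivalDataset, TimeGrid, _eval_step, _km_curve

__all__ = [
    "mse_survival",
    "bias_survival",
    "brier_score",
    "c_index",
    "GEEFit",
    "fit_gee",
    "censoring_km",
]

logger = logging.getLogger(__name__)


def mse_survival(estimates, truths):
    """Mean squared error over all n*K entries, and its square root."""
    est = np.asarray(estimates, dtype=float)
    tru = np.asarray(truths, dtype=float)
    if est.shape != tru.shape:
        raise InvalidInputError("estimate and truth shapes differ")
    mse = float(np.mean((est - tru) ** 2))
    return mse, float(np.sqrt(mse))


def bias_survival(estimates, truths):
    """Mean deviation (estimate - truth) per time point and overall.

    Returns (per-time vector, mean across the K time points).
    """
    est = np.asarray(estimates, dtype=float)
    tru = np.asarray(truths, dtype=float)
    if est.shape != tru.shape:
        raise InvalidInputError("estimate and truth shapes differ")
    per_time = (est - tru).mean(axis=0)
    return per_time, float(per_time.mean())


def censoring_km(time, event):
    """Reversed-role Kaplan-Meier estimate of the censoring survival G.

    Censorings play the role of events.  Returns a callable G(t, left=False);
    ``left=True`` evaluates the left limit G(t-), used to weight event terms.
    """
    time = np.asarray(time, dtype=float)
    cens = 1 - np.asarray(event, dtype=int)
    et, surv = _km_curve(time, cens)

    def G(t, left=False):
        t = np.atleast_1d(np.asarray(t, dtype=float))
        side = "left" if left else "right"
        idx = np.searchsorted(et, t, side=side)
        out = np.ones(t.shape)
        pos = idx > 0
        out[pos] = surv[idx[pos] - 1]
        return out

    return G


def brier_score(dataset: SurvivalDataset, predictions: np.ndarray, grid: TimeGrid):
    """IPCW Brier score per grid time and its time average.

    At horizon t the score is the mean over individuals of

        S_hat(t|X)^2 * 1{T~ <= t, event} / G(T~ -)
        + (1 - S_hat(t|X))^2 * 1{T~ > t} / G(t),

    with G the reversed-role Kaplan-Meier estimate of the censoring survival.
    Terms whose weight denominator is zero are dropped with a logged count.
    """
    pred = np.asarray(predictions, dtype=float)
    if pred.shape != (dataset.n, grid.K):
        raise InvalidInputError("prediction matrix must be n x K")
    if np.any((pred < 0) | (pred > 1)):
        raise InvalidInputError("predictions must lie in [0, 1]")
    G = censoring_km(dataset.time, dataset.event)
    g_event = G(dataset.time, left=True)  # G(T~ -) per individual
    scores = np.empty(grid.K)
    dropped = 0
    for k, t in enumerate(grid.points):
        g_t = G(np.array([t]))[0]
        died = (dataset.time <= t) & (dataset.event == 1)
        alive = dataset.time > t
        term = np.zeros(dataset.n)
        ok_d = died & (g_event > 0)
        term[ok_d] = pred[ok_d, k] ** 2 / g_event[ok_d]
        if g_t > 0:
            term[alive] = (1.0 - pred[alive, k]) ** 2 / g_t
            bad = int((died & (g_event <= 0)).sum())
        else:
            bad = int((died & (g_event <= 0)).sum() + alive.sum())
        dropped += bad
        scores[k] = term.sum() / dataset.n
    if dropped:
        logger.info("Brier score: dropped %d terms with zero censoring weight", dropped)
    return scores, float(scores.mean())


def c_index(dataset: SurvivalDataset, risk: np.ndarray, tau: float):
    """Truncated IPCW concordance index.

    Pairs (i, j) with an observed event for i before both T~_j and the horizon
    tau are weighted by G(T~_i -)^-2; a pair is concordant when the
    earlier-event individual has the larger risk score (ties count 1/2).
    Returns None when no admissible pair exists.
    """
    risk = np.asarray(risk, dtype=float)
    time = dataset.time
    event = dataset.event
    G = censoring_km(time, event)
    g_i = G(time, left=True)
    valid_i = (event == 1) & (time < tau) & (g_i > 0)
    w = np.zeros(dataset.n)
    w[valid_i] = 1.0 / g_i[valid_i] ** 2
    comparable = valid_i[:, None] & (time[:, None] < time[None, :])
    if not comparable.any():
        return None
    conc = (risk[:, None] > risk[None, :]) + 0.5 * (risk[:, None] == risk[None, :])
    num = (w[:, None] * comparable * conc).sum()
    den = (w[:, None] * comparable).sum()
    return float(num / den)


@dataclass
class GEEFit:
    """Solution of the pseudo-value estimating equation."""

    beta: np.ndarray  # (alpha_1..alpha_K, gamma_1..gamma_p)
    alpha: np.ndarray
    gamma: np.ndarray
    columns: list
    converged: bool
    n_iter: int
    score_norm: float

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Survival probability matrix (n x K) for covariate matrix X."""
        f = self.alpha[None, :] + (X @ self.gamma)[:, None]
        return cloglog_response(f)


def _gee_design(table: pd.DataFrame, grid_points: np.ndarray):
    reserved = {"id", "time", "pseudo", "x0"}
    columns = [c for c in table.columns if c not in reserved]
    K = len(grid_points)
    kidx = np.searchsorted(grid_points, table["time"].to_numpy(dtype=float))
    n_rows = len(table)
    D = np.zeros((n_rows, K + len(columns)))
    D[np.arange(n_rows), kidx] = 1.0
    if columns:
        D[:, K:] = table[columns].to_numpy(dtype=float)
    theta = table["pseudo"].to_numpy(dtype=float)
    return D, theta, columns


def fit_gee(table: pd.DataFrame, grid: TimeGrid, max_iter: int = 200, tol: float = 1e-8) -> GEEFit:
    """Solve the independence-working-covariance estimating equation.

    The augmented design holds K time-indicator columns followed by the
    covariates; the score sum_rows h'(f) x (theta - h(f)) is driven to zero by
    damped Gauss-Newton with step halving.  Initialization puts the per-time
    link-transformed mean pseudo-value into the alpha coefficients.
    """
    K = grid.K
    D, theta, columns = _gee_design(table, grid.points)
    p = len(columns)
    if np.linalg.matrix_rank(D) < D.shape[1]:
        raise InvalidInputError("augmented design is rank deficient")
    beta = np.zeros(K + p)
    for k in range(K):
        beta[k] = cloglog_link(theta[D[:, k] == 1].mean())

    def score_and_jac(b):
        f = D @ b
        inner = np.exp(np.clip(-f, -700, 700))
        h = 1.0 - np.exp(-inner)
        hp = -np.exp(-inner) * inner
        r = theta - h
        J = hp[:, None] * D
        return J.T @ r, J, r

    sse = float(((theta - cloglog_response(D @ beta)) ** 2).sum())
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        U, J, r = score_and_jac(beta)
        if np.max(np.abs(U)) < tol:
            converged = True
            break
        JtJ = J.T @ J
        try:
            delta = np.linalg.solve(JtJ + 1e-12 * np.eye(len(beta)), U)
        except np.linalg.LinAlgError:
            break
        step = 1.0
        for _ in range(30):
            cand = beta + step * delta
            cand_sse = float(((theta - cloglog_response(D @ cand)) ** 2).sum())
            if cand_sse <= sse + 1e-14:
                beta, sse = cand, cand_sse
                break
            step *= 0.5
        else:
            break
    U, _, _ = score_and_jac(beta)
    score_norm = float(np.max(np.abs(U)))
    if not converged and score_norm < tol:
        converged = True
    if not converged:
        logger.warning("GEE did not converge: score sup-norm %.3e after %d iterations", score_norm, it)
    return GEEFit(
        beta=beta,
        alpha=beta[:K],
        gamma=beta[K:],
        columns=columns,
        converged=converged,
        n_iter=it,
        score_norm=score_norm,
    )
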