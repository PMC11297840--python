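"""Generators for the two lognormal right-censored benchmark designs.

Both designs draw event times from a lognormal accelerated-failure-time model

    log T_i = eta_i + eps_i,   eps_i ~ N(0, 1),

so the exact conditional survival function S(t | X_i) = 1 - Phi(log t - eta_i)
is available for error evaluation.  Censoring times are drawn by an identical,
fully independent pipeline (fresh covariates and fresh error), which by
symmetry censors about half of the individuals.

Design 1 ("tree" design): ten correlated standard-uniform covariates (pairwise
Pearson correlations capped at 0.5 in absolute value), individuals routed by
median rules on x1, then x2 / x3, into four terminal groups each with its own
sparse linear predictor (five of the ten coefficients are zero per group).

Design 2 ("additive" design): thirty correlated unit-variance normal
covariates; a main-effect predictor over five informative covariates and an
interaction-only predictor over their ten pairwise products are standardized
empirically and mixed with weight lambda; the mixture is standardized again
before adding noise, so the signal-to-noise ratio is the same for every
lambda.  Coefficient vectors and the covariance structure are frozen under a
master seed and shared across Monte-Carlo replications.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .pseudo import InvalidInputError, SurvivalDataset, TimeGrid, choose_time_grid

__all__ = [
    "Study1Spec",
    "Study2Spec",
    "SimTruth",
    "random_correlation_matrix",
    "sample_correlated_uniforms",
    "simulate_study1",
    "simulate_study2",
    "build_default_time_grid",
    "STUDY1_COEFFICIENTS",
]

#: node-wise covariate effects gamma_j^(m) of design 1 (terminal groups 3,4,6,7;
#: five zero coefficients per group, x9 without effect everywhere)
STUDY1_COEFFICIENTS = {
    3: np.array([0.0, -1.19, -0.94, -0.82, -0.94, 0.0, -0.95, 0.0, 0.0, 0.0]),
    4: np.array([-0.63, -0.47, -0.43, 0.67, 0.0, -0.54, 0.0, 0.0, 0.0, 0.0]),
    6: np.array([0.0, -0.47, -0.39, 0.0, -0.64, 0.0, 0.0, -0.09, 0.0, 0.01]),
    7: np.array([0.50, 0.48, 0.0, 0.24, 0.0, 0.0, 0.68, 0.77, 0.0, 0.0]),
}

DEFAULT_MASTER_SEED = 2024
_QUANTILE_LEVELS = (0.1, 0.3, 0.5, 0.7, 0.9)


def random_correlation_matrix(dim: int, rng: np.random.Generator, max_abs: float | None = None) -> np.ndarray:
    """Random correlation matrix via a random-orthogonal-eigenvalue construction.

    Eigenvalues are drawn uniformly and rescaled to sum to ``dim``; if
    ``max_abs`` is given, off-diagonal entries are shrunk toward the identity
    until they respect the bound (a convex combination, hence still positive
    definite).
    """
    eig = rng.uniform(0.2, 1.8, size=dim)
    eig = eig * dim / eig.sum()
    R = stats.random_correlation.rvs(eig, random_state=rng, tol=1e-10)
    if max_abs is not None:
        off = np.abs(R - np.diag(np.diag(R))).max()
        if off > max_abs:
            c = max_abs / off
            R = c * R + (1.0 - c) * np.eye(dim)
    return (R + R.T) / 2.0


def _nearest_pd(R: np.ndarray) -> np.ndarray:
    w, V = np.linalg.eigh(R)
    if w.min() > 1e-10:
        return R
    w = np.clip(w, 1e-8, None)
    A = (V * w) @ V.T
    d = np.sqrt(np.diag(A))
    return A / np.outer(d, d)


def sample_correlated_uniforms(n: int, R: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Standard-uniform marginals with target Pearson correlations ~= R.

    Normal-copula construction with the intermediate-correlation adjustment
    r_normal = 2 sin(pi r_target / 6), which makes the Pearson correlation of
    the transformed uniforms match the target exactly in the bivariate case.
    If the adjusted matrix loses positive definiteness it is repaired to the
    nearest correlation matrix.
    """
    R = np.asarray(R, dtype=float)
    if R.ndim != 2 or R.shape[0] != R.shape[1]:
        raise InvalidInputError("R must be square")
    R_norm = 2.0 * np.sin(np.pi * R / 6.0)
    np.fill_diagonal(R_norm, 1.0)
    R_norm = _nearest_pd(R_norm)
    L = np.linalg.cholesky(R_norm)
    Z = rng.standard_normal((n, R.shape[0])) @ L.T
    return stats.norm.cdf(Z)


@dataclass
class SimTruth:
    """Generated dataset plus the exact survival function of each individual."""

    dataset: SurvivalDataset
    eta: np.ndarray  # true linear predictor (log-time location)
    censoring_time: np.ndarray | None = None  # latent C_i (kept for diagnostics)

    def survival(self, times) -> np.ndarray:
        """True S(t | X_i) = 1 - Phi(log t - eta_i), shape (n, len(times))."""
        t = np.asarray(times, dtype=float)
        if np.any(t <= 0):
            raise InvalidInputError("survival truth requires positive times")
        return 1.0 - stats.norm.cdf(np.log(t)[None, :] - self.eta[:, None])

    @property
    def censoring_fraction(self) -> float:
        return float(1.0 - self.dataset.event.mean())


@dataclass
class Study1Spec:
    """Frozen structure of the tree design (shared across replications)."""

    n: int = 1000
    corr: np.ndarray = field(default=None)
    coefficients: dict = field(default_factory=lambda: {m: v.copy() for m, v in STUDY1_COEFFICIENTS.items()})
    error_sd: float = 1.0
    master_seed: int = DEFAULT_MASTER_SEED

    def __post_init__(self) -> None:
        if self.corr is None:
            rng = np.random.default_rng(self.master_seed)
            self.corr = random_correlation_matrix(10, rng, max_abs=0.5)
        self.corr = np.asarray(self.corr, dtype=float)
        if self.corr.shape != (10, 10):
            raise InvalidInputError("design 1 uses exactly 10 covariates")
        if sorted(self.coefficients) != [3, 4, 6, 7]:
            raise InvalidInputError("design 1 requires coefficients for terminal groups 3,4,6,7")
        for m, g in self.coefficients.items():
            if len(g) != 10:
                raise InvalidInputError(f"terminal group {m} needs 10 coefficients")


def _study1_eta(X: np.ndarray, coefficients: dict) -> np.ndarray:
    """Route individuals by the sample-median rules and evaluate eta."""
    x1, x2, x3 = X[:, 0], X[:, 1], X[:, 2]
    xi1 = np.median(x1)
    left = x1 <= xi1
    xi2 = np.median(x2[left])
    xi3 = np.median(x3[~left])
    node = np.where(
        left,
        np.where(x2 <= xi2, 3, 4),
        np.where(x3 <= xi3, 6, 7),
    )
    eta = np.zeros(len(X))
    for m, g in coefficients.items():
        mask = node == m
        eta[mask] = X[mask] @ np.asarray(g, dtype=float)
    return eta


def _draw_study1_logtimes(spec: Study1Spec, n: int, rng: np.random.Generator):
    X = sample_correlated_uniforms(n, spec.corr, rng)
    eta = _study1_eta(X, spec.coefficients)
    logt = eta + spec.error_sd * rng.standard_normal(n)
    return logt, eta, X


def simulate_study1(spec: Study1Spec, rng: np.random.Generator | None = None) -> SimTruth:
    """One replication of the tree design with ~50% independent censoring."""
    rng = np.random.default_rng(rng)
    log_t, eta, X = _draw_study1_logtimes(spec, spec.n, rng)
    log_c, _, _ = _draw_study1_logtimes(spec, spec.n, rng)  # fresh, independent pipeline
    T, C = np.exp(log_t), np.exp(log_c)
    obs = np.minimum(T, C)
    event = (T <= C).astype(int)
    cov = pd.DataFrame(X, columns=[f"x{j + 1}" for j in range(10)])
    ds = SurvivalDataset(ids=np.arange(spec.n), time=obs, event=event, covariates=cov)
    return SimTruth(dataset=ds, eta=eta, censoring_time=C)


@dataclass
class Study2Spec:
    """Frozen structure of the additive design (shared across replications)."""

    n: int = 1000
    corr: np.ndarray = field(default=None)
    informative: np.ndarray = field(default=None)  # indices of the 5 signal covariates
    gamma_main: np.ndarray = field(default=None)  # length 30
    gamma_int: dict = field(default=None)  # (j, l) -> coefficient, 10 pairs
    master_seed: int = DEFAULT_MASTER_SEED

    def __post_init__(self) -> None:
        rng = np.random.default_rng(self.master_seed)
        if self.corr is None:
            self.corr = random_correlation_matrix(30, rng)
        self.corr = np.asarray(self.corr, dtype=float)
        if self.corr.shape != (30, 30):
            raise InvalidInputError("design 2 uses exactly 30 covariates")
        if self.informative is None:
            self.informative = np.sort(rng.choice(30, size=5, replace=False))
        self.informative = np.asarray(self.informative, dtype=int)
        if self.gamma_main is None:
            g = np.zeros(30)
            g[self.informative] = rng.uniform(-1.0, 1.0, size=5)
            self.gamma_main = g
        self.gamma_main = np.asarray(self.gamma_main, dtype=float)
        if self.gamma_int is None:
            pairs = [
                (int(a), int(b))
                for i, a in enumerate(self.informative)
                for b in self.informative[i + 1 :]
            ]
            self.gamma_int = {p: float(rng.uniform(-1.0, 1.0)) for p in pairs}
        if len(self.gamma_int) != 10:
            raise InvalidInputError("design 2 requires 10 two-way interaction coefficients")


def _standardize(v: np.ndarray, what: str) -> np.ndarray:
    sd = v.std()
    if sd <= 0:
        raise InvalidInputError(f"degenerate predictor component: zero variance in {what}")
    return (v - v.mean()) / sd


def _draw_study2_logtimes(spec: Study2Spec, lam: float, n: int, rng: np.random.Generator):
    L = np.linalg.cholesky(_nearest_pd(spec.corr))
    X = rng.standard_normal((n, 30)) @ L.T
    eta1 = X @ spec.gamma_main
    eta2 = np.zeros(n)
    for (j, l), g in spec.gamma_int.items():
        eta2 += g * X[:, j] * X[:, l]
    eta = np.zeros(n)
    if lam > 0:
        eta += lam * _standardize(eta1, "main effects")
    if lam < 1:
        eta += (1.0 - lam) * _standardize(eta2, "interactions")
    eta = _standardize(eta, "combined predictor")
    logt = eta + rng.standard_normal(n)
    return logt, eta, X


def simulate_study2(spec: Study2Spec, lam: float, rng: np.random.Generator | None = None) -> SimTruth:
    """One replication of the additive design with mixing weight lambda."""
    if not (0.0 <= lam <= 1.0):
        raise InvalidInputError("lambda must lie in [0, 1]")
    rng = np.random.default_rng(rng)
    log_t, eta, X = _draw_study2_logtimes(spec, lam, spec.n, rng)
    log_c, _, _ = _draw_study2_logtimes(spec, lam, spec.n, rng)
    T, C = np.exp(log_t), np.exp(log_c)
    obs = np.minimum(T, C)
    event = (T <= C).astype(int)
    cov = pd.DataFrame(X, columns=[f"x{j + 1}" for j in range(30)])
    ds = SurvivalDataset(ids=np.arange(spec.n), time=obs, event=event, covariates=cov)
    return SimTruth(dataset=ds, eta=eta, censoring_time=C)


def build_default_time_grid(
    spec, rng: np.random.Generator | None = None, lam: float | None = None, pilot_n: int = 1000
) -> TimeGrid:
    """Evaluation grid from an independent pilot sample of observed times.

    Draws ``pilot_n`` fresh individuals from the study's own process and takes
    the empirical 10/30/50/70/90% quantiles of the observed (censored) times.
    """
    rng = np.random.default_rng(rng)
    if isinstance(spec, Study1Spec):
        pilot_spec = Study1Spec(
            n=pilot_n, corr=spec.corr, coefficients=spec.coefficients, master_seed=spec.master_seed
        )
        pilot = simulate_study1(pilot_spec, rng)
    elif isinstance(spec, Study2Spec):
        if lam is None:
            raise InvalidInputError("lambda is required for the additive design")
        pilot_spec = Study2Spec(
            n=pilot_n,
            corr=spec.corr,
            informative=spec.informative,
            gamma_main=spec.gamma_main,
            gamma_int=spec.gamma_int,
            master_seed=spec.master_seed,
        )
        pilot = simulate_study2(pilot_spec, lam, rng)
    else:
        raise InvalidInputError("unknown study spec")
    return choose_time_grid(pilot.dataset.time, _QUANTILE_LEVELS)
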