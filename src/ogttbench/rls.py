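"""Regularized least-squares classification and repeated nested CV scoring.

The classifier is ridge regression on a +/-1-coded outcome: with centered
features X and centered targets y, the weights minimize
``||y - Xw||^2 + lambda ||w||^2`` (intercept unpenalized). Scores are used
only for ranking (ROC), so the +/-1 coding is immaterial to AUC.

Performance is estimated by repeated nested cross-validation: outer
stratified folds hold data out for scoring; within each outer training set an
inner stratified CV picks the penalty from a grid by out-of-fold AUC; the
model is refit on the full outer training set and scores the held-out fold.
The whole procedure is repeated with re-randomized folds (100 repetitions by
default) and each participant's out-of-fold scores are averaged across
repetitions. Feature standardization is estimated on training folds only and
applied to the held-out folds, so no information leaks from test to train.

One SVD of each training matrix is reused across the entire penalty grid, so
the default 100-repetition protocol over hundreds of candidate models runs
comfortably on a single CPU.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata
from sklearn.model_selection import StratifiedKFold

__all__ = ["RLSModel", "CVConfig", "fit_rls", "nested_cv_scores"]


def default_lambda_grid() -> np.ndarray:
    """2^-10 .. 2^10: spans under- to over-regularized on standardized data."""
    return np.power(2.0, np.arange(-10, 11))


@dataclass
class RLSModel:
    """Fitted ridge classifier: per-feature weights plus an unpenalized
    intercept."""

    weights: np.ndarray
    intercept: float
    lam: float

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X, dtype=float) @ self.weights + self.intercept


@dataclass
class CVConfig:
    """Repeated nested cross-validation settings.

    repetitions : fold re-randomizations to average over (100 by default).
    outer_folds / inner_folds : stratified fold counts (10/10).
    lambda_grid : ridge penalties searched by inner out-of-fold AUC.
    seed : master seed; per-repetition fold seeds are derived from it.
    """

    repetitions: int = 100
    outer_folds: int = 10
    inner_folds: int = 10
    lambda_grid: np.ndarray = field(default_factory=default_lambda_grid)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.repetitions < 1:
            raise ValueError("repetitions must be >= 1")
        if self.outer_folds < 2 or self.inner_folds < 2:
            raise ValueError("fold counts must be >= 2")
        self.lambda_grid = np.asarray(self.lambda_grid, dtype=float)
        if self.lambda_grid.size == 0 or (self.lambda_grid < 0).any():
            raise ValueError("lambda grid must be non-empty and nonnegative")


def fit_rls(X: np.ndarray, y: np.ndarray, lam: float) -> RLSModel:
    """Closed-form ridge fit of a +/-1-coded outcome.

    X must have no missing entries. The intercept is unpenalized: features
    and targets are centered, weights solved in the centered problem, and the
    intercept recovered from the means. At ``lam = 0`` this is ordinary least
    squares and raises on a singular (collinear) system.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or len(X) != len(y):
        raise ValueError("X must be 2-D and aligned with y")
    if len(y) < 2:
        raise ValueError("need at least two observations")
    if lam < 0:
        raise ValueError("lambda must be nonnegative")
    x_mean = X.mean(axis=0)
    y_mean = y.mean()
    Xc = X - x_mean
    yc = y - y_mean
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    if lam == 0 and (s < 1e-10 * max(s.max(), 1.0)).any():
        raise np.linalg.LinAlgError(
            "singular system at lambda = 0 (collinear features)"
        )
    shrink = s / (s**2 + lam)
    w = Vt.T @ (shrink * (U.T @ yc))
    intercept = y_mean - float(x_mean @ w)
    return RLSModel(weights=w, intercept=intercept, lam=float(lam))


def _ridge_path_scores(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_test: np.ndarray,
    lambdas: np.ndarray,
) -> np.ndarray:
    """Held-out decision scores for every penalty at once (shared SVD).

    Standardizes with training-fold statistics, computes one SVD, and returns
    an (n_test, n_lambda) score matrix.
    """
    mu = X_train.mean(axis=0)
    sd = X_train.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    Xtr = (X_train - mu) / sd
    Xte = (X_test - mu) / sd
    y_mean = y_train.mean()
    yc = y_train - y_mean
    U, s, Vt = np.linalg.svd(Xtr, full_matrices=False)
    uty = U.T @ yc
    # shrink factors per (singular value, lambda)
    shrink = s[:, None] / (s[:, None] ** 2 + lambdas[None, :])
    W = Vt.T @ (shrink * uty[:, None])  # (d, L)
    return Xte @ W + y_mean  # intercept shift is rank-invariant but kept


def _auc_columns(scores: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Mann-Whitney AUC (ties = 1/2) of each score column against labels y."""
    pos = y == 1
    m = int(pos.sum())
    n = len(y) - m
    ranks = rankdata(scores, axis=0)
    return (ranks[pos].sum(axis=0) - m * (m + 1) / 2) / (m * n)


def nested_cv_scores(
    X: np.ndarray, y: np.ndarray, config: CVConfig
) -> np.ndarray:
    """Per-participant prediction scores, averaged over repetitions.

    Parameters
    ----------
    X : complete-case feature matrix (n, d), raw scale.
    y : binary outcome (0/1), both classes present.

    Returns the length-n vector of out-of-fold scores averaged over
    ``config.repetitions`` re-randomized nested CV runs. Deterministic for a
    given ``config.seed``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if X.ndim != 2 or X.shape[1] == 0:
        raise ValueError("empty variable set")
    if np.isnan(X).any():
        raise ValueError("X contains missing values; take complete cases first")
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise ValueError("both outcome classes must be present")
    if counts.min() < config.outer_folds:
        raise ValueError(
            f"minority class ({counts.min()}) smaller than outer_folds "
            f"({config.outer_folds}); stratified folds impossible"
        )
    target = np.where(y == 1, 1.0, -1.0)
    total = np.zeros(len(y))

    for rep in range(config.repetitions):
        rep_seed = np.random.SeedSequence([config.seed, rep]).generate_state(1)[0]
        outer = StratifiedKFold(
            n_splits=config.outer_folds, shuffle=True, random_state=int(rep_seed % 2**31)
        )
        rep_scores = np.empty(len(y))
        for tr, te in outer.split(X, y):
            lam = _select_lambda(X[tr], y[tr], target[tr], config, rep_seed)
            scores = _ridge_path_scores(
                X[tr], target[tr], X[te], np.array([lam])
            )[:, 0]
            rep_scores[te] = scores
        total += rep_scores
    return total / config.repetitions


def _select_lambda(
    X: np.ndarray,
    y: np.ndarray,
    target: np.ndarray,
    config: CVConfig,
    rep_seed: int,
) -> float:
    """Inner stratified CV: penalty maximizing mean out-of-fold AUC.

    Ties broken toward the larger penalty (more regularization)."""
    lambdas = config.lambda_grid
    if len(lambdas) == 1:
        return float(lambdas[0])
    n_splits = min(config.inner_folds, np.bincount(y).min())
    if n_splits < 2:
        return float(np.median(lambdas))
    inner = StratifiedKFold(
        n_splits=n_splits, shuffle=True, random_state=int((rep_seed + 1) % 2**31)
    )
    aucs = np.zeros(len(lambdas))
    for tr, te in inner.split(X, y):
        scores = _ridge_path_scores(X[tr], target[tr], X[te], lambdas)
        aucs += _auc_columns(scores, y[te])
    best = np.flatnonzero(aucs == aucs.max())[-1]
    return float(lambdas[best])
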