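"""Preference predictors: neighborhood collaborative filtering and SLIM.

Two ways of aggregating peers' responses to predict a participant's own:

* ``predict_neighborhood`` — the classical user-based formula, weighting
  peers' mean-centered responses by inter-subject Pearson similarity.
* ``fit_slim`` / ``predict_slim`` — the Sparse Linear Method: learn a
  nonnegative, zero-diagonal n x n aggregation matrix ``W`` minimizing

      1/2 ||A - A W||_F^2 + beta/2 ||W||_F^2 + lam ||W||_1
      s.t.  W >= 0,  diag(W) = 0

  The problem is column-separable: each participant's column of ``W`` is a
  nonnegative elastic-net regression of their responses on all peers'
  responses.  Because cross-domain transfer re-applies ``W`` to a different
  domain's ratings, the learned weights act as data-driven similarities.

Solver mapping: scikit-learn's ``ElasticNet`` minimizes
``1/(2 n_samples) ||y - X w||^2 + alpha l1 ||w||_1 + alpha (1 - l1)/2 ||w||^2``,
so the objective above corresponds to ``alpha = (beta + lam) / n_samples``
and ``l1_ratio = lam / (beta + lam)``; the ``beta = lam = 0`` corner is
ordinary nonnegative least squares.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import nnls
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import ElasticNet

from .core_data import NORMALIZED, RatingMatrix
from .similarity import SimilarityMatrix

logger = logging.getLogger("xdomcf")

#: Decade-spaced default grids covering beta in [1e-4, 1e12], lam in [1e-3, 1e2].
DEFAULT_BETA_GRID: tuple[float, ...] = tuple(10.0 ** k for k in range(-4, 13))
DEFAULT_LAM_GRID: tuple[float, ...] = tuple(10.0 ** k for k in range(-3, 3))


@dataclass
class SlimWeights:
    """Nonnegative zero-diagonal aggregation matrix between participants."""

    values: np.ndarray
    participant_ids: list[str]
    source_domain: str
    beta: float
    lam: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.participant_ids)
        if self.values.shape != (n, n):
            raise ValueError("W shape must match participant ids")
        if self.values.min() < 0:
            raise ValueError("W must be nonnegative")
        if np.any(np.diag(self.values) != 0):
            raise ValueError("diag(W) must be exactly zero")
        if self.beta < 0 or self.lam < 0:
            raise ValueError("beta and lam must be nonnegative")


@dataclass
class PredictionSet:
    """Predicted responses for a set of held-out items."""

    predicted: np.ndarray
    item_ids: list[str]
    participant_ids: list[str]
    condition: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.predicted = np.asarray(self.predicted, dtype=float)
        if self.predicted.shape != (len(self.item_ids), len(self.participant_ids)):
            raise ValueError("prediction shape must match ids")
        if not np.all(np.isfinite(self.predicted)):
            raise ValueError("predictions must be finite")


@dataclass
class GridSearchResult:
    """Outcome of the (beta, lam) half-split validation search."""

    best_beta: float
    best_lam: float
    score_table: list[dict]
    seed: int
    weights: "SlimWeights | None" = None


# ---------------------------------------------------------------------------
# Neighborhood CF


def predict_neighborhood(sim: SimilarityMatrix, ratings: RatingMatrix,
                         items: Sequence[str]) -> PredictionSet:
    """User-based CF: r_hat_ui = rbar_u + sum_v sim_uv (r_vi - rbar_v) / sum_v |sim_uv|.

    The neighborhood is every *other* participant with an observed response
    to item i.  When the similarity mass is zero the prediction falls back
    to the participant's mean response (and the event is logged).
    """
    if sim.participant_ids != ratings.participant_ids:
        raise ValueError("similarity and ratings must share participant ids")
    sub = ratings.subset_items(items)
    X = sub.values
    n = ratings.n_participants
    if ratings.scale == NORMALIZED:
        rbar = np.zeros(n)           # centering is exact on normalized data
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            rbar = np.nanmean(ratings.values, axis=0)
        rbar = np.where(np.isfinite(rbar), rbar, 0.0)
    C = X - rbar[None, :]
    obs = ~np.isnan(C)
    Cf = np.where(obs, C, 0.0)
    S = sim.values.copy()
    np.fill_diagonal(S, 0.0)
    numer = Cf @ S                      # (m_items, n): sum_v C_vi * sim_vu
    denom = obs.astype(float) @ np.abs(S)
    fallback = denom <= 0
    if fallback.any():
        logger.info("predict_neighborhood: %d (item, participant) cells fell back "
                    "to the participant mean (zero similarity mass)", int(fallback.sum()))
    with np.errstate(divide="ignore", invalid="ignore"):
        pred = np.where(fallback, 0.0, numer / np.where(fallback, 1.0, denom))
    pred = pred + rbar[None, :]
    return PredictionSet(pred, list(sub.item_ids), list(ratings.participant_ids),
                         condition={"predictor": "neighborhood"})


# ---------------------------------------------------------------------------
# SLIM


def slim_objective(A: RatingMatrix, W: SlimWeights, beta: float, lam: float) -> float:
    """Regularized SLIM objective; missing entries of A leave the residual."""
    if beta < 0 or lam < 0:
        raise ValueError("beta and lam must be nonnegative")
    X = A.values
    Xf = np.nan_to_num(X, nan=0.0)
    R = X - Xf @ W.values
    resid = np.nansum(R ** 2)
    return float(0.5 * resid + 0.5 * beta * np.sum(W.values ** 2)
                 + lam * np.sum(np.abs(W.values)))


def _fit_column(X: np.ndarray, y: np.ndarray, beta: float, lam: float,
                max_iter: int, tol: float) -> np.ndarray:
    """Nonnegative elastic net for one participant column."""
    m = X.shape[0]
    if beta == 0 and lam == 0:
        w, _ = nnls(X, y)
        return w
    alpha = (beta + lam) / m
    l1_ratio = lam / (beta + lam)
    model = ElasticNet(alpha=alpha, l1_ratio=l1_ratio, positive=True,
                       fit_intercept=False, max_iter=max_iter, tol=tol)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        model.fit(X, y)
    return np.maximum(model.coef_, 0.0)


def fit_slim(A_train: RatingMatrix, beta: float, lam: float,
             max_iter: int = 20_000, tol: float = 1e-8,
             kkt_tol: float | None = None) -> SlimWeights:
    """Fit the SLIM aggregation matrix column by column.

    Each participant's responses are regressed on all other participants'
    responses with nonnegative coefficients; the self column is excluded,
    which enforces ``diag(W) = 0`` exactly.  Rows with a missing target
    response are dropped from that column's fit; missing peer responses are
    treated as the (normalized) mean, i.e. zero.

    ``kkt_tol``, when given, verifies first-order optimality of every
    column and raises carrying the worst residual gradient norm.
    """
    if beta < 0 or lam < 0:
        raise ValueError("beta and lam must be nonnegative")
    X = A_train.values
    m, n = X.shape
    if n < 2:
        raise ValueError("SLIM needs at least 2 participants")
    W = np.zeros((n, n))
    worst = 0.0
    for u in range(n):
        y = X[:, u]
        rows = ~np.isnan(y)
        others = np.arange(n) != u
        B = np.nan_to_num(X[np.ix_(rows, others)], nan=0.0)
        w = _fit_column(B, y[rows], beta, lam, max_iter, tol)
        W[others, u] = w
        if kkt_tol is not None:
            g = B.T @ (B @ w - y[rows]) + beta * w + lam
            viol = max(np.abs(g[w > 0]).max(initial=0.0),
                       float(np.maximum(-g[w == 0], 0.0).max(initial=0.0)))
            worst = max(worst, viol)
    if kkt_tol is not None and worst > kkt_tol:
        raise RuntimeError(
            f"SLIM solver did not reach stationarity: worst residual gradient "
            f"norm {worst:.3g} > {kkt_tol:.3g}")
    return SlimWeights(W, list(A_train.participant_ids), A_train.domain, beta, lam)


def predict_slim(W: SlimWeights, target_ratings: RatingMatrix,
                 items: Sequence[str]) -> PredictionSet:
    """Apply aggregation weights to a (possibly different) domain's ratings.

    ``r_hat_ui = sum_{v != u} W[v, u] * r_vi`` over peers' observed
    responses; the predicted participant's own response is never used (the
    diagonal is masked at prediction time, so the guarantee holds even for
    externally manipulated weight matrices).
    """
    if W.participant_ids != target_ratings.participant_ids:
        raise ValueError("W and target ratings must share participant ids")
    sub = target_ratings.subset_items(items)
    Wm = W.values.copy()
    np.fill_diagonal(Wm, 0.0)
    zero_cols = np.where(Wm.sum(axis=0) == 0)[0]
    if zero_cols.size:
        logger.info("predict_slim: %d participants have an all-zero weight column; "
                    "their predictions are 0 (the normalized mean)", zero_cols.size)
    pred = np.nan_to_num(sub.values, nan=0.0) @ Wm
    return PredictionSet(pred, list(sub.item_ids), list(sub.participant_ids),
                         condition={"predictor": "slim",
                                    "source_domain": W.source_domain,
                                    "target_domain": target_ratings.domain})


# ---------------------------------------------------------------------------
# Grid search


def _halfsplit_score(A: RatingMatrix, beta: float, lam: float,
                     fit_pos: np.ndarray, val_pos: np.ndarray,
                     metric: str) -> float:
    from .evaluation import evaluate  # local import to avoid a cycle

    fit_items = [A.item_ids[i] for i in fit_pos]
    val_items = [A.item_ids[i] for i in val_pos]
    W = fit_slim(A.subset_items(fit_items), beta, lam)
    pred = predict_slim(W, A, val_items)
    report = evaluate(pred, A)
    if metric == "fisher_r":
        return report.group_r
    if metric == "mse":
        return -report.mse
    raise ValueError(f"unknown validation metric {metric!r}")


def grid_search(A_train: RatingMatrix, beta_grid: Sequence[float] = DEFAULT_BETA_GRID,
                lam_grid: Sequence[float] = DEFAULT_LAM_GRID, repeats: int = 20,
                seed: int = 0, metric: str = "fisher_r",
                refit: bool = True) -> GridSearchResult:
    """Select (beta, lam) by repeated half-split validation on training items.

    For every grid pair and each of ``repeats`` seeded half-splits of the
    training items, SLIM is fit on one half and scored on the other
    (Fisher-averaged per-participant correlation by default; negative MSE
    with ``metric='mse'``).  The pair with the best mean score wins and the
    model is refit on all training items.
    """
    if not len(beta_grid) or not len(lam_grid):
        raise ValueError("grids must be non-empty")
    m = A_train.n_items
    if m < 4:
        raise ValueError("need at least 4 training items for half-split validation")
    rng = np.random.default_rng(seed)
    half = m // 2
    splits = []
    for _ in range(repeats):
        perm = rng.permutation(m)
        splits.append((np.sort(perm[:half]), np.sort(perm[half:])))
    table: list[dict] = []
    best: tuple[float, float, float] | None = None
    any_defined = False
    for beta in beta_grid:
        for lam in lam_grid:
            scores = []
            for fit_pos, val_pos in splits:
                try:
                    s = _halfsplit_score(A_train, beta, lam, fit_pos, val_pos, metric)
                except ValueError:
                    s = np.nan
                scores.append(s)
            mean_score = float(np.nanmean(scores)) if np.any(np.isfinite(scores)) else -np.inf
            if np.isfinite(mean_score):
                any_defined = True
            table.append({"beta": beta, "lam": lam, "mean_score": mean_score,
                          "repeats": repeats})
            if best is None or mean_score > best[2]:
                best = (beta, lam, mean_score)
    if not any_defined:
        raise ValueError("all validation scores undefined (constant predictions)")
    assert best is not None
    result = GridSearchResult(best_beta=best[0], best_lam=best[1],
                              score_table=table, seed=seed)
    if refit:
        result.weights = fit_slim(A_train, best[0], best[1])
    return result
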