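"""Feature-based comparison model: per-participant ridge regression with LOOCV.

Instead of anchoring a participant to the cohort, this baseline maps
precomputed item features (e.g. deep-network embeddings, or any items x
features matrix) directly to that participant's responses with ridge
regression.  The penalty alpha is chosen by leave-one-item-out
cross-validation using the closed-form ridge LOOCV identity; cross-domain
prediction refits on all source items at the selected alpha and applies
the model to the target domain's features.

Conventions: features are standardized per column with *source-domain*
statistics, responses are centered by their source mean, and the ridge has
no intercept on the centered problem.  The LOOCV shortcut is exact under
these conventions and is verified against explicit refits in the tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core_data import NORMALIZED, RatingMatrix
from .evaluation import EvaluationReport, _per_participant_stats, group_correlation

DEFAULT_ALPHA_GRID: tuple[float, ...] = tuple(10.0 ** k for k in range(-3, 5))


@dataclass
class FeatureMatrix:
    """Items x features design matrix for one domain."""

    values: np.ndarray
    item_ids: list[str]
    source_tag: str = "unspecified"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != len(self.item_ids):
            raise ValueError("row count must equal the number of item ids")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature matrices must be complete (no missing values)")

    @property
    def feature_dim(self) -> int:
        return self.values.shape[1]


def _standardize(X: np.ndarray, mu: np.ndarray, sd: np.ndarray) -> np.ndarray:
    sd = np.where(sd > 0, sd, 1.0)
    return (X - mu) / sd


def fit_ridge_loocv(features: FeatureMatrix, responses: Sequence[float],
                    alpha_grid: Sequence[float] = DEFAULT_ALPHA_GRID,
                    ) -> tuple[float, np.ndarray]:
    """Select alpha by leave-one-item-out CV; return (alpha, LOOCV predictions).

    For each alpha the held-out predictions come from the hat-matrix
    identity ``e_i = (y_i - yhat_i) / (1 - H_ii)`` evaluated via a single
    SVD, equivalent to m explicit refits.  Alpha maximizes the Pearson
    correlation between LOOCV predictions and responses.
    """
    y = np.asarray(responses, dtype=float)
    X = features.values
    m = X.shape[0]
    if y.shape != (m,):
        raise ValueError("responses must match the item count")
    if m < 4:
        raise ValueError("need at least 4 items for LOOCV")
    if y.std() == 0:
        raise ValueError("constant responses: correlation undefined")
    if not len(alpha_grid) or min(alpha_grid) <= 0:
        raise ValueError("alpha grid must be positive")
    mu, sd = X.mean(axis=0), X.std(axis=0)
    Xs = _standardize(X, mu, sd)
    ybar = y.mean()
    yc = y - ybar
    U, s, _ = np.linalg.svd(Xs, full_matrices=False)
    Uty = U.T @ yc
    best: tuple[float, float, np.ndarray] | None = None
    for alpha in alpha_grid:
        d = s ** 2 / (s ** 2 + alpha)
        yhat = U @ (d * Uty)
        h = (U ** 2) @ d
        loo = ybar + yc - (yc - yhat) / (1.0 - h)
        if loo.std() == 0:
            r = -np.inf
        else:
            r = float(np.corrcoef(loo, y)[0, 1])
        if best is None or r > best[0]:
            best = (r, float(alpha), loo)
    assert best is not None
    return best[1], best[2]


def ridge_predict(train_features: FeatureMatrix, responses: Sequence[float],
                  alpha: float, test_features: FeatureMatrix) -> np.ndarray:
    """Refit ridge on all training items and predict test-item responses.

    Test features are standardized with the training-domain statistics.
    """
    if train_features.feature_dim != test_features.feature_dim:
        raise ValueError("feature dimension mismatch between domains")
    y = np.asarray(responses, dtype=float)
    X = train_features.values
    mu, sd = X.mean(axis=0), X.std(axis=0)
    Xs = _standardize(X, mu, sd)
    ybar = y.mean()
    k = Xs.shape[1]
    w = np.linalg.solve(Xs.T @ Xs + alpha * np.eye(k), Xs.T @ (y - ybar))
    return ybar + _standardize(test_features.values, mu, sd) @ w


def baseline_condition(source: RatingMatrix, target: RatingMatrix,
                       features: dict[str, FeatureMatrix],
                       alpha_grid: Sequence[float] = DEFAULT_ALPHA_GRID,
                       ) -> EvaluationReport:
    """Per-participant ridge baseline, within- or cross-domain.

    Within-domain (``source is target``): the LOOCV predictions themselves
    are scored.  Cross-domain: for each participant, alpha is selected on
    the source domain, the model is refit on all source items, and the
    predictions on the target domain's features are scored against that
    participant's target responses.
    """
    f_src = features[source.domain]
    f_tgt = features[target.domain]
    if f_src.feature_dim != f_tgt.feature_dim:
        raise ValueError("feature dimension must match across domains")
    if source.participant_ids != target.participant_ids:
        raise ValueError("source and target must share participant ids")
    within = source.domain == target.domain
    n = source.n_participants
    preds = np.zeros((target.n_items, n))
    for u in range(n):
        y_src = source.values[:, u]
        alpha, loo = fit_ridge_loocv(f_src, y_src, alpha_grid)
        if within:
            preds[:, u] = loo
        else:
            preds[:, u] = ridge_predict(f_src, y_src, alpha, f_tgt)
    rs, per_mse = _per_participant_stats(preds, target.values)
    mask = np.isfinite(target.values)
    pooled = float(np.mean((preds[mask] - target.values[mask]) ** 2))
    return EvaluationReport(
        per_participant_r=rs, group_r=group_correlation(rs), mse=pooled,
        condition={"predictor": "feature_baseline", "source_domain": source.domain,
                   "target_domain": target.domain, "features": f_src.source_tag},
        n_items_tested=target.n_items, participant_ids=list(target.participant_ids),
        per_participant_mse=per_mse)
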