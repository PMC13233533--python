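"""Model evaluation: MSE, Fisher-averaged correlations, paired tests, permutation nulls.

Per-participant prediction quality is the Pearson correlation between
predicted and observed held-out responses.  The group-level summary applies
Fisher's variance-stabilizing transform z = atanh(r), averages, and maps
back with tanh.  Statistical comparisons between conditions use a paired
t-test on Fisher-transformed correlations; specificity of the learned
peer mapping is assessed with a weight-shuffling permutation test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import stats

from .cf_predict import PredictionSet, SlimWeights, predict_slim
from .core_data import RatingMatrix

logger = logging.getLogger("xdomcf")

_R_CLIP = 1.0 - 1e-7


def fisher_z(r: np.ndarray | float) -> np.ndarray | float:
    """z = atanh(r), with r clipped to +-(1 - 1e-7) to stay finite."""
    return np.arctanh(np.clip(r, -_R_CLIP, _R_CLIP))


def fisher_inverse(z: np.ndarray | float) -> np.ndarray | float:
    return np.tanh(z)


def mse(observed: Sequence[float], predicted: Sequence[float]) -> float:
    """Mean squared error between two equal-length response vectors."""
    a = np.asarray(observed, dtype=float)
    b = np.asarray(predicted, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 1:
        raise ValueError("observed and predicted must be equal-length 1-D vectors")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("inputs must be finite")
    return float(np.mean((a - b) ** 2))


@dataclass
class EvaluationReport:
    """Per-participant and group-level accuracy for one condition."""

    per_participant_r: np.ndarray
    group_r: float
    mse: float
    condition: dict
    n_items_tested: int
    participant_ids: list[str] = field(default_factory=list)
    per_participant_mse: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.per_participant_r = np.asarray(self.per_participant_r, dtype=float)
        finite = self.per_participant_r[np.isfinite(self.per_participant_r)]
        if finite.size and (finite.min() < -1 - 1e-9 or finite.max() > 1 + 1e-9):
            raise ValueError("per-participant correlations must lie in [-1, 1]")
        if not -1 - 1e-9 <= self.group_r <= 1 + 1e-9:
            raise ValueError("group r must lie in [-1, 1]")
        if self.mse < 0:
            raise ValueError("mse must be nonnegative")

    def to_dict(self) -> dict:
        return {
            "per_participant_r": [None if not np.isfinite(r) else float(r)
                                  for r in self.per_participant_r],
            "group_r": self.group_r,
            "mse": self.mse,
            "condition": self.condition,
            "n_items_tested": self.n_items_tested,
            "participant_ids": self.participant_ids,
            "per_participant_mse": (None if self.per_participant_mse is None else
                                    [float(x) for x in self.per_participant_mse]),
        }


def _per_participant_stats(pred: np.ndarray, obs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Pearson r and MSE per column over jointly observed entries; r is NaN
    when either side has zero variance."""
    n = pred.shape[1]
    rs = np.full(n, np.nan)
    mses = np.full(n, np.nan)
    for u in range(n):
        mask = np.isfinite(obs[:, u])
        if mask.sum() < 3:
            continue
        p, o = pred[mask, u], obs[mask, u]
        mses[u] = np.mean((p - o) ** 2)
        if p.std() == 0 or o.std() == 0:
            continue
        rs[u] = np.corrcoef(p, o)[0, 1]
    return rs, mses


def group_correlation(per_participant_r: np.ndarray) -> float:
    """Fisher-average: tanh(mean(atanh(r))) over defined correlations."""
    r = np.asarray(per_participant_r, dtype=float)
    ok = np.isfinite(r)
    if not ok.any():
        raise ValueError("no defined per-participant correlations to average")
    return float(np.tanh(np.mean(np.arctanh(np.clip(r[ok], -_R_CLIP, _R_CLIP)))))


def evaluate(pred: PredictionSet, truth: RatingMatrix) -> EvaluationReport:
    """Score predictions against observed responses on the predicted items.

    Participants with undefined correlations (zero-variance predictions or
    observations, or < 3 observed test items) carry NaN and are excluded
    from the Fisher mean; the exclusion is logged.  MSE is pooled over all
    observed participant-item pairs.
    """
    if pred.participant_ids != truth.participant_ids:
        raise ValueError("prediction and truth must share participant ids")
    obs = truth.subset_items(pred.item_ids).values
    rs, per_mse = _per_participant_stats(pred.predicted, obs)
    excluded = int(np.sum(~np.isfinite(rs)))
    if excluded:
        logger.info("evaluate: %d participants excluded from the Fisher mean "
                    "(undefined correlation)", excluded)
    mask = np.isfinite(obs)
    pooled = float(np.mean((pred.predicted[mask] - obs[mask]) ** 2))
    return EvaluationReport(per_participant_r=rs,
                            group_r=group_correlation(rs),
                            mse=pooled,
                            condition=dict(pred.condition),
                            n_items_tested=len(pred.item_ids),
                            participant_ids=list(pred.participant_ids),
                            per_participant_mse=per_mse)


# ---------------------------------------------------------------------------
# Paired t-test


@dataclass
class PairedTestResult:
    t: float
    dof: int
    p_two_tailed: float
    mean_diff: float
    sd_diff: float
    n: int

    def __post_init__(self) -> None:
        if self.dof != self.n - 1:
            raise ValueError("dof must equal n - 1")
        if not 0 <= self.p_two_tailed <= 1:
            raise ValueError("p must lie in [0, 1]")


def paired_ttest(x1: Sequence[float], x2: Sequence[float]) -> PairedTestResult:
    """Two-tailed paired t-test: t = dbar / (s_d / sqrt(n)), sample SD (n-1).

    Callers comparing correlations are expected to Fisher-transform first.
    """
    a = np.asarray(x1, dtype=float)
    b = np.asarray(x2, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 2:
        raise ValueError("paired t-test needs two equal-length vectors, n >= 2")
    d = a - b
    n = d.size
    dbar = float(d.mean())
    sd = float(d.std(ddof=1))
    if sd == 0:
        if dbar == 0:
            return PairedTestResult(t=0.0, dof=n - 1, p_two_tailed=1.0,
                                    mean_diff=0.0, sd_diff=0.0, n=n)
        raise ValueError("zero-variance nonzero differences: t undefined")
    t = dbar / (sd / np.sqrt(n))
    p = float(2 * stats.t.sf(abs(t), df=n - 1))
    return PairedTestResult(t=float(t), dof=n - 1, p_two_tailed=p,
                            mean_diff=dbar, sd_diff=sd, n=n)


# ---------------------------------------------------------------------------
# Permutation test


@dataclass
class PermutationResult:
    observed: float
    null_distribution: np.ndarray
    p_value: float
    B: int
    seed: int
    scheme: str = "rows"

    def __post_init__(self) -> None:
        self.null_distribution = np.asarray(self.null_distribution, dtype=float)
        if len(self.null_distribution) != self.B:
            raise ValueError("null distribution length must equal B")
        if not 0 <= self.p_value <= 1:
            raise ValueError("p must lie in [0, 1]")


def _shuffle_weights(W: np.ndarray, rng: np.random.Generator, scheme: str) -> np.ndarray:
    n = W.shape[0]
    if scheme == "rows":
        return W[rng.permutation(n), :]
    if scheme == "per_column":
        out = W.copy()
        for u in range(n):
            others = np.flatnonzero(np.arange(n) != u)
            out[others, u] = W[rng.permutation(others), u]
        return out
    if scheme == "entries":
        mask = ~np.eye(n, dtype=bool)
        out = np.zeros_like(W)
        vals = W[mask]
        out[mask] = vals[rng.permutation(vals.size)]
        return out
    raise ValueError(f"unknown shuffling scheme {scheme!r}")


def _default_statistic(pred: np.ndarray, obs: np.ndarray) -> float:
    rs, _ = _per_participant_stats(pred, obs)
    return group_correlation(rs)


def permutation_test(W: SlimWeights, target_ratings: RatingMatrix, B: int = 1000,
                     seed: int = 0,
                     statistic: Callable[[np.ndarray, np.ndarray], float] | None = None,
                     scheme: str = "rows", add_one: bool = False) -> PermutationResult:
    """Weight-shuffling null for cross-domain prediction accuracy.

    The observed statistic (Fisher-averaged group r by default) comes from
    predictions with the intact ``W`` on *all* target items; each of ``B``
    iterations re-scores predictions after randomly permuting the peer
    identities (rows) of ``W``.  Self-responses are never used: the
    diagonal is masked at prediction time for intact and shuffled weights
    alike.  ``p`` is the raw proportion of null values >= observed, or the
    add-one-smoothed ``(1 + #) / (B + 1)`` when ``add_one`` is set.
    """
    if B < 100:
        logger.warning("permutation_test: B=%d (< 100) gives a coarse null", B)
    Wv = W.values
    if not Wv.any():
        raise ValueError("degenerate all-zero weight matrix")
    stat = statistic or _default_statistic
    obs_matrix = target_ratings.values
    Xf = np.nan_to_num(obs_matrix, nan=0.0)
    n = Wv.shape[0]
    eye = np.eye(n, dtype=bool)

    def score(Wmat: np.ndarray) -> float:
        Wm = np.where(eye, 0.0, Wmat)
        return stat(Xf @ Wm, obs_matrix)

    observed = score(Wv)
    rng = np.random.default_rng(seed)
    null = np.array([score(_shuffle_weights(Wv, rng, scheme)) for _ in range(B)])
    exceed = int(np.sum(null >= observed))
    p = (exceed + 1) / (B + 1) if add_one else exceed / B
    return PermutationResult(observed=observed, null_distribution=null,
                             p_value=float(p), B=B, seed=seed, scheme=scheme)
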