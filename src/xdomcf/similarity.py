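"""Inter-subject similarity within domains and second-order similarity between domains.

Each domain yields an n x n matrix of Pearson correlations between
participants' response profiles.  Vectorizing the strict lower triangle of
each domain's matrix and correlating those vectors across domains gives the
second-order (inter-domain) correlation matrix, which quantifies how well
the social similarity structure is preserved across stimulus categories.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .core_data import RatingMatrix

_SYM_TOL = 1e-12


@dataclass
class SimilarityMatrix:
    """Participants x participants Pearson similarity for one domain."""

    values: np.ndarray
    participant_ids: list[str]
    domain: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.participant_ids)
        if self.values.shape != (n, n):
            raise ValueError("similarity matrix shape must match participant ids")
        if not np.allclose(self.values, self.values.T, atol=_SYM_TOL, rtol=0):
            raise ValueError("similarity matrix must be symmetric")
        if not np.all(np.diag(self.values) == 1.0):
            raise ValueError("similarity diagonal must be exactly 1")
        off = self.values[~np.eye(n, dtype=bool)]
        if off.size and (np.nanmin(off) < -1 - 1e-12 or np.nanmax(off) > 1 + 1e-12):
            raise ValueError("similarities must lie in [-1, 1]")

    @property
    def n(self) -> int:
        return len(self.participant_ids)

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(self.values, index=self.participant_ids,
                     columns=self.participant_ids).to_csv(path)


@dataclass
class InterDomainMatrix:
    """d x d second-order correlation between domains' similarity structures."""

    values: np.ndarray
    domain_labels: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        d = len(self.domain_labels)
        if self.values.shape != (d, d):
            raise ValueError("inter-domain matrix shape must match labels")
        if not np.allclose(self.values, self.values.T, atol=1e-12, rtol=0):
            raise ValueError("inter-domain matrix must be symmetric")

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(self.values, index=self.domain_labels,
                     columns=self.domain_labels).to_csv(path)

    def mean_offdiagonal(self) -> float:
        d = len(self.domain_labels)
        mask = ~np.eye(d, dtype=bool)
        return float(self.values[mask].mean())


def pairwise_similarity(rm: RatingMatrix, min_overlap: int = 3) -> SimilarityMatrix:
    """Pearson correlation between every participant pair's responses.

    Correlations use pairwise-complete items (both responses observed).
    A pair with fewer than ``min_overlap`` joint items, or with zero
    response variance over the joint items, is an error naming the pair.
    """
    X = rm.values
    m, n = X.shape
    obs = ~np.isnan(X)
    if not np.isnan(X).any():
        # complete-data fast path
        sds = X.std(axis=0)
        if np.any(sds == 0):
            j = int(np.where(sds == 0)[0][0])
            k = 0 if j != 0 else 1
            raise ValueError(
                f"zero-variance overlap for pair ({rm.participant_ids[j]!r}, "
                f"{rm.participant_ids[k]!r}) in domain {rm.domain!r}")
        if m < min_overlap:
            raise ValueError(f"pairs share only {m} items (< {min_overlap})")
        S = np.corrcoef(X.T)
    else:
        S = np.eye(n)
        for u in range(n):
            for v in range(u + 1, n):
                joint = obs[:, u] & obs[:, v]
                pair = (rm.participant_ids[u], rm.participant_ids[v])
                if joint.sum() < min_overlap:
                    raise ValueError(
                        f"pair {pair} shares only {int(joint.sum())} items "
                        f"(< {min_overlap}) in domain {rm.domain!r}")
                a, b = X[joint, u], X[joint, v]
                if a.std() == 0 or b.std() == 0:
                    raise ValueError(
                        f"zero-variance overlap for pair {pair} in domain {rm.domain!r}")
                r = np.corrcoef(a, b)[0, 1]
                S[u, v] = S[v, u] = r
    np.fill_diagonal(S, 1.0)
    S = np.clip((S + S.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(S, 1.0)
    return SimilarityMatrix(S, list(rm.participant_ids), rm.domain)


def lower_triangle(sm: SimilarityMatrix) -> np.ndarray:
    """Strictly-below-diagonal entries in fixed row-major order (i > j)."""
    i, j = np.tril_indices(sm.n, k=-1)
    return sm.values[i, j]


def inter_domain_matrix(sms: Sequence[SimilarityMatrix]) -> InterDomainMatrix:
    """Second-order Pearson correlation between domains' similarity vectors."""
    pids = sms[0].participant_ids
    for sm in sms[1:]:
        if sm.participant_ids != pids:
            raise ValueError(
                f"participant sets differ between domains {sms[0].domain!r} "
                f"and {sm.domain!r}")
    vecs = np.stack([lower_triangle(sm) for sm in sms])
    C = np.corrcoef(vecs)
    C = np.atleast_2d(C)
    np.fill_diagonal(C, 1.0)
    C = (C + C.T) / 2.0
    return InterDomainMatrix(C, [sm.domain for sm in sms])


def mean_similarity(sm: SimilarityMatrix) -> float:
    """Plain arithmetic mean of the lower-triangle similarities."""
    return float(lower_triangle(sm).mean())
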