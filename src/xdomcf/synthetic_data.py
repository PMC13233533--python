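"""Seeded generator of multi-domain rating cohorts with a shared latent trait.

The generator emulates a behavioral study in which the same cohort rates
items in several aesthetic domains: monetary valuations for art and
block-wise rank responses for faces and scenes.  Each participant u holds a
shared trait vector p_u; the effective trait in domain d is

    q_du = c * p_u + gamma * g_{gender(u), d} + sqrt(1 - c^2 - gamma^2) * e_du

with e_du independent standard normal.  ``c`` (consistency) controls how
much of every domain's preference is domain-invariant, ``gamma`` adds a
gender-shared component, and the residual is domain-specific.  Item
attributes are i.i.d. standard normal vectors; the latent response is the
trait-attribute inner product plus Gaussian noise of SD ``noise_sd``.

Raw-scale transforms then mimic the tasks: monetary domains map latent
responses through an exponential curve anchored at a median of 10,000
(range clipped to [100, 1e7]); rank domains replace responses within
consecutive blocks by their descending rank (1 = most preferred).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .core_data import (RAW_MONETARY, RAW_RANK, Cohort, RatingMatrix)

DEFAULT_ITEMS: dict[str, int] = {"art": 400, "face_male": 80, "face_female": 80,
                                 "scene": 400}
DEFAULT_SCALES: dict[str, str] = {"art": "monetary", "face_male": "rank",
                                  "face_female": "rank", "scene": "rank"}

#: Decades of price spread per 1 SD of latent response in the monetary map.
MONETARY_SLOPE = 0.4


@dataclass
class SyntheticConfig:
    """Study-design knobs for one simulated cohort."""

    n_participants: int = 37
    n_male: int = 9
    items_per_domain: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_ITEMS))
    latent_dim: int = 8
    consistency: float = 0.7
    gender_strength: float = 0.3
    noise_sd: float = 0.3
    scales: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_SCALES))
    rank_block: int = 80
    #: strength of a shared "attractiveness" consensus that contaminates
    #: responses to the *opposite*-gender face domain, displacing the
    #: domain-invariant trait there (0 = symmetric face domains)
    opposite_gender_attraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_male > self.n_participants or self.n_male < 0:
            raise ValueError("n_male must lie in [0, n_participants]")
        if not all(m > 0 for m in self.items_per_domain.values()):
            raise ValueError("all item counts must be positive")
        if self.n_participants < 2 or self.latent_dim < 1 or self.rank_block < 2:
            raise ValueError("counts must be positive (n >= 2, k >= 1, block >= 2)")
        c, g, a = self.consistency, self.gender_strength, self.opposite_gender_attraction
        if not (0 <= c <= 1) or g < 0 or c ** 2 + g ** 2 > 1 + 1e-12:
            raise ValueError("need 0 <= c <= 1, gamma >= 0, c^2 + gamma^2 <= 1")
        if not 0 <= a <= c + 1e-12 and a != 0:
            raise ValueError("need 0 <= attraction <= consistency (it displaces trait share)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        for d, s in self.scales.items():
            if s not in {"monetary", "rank"}:
                raise ValueError(f"unknown raw scale {s!r} for domain {d!r}")
        for d, m in self.items_per_domain.items():
            if self.scales.get(d) == "rank" and m % self.rank_block:
                raise ValueError(
                    f"rank block {self.rank_block} does not divide {m} items of {d!r}")


@dataclass
class SyntheticTruth:
    """Ground-truth latents behind a simulated cohort, for recovery tests."""

    participant_traits: np.ndarray                  # (n, k) shared p_u
    domain_traits: dict[str, np.ndarray]            # per domain (n, k) q_du
    item_attributes: dict[str, np.ndarray]          # per domain (m_d, k)
    latent_responses: dict[str, np.ndarray]         # per domain (m_d, n)
    config: SyntheticConfig


def _participant_ids(cfg: SyntheticConfig) -> tuple[list[str], list[str]]:
    ids = [f"p{k + 1:02d}" for k in range(cfg.n_participants)]
    gender = ["male"] * cfg.n_male + ["female"] * (cfg.n_participants - cfg.n_male)
    return ids, gender


def monetary_transform(latent: np.ndarray, slope: float = MONETARY_SLOPE) -> np.ndarray:
    """Monotone per-participant map to prices in [100, 1e7], median 10,000.

    Each column's latent responses are standardized, scaled to ``slope``
    decades per SD, and exponentiated around the task's starting value of
    10^4; the exponent is clipped to [2, 7].  A gentle slope keeps Pearson
    structure largely intact while producing a realistic right-skewed price
    distribution.
    """
    out = np.empty_like(latent, dtype=float)
    for j in range(latent.shape[1]):
        col = latent[:, j]
        med = np.median(col)
        sd = col.std()
        z = (col - med) / sd if sd > 0 else np.zeros_like(col)
        out[:, j] = 10.0 ** np.clip(4.0 + slope * z, 2.0, 7.0)
    return out


def rank_transform(latent: np.ndarray, block: int) -> np.ndarray:
    """Within consecutive blocks, descending rank (1 = largest latent).

    Ties are broken by item order (stable sort), mirroring a sequential
    grid-ranking task where each block of items is ranked independently.
    """
    m, n = latent.shape
    if m % block:
        raise ValueError(f"block size {block} does not divide {m} items")
    out = np.empty_like(latent, dtype=float)
    for start in range(0, m, block):
        seg = latent[start:start + block]
        order = np.argsort(-seg, axis=0, kind="stable")
        ranks = np.empty_like(order)
        rows = np.arange(1, block + 1)[:, None]
        np.put_along_axis(ranks, order, np.broadcast_to(rows, order.shape), axis=0)
        out[start:start + block] = ranks
    return out


def to_raw_scales(latent: Mapping[str, np.ndarray], cfg: SyntheticConfig,
                  participant_ids: list[str] | None = None) -> list[RatingMatrix]:
    """Apply each domain's raw-scale transform to its latent responses."""
    pids = participant_ids or _participant_ids(cfg)[0]
    out = []
    for domain, vals in latent.items():
        if not np.all(np.isfinite(vals)):
            raise ValueError(f"latent responses for {domain!r} must be finite")
        item_ids = [f"{domain}_{k + 1:03d}" for k in range(vals.shape[0])]
        if cfg.scales[domain] == "monetary":
            raw = monetary_transform(vals)
            scale = RAW_MONETARY
        else:
            raw = rank_transform(vals, cfg.rank_block)
            scale = RAW_RANK
        out.append(RatingMatrix(raw, item_ids, pids, domain, scale))
    return out


def generate_cohort(cfg: SyntheticConfig) -> tuple[list[RatingMatrix], Cohort, SyntheticTruth]:
    """Sample one cohort: raw rating matrices, roster, and ground truth."""
    rng = np.random.default_rng(cfg.seed)
    n, k = cfg.n_participants, cfg.latent_dim
    pids, gender = _participant_ids(cfg)
    p = rng.standard_normal((n, k))
    domain_traits: dict[str, np.ndarray] = {}
    item_attrs: dict[str, np.ndarray] = {}
    latent: dict[str, np.ndarray] = {}
    gidx = np.array([0 if g == "male" else 1 for g in gender])
    a = cfg.opposite_gender_attraction
    for domain, m in cfg.items_per_domain.items():
        g_dirs = rng.standard_normal((2, k))          # one direction per gender
        e = rng.standard_normal((n, k))
        attract_dir = rng.standard_normal(k)
        # raters of the opposite gender share an "attractiveness" consensus in
        # a face domain; it displaces part of their domain-invariant trait
        if domain == "face_male":
            attracted = gidx == 1
        elif domain == "face_female":
            attracted = gidx == 0
        else:
            attracted = np.zeros(n, dtype=bool)
        a_u = np.where(attracted, a, 0.0)[:, None]
        # the consensus displaces invariant-trait share for attracted raters,
        # keeping total trait variance at 1
        c_u = np.sqrt(np.maximum(0.0, cfg.consistency ** 2 - a_u ** 2))
        resid = np.sqrt(max(0.0, 1.0 - cfg.consistency ** 2 - cfg.gender_strength ** 2))
        q = (c_u * p + cfg.gender_strength * g_dirs[gidx]
             + a_u * attract_dir[None, :] + resid * e)
        X = rng.standard_normal((m, k))
        s = X @ q.T + cfg.noise_sd * rng.standard_normal((m, n))
        domain_traits[domain] = q
        item_attrs[domain] = X
        latent[domain] = s
    ratings = to_raw_scales(latent, cfg, pids)
    cohort = Cohort(pids, gender)
    truth = SyntheticTruth(participant_traits=p, domain_traits=domain_traits,
                           item_attributes=item_attrs, latent_responses=latent,
                           config=cfg)
    return ratings, cohort, truth


def generate_feature_linked_cohort(
        n_participants: int = 37, items_per_domain: Mapping[str, int] | None = None,
        latent_dim: int = 8, n_features: int = 50, noise_sd: float = 0.1,
        shared_map: bool = False, seed: int = 0,
) -> tuple[list[RatingMatrix], dict[str, np.ndarray], dict]:
    """Cohort whose ratings are linear in observable item features.

    Ratings in domain d are ``X_d @ M_d @ Q.T`` plus noise, with shared
    participant traits Q (fully domain-consistent) and a per-domain
    feature-to-trait map ``M_d``.  With ``shared_map=False`` the maps are
    drawn independently, so feature-based regression cannot transfer across
    domains even though the inter-subject structure (and hence similarity-
    based transfer) is fully preserved — the construction behind the
    feature-baseline comparison.

    Returns continuous-valued raw matrices, per-domain feature arrays
    (items x features), and a truth dict with ``traits`` and ``maps``.
    """
    items = dict(items_per_domain or {"art": 200, "face": 160})
    rng = np.random.default_rng(seed)
    Q = rng.standard_normal((n_participants, latent_dim))
    pids = [f"p{k + 1:02d}" for k in range(n_participants)]
    M_shared = rng.standard_normal((n_features, latent_dim)) / np.sqrt(n_features)
    ratings, features, maps = [], {}, {}
    for domain, m in items.items():
        M = M_shared if shared_map else rng.standard_normal(
            (n_features, latent_dim)) / np.sqrt(n_features)
        X = rng.standard_normal((m, n_features))
        vals = X @ M @ Q.T + noise_sd * rng.standard_normal((m, n_participants))
        item_ids = [f"{domain}_{j + 1:03d}" for j in range(m)]
        ratings.append(RatingMatrix(vals, item_ids, pids, domain, RAW_MONETARY))
        features[domain] = X
        maps[domain] = M
    return ratings, features, {"traits": Q, "maps": maps}
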