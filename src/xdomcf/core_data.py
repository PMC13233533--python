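"""Data model and file I/O for multi-domain preference-rating studies.

A study consists of several *domains* (stimulus categories such as art,
male faces, female faces, scenes), each holding an items x participants
response matrix.  Responses may be raw monetary valuations, raw within-block
ranks, or z-score normalized values.  Missing responses are represented as
``NaN`` and are excluded from every statistic downstream.

The on-disk format is a single wide CSV/TSV with columns
``domain,item_id,<participant_1>,...,<participant_n>`` where empty cells or
``NA`` denote missing responses.  An optional leading comment line
``# scales: art=raw_monetary,...`` records the scale tag per domain.
"""

from __future__ import annotations

import io
import logging
from dataclasses import InitVar, dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("xdomcf")

RAW_MONETARY = "raw_monetary"
RAW_RANK = "raw_rank"
NORMALIZED = "normalized"
RAW_SCALES = frozenset({RAW_MONETARY, RAW_RANK})
VALID_SCALES = frozenset({RAW_MONETARY, RAW_RANK, NORMALIZED})

_NORM_TOL = 1e-9


@dataclass
class RatingMatrix:
    """Items x participants response matrix for one stimulus domain.

    Parameters
    ----------
    values : ndarray of shape (m, n)
        Real responses; ``NaN`` marks a missing response.
    item_ids, participant_ids : sequences of str
        Row and column identifiers, unique within the matrix.
    domain : str
        Domain label, e.g. ``"art"`` or ``"face_male"``.
    scale : str
        One of ``raw_monetary``, ``raw_rank``, ``normalized``.
    """

    values: np.ndarray
    item_ids: list[str]
    participant_ids: list[str]
    domain: str
    scale: str = RAW_MONETARY
    #: skip the strict normalized-column check (item subsets of a normalized
    #: matrix keep the tag but are only approximately standardized)
    check_normalized: InitVar[bool] = True

    def __post_init__(self, check_normalized: bool = True) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.item_ids = [str(i) for i in self.item_ids]
        self.participant_ids = [str(p) for p in self.participant_ids]
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (items x participants)")
        m, n = self.values.shape
        if m != len(self.item_ids) or n != len(self.participant_ids):
            raise ValueError(
                f"shape {self.values.shape} does not match "
                f"{len(self.item_ids)} item ids x {len(self.participant_ids)} participant ids"
            )
        if len(set(self.item_ids)) != m:
            dup = _first_duplicate(self.item_ids)
            raise ValueError(f"duplicate item id {dup!r} in domain {self.domain!r}")
        if len(set(self.participant_ids)) != n:
            dup = _first_duplicate(self.participant_ids)
            raise ValueError(f"duplicate participant id {dup!r}")
        if self.scale not in VALID_SCALES:
            raise ValueError(f"unknown scale {self.scale!r}")
        if self.scale == NORMALIZED and check_normalized:
            self._check_normalized()

    def _check_normalized(self) -> None:
        with np.errstate(invalid="ignore"):
            mu = np.nanmean(self.values, axis=0)
            sd = np.nanstd(self.values, axis=0)
        bad = np.where((np.abs(mu) > _NORM_TOL) | (np.abs(sd - 1.0) > _NORM_TOL))[0]
        if bad.size:
            pid = self.participant_ids[bad[0]]
            raise ValueError(
                f"column {pid!r} tagged normalized but mean={mu[bad[0]]:.3g}, sd={sd[bad[0]]:.3g}"
            )

    @property
    def n_items(self) -> int:
        return self.values.shape[0]

    @property
    def n_participants(self) -> int:
        return self.values.shape[1]

    def copy(self) -> "RatingMatrix":
        return RatingMatrix(self.values.copy(), list(self.item_ids),
                            list(self.participant_ids), self.domain, self.scale,
                            check_normalized=False)

    def item_index(self, items: Sequence[str]) -> np.ndarray:
        pos = {iid: k for k, iid in enumerate(self.item_ids)}
        try:
            return np.array([pos[i] for i in items], dtype=int)
        except KeyError as e:  # pragma: no cover - defensive
            raise KeyError(f"unknown item id {e.args[0]!r} in domain {self.domain!r}")

    def subset_items(self, items: Sequence[str]) -> "RatingMatrix":
        idx = self.item_index(items)
        return RatingMatrix(self.values[idx].copy(),
                            [self.item_ids[i] for i in idx],
                            list(self.participant_ids), self.domain, self.scale,
                            check_normalized=False)

    def subset_participants(self, pids: Sequence[str]) -> "RatingMatrix":
        pos = {p: k for k, p in enumerate(self.participant_ids)}
        idx = np.array([pos[p] for p in pids], dtype=int)
        return RatingMatrix(self.values[:, idx].copy(), list(self.item_ids),
                            list(pids), self.domain, self.scale,
                            check_normalized=False)


@dataclass
class Cohort:
    """Participant roster with gender labels (``male``/``female``/``other``)."""

    participant_ids: list[str]
    gender: list[str]

    def __post_init__(self) -> None:
        if len(self.participant_ids) != len(self.gender):
            raise ValueError("one gender label per participant id required")
        if len(set(self.participant_ids)) != len(self.participant_ids):
            raise ValueError("participant ids must be unique")

    def ids_of(self, gender: str) -> list[str]:
        return [p for p, g in zip(self.participant_ids, self.gender) if g == gender]

    @property
    def n(self) -> int:
        return len(self.participant_ids)


@dataclass
class SplitIndex:
    """Item-level train/test partition shared by all participants."""

    train_items: list[str]
    test_items: list[str]
    seed: int
    fraction: float

    def __post_init__(self) -> None:
        overlap = set(self.train_items) & set(self.test_items)
        if overlap:
            raise ValueError(f"train/test overlap: {sorted(overlap)[:3]}")


def _first_duplicate(seq: Iterable[str]) -> str:
    seen: set[str] = set()
    for x in seq:
        if x in seen:
            return x
        seen.add(x)
    return ""


# ---------------------------------------------------------------------------
# File I/O


def write_ratings(matrices: Sequence[RatingMatrix], path: str | Path) -> None:
    """Write domains to one wide CSV/TSV with a `# scales:` directive line."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    pids = matrices[0].participant_ids
    for rm in matrices:
        if rm.participant_ids != pids:
            raise ValueError("all domains must share participant ids and order")
    frames = []
    for rm in matrices:
        df = pd.DataFrame(rm.values, columns=pids)
        df.insert(0, "item_id", rm.item_ids)
        df.insert(0, "domain", rm.domain)
        frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    directive = "# scales: " + ",".join(f"{rm.domain}={rm.scale}" for rm in matrices)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(directive + "\n")
        out.to_csv(fh, sep=sep, index=False, na_rep="NA", float_format="%.17g")


def read_ratings(path: str | Path, scales: Mapping[str, str] | str | None = None,
                 orientation: str = "wide") -> list[RatingMatrix]:
    """Read one :class:`RatingMatrix` per domain from a wide CSV/TSV.

    ``scales`` overrides the file's ``# scales:`` directive; a single string
    applies to every domain.  Non-numeric cells other than the missing
    sentinel (``NA`` / empty) are reported with row and column context.
    """
    if orientation != "wide":
        raise ValueError("only the wide orientation is supported")
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    text = path.read_text(encoding="utf-8")
    directive_scales: dict[str, str] = {}
    lines = text.splitlines(keepends=True)
    body_start = 0
    for ln in lines:
        if ln.startswith("#"):
            body_start += 1
            if ln.lstrip("# ").startswith("scales:"):
                directive = ln.split("scales:", 1)[1].strip()
                for part in directive.split(","):
                    if "=" in part:
                        d, s = part.split("=", 1)
                        directive_scales[d.strip()] = s.strip()
        else:
            break
    df = pd.read_csv(io.StringIO("".join(lines[body_start:])), sep=sep, dtype=str,
                     keep_default_na=False)
    if list(df.columns[:2]) != ["domain", "item_id"]:
        raise ValueError("expected leading columns 'domain,item_id'")
    pids = list(df.columns[2:])
    matrices: list[RatingMatrix] = []
    for domain in df["domain"].drop_duplicates():
        sub = df[df["domain"] == domain]
        item_ids = list(sub["item_id"])
        dup = _first_duplicate(item_ids)
        if len(set(item_ids)) != len(item_ids):
            raise ValueError(f"duplicate item id {dup!r} in domain {domain!r}")
        raw = sub[pids].to_numpy()
        missing = (raw == "NA") | (raw == "")
        vals = pd.to_numeric(pd.Series(raw.ravel()), errors="coerce").to_numpy(dtype=float)
        vals = vals.reshape(raw.shape)
        bad = np.isnan(vals) & ~missing
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"non-numeric cell {raw[i, j]!r} at domain {domain!r}, "
                f"item {item_ids[i]!r}, participant {pids[j]!r}"
            )
        vals[missing] = np.nan
        if isinstance(scales, str):
            scale = scales
        elif scales is not None and domain in scales:
            scale = scales[domain]
        else:
            scale = directive_scales.get(domain, RAW_MONETARY)
        matrices.append(RatingMatrix(vals, item_ids, pids, domain, scale))
    return matrices


def write_cohort(cohort: Cohort, path: str | Path) -> None:
    pd.DataFrame({"participant_id": cohort.participant_ids,
                  "gender": cohort.gender}).to_csv(path, index=False)


def read_cohort(path: str | Path) -> Cohort:
    df = pd.read_csv(path, dtype=str)
    if not {"participant_id", "gender"} <= set(df.columns):
        raise ValueError("participants file needs columns participant_id,gender")
    return Cohort(list(df["participant_id"]), list(df["gender"]))


# ---------------------------------------------------------------------------
# Transforms


def orient_preferences(rm: RatingMatrix, higher_is_better: bool) -> RatingMatrix:
    """Flip response sign so that larger always means more preferred.

    Rank tasks encode rank 1 as the most preferred item, so they are read in
    with ``higher_is_better=False``; monetary valuations pass through.
    """
    if rm.scale not in RAW_SCALES:
        raise ValueError("orient_preferences expects a raw-scale matrix")
    if higher_is_better:
        return rm.copy()
    return replace(rm, values=-rm.values)


def zscore_normalize(rm: RatingMatrix, log10_monetary: bool = False) -> RatingMatrix:
    """Z-score each participant column within the domain (population SD).

    Missing entries are preserved and excluded from the column statistics.
    ``log10_monetary`` optionally applies a log10 pre-transform to monetary
    responses whose scale spans several orders of magnitude.
    """
    vals = rm.values.copy()
    if log10_monetary:
        if rm.scale != RAW_MONETARY:
            raise ValueError("log10 pre-transform only applies to monetary scales")
        if np.nanmin(vals) <= 0:
            raise ValueError("log10 pre-transform requires positive responses")
        vals = np.log10(vals)
    out = np.full_like(vals, np.nan)
    for j, pid in enumerate(rm.participant_ids):
        col = vals[:, j]
        obs = ~np.isnan(col)
        if obs.sum() == 0:
            raise ValueError(f"participant {pid!r}: all responses missing in {rm.domain!r}")
        if obs.sum() < 2:
            raise ValueError(f"participant {pid!r}: fewer than 2 responses in {rm.domain!r}")
        mu = col[obs].mean()
        sd = col[obs].std()  # population SD
        if sd == 0:
            raise ValueError(f"participant {pid!r}: zero response spread in {rm.domain!r}")
        out[obs, j] = (col[obs] - mu) / sd
    return replace(rm, values=out, scale=NORMALIZED)


def split_items(rm: RatingMatrix, fraction: float, seed: int) -> SplitIndex:
    """Uniform random item-level split, identical across participants.

    ``fraction`` is the test share; ``|test| = round(fraction * m)``.
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must lie in (0, 1)")
    m = rm.n_items
    if m < 4:
        raise ValueError("need at least 4 items to split")
    n_test = int(round(fraction * m))
    if n_test == 0 or n_test == m:
        raise ValueError(f"fraction {fraction} yields an empty train or test side")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(m)
    test_pos = np.sort(perm[:n_test])
    train_pos = np.sort(perm[n_test:])
    return SplitIndex(train_items=[rm.item_ids[i] for i in train_pos],
                      test_items=[rm.item_ids[i] for i in test_pos],
                      seed=seed, fraction=fraction)


def concat_domains(matrices: Sequence[RatingMatrix], domain: str) -> RatingMatrix:
    """Stack domains item-wise into one matrix (e.g. male + female faces)."""
    pids = matrices[0].participant_ids
    scale = matrices[0].scale
    for rm in matrices[1:]:
        if rm.participant_ids != pids:
            raise ValueError("domains must share participant ids to concatenate")
        if rm.scale != scale:
            raise ValueError("domains must share the scale tag to concatenate")
    values = np.vstack([rm.values for rm in matrices])
    item_ids = [f"{rm.domain}:{iid}" for rm in matrices for iid in rm.item_ids]
    return RatingMatrix(values, item_ids, pids, domain, scale,
                        check_normalized=False)
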