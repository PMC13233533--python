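"""End-to-end study orchestration: within/cross-domain conditions, permutation
validation, cohort-size ablation, and gender-stratified comparisons.

The canonical pipeline for one (source, target) condition is

    orient raw scales -> z-score normalize -> 75/25 item split
    -> (beta, lam) grid search on the source training items
    -> SLIM fit -> predict the target domain's test items -> evaluate.

``"face"`` as a source or target label means the concatenation of the
male- and female-face subdomains.  All randomness descends from a single
master seed so that a full study re-runs bit-identically.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from . import cf_predict, core_data, evaluation, similarity, synthetic_data
from .cf_predict import (GridSearchResult, SlimWeights, fit_slim, grid_search,
                         predict_neighborhood, predict_slim)
from .core_data import Cohort, RatingMatrix, concat_domains, orient_preferences, split_items, zscore_normalize
from .evaluation import EvaluationReport, PairedTestResult, PermutationResult, evaluate, fisher_z, paired_ttest, permutation_test
from .synthetic_data import SyntheticConfig, generate_cohort

logger = logging.getLogger("xdomcf")

FACE = "face"
FACE_SUBDOMAINS = ("face_male", "face_female")

#: Reduced default grids for multi-cohort study runs (the full decade grids
#: remain the defaults of :func:`xdomcf.cf_predict.grid_search`).
STUDY_BETA_GRID: tuple[float, ...] = (1e-2, 1.0, 1e2, 1e4)
STUDY_LAM_GRID: tuple[float, ...] = (1e-3, 1e-2, 1e-1)


@dataclass
class StudyConfig:
    """All knobs for one full study run."""

    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    domains: tuple[str, ...] = ("art", "face_male", "face_female", "scene")
    split_fraction: float = 0.25
    beta_grid: tuple[float, ...] = STUDY_BETA_GRID
    lam_grid: tuple[float, ...] = STUDY_LAM_GRID
    grid_repeats: int = 3
    grid_metric: str = "fisher_r"
    permutation_B: int = 1000
    ablation_sizes: tuple[int, ...] = (5, 10, 20, 30)
    ablation_repeats: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.split_fraction < 1:
            raise ValueError("split_fraction must lie in (0, 1)")
        if any(s > self.synthetic.n_participants for s in self.ablation_sizes):
            raise ValueError("ablation sizes must not exceed the cohort size")
        if any(s < 3 for s in self.ablation_sizes):
            raise ValueError("ablation sizes must be >= 3")

    def subseed(self, *tags: object) -> int:
        """Deterministic child seed below 2**31 derived from the master seed."""
        h = hashlib.sha256(("|".join(map(str, (self.seed,) + tags))).encode())
        return int.from_bytes(h.digest()[:4], "big") % (2 ** 31)


@dataclass
class ConditionResult:
    report: EvaluationReport
    grid: GridSearchResult | None = None
    permutation: PermutationResult | None = None
    provenance: dict = field(default_factory=dict)


def prepare_normalized(ratings: Sequence[RatingMatrix],
                       log10_monetary: bool = True) -> dict[str, RatingMatrix]:
    """Orient raw scales (rank 1 = best -> negate) and z-score per participant.

    Monetary valuations span several orders of magnitude, so they are
    log10-transformed before normalization by default; otherwise a handful
    of extreme prices dominates every participant's z-scored column and the
    multiplicative response scale leaks spurious consensus into Pearson
    correlations.
    """
    out: dict[str, RatingMatrix] = {}
    for rm in ratings:
        oriented = orient_preferences(rm, higher_is_better=(rm.scale != core_data.RAW_RANK))
        log_it = log10_monetary and rm.scale == core_data.RAW_MONETARY
        out[rm.domain] = zscore_normalize(oriented, log10_monetary=log_it)
    return out


def _domain_matrix(norm: Mapping[str, RatingMatrix], label: str) -> RatingMatrix:
    if label == FACE:
        return concat_domains([norm[d] for d in FACE_SUBDOMAINS], FACE)
    return norm[label]


def run_condition(source: str, target: str, cfg: StudyConfig,
                  norm: Mapping[str, RatingMatrix]) -> ConditionResult:
    """One within- or cross-domain SLIM condition on normalized ratings.

    The target domain's items are 75/25 split; the model is fit (with grid
    search) on the source domain's *training* items and scored on the
    target domain's *test* items.  For ``source == target`` that is the
    within-domain condition on a single split.
    """
    A_src = _domain_matrix(norm, source)
    A_tgt = _domain_matrix(norm, target)
    tgt_split = split_items(A_tgt, cfg.split_fraction, cfg.subseed("split", target))
    if source == target:
        fit_matrix = A_src.subset_items(tgt_split.train_items)
    else:
        src_split = split_items(A_src, cfg.split_fraction, cfg.subseed("split", source))
        fit_matrix = A_src.subset_items(src_split.train_items)
    gs = grid_search(fit_matrix, cfg.beta_grid, cfg.lam_grid,
                     repeats=cfg.grid_repeats, seed=cfg.subseed("grid", source, target),
                     metric=cfg.grid_metric)
    assert gs.weights is not None
    W = replace(gs.weights, source_domain=source)
    pred = predict_slim(W, A_tgt, tgt_split.test_items)
    report = evaluate(pred, A_tgt)
    report.condition.update({"source_domain": source, "target_domain": target})
    prov = {"source": source, "target": target, "seed": cfg.seed,
            "split_seed": tgt_split.seed, "grid_seed": gs.seed,
            "beta": gs.best_beta, "lam": gs.best_lam}
    return ConditionResult(report=report, grid=gs, provenance=prov)


def run_neighborhood_condition(source: str, target: str,
                               norm: Mapping[str, RatingMatrix]) -> ConditionResult:
    """Cross-domain transfer via the neighborhood CF formula.

    Inter-subject Pearson similarities estimated in the source domain weight
    peers' target-domain responses; no model is fit on the target domain, so
    all target items are predicted.  Unlike SLIM, the signed similarities
    let anti-correlated peers contribute, which makes this estimator far
    more sensitive when the shared-trait signal is weak.
    """
    from .similarity import pairwise_similarity

    A_src = _domain_matrix(norm, source)
    A_tgt = _domain_matrix(norm, target)
    sim = pairwise_similarity(A_src)
    pred = predict_neighborhood(sim, A_tgt, A_tgt.item_ids)
    report = evaluate(pred, A_tgt)
    report.condition.update({"source_domain": source, "target_domain": target,
                             "predictor": "neighborhood"})
    return ConditionResult(report=report,
                           provenance={"source": source, "target": target,
                                       "predictor": "neighborhood"})


def run_permutation_condition(source: str, target: str, cfg: StudyConfig,
                              norm: Mapping[str, RatingMatrix],
                              beta: float | None = None, lam: float | None = None,
                              add_one: bool = False) -> ConditionResult:
    """Permutation validation: fit on all source items, test on all target items."""
    A_src = _domain_matrix(norm, source)
    A_tgt = _domain_matrix(norm, target)
    if beta is None or lam is None:
        gs = grid_search(A_src, cfg.beta_grid, cfg.lam_grid, repeats=cfg.grid_repeats,
                         seed=cfg.subseed("permgrid", source, target),
                         metric=cfg.grid_metric)
        beta, lam = gs.best_beta, gs.best_lam
        W = replace(gs.weights, source_domain=source)
    else:
        gs = None
        W = replace(fit_slim(A_src, beta, lam), source_domain=source)
    perm = permutation_test(W, A_tgt, B=cfg.permutation_B,
                            seed=cfg.subseed("perm", source, target), add_one=add_one)
    pred = predict_slim(W, A_tgt, A_tgt.item_ids)
    report = evaluate(pred, A_tgt)
    report.condition.update({"source_domain": source, "target_domain": target,
                             "protocol": "permutation_all_items"})
    return ConditionResult(report=report, grid=gs, permutation=perm,
                           provenance={"source": source, "target": target,
                                       "beta": beta, "lam": lam, "B": cfg.permutation_B})


def run_ablation(cfg: StudyConfig, norm: Mapping[str, RatingMatrix],
                 source: str = FACE, target: str = "art",
                 sizes: Sequence[int] | None = None,
                 repeats: int | None = None) -> list[dict]:
    """Cross-domain accuracy as a function of cohort size.

    For each size, ``repeats`` seeded participant subsamples are drawn and
    the (source -> target) condition re-run within the subsample; rows of
    (size, mean group r, SD) come back in size order.
    """
    sizes = list(sizes if sizes is not None else cfg.ablation_sizes)
    repeats = repeats if repeats is not None else cfg.ablation_repeats
    pids = _domain_matrix(norm, target).participant_ids
    if any(s > len(pids) for s in sizes):
        raise ValueError("ablation size exceeds the cohort size")
    rows = []
    for size in sizes:
        scores = []
        for rep in range(repeats):
            rng = np.random.default_rng(cfg.subseed("ablation", size, rep))
            if size == len(pids) and repeats == 1:
                subset = list(pids)
            else:
                subset = [pids[i] for i in np.sort(rng.choice(len(pids), size, replace=False))]
            sub_norm = {d: rm.subset_participants(subset) for d, rm in norm.items()}
            res = run_condition(source, target, cfg, sub_norm)
            scores.append(res.report.group_r)
        rows.append({"size": size, "mean_group_r": float(np.mean(scores)),
                     "sd_group_r": float(np.std(scores, ddof=1)) if len(scores) > 1 else 0.0,
                     "repeats": repeats})
    return rows


def run_gender_conditions(cfg: StudyConfig, norm: Mapping[str, RatingMatrix],
                          cohort: Cohort, targets: Sequence[str] = ("art", "scene"),
                          ) -> dict:
    """Gender-stratified transfer: same- vs opposite-gender face training sets.

    Four training regimes — {male, female participants} x {own-gender,
    opposite-gender face subset} — each scored on every target domain.
    Weights are fit on the *full cohort's* responses to the designated face
    subset; evaluation is restricted to the participant group.  Same- vs
    opposite-gender comparisons are paired t-tests on Fisher-transformed
    per-participant correlations and on per-participant MSE.
    """
    face_of = {"male": "face_male", "female": "face_female"}
    groups = {"male": cohort.ids_of("male"), "female": cohort.ids_of("female")}
    for g, ids in groups.items():
        if len(ids) < 3:
            raise ValueError(f"gender group {g!r} has fewer than 3 participants")
    rows: dict[tuple[str, str, str], EvaluationReport] = {}
    weights: dict[str, SlimWeights] = {}
    for subdomain in FACE_SUBDOMAINS:
        gs = grid_search(norm[subdomain], cfg.beta_grid, cfg.lam_grid,
                         repeats=cfg.grid_repeats,
                         seed=cfg.subseed("gender_grid", subdomain),
                         metric=cfg.grid_metric)
        assert gs.weights is not None
        weights[subdomain] = gs.weights
    for group, ids in groups.items():
        for condition in ("same", "opposite"):
            own = face_of[group]
            train = own if condition == "same" else face_of["male" if group == "female" else "female"]
            W = weights[train]
            for target in targets:
                A_tgt = _domain_matrix(norm, target)
                tgt_split = split_items(A_tgt, cfg.split_fraction,
                                        cfg.subseed("split", target))
                pred = predict_slim(W, A_tgt, tgt_split.test_items)
                report = evaluate(pred, A_tgt)
                # restrict the report to the participant group
                pos = {p: i for i, p in enumerate(A_tgt.participant_ids)}
                idx = np.array([pos[p] for p in ids])
                rs = report.per_participant_r[idx]
                pm = report.per_participant_mse[idx]
                rows[(group, condition, target)] = EvaluationReport(
                    per_participant_r=rs,
                    group_r=evaluation.group_correlation(rs),
                    mse=float(np.nanmean(pm)),
                    condition={"participant_group": group, "condition": condition,
                               "train_faces": train, "target_domain": target},
                    n_items_tested=len(tgt_split.test_items),
                    participant_ids=ids, per_participant_mse=pm)
    tests: dict[tuple[str, str, str], PairedTestResult] = {}
    for group in groups:
        for target in targets:
            same = rows[(group, "same", target)]
            opp = rows[(group, "opposite", target)]
            ok = np.isfinite(same.per_participant_r) & np.isfinite(opp.per_participant_r)
            tests[(group, target, "r")] = paired_ttest(
                fisher_z(same.per_participant_r[ok]), fisher_z(opp.per_participant_r[ok]))
            tests[(group, target, "mse")] = paired_ttest(
                same.per_participant_mse[ok], opp.per_participant_mse[ok])
    return {"reports": rows, "paired_tests": tests}


# ---------------------------------------------------------------------------
# Full study


def _json_default(o):
    if isinstance(o, np.ndarray):
        return [None if not np.isfinite(x) else float(x) for x in o.ravel()]
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    raise TypeError(f"not JSON serializable: {type(o)}")


def _dump(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=1, sort_keys=True, default=_json_default,
                               allow_nan=False) + "\n", encoding="utf-8")


def _report_dict(res: ConditionResult) -> dict:
    d = {"report": res.report.to_dict(), "provenance": res.provenance}
    if res.grid is not None:
        d["grid"] = {"best_beta": res.grid.best_beta, "best_lam": res.grid.best_lam,
                     "seed": res.grid.seed, "score_table": res.grid.score_table}
    if res.permutation is not None:
        pm = res.permutation
        d["permutation"] = {"observed": pm.observed, "p_value": pm.p_value,
                            "B": pm.B, "seed": pm.seed, "scheme": pm.scheme,
                            "null_mean": float(pm.null_distribution.mean()),
                            "null_sd": float(pm.null_distribution.std())}
    return d


def run_full_study(cfg: StudyConfig, outdir: str | Path,
                   conditions: Sequence[tuple[str, str]] = (
                       ("art", "art"), (FACE, "art"), (FACE, FACE), ("art", FACE)),
                   permutation_conditions: Sequence[tuple[str, str]] = ((FACE, "art"),),
                   with_gender: bool = True, with_ablation: bool = True,
                   ) -> dict:
    """Simulate a cohort and execute every analysis stage, writing artifacts.

    Outputs (CSV/JSON under ``outdir``) are a deterministic function of the
    config; a manifest lists every file with its producing stage.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: list[dict] = []

    def record(name: str, stage: str) -> Path:
        manifest.append({"file": name, "stage": stage})
        return outdir / name

    syn = replace(cfg.synthetic, seed=cfg.subseed("cohort"))
    ratings, cohort, _truth = generate_cohort(syn)
    core_data.write_ratings(ratings, record("ratings.csv", "simulate"))
    core_data.write_cohort(cohort, record("participants.csv", "simulate"))

    norm = prepare_normalized(ratings)
    sims = [similarity.pairwise_similarity(norm[d]) for d in cfg.domains]
    for sm in sims:
        sm.to_csv(record(f"similarity_{sm.domain}.csv", "similarity"))
    inter = similarity.inter_domain_matrix(sims)
    inter.to_csv(record("inter_domain.csv", "similarity"))
    bundle: dict = {
        "config_hash": hashlib.sha256(
            json.dumps(asdict(cfg), sort_keys=True, default=str).encode()).hexdigest(),
        "mean_similarity": {sm.domain: similarity.mean_similarity(sm) for sm in sims},
        "inter_domain_mean_offdiag": inter.mean_offdiagonal(),
        "conditions": {}, "permutations": {},
    }

    for source, target in conditions:
        res = run_condition(source, target, cfg, norm)
        key = f"{source}_to_{target}"
        bundle["conditions"][key] = _report_dict(res)
        logger.info("condition %s: group_r=%.3f mse=%.3f", key,
                    res.report.group_r, res.report.mse)
    for source, target in permutation_conditions:
        res = run_permutation_condition(source, target, cfg, norm)
        key = f"{source}_to_{target}"
        bundle["permutations"][key] = _report_dict(res)
    if with_ablation:
        sizes = [s for s in cfg.ablation_sizes] + [cfg.synthetic.n_participants]
        bundle["ablation"] = run_ablation(cfg, norm, sizes=sizes)
    if with_gender:
        g = run_gender_conditions(cfg, norm, cohort)
        bundle["gender"] = {
            "reports": {"/".join(k): v.to_dict() for k, v in g["reports"].items()},
            "paired_tests": {"/".join(k): asdict(v) for k, v in g["paired_tests"].items()},
        }
    _dump(bundle, record("study.json", "report"))
    _dump({"files": manifest, "master_seed": cfg.seed}, outdir / "manifest.json")
    return bundle
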