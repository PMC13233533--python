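import json
from pathlib import Path

import numpy as np
import pytest

from xdomcf import (StudyConfig, SyntheticConfig, generate_cohort,
                    prepare_normalized, run_ablation, run_condition,
                    run_full_study, run_gender_conditions)


@pytest.fixture(scope="module")
def small_study():
    syn = SyntheticConfig(
        n_participants=12, n_male=5,
        items_per_domain={"art": 80, "face_male": 40, "face_female": 40,
                          "scene": 80},
        rank_block=40, seed=0)
    cfg = StudyConfig(synthetic=syn, seed=99, grid_repeats=2,
                      beta_grid=(1e-2, 1.0), lam_grid=(1e-3, 1e-1),
                      permutation_B=100, ablation_sizes=(5, 8),
                      ablation_repeats=2)
    ratings, cohort, truth = generate_cohort(syn)
    return cfg, prepare_normalized(ratings), cohort


class TestRunCondition:
    def test_reports_condition_labels(self, small_study):
        cfg, norm, _ = small_study
        res = run_condition("face", "art", cfg, norm)
        assert res.report.condition["source_domain"] == "face"
        assert res.report.condition["target_domain"] == "art"
        assert res.grid is not None
        assert -1 <= res.report.group_r <= 1

    def test_swapped_labels_run_symmetrically(self, small_study):
        cfg, norm, _ = small_study
        res = run_condition("art", "face", cfg, norm)
        assert res.report.condition["source_domain"] == "art"
        assert res.report.condition["target_domain"] == "face"

    def test_within_domain_uses_item_split(self, small_study):
        cfg, norm, _ = small_study
        res = run_condition("art", "art", cfg, norm)
        # 25% of 80 art items are held out
        assert res.report.n_items_tested == 20


class TestAblation:
    def test_degenerate_ablation_reproduces_condition(self, small_study):
        cfg, norm, _ = small_study
        rows = run_ablation(cfg, norm, sizes=[12], repeats=1)
        direct = run_condition("face", "art", cfg, norm)
        assert rows[0]["mean_group_r"] == pytest.approx(direct.report.group_r)

    def test_oversized_request_rejected(self, small_study):
        cfg, norm, _ = small_study
        with pytest.raises(ValueError):
            run_ablation(cfg, norm, sizes=[40], repeats=1)

    def test_row_per_size(self, small_study):
        cfg, norm, _ = small_study
        rows = run_ablation(cfg, norm, sizes=[5, 8], repeats=2)
        assert [r["size"] for r in rows] == [5, 8]
        assert all(r["repeats"] == 2 for r in rows)


class TestGenderConditions:
    def test_table_cross_product(self, small_study):
        cfg, norm, cohort = small_study
        out = run_gender_conditions(cfg, norm, cohort)
        assert len(out["reports"]) == 8  # 2 groups x 2 conditions x 2 targets
        keys = {(g, c, t) for (g, c, t) in out["reports"]}
        assert keys == {(g, c, t) for g in ("male", "female")
                        for c in ("same", "opposite") for t in ("art", "scene")}
        assert len(out["paired_tests"]) == 8  # 2 groups x 2 targets x {r, mse}

    def test_reports_restricted_to_group(self, small_study):
        cfg, norm, cohort = small_study
        out = run_gender_conditions(cfg, norm, cohort)
        male_rep = out["reports"][("male", "same", "art")]
        assert len(male_rep.per_participant_r) == 5

    def test_tiny_group_rejected(self, small_study):
        cfg, norm, _ = small_study
        from xdomcf import Cohort
        lopsided = Cohort([f"p{k + 1:02d}" for k in range(12)],
                          ["male"] * 2 + ["female"] * 10)
        with pytest.raises(ValueError, match="male"):
            run_gender_conditions(cfg, norm, lopsided)


def _gender_cohort_cfg(seed, attraction):
    syn = SyntheticConfig(
        n_participants=20, n_male=10, consistency=0.7, gender_strength=0.0,
        opposite_gender_attraction=attraction, noise_sd=0.3,
        items_per_domain={"art": 120, "face_male": 60, "face_female": 60,
                          "scene": 120}, rank_block=60, seed=seed)
    return StudyConfig(synthetic=syn, seed=seed, beta_grid=(1e-2, 1.0),
                       lam_grid=(1e-3, 1e-1), grid_repeats=2,
                       ablation_sizes=(5, 10))


class TestGenderModulation:
    def test_attraction_gives_same_gender_advantage(self):
        """When opposite-gender face ratings are dominated by a shared
        attractiveness consensus, training on own-gender faces transfers
        better (higher group correlation) for both groups."""
        diffs = []
        for seed in range(8):
            cfg = _gender_cohort_cfg(300 + seed, attraction=0.7)
            ratings, cohort, _ = generate_cohort(cfg.synthetic)
            out = run_gender_conditions(cfg, prepare_normalized(ratings), cohort)
            for group in ("male", "female"):
                for target in ("art", "scene"):
                    same = out["reports"][(group, "same", target)].group_r
                    opp = out["reports"][(group, "opposite", target)].group_r
                    diffs.append(np.arctanh(same) - np.arctanh(opp))
        assert np.mean(diffs) > 0

    def test_symmetric_cohorts_give_uniform_paired_pvalues(self):
        """Without gender modulation the same/opposite contrast is exactly
        exchangeable, so the paired-test p-values are uniform."""
        ps = []
        for seed in range(40):
            cfg = _gender_cohort_cfg(600 + seed, attraction=0.0)
            ratings, cohort, _ = generate_cohort(cfg.synthetic)
            out = run_gender_conditions(cfg, prepare_normalized(ratings), cohort)
            ps.append(out["paired_tests"][("female", "art", "r")].p_two_tailed)
        from scipy import stats
        assert stats.kstest(ps, "uniform").pvalue > 0.01


class TestFullStudy:
    def test_study_runs_and_manifest_lists_outputs(self, small_study, tmp_path):
        cfg, _, _ = small_study
        bundle = run_full_study(cfg, tmp_path / "study", with_gender=False,
                                with_ablation=False,
                                permutation_conditions=())
        manifest = json.loads((tmp_path / "study" / "manifest.json").read_text())
        files = {f["file"] for f in manifest["files"]}
        assert {"ratings.csv", "participants.csv", "inter_domain.csv",
                "study.json"} <= files
        for f in files:
            assert (tmp_path / "study" / f).exists()
        assert set(bundle["conditions"]) == {"art_to_art", "face_to_art",
                                             "face_to_face", "art_to_face"}

    def test_same_master_seed_is_byte_identical(self, small_study, tmp_path):
        cfg, _, _ = small_study
        run_full_study(cfg, tmp_path / "a", with_gender=False,
                       with_ablation=False, permutation_conditions=())
        run_full_study(cfg, tmp_path / "b", with_gender=False,
                       with_ablation=False, permutation_conditions=())
        for f in sorted((tmp_path / "a").iterdir()):
            assert f.read_bytes() == (tmp_path / "b" / f.name).read_bytes(), f.name
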