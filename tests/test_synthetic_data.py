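import numpy as np
import pytest
from scipy import stats

from xdomcf import (SyntheticConfig, generate_cohort,
                    generate_feature_linked_cohort, pairwise_similarity,
                    prepare_normalized, mean_similarity)
from xdomcf.similarity import lower_triangle
from xdomcf.synthetic_data import monetary_transform, rank_transform


class TestConfig:
    def test_defaults_match_study_design(self):
        cfg = SyntheticConfig()
        assert cfg.n_participants == 37 and cfg.n_male == 9
        assert cfg.items_per_domain == {"art": 400, "face_male": 80,
                                        "face_female": 80, "scene": 400}

    @pytest.mark.parametrize("kwargs", [
        {"consistency": 1.1},
        {"consistency": 0.9, "gender_strength": 0.9},
        {"noise_sd": -1.0},
        {"n_male": 40},
        {"items_per_domain": {"art": 100, "face_male": 81, "face_female": 80,
                              "scene": 400}},  # block must divide
    ])
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SyntheticConfig(**kwargs)


class TestShapes:
    def test_default_shapes(self):
        ratings, cohort, truth = generate_cohort(SyntheticConfig(seed=1))
        shapes = {rm.domain: rm.values.shape for rm in ratings}
        assert shapes == {"art": (400, 37), "face_male": (80, 37),
                          "face_female": (80, 37), "scene": (400, 37)}
        assert cohort.gender.count("male") == 9

    def test_seed_contract_byte_identical(self, small_cfg):
        a = generate_cohort(small_cfg)
        b = generate_cohort(small_cfg)
        for rma, rmb in zip(a[0], b[0]):
            np.testing.assert_array_equal(rma.values, rmb.values)
        np.testing.assert_array_equal(a[2].participant_traits,
                                      b[2].participant_traits)


class TestRawTransforms:
    def test_monetary_range_and_median(self):
        ratings, _, _ = generate_cohort(SyntheticConfig(seed=2))
        art = next(rm for rm in ratings if rm.domain == "art")
        assert art.values.min() >= 100 and art.values.max() <= 1e7
        med = np.median(art.values, axis=0)
        np.testing.assert_allclose(med, 1e4, rtol=0.05)

    def test_rank_blocks_are_permutations(self):
        ratings, _, _ = generate_cohort(SyntheticConfig(seed=3))
        scene = next(rm for rm in ratings if rm.domain == "scene")
        for start in range(0, 400, 80):
            block = scene.values[start:start + 80]
            for j in range(block.shape[1]):
                assert sorted(block[:, j]) == list(range(1, 81))

    def test_rank_is_monotone_in_latent(self, rng):
        latent = rng.standard_normal((80, 5))
        ranks = rank_transform(latent, 80)
        for j in range(5):
            rho = stats.spearmanr(latent[:, j], -ranks[:, j]).statistic
            assert rho == pytest.approx(1.0)

    def test_monetary_is_monotone_in_latent(self, rng):
        latent = rng.standard_normal((60, 3))
        money = monetary_transform(latent)
        for j in range(3):
            order = np.argsort(latent[:, j])
            assert np.all(np.diff(money[order, j]) >= 0)


class TestLatentStructure:
    def test_full_consistency_preserves_similarity_structure(self):
        # 400 items per domain: with only 80 face items, estimator noise in
        # the pairwise similarities attenuates the second-order correlation
        # to ~0.92 even under identical traits
        cfg = SyntheticConfig(consistency=1.0, gender_strength=0.0, noise_sd=0.0,
                              items_per_domain={"art": 400, "face_male": 400,
                                                "face_female": 400, "scene": 400},
                              seed=4)
        ratings, _, truth = generate_cohort(cfg)
        norm = prepare_normalized(ratings)
        from xdomcf import inter_domain_matrix
        sms = [pairwise_similarity(norm[d]) for d in cfg.items_per_domain]
        inter = inter_domain_matrix(sms)
        off = inter.values[~np.eye(4, dtype=bool)]
        assert off.min() >= 0.95

    def test_pipeline_recovers_latent_similarity(self):
        cfg = SyntheticConfig(noise_sd=0.0, seed=5)
        ratings, _, truth = generate_cohort(cfg)
        norm = prepare_normalized(ratings)
        for rm in ratings:
            obs = pairwise_similarity(norm[rm.domain])
            lat = np.corrcoef(truth.latent_responses[rm.domain].T)
            v_obs = lower_triangle(obs)
            i, j = np.tril_indices(cfg.n_participants, k=-1)
            r = np.corrcoef(v_obs, lat[i, j])[0, 1]
            assert r >= 0.9, rm.domain

    def test_gender_motif_within_exceeds_between(self):
        deltas = []
        for seed in range(20):
            cfg = SyntheticConfig(
                n_participants=16, n_male=8, gender_strength=0.5, consistency=0.5,
                items_per_domain={"art": 60, "face_male": 30, "face_female": 30,
                                  "scene": 60}, rank_block=30, seed=seed)
            ratings, cohort, _ = generate_cohort(cfg)
            norm = prepare_normalized(ratings)
            for d in cfg.items_per_domain:
                S = pairwise_similarity(norm[d]).values
                male = np.array([g == "male" for g in cohort.gender])
                same = np.concatenate([
                    S[np.ix_(male, male)][np.tril_indices(male.sum(), -1)],
                    S[np.ix_(~male, ~male)][np.tril_indices((~male).sum(), -1)]])
                between = S[np.ix_(male, ~male)].ravel()
                deltas.append(same.mean() - between.mean())
        assert np.mean(deltas) > 0
        assert np.mean(np.array(deltas) > 0) > 0.9


class TestFeatureLinkedCohort:
    def test_disjoint_maps_share_participant_structure(self):
        ratings, features, truth = generate_feature_linked_cohort(
            n_participants=20, items_per_domain={"a": 150, "b": 150},
            shared_map=False, seed=6)
        norm = prepare_normalized(ratings, log10_monetary=False)
        sims = [pairwise_similarity(norm[d]).values for d in ("a", "b")]
        i, j = np.tril_indices(20, k=-1)
        r = np.corrcoef(sims[0][i, j], sims[1][i, j])[0, 1]
        assert r > 0.8  # same traits -> same inter-subject structure

    def test_feature_shapes(self):
        ratings, features, truth = generate_feature_linked_cohort(
            n_participants=10, items_per_domain={"a": 40, "b": 60},
            n_features=25, seed=7)
        assert features["a"].shape == (40, 25)
        assert features["b"].shape == (60, 25)
        assert truth["traits"].shape == (10, 8)
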