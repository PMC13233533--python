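import numpy as np
import pytest

from xdomcf import (RatingMatrix, SimilarityMatrix, SlimWeights, fit_slim,
                    grid_search, predict_neighborhood, predict_slim,
                    slim_objective, zscore_normalize)
from xdomcf.core_data import NORMALIZED

from _oracles import pg_slim_column, column_objective, kkt_residual


def _norm_rm(vals, domain="art"):
    vals = np.asarray(vals, dtype=float)
    return RatingMatrix(vals, [f"i{k}" for k in range(vals.shape[0])],
                        [f"p{k}" for k in range(vals.shape[1])], domain,
                        NORMALIZED, check_normalized=False)


class TestNeighborhood:
    def _setup(self, sims, centered):
        """3 participants: p0 is predicted from peers p1, p2."""
        n = len(sims) + 1
        S = np.eye(n)
        for k, s in enumerate(sims, start=1):
            S[0, k] = S[k, 0] = s
        sm = SimilarityMatrix(S, [f"p{k}" for k in range(n)], "art")
        vals = np.zeros((1, n))
        vals[0, 1:] = centered
        vals[0, 0] = np.nan       # the predicted response is unobserved
        rm = _norm_rm(vals)
        return sm, rm

    def test_opposing_peers_cancel(self):
        sm, rm = self._setup([0.5, -0.5], [1.0, 1.0])
        pred = predict_neighborhood(sm, rm, rm.item_ids)
        assert pred.predicted[0, 0] == pytest.approx(0.0)

    def test_single_peer_identity_weight(self):
        sm, rm = self._setup([1.0], [2.0])
        pred = predict_neighborhood(sm, rm, rm.item_ids)
        assert pred.predicted[0, 0] == pytest.approx(2.0)

    def test_zero_similarity_falls_back_to_mean(self):
        sm, rm = self._setup([0.0, 0.0], [1.0, 2.0])
        pred = predict_neighborhood(sm, rm, rm.item_ids)
        assert pred.predicted[0, 0] == pytest.approx(0.0)  # normalized mean

    def test_uniform_sims_equal_peer_average(self, rng):
        n, m = 6, 10
        S = np.full((n, n), 0.5)
        np.fill_diagonal(S, 1.0)
        sm = SimilarityMatrix(S, [f"p{k}" for k in range(n)], "art")
        vals = rng.standard_normal((m, n))
        vals -= vals.mean(axis=0)  # centered so rbar = 0
        rm = _norm_rm(vals)
        pred = predict_neighborhood(sm, rm, rm.item_ids)
        for u in range(n):
            peers = [v for v in range(n) if v != u]
            np.testing.assert_allclose(pred.predicted[:, u],
                                       vals[:, peers].mean(axis=1), atol=1e-12)


class TestSlimObjective:
    def test_zero_weights_gives_half_frobenius(self, rng):
        A = _norm_rm(rng.standard_normal((5, 3)))
        W = SlimWeights(np.zeros((3, 3)), A.participant_ids, "art", 0.0, 0.0)
        assert slim_objective(A, W, 0.0, 0.0) == pytest.approx(
            0.5 * np.sum(A.values ** 2))

    def test_duplicated_column_scalar_expansion(self):
        # A = [a, a] with a = [1, -1]^T; W puts w at (0, 1)
        A = _norm_rm(np.array([[1.0, 1.0], [-1.0, -1.0]]))
        for w, beta, lam in [(0.3, 0.5, 0.2), (1.0, 0.0, 0.0)]:
            Wv = np.zeros((2, 2))
            Wv[0, 1] = w
            W = SlimWeights(Wv, A.participant_ids, "art", beta, lam)
            # column 1 residual: 2(1-w)^2 /2; column 0 untouched: ||a||^2/2
            expected = 0.5 * 2 * (1 - w) ** 2 + 0.5 * 2 + 0.5 * beta * w ** 2 + lam * w
            assert slim_objective(A, W, beta, lam) == pytest.approx(expected)

    def test_negative_penalty_rejected(self, rng):
        A = _norm_rm(rng.standard_normal((4, 2)))
        W = SlimWeights(np.zeros((2, 2)), A.participant_ids, "art", 0.0, 0.0)
        with pytest.raises(ValueError):
            slim_objective(A, W, -1.0, 0.0)


class TestFitSlim:
    @pytest.mark.parametrize("beta,lam", [(0.0, 0.0), (1.0, 0.0), (0.0, 0.5),
                                          (2.0, 0.5)])
    def test_duplicated_column_closed_form(self, beta, lam):
        A = _norm_rm(np.array([[1.0, 1.0], [-1.0, -1.0]]))
        W = fit_slim(A, beta, lam)
        expected = max((2.0 - lam) / (2.0 + beta), 0.0)
        assert W.values[0, 1] == pytest.approx(expected, abs=1e-6)
        assert W.values[1, 0] == pytest.approx(expected, abs=1e-6)

    def test_huge_l1_gives_zero(self, rng):
        A = _norm_rm(rng.standard_normal((8, 4)))
        W = fit_slim(A, 0.0, 1e12)
        assert np.all(W.values == 0)

    def test_constraints_hold(self, rng):
        A = _norm_rm(rng.standard_normal((10, 5)))
        for beta, lam in [(0.0, 0.0), (0.1, 0.01), (10.0, 1.0)]:
            W = fit_slim(A, beta, lam)
            assert W.values.min() >= 0
            assert np.all(np.diag(W.values) == 0)

    def test_l1_norm_monotone_in_lam(self, rng):
        A = _norm_rm(rng.standard_normal((20, 6)))
        norms = [np.abs(fit_slim(A, 1.0, lam).values).sum()
                 for lam in [1e-3, 1e-2, 1e-1, 1.0, 10.0]]
        assert all(a >= b - 1e-8 for a, b in zip(norms, norms[1:]))

    def test_matches_nnls_limit_two_participants(self, rng):
        y = rng.standard_normal(12)
        x = 0.8 * y + 0.1 * rng.standard_normal(12)
        A = _norm_rm(np.column_stack([x, y]))
        W = fit_slim(A, 0.0, 0.0)
        # closed-form nonnegative LS for a single regressor
        w01 = max(x @ y / (x @ x), 0.0)
        w10 = max(x @ y / (y @ y), 0.0)
        assert W.values[0, 1] == pytest.approx(w01, abs=1e-6)
        assert W.values[1, 0] == pytest.approx(w10, abs=1e-6)

    def test_agrees_with_projected_gradient_oracle(self, rng):
        # spot check here; the full 50-instance sweep lives in the acceptance suite
        A = _norm_rm(rng.standard_normal((9, 4)))
        for beta, lam in [(0.1, 0.1), (1.0, 0.0)]:
            W = fit_slim(A, beta, lam)
            for u in range(4):
                others = np.arange(4) != u
                B, y = A.values[:, others], A.values[:, u]
                w_ref = pg_slim_column(B, y, beta, lam, n_iter=30_000)
                f_impl = column_objective(B, y, W.values[others, u], beta, lam)
                f_ref = column_objective(B, y, w_ref, beta, lam)
                assert f_impl <= f_ref + 1e-4 * max(abs(f_ref), 1.0)
                assert kkt_residual(B, y, W.values[others, u], beta, lam) < 1e-3


class TestPredictSlim:
    def test_copy_peer(self, rng):
        vals = rng.standard_normal((6, 3))
        A = _norm_rm(vals)
        Wv = np.zeros((3, 3))
        Wv[1, 0] = 1.0  # participant 0 copies participant 1
        W = SlimWeights(Wv, A.participant_ids, "art", 0.0, 0.0)
        pred = predict_slim(W, A, A.item_ids)
        np.testing.assert_allclose(pred.predicted[:, 0], vals[:, 1], atol=1e-12)

    def test_equal_weights_average_peers(self, rng):
        vals = rng.standard_normal((5, 4))
        A = _norm_rm(vals)
        Wv = np.zeros((4, 4))
        Wv[1:, 0] = 1 / 3
        W = SlimWeights(Wv, A.participant_ids, "art", 0.0, 0.0)
        pred = predict_slim(W, A, A.item_ids)
        np.testing.assert_allclose(pred.predicted[:, 0], vals[:, 1:].mean(axis=1),
                                   atol=1e-12)

    def test_own_response_never_used(self, rng):
        """A participant's prediction is invariant to their own target ratings."""
        vals = rng.standard_normal((6, 3))
        A = _norm_rm(vals)
        W = fit_slim(A, 0.1, 0.01)
        pred = predict_slim(W, A, A.item_ids)
        vals2 = vals.copy()
        vals2[:, 0] = rng.standard_normal(6)
        pred2 = predict_slim(W, _norm_rm(vals2), A.item_ids)
        np.testing.assert_allclose(pred.predicted[:, 0], pred2.predicted[:, 0],
                                   atol=1e-12)

    def test_duplicated_column_recovered_on_held_out_items(self):
        rng = np.random.default_rng(0)
        base = rng.standard_normal(10)
        third = rng.standard_normal(10)
        A = _norm_rm(np.column_stack([base, base, third]))
        W = fit_slim(A.subset_items(A.item_ids[:6]), 0.0, 0.0)
        held_out = A.item_ids[6:]
        pred = predict_slim(W, A, held_out)
        np.testing.assert_allclose(pred.predicted[:, 0], base[6:], atol=1e-5)
        np.testing.assert_allclose(pred.predicted[:, 1], base[6:], atol=1e-5)


class TestGridSearch:
    def test_single_cell_grid(self, rng):
        A = _norm_rm(rng.standard_normal((12, 4)))
        res = grid_search(A, [0.5], [0.01], repeats=2, seed=1)
        assert (res.best_beta, res.best_lam) == (0.5, 0.01)
        assert len(res.score_table) == 1
        assert res.score_table[0]["repeats"] == 2
        assert res.weights is not None and res.weights.beta == 0.5

    def test_best_pair_attains_max_score(self, rng):
        A = _norm_rm(rng.standard_normal((16, 5)))
        res = grid_search(A, [0.1, 10.0], [1e-3, 1e-1], repeats=3, seed=2)
        best_row = max(res.score_table, key=lambda r: r["mean_score"])
        assert (res.best_beta, res.best_lam) == (best_row["beta"], best_row["lam"])

    def test_noiseless_duplicates_prefer_weak_regularization(self):
        picks = []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            base = rng.standard_normal(24)
            A = _norm_rm(np.column_stack([base, base, base]))
            res = grid_search(A, [1e-2, 1e2], [1e-3, 1e-1, 1e1], repeats=3,
                              seed=seed)
            picks.append(res.best_lam)
        assert all(lam <= 1e-1 for lam in picks)
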