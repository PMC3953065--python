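"""Plackett-Luce distributions, listwise losses, gradients and training."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from figrank.corpus import GoldRanking
from figrank.ranker import (
    FigureRanker,
    FigureRankerResults,
    RankingInstance,
    TrainerConfig,
    gold_scores,
    gradient,
    loss_top1,
    loss_top2,
    predict_ranking,
    score,
    top1_distribution,
    top2_distribution,
    train,
)

from _oracles import brute_force_pair_marginal

finite_scores = arrays(
    float,
    st.integers(min_value=2, max_value=6),
    elements=st.floats(min_value=-5, max_value=5),
)


class TestScore:
    def test_zero_weights(self):
        assert score(np.zeros(4), np.random.default_rng(0).normal(size=4)) == 0.0

    def test_unit_weight_selects_feature(self):
        w = np.zeros(3)
        w[1] = 1.0
        assert score(w, np.array([5.0, 7.0, 9.0])) == 7.0

    def test_matches_manual_sum(self):
        rng = np.random.default_rng(1)
        w, x = rng.normal(size=6), rng.normal(size=6)
        assert score(w, x) == pytest.approx(sum(a * b for a, b in zip(w, x)))

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            score(np.zeros(3), np.zeros(4))


class TestTop1:
    def test_uniform(self):
        assert top1_distribution(np.zeros(3)) == pytest.approx([1 / 3] * 3)

    def test_closed_form(self):
        p = top1_distribution(np.array([math.log(2), 0.0]))
        assert p == pytest.approx([2 / 3, 1 / 3])

    @given(finite_scores, st.floats(min_value=-50, max_value=50))
    @settings(max_examples=50, deadline=None)
    def test_shift_invariance_and_normalisation(self, z, c):
        p = top1_distribution(z)
        assert p.sum() == pytest.approx(1.0)
        assert (p > 0).all()
        assert top1_distribution(z + c) == pytest.approx(p)

    def test_overflow_safe(self):
        p = top1_distribution(np.array([1000.0, 1000.0, 0.0]))
        assert p == pytest.approx([0.5, 0.5, 0.0], abs=1e-12)


class TestTop2:
    def test_uniform_scores_give_one_sixth(self):
        P = top2_distribution(np.zeros(3))
        off = P[~np.eye(3, dtype=bool)]
        assert off == pytest.approx([1 / 6] * 6)

    def test_ratio_211_pair_probability(self):
        # exp(z) proportional to (2,1,1): P(1,2) = (2/4)*(1/2) = 0.25,
        # equal to the brute-force sum over permutations starting (1,2)
        z = np.log(np.array([2.0, 1.0, 1.0]))
        P = top2_distribution(z)
        assert P[0, 1] == pytest.approx(0.25)

    @pytest.mark.parametrize("n", [2, 3, 4, 5, 6])
    def test_matches_permutation_enumeration(self, n):
        rng = np.random.default_rng(n)
        z = rng.normal(size=n)
        P = top2_distribution(z)
        assert P.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.abs(P - brute_force_pair_marginal(z)).max() < 1e-10

    @pytest.mark.parametrize("n", [2, 3, 4, 5, 6])
    def test_first_element_marginal_equals_top1(self, n):
        z = np.random.default_rng(10 + n).normal(size=n)
        P = top2_distribution(z)
        assert P.sum(axis=1) == pytest.approx(top1_distribution(z))

    def test_single_figure_rejected(self):
        with pytest.raises(ValueError, match="top1"):
            top2_distribution(np.array([1.0]))


class TestLosses:
    def test_top1_gibbs_equality(self):
        y = np.array([1.0, 0.5, 1 / 3])
        p = top1_distribution(y)
        entropy = -(p * np.log(p)).sum()
        assert loss_top1(y, y) == pytest.approx(entropy)

    def test_top1_concentrated_vs_uniform(self):
        # target effectively concentrated on one of 2 figures, uniform scores
        y = np.array([50.0, 0.0])
        assert loss_top1(y, np.zeros(2)) == pytest.approx(math.log(2), abs=1e-9)

    @given(finite_scores)
    @settings(max_examples=50, deadline=None)
    def test_top1_gibbs_inequality(self, y):
        z = np.random.default_rng(0).normal(size=len(y))
        p = top1_distribution(y)
        entropy = -(p * np.log(p)).sum()
        assert loss_top1(y, z) >= entropy - 1e-10

    def test_top2_uniform_is_log6(self):
        assert loss_top2(np.zeros(3), np.zeros(3)) == pytest.approx(math.log(6))

    def test_top2_gibbs_equality(self):
        y = np.array([1.0, 0.5, 1 / 3, 0.25])
        P = top2_distribution(y)
        off = P[~np.eye(4, dtype=bool)]
        entropy = -(off * np.log(off)).sum()
        assert loss_top2(y, y) == pytest.approx(entropy)

    @pytest.mark.parametrize("n", [2, 3, 4, 5])
    def test_top2_matches_direct_sum(self, n):
        rng = np.random.default_rng(n)
        y, z = rng.normal(size=n), rng.normal(size=n)
        A = top2_distribution(y)
        B = top2_distribution(z)
        direct = -sum(
            A[j, k] * math.log(B[j, k])
            for j in range(n)
            for k in range(n)
            if j != k
        )
        assert loss_top2(y, z) == pytest.approx(direct, abs=1e-10)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            loss_top1(np.zeros(2), np.zeros(3))


class TestGradient:
    @pytest.mark.parametrize("mode", ["top1", "top2"])
    def test_finite_difference_agreement(self, mode):
        rng = np.random.default_rng(123)
        loss_fn = loss_top1 if mode == "top1" else loss_top2
        for _ in range(25):
            n = int(rng.integers(2, 7))
            d = int(rng.integers(1, 11))
            X = rng.normal(size=(n, d))
            y = rng.normal(size=n)
            w = rng.normal(size=d)
            g = gradient(mode, X, y, w)
            h = 1e-6
            for i in range(d):
                wp, wm = w.copy(), w.copy()
                wp[i] += h
                wm[i] -= h
                num = (loss_fn(y, X @ wp) - loss_fn(y, X @ wm)) / (2 * h)
                denom = max(1.0, abs(num))
                assert abs(g[i] - num) / denom < 1e-5

    @pytest.mark.parametrize("mode", ["top1", "top2"])
    def test_stationary_at_matching_scores(self, mode):
        # w such that z = y exactly -> gradient vanishes
        y = np.array([1.0, 0.5, 1 / 3])
        X = np.eye(3)
        g = gradient(mode, X, y, y)
        assert np.linalg.norm(g) < 1e-8

    def test_duplicated_figure_symmetry(self):
        x = np.array([0.3, -0.7])
        X = np.vstack([x, x, np.array([1.0, 1.0])])
        y = np.array([0.5, 0.5, 1.0])
        w = np.array([0.2, 0.1])
        for mode in ("top1", "top2"):
            z = X @ w
            # contributions of the duplicated pair are identical
            from figrank.ranker import _grad_z_top1, _grad_z_top2

            gz = _grad_z_top1(y, z) if mode == "top1" else _grad_z_top2(y, z)
            assert gz[0] == pytest.approx(gz[1], abs=1e-12)


class TestPredictRanking:
    def test_score_ordering(self):
        inst = RankingInstance("a", np.array([[0.9], [0.1], [0.5]]), [1, 3, 2])
        r = predict_ranking(np.array([1.0]), inst)
        assert r.system_ranks.tolist() == [1, 3, 2]

    def test_tie_break_by_position(self):
        inst = RankingInstance("a", np.zeros((4, 2)), [1, 2, 3, 4])
        r = predict_ranking(np.array([1.0, 1.0]), inst)
        assert r.system_ranks.tolist() == [1, 2, 3, 4]

    @given(st.integers(min_value=1, max_value=8), st.integers(min_value=0, max_value=10**6))
    @settings(max_examples=30, deadline=None)
    def test_always_a_permutation(self, n, seed):
        rng = np.random.default_rng(seed)
        inst = RankingInstance("a", rng.normal(size=(n, 3)), [1] * n)
        r = predict_ranking(rng.normal(size=3), inst)
        assert sorted(r.system_ranks.tolist()) == list(range(1, n + 1))


class TestGoldScores:
    @pytest.mark.parametrize(
        "ranks,expected",
        [
            ([1, 2, 3], [1.0, 0.5, 1 / 3]),
            ([1, 1], [1.0, 1.0]),
            ([2, 1, 2], [0.5, 1.0, 0.5]),
        ],
    )
    def test_reciprocal(self, ranks, expected):
        assert gold_scores(GoldRanking("a", ranks)) == pytest.approx(expected)


class TestTrain:
    def test_all_zero_features_keep_zero_weights_top1(self):
        data = [RankingInstance("a", np.zeros((3, 4)), [1, 2, 3])]
        cfg = TrainerConfig(loss_mode="top1", iterations=5, training_metric="loss")
        w, trace = train(data, cfg)
        assert np.all(w == 0.0)

    def test_loss_decreases_on_planted_data(self, tiny_dataset):
        cfg = TrainerConfig(loss_mode="top2", learning_rate=0.01, iterations=50)
        w, trace = train(tiny_dataset, cfg)
        assert trace[-1]["loss"] <= trace[0]["loss"]

    def test_bitwise_reproducible(self, tiny_dataset):
        cfg = TrainerConfig(iterations=10)
        w1, t1 = train(tiny_dataset, cfg)
        w2, t2 = train(tiny_dataset, cfg)
        assert np.array_equal(w1, w2)
        assert t1 == t2

    def test_adaptive_rate_decays_on_improvement(self, tiny_dataset):
        cfg = TrainerConfig(iterations=5, learning_rate=0.01)
        _, trace = train(tiny_dataset, cfg)
        # first iteration always counts as improvement -> decay applied
        assert trace[0]["lr"] == pytest.approx(0.01 * 0.875)

    def test_lr_floor_respected(self, tiny_dataset):
        cfg = TrainerConfig(iterations=3, learning_rate=2e-6)
        _, trace = train(tiny_dataset, cfg)
        assert all(t["lr"] >= 1e-6 * 0.875 for t in trace)

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError):
            train([], TrainerConfig())


class TestModelObjects:
    def test_fit_predict_and_summary(self, tiny_dataset):
        cfg = TrainerConfig(iterations=30, learning_rate=0.05)
        res = FigureRanker(tiny_dataset, config=cfg).fit()
        assert isinstance(res.summary(), str)
        pred = res.predict(tiny_dataset[0])
        assert sorted(pred.system_ranks.tolist()) == list(
            range(1, tiny_dataset[0].n + 1)
        )

    def test_save_load_round_trip(self, tiny_dataset, tmp_path):
        cfg = TrainerConfig(iterations=5)
        res = FigureRanker(tiny_dataset, config=cfg).fit()
        path = tmp_path / "model.json"
        res.save(path)
        loaded = FigureRankerResults.load(path)
        assert np.allclose(loaded.params, res.params)
        p1 = res.predict(tiny_dataset[0]).system_ranks
        p2 = loaded.predict(tiny_dataset[0]).system_ranks
        assert np.array_equal(p1, p2)
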