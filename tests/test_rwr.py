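"""Seed construction, column normalization, the restart walk, ranking."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from irwrlda.rwr import (
    WalkConfig,
    column_normalize,
    initial_probability,
    rank_candidates,
    score1,
    score2,
    walk,
)

from conftest import random_column_stochastic


def df(values, labels_r, labels_c=None):
    return pd.DataFrame(values, index=labels_r, columns=labels_c or labels_r)


@pytest.fixture
def small():
    """3 lncRNAs x 2 diseases with simple similarity matrices."""
    assoc = df([[1, 0], [0, 1], [0, 0]], ["a", "b", "c"], ["d1", "d2"])
    es = df([[1.0, 0.2, 0.7], [0.2, 1.0, -0.4], [0.7, -0.4, 1.0]], ["a", "b", "c"])
    ss = df([[1.0, 0.6], [0.6, 1.0]], ["d1", "d2"])
    return assoc, es, ss


class TestScores:
    def test_score1_empty_known_set_is_zero(self, small):
        assoc, es, _ = small
        assoc = assoc.copy()
        assoc["d1"] = 0
        assert score1("d1", "c", es, assoc) == 0.0

    def test_score1_is_max_over_known(self, small):
        assoc, es, _ = small
        assoc = assoc.copy()
        assoc.loc["b", "d1"] = 1  # L(d1) = {a, b}; ES(c,a)=0.7, ES(c,b)=-0.4
        assert score1("d1", "c", es, assoc) == pytest.approx(0.7)

    def test_score1_self_known(self, small):
        assoc, es, _ = small
        assert score1("d1", "a", es, assoc) == pytest.approx(1.0)

    def test_score2_empty_known_set_is_zero(self, small):
        assoc, _, ss = small
        assert score2("d1", "c", ss, assoc) == 0.0

    def test_score2_is_max_over_diseases(self, small):
        assoc, _, ss = small
        assoc = assoc.copy()
        assoc.loc["c", "d2"] = 1  # D(c) = {d2}; SS(d1,d2)=0.6
        assert score2("d1", "c", ss, assoc) == pytest.approx(0.6)

    def test_score2_known_disease_of_lncrna(self, small):
        assoc, _, ss = small
        assert score2("d2", "b", ss, assoc) == pytest.approx(1.0)


class TestInitialProbability:
    def test_all_known_gives_all_ones(self, small):
        assoc, es, ss = small
        assoc = assoc.copy()
        assoc["d1"] = 1
        p0 = initial_probability("d1", es, ss, assoc)
        assert (p0.to_numpy() == 1.0).all()

    def test_seed_from_semantic_similarity_without_known_lncrnas(self, small):
        assoc, es, ss = small
        # d1 has no known lncRNAs; b is known for d2 with SS(d1,d2)=0.6.
        assoc = assoc.copy()
        assoc["d1"] = 0
        es_zero = es * 0.0
        p0 = initial_probability("d1", es_zero, ss, assoc)
        assert p0["b"] == pytest.approx(0.6)
        assert p0["a"] == 0.0 and p0["c"] == 0.0

    def test_negative_expression_similarity_clamped_to_zero(self, small):
        assoc, es, ss = small
        # c's best ES to L(d2)={b} is -0.4; no semantic evidence.
        ss_zero = ss * 0.0
        p0 = initial_probability("d2", es, ss_zero, assoc)
        assert p0["c"] == 0.0

    def test_vectorized_matches_scalar_scores(self, rng):
        lncs = [f"l{i}" for i in range(8)]
        diss = [f"d{j}" for j in range(5)]
        assoc = df((rng.random((8, 5)) < 0.3).astype(float), lncs, diss)
        es_v = rng.uniform(-1, 1, (8, 8))
        es = df((es_v + es_v.T) / 2, lncs)
        ss_v = rng.uniform(0, 1, (5, 5))
        ss = df((ss_v + ss_v.T) / 2, diss)
        from irwrlda.rwr import score1 as s1, score2 as s2

        for d in diss:
            p0 = initial_probability(d, es, ss, assoc)
            for l in lncs:
                if assoc.loc[l, d] > 0:
                    assert p0[l] == 1.0
                else:
                    expected = min(1.0, max(0.0, max(s1(d, l, es, assoc), s2(d, l, ss, assoc))))
                    assert p0[l] == pytest.approx(expected, abs=1e-12)


class TestColumnNormalize:
    def test_simple_column(self):
        m = df([[2.0], [2.0]], ["a", "b"], ["a"])
        out = column_normalize(m)
        np.testing.assert_allclose(out.to_numpy().ravel(), [0.5, 0.5])

    def test_idempotent_on_stochastic_matrix(self, rng):
        w = df(random_column_stochastic(rng, 5), [f"l{i}" for i in range(5)])
        out = column_normalize(w)
        np.testing.assert_allclose(out.to_numpy(), w.to_numpy(), atol=1e-12)

    def test_random_nonnegative_columns_sum_to_one(self, rng):
        m = df(rng.random((5, 5)) + 0.1, [f"l{i}" for i in range(5)])
        out = column_normalize(m)
        np.testing.assert_allclose(out.to_numpy().sum(axis=0), np.ones(5), atol=1e-12)

    def test_negative_entry_names_cell(self):
        m = df([[1.0, -0.5], [0.0, 1.0]], ["a", "b"])
        with pytest.raises(ValueError, match="'a'.*'b'"):
            column_normalize(m)

    def test_zero_column_left_zero_with_warning(self):
        m = df([[1.0, 0.0], [1.0, 0.0]], ["a", "b"])
        with pytest.warns(UserWarning, match="all-zero"):
            out = column_normalize(m)
        assert (out["b"] == 0).all()


class TestWalk:
    def test_restart_one_returns_seed(self, rng):
        labels = [f"l{i}" for i in range(4)]
        w = df(random_column_stochastic(rng, 4), labels)
        p0 = pd.Series([0.2, 0.0, 0.5, 0.0], index=labels)
        state = walk(p0, w, WalkConfig(restart=1.0))
        np.testing.assert_allclose(state.p_inf.to_numpy(), p0.to_numpy(), atol=1e-15)

    def test_two_node_swap_closed_form(self):
        # W = [[0,1],[1,0]], p0 = (1,0), r = 0.5 -> p_inf = (2/3, 1/3)
        w = df([[0.0, 1.0], [1.0, 0.0]], ["a", "b"])
        p0 = pd.Series([1.0, 0.0], index=["a", "b"])
        state = walk(p0, w, WalkConfig(restart=0.5, cutoff=1e-14))
        np.testing.assert_allclose(state.p_inf.to_numpy(), [2 / 3, 1 / 3], atol=1e-12)
        assert state.converged

    def test_mass_conservation_for_stochastic_w(self, rng):
        labels = [f"l{i}" for i in range(6)]
        w = df(random_column_stochastic(rng, 6), labels)
        for r in (0.1, 0.5, 0.9, 1.0):
            p0 = pd.Series(rng.random(6), index=labels)
            state = walk(p0, w, WalkConfig(restart=r))
            assert state.p_inf.sum() == pytest.approx(p0.sum(), abs=1e-8)

    def test_iterative_matches_linear_solve(self, rng):
        cutoff = 1e-10
        for _ in range(10):
            n = int(rng.integers(2, 20))
            w = random_column_stochastic(rng, n)
            labels = [f"l{i}" for i in range(n)]
            p0 = pd.Series(rng.random(n), index=labels)
            for r in (0.1, 0.5, 0.9):
                state = walk(p0, df(w, labels), WalkConfig(restart=r, cutoff=cutoff))
                direct = r * np.linalg.solve(np.eye(n) - (1 - r) * w, p0.to_numpy())
                assert np.abs(state.p_inf.to_numpy() - direct).sum() <= 10 * cutoff

    def test_contraction_iteration_bound(self, rng):
        labels = [f"l{i}" for i in range(10)]
        w = df(random_column_stochastic(rng, 10), labels)
        p0 = pd.Series(rng.random(10), index=labels)
        cfg = WalkConfig(restart=0.7, cutoff=1e-10)
        state = walk(p0, w, cfg)
        first = (1 - 0.7) * (w.to_numpy() @ p0.to_numpy()) + 0.7 * p0.to_numpy()
        d1 = np.abs(first - p0.to_numpy()).sum()
        if d1 > 0:
            bound = int(np.ceil(np.log(cfg.cutoff / d1) / np.log(1 - 0.7))) + 1
            assert state.iterations_used <= bound

    def test_all_zero_seed_stays_zero(self, rng):
        labels = [f"l{i}" for i in range(5)]
        w = df(random_column_stochastic(rng, 5), labels)
        p0 = pd.Series(np.zeros(5), index=labels)
        state = walk(p0, w)
        assert (state.p_inf.to_numpy() == 0).all()

    def test_seed_monotonicity(self, rng):
        labels = [f"l{i}" for i in range(6)]
        w = df(random_column_stochastic(rng, 6), labels)
        p0 = pd.Series(rng.random(6), index=labels)
        base = walk(p0, w).p_inf["l2"]
        p0_up = p0.copy()
        p0_up["l2"] += 0.5
        assert walk(p0_up, w).p_inf["l2"] >= base - 1e-12


class TestRankCandidates:
    def make_state_scores(self, scores: dict[str, float]) -> pd.Series:
        return pd.Series(scores)

    def test_distinct_scores_rank_permutation(self):
        assoc = df([[0], [0], [1]], ["a", "b", "k"], ["d"])
        scores = self.make_state_scores({"a": 0.3, "b": 0.9, "k": 1.0})
        cand, known = rank_candidates(scores, "d", assoc)
        assert sorted(cand["rank"]) == [1.0, 2.0]
        assert cand.index[0] == "b"
        assert list(known.index) == ["k"]

    def test_all_equal_scores_all_get_average_rank(self):
        assoc = df([[0], [0], [0]], ["a", "b", "c"], ["d"])
        scores = self.make_state_scores({"a": 0.0, "b": 0.0, "c": 0.0})
        cand, _ = rank_candidates(scores, "d", assoc)
        assert (cand["rank"] == 2.0).all()  # (N+1)/2 with N=3

    def test_tie_average_arithmetic(self):
        assoc = df([[0], [0], [0]], ["a", "b", "c"], ["d"])
        scores = self.make_state_scores({"a": 0.5, "b": 0.2, "c": 0.5})
        cand, _ = rank_candidates(scores, "d", assoc)
        assert cand.loc["a", "rank"] == 1.5
        assert cand.loc["c", "rank"] == 1.5
        assert cand.loc["b", "rank"] == 3.0


class TestWalkConfigValidation:
    @pytest.mark.parametrize("kwargs", [
        {"restart": 0.0}, {"restart": 1.5}, {"cutoff": 0.0}, {"max_iter": 0},
    ])
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ValueError):
            WalkConfig(**kwargs)
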