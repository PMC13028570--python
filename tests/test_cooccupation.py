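import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fungalnet.cooccupation import (
    NullEnsemble,
    call_edges,
    cooccupation_network,
    pair_statistics,
    togetherness,
)
from fungalnet.datamodel import binarize

from conftest import make_table


def brute_force_togetherness(pi, pj):
    s = a = 0
    for x, y in zip(pi, pj):
        if x == 1 and y == 1:
            s += 1
        if x == 0 and y == 0:
            a += 1
    return s, a, s * a


class TestTogetherness:
    def test_worked_example(self):
        t = make_table(np.array([[1, 1], [1, 0], [0, 0], [0, 0]]))
        p = binarize(t)
        stat = togetherness(p, "OTU01", "OTU02")
        assert (stat.S, stat.A, stat.togetherness) == (1, 2, 2)

    def test_identical_columns_saturate_maximum(self):
        t = make_table(np.array([[1, 1], [0, 0], [1, 1], [0, 0]]))
        stat = togetherness(binarize(t), "OTU01", "OTU02")
        assert stat.togetherness == (4 // 2) ** 2 == 4

    def test_checkerboard_minimum(self):
        t = make_table(np.array([[1, 0], [1, 0], [0, 1], [0, 1]]))
        stat = togetherness(binarize(t), "OTU01", "OTU02")
        assert (stat.S, stat.A, stat.togetherness) == (0, 0, 0)

    def test_self_pair_rejected(self):
        t = make_table(np.array([[1, 0], [0, 1]]))
        with pytest.raises(ValueError):
            togetherness(binarize(t), "OTU01", "OTU01")

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(st.integers(min_value=0, max_value=2**80 - 1))
    def test_matches_brute_force_on_random_matrices(self, bits):
        p = np.array([(bits >> k) & 1 for k in range(80)], dtype=np.int8).reshape(10, 8)
        stats = pair_statistics(
            type("P", (), {"presence": p, "otu_ids": [f"O{j}" for j in range(8)]})()
        )
        for i in range(8):
            for j in range(i + 1, 8):
                s, a, t = brute_force_togetherness(p[:, i], p[:, j])
                assert stats.S[i, j] == s and stats.A[i, j] == a and stats.T[i, j] == t


class TestNullEnsemble:
    def test_margins_preserved_every_draw(self):
        rng = np.random.default_rng(0)
        counts = rng.poisson(2.0, size=(12, 9))
        ens = NullEnsemble(counts, n_null=50, seed=1)
        r, c = counts.sum(1), counts.sum(0)
        for pres in ens.presence_draws():
            assert set(np.unique(pres)) <= {0, 1}
        # margin equality is asserted inside presence_draws on the integer
        # tables; re-check on raw Patefield draws via scipy directly
        from scipy.stats import random_table

        draws = random_table(r, c).rvs(20, random_state=np.random.default_rng(3))
        assert (draws.sum(axis=2) == r).all() and (draws.sum(axis=1) == c).all()

    def test_seeded_ensemble_is_reproducible(self):
        counts = np.random.default_rng(4).poisson(1.0, size=(8, 6))
        a = [p.copy() for p in NullEnsemble(counts, 10, seed=9).presence_draws()]
        b = [p.copy() for p in NullEnsemble(counts, 10, seed=9).presence_draws()]
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x, y)

    def test_curveball_preserves_binary_margins(self):
        rng = np.random.default_rng(2)
        counts = (rng.random((10, 8)) < 0.4).astype(int) * rng.poisson(3, (10, 8))
        ens = NullEnsemble(counts, n_null=20, seed=5, null_model="curveball")
        p = (counts > 0).astype(int)
        for pres in ens.presence_draws():
            np.testing.assert_array_equal(pres.sum(axis=1), p.sum(axis=1))
            np.testing.assert_array_equal(pres.sum(axis=0), p.sum(axis=0))

    def test_degenerate_zero_margins_pass_through(self):
        counts = np.array([[2, 0], [0, 0]])  # zero row and zero column
        for pres in NullEnsemble(counts, 5, seed=0).presence_draws():
            assert pres[1].sum() == 0 and pres[:, 1].sum() == 0


class FakeEnsemble:
    """Deterministic stand-in ensemble built from explicit presence draws."""

    def __init__(self, draws):
        self.draws = draws
        self.n_null = len(draws)

    def presence_draws(self, chunk=None):
        yield from self.draws


class TestCallEdges:
    def _obs(self, p):
        t = make_table(p)
        return pair_statistics(binarize(t))

    def test_extreme_rank_gives_add_one_p_and_positive_sign(self):
        # observed pair perfectly together; nulls all checkerboard (T=0)
        obs = self._obs(np.array([[1, 1], [1, 1], [0, 0], [0, 0]]))
        null = np.array([[1, 0], [0, 1], [1, 0], [0, 1]], dtype=np.int8)
        net = call_edges(obs, FakeEnsemble([null] * 9), alpha=0.5)
        d = net.graph.get_edge_data("OTU01", "OTU02")
        assert d["p"] == pytest.approx(2 * 1 / 10)
        assert d["sign"] == +1

    def test_observed_at_null_median_gives_p_one_no_edge(self):
        obs = self._obs(np.array([[1, 1], [1, 1], [0, 0], [0, 0]]))
        same = (obs.T > 0).astype(np.int8)  # placeholder; draws equal observed
        draws = [np.array([[1, 1], [1, 1], [0, 0], [0, 0]], dtype=np.int8)] * 9
        net = call_edges(obs, FakeEnsemble(draws), alpha=0.9999)
        assert net.graph.number_of_edges() == 0  # p capped at 1 everywhere

    def test_lower_tail_is_negative_sign(self):
        # observed checkerboard (T=0); nulls perfectly together (T=4)
        obs = self._obs(np.array([[1, 0], [1, 0], [0, 1], [0, 1]]))
        null = np.array([[1, 1], [1, 1], [0, 0], [0, 0]], dtype=np.int8)
        net = call_edges(obs, FakeEnsemble([null] * 9), alpha=0.5)
        assert net.graph.get_edge_data("OTU01", "OTU02")["sign"] == -1

    def test_alpha_range_validated(self):
        obs = self._obs(np.array([[1, 0], [0, 1]]))
        with pytest.raises(ValueError, match="alpha"):
            call_edges(obs, FakeEnsemble([]), alpha=1.5)

    def test_p_floor_and_cap(self):
        rng = np.random.default_rng(8)
        counts = rng.poisson(1.0, size=(20, 10))
        net = cooccupation_network(make_table(counts), n_null=49, seed=3)
        p = net.pair_p[np.triu_indices(10, 1)]
        assert (p >= 2 / 50).all() and (p <= 1).all()

    def test_network_deterministic_under_seed(self):
        counts = np.random.default_rng(10).poisson(1.0, size=(15, 8))
        t = make_table(counts)
        n1 = cooccupation_network(t, n_null=99, seed=42)
        n2 = cooccupation_network(t, n_null=99, seed=42)
        assert sorted(n1.graph.edges) == sorted(n2.graph.edges)
        np.testing.assert_array_equal(n1.pair_p, n2.pair_p)
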