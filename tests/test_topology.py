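import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from fungalnet.commonness import CommonnessAssignment
from fungalnet.network import SignedNetwork
from fungalnet.topology import (
    clustering_coefficient,
    connectance,
    detect_communities,
    modularity,
    neg_pos_ratio,
    niche_width,
    niche_width_all,
    summarize,
)

from conftest import make_table


def modularity_oracle(g, partition):
    """Independent double-sum evaluation over ordered node pairs."""
    m = g.number_of_edges()
    nodes = list(g.nodes)
    a = nx.to_numpy_array(g, nodelist=nodes)
    k = a.sum(axis=1)
    total = 0.0
    for i, u in enumerate(nodes):
        for j, v in enumerate(nodes):
            if partition[u] == partition[v]:
                total += a[i, j] - k[i] * k[j] / (2 * m)
    return total / (2 * m)


def two_triangles():
    return nx.Graph([(0, 1), (1, 2), (2, 0), (3, 4), (4, 5), (5, 3)])


class TestModularity:
    def test_two_triangles_clique_partition_is_half(self):
        part = {0: 0, 1: 0, 2: 0, 3: 1, 4: 1, 5: 1}
        assert modularity(two_triangles(), part) == pytest.approx(0.5)

    def test_single_module_is_zero(self):
        g = nx.gnm_random_graph(9, 14, seed=2)
        assert modularity(g, {n: 0 for n in g.nodes}) == pytest.approx(0.0, abs=1e-15)

    def test_matches_double_sum_oracle_on_random_partitions(self):
        rng = np.random.default_rng(0)
        for seed in range(5):
            g = nx.gnm_random_graph(10, 18, seed=seed)
            part = {n: int(rng.integers(3)) for n in g.nodes}
            assert modularity(g, part) == pytest.approx(modularity_oracle(g, part), abs=1e-12)

    def test_empty_edge_set_rejected(self):
        g = nx.empty_graph(4)
        with pytest.raises(ValueError, match="m = 0"):
            modularity(g, {n: 0 for n in g.nodes})

    def test_partition_must_cover_nodes(self):
        with pytest.raises(ValueError, match="cover"):
            modularity(two_triangles(), {0: 0})


class TestDetectCommunities:
    def test_recovers_triangle_cliques_exactly(self):
        part, m = detect_communities(two_triangles(), seed=0)
        assert m == pytest.approx(0.5)
        blocks = {frozenset(n for n in part if part[n] == c) for c in set(part.values())}
        assert blocks == {frozenset({0, 1, 2}), frozenset({3, 4, 5})}

    def test_complete_graph_single_module_zero(self):
        part, m = detect_communities(nx.complete_graph(6), seed=0)
        assert m == pytest.approx(0.0, abs=1e-12)

    def test_louvain_recovers_planted_blocks(self):
        hits = 0
        for seed in range(20):
            g = nx.planted_partition_graph(4, 8, 0.9, 0.02, seed=seed)
            planted = {frozenset(range(b * 8, (b + 1) * 8)) for b in range(4)}
            part, _ = detect_communities(g, seed=seed, method="louvain")
            blocks = {
                frozenset(n for n in part if part[n] == c) for c in set(part.values())
            }
            hits += blocks == planted
        assert hits >= 18

    def test_never_below_single_module_baseline(self):
        for seed in range(5):
            g = nx.gnm_random_graph(25, 40, seed=seed)
            g.remove_nodes_from(list(nx.isolates(g)))
            _, m = detect_communities(g, seed=seed, method="louvain")
            assert m >= -1e-12


class TestClosedForms:
    def test_connectance_complete_and_sparse_and_empty(self):
        assert connectance(nx.complete_graph(7)) == pytest.approx(1.0)
        g = nx.gnm_random_graph(10, 9, seed=1)
        assert connectance(g) == pytest.approx(9 / 45)
        assert connectance(nx.empty_graph(5)) == 0.0
        assert np.isnan(connectance(nx.empty_graph(1)))

    def test_neg_pos_ratio_percentages(self):
        g = nx.Graph()
        for i in range(300):
            g.add_edge(f"p{i}", f"q{i}", sign=+1)
        for i in range(3):
            g.add_edge(f"n{i}", f"m{i}", sign=-1)
        assert neg_pos_ratio(g) == pytest.approx(1.0)

    def test_neg_pos_ratio_guards(self):
        g = nx.Graph()
        g.add_edge(0, 1, sign=+1)
        assert neg_pos_ratio(g) == 0.0
        g2 = nx.Graph()
        g2.add_edge(0, 1, sign=-1)
        with pytest.warns(UserWarning, match="undefined"):
            assert np.isnan(neg_pos_ratio(g2))

    def test_clustering_triangle_star_and_bruteforce(self):
        assert clustering_coefficient(nx.complete_graph(3)) == pytest.approx(1.0)
        assert clustering_coefficient(nx.star_graph(4)) == pytest.approx(0.0)
        g = nx.gnm_random_graph(12, 24, seed=3)
        # brute-force local clustering: triangles over possible wedges
        vals = []
        for n in g.nodes:
            nbrs = list(g.neighbors(n))
            d = len(nbrs)
            if d < 2:
                vals.append(0.0)
                continue
            tri = sum(
                1 for u, v in itertools.combinations(nbrs, 2) if g.has_edge(u, v)
            )
            vals.append(2 * tri / (d * (d - 1)))
        assert clustering_coefficient(g) == pytest.approx(np.mean(vals), abs=1e-12)


class TestNicheWidth:
    def test_uniform_four_bins_gives_four(self):
        t = make_table(np.full((4, 1), 5), belts=["B1", "B2", "B3", "B4"])
        assert niche_width(t, "OTU01") == pytest.approx(4.0)

    def test_single_bin_specialist_gives_one(self):
        t = make_table([[9], [0], [0]], belts=["B1", "B2", "B3"])
        assert niche_width(t, "OTU01") == pytest.approx(1.0)

    def test_direct_evaluation(self):
        t = make_table([[5], [3], [2]], belts=["B1", "B2", "B3"])
        assert niche_width(t, "OTU01") == pytest.approx(1 / 0.38, abs=1e-12)

    def test_rescale_invariance(self):
        t1 = make_table([[5], [3], [2]], belts=["B1", "B2", "B3"])
        t2 = make_table([[50], [30], [20]], belts=["B1", "B2", "B3"])
        assert niche_width(t1, "OTU01") == pytest.approx(niche_width(t2, "OTU01"), abs=1e-12)

    def test_zero_total_species_is_na(self):
        t = make_table([[0, 1], [0, 2]], belts=["B1", "B2"])
        assert np.isnan(niche_width_all(t)["OTU01"])

    def test_bounds_one_to_r(self):
        rng = np.random.default_rng(5)
        t = make_table(rng.poisson(2.0, size=(8, 10)),
                       belts=[f"B{i % 4}" for i in range(8)])
        nw = niche_width_all(t).dropna()
        assert ((nw >= 1 - 1e-12) & (nw <= 4 + 1e-12)).all()


def toy_assignment(labels: dict) -> CommonnessAssignment:
    df = pd.DataFrame(
        {
            "occupancy": 0.5,
            "abundance_index": 1.0,
            "membership_common": [1.0 if v == "common" else 0.0 for v in labels.values()],
            "label": list(labels.values()),
        },
        index=list(labels.keys()),
    )
    return CommonnessAssignment(df, np.zeros((2, 2)), 1.0)


class TestSummarize:
    def _scene(self):
        labels = {"A": "common", "B": "common", "C": "rare", "D": "rare"}
        g = nx.Graph()
        g.add_nodes_from(labels)
        g.add_edge("A", "B", sign=+1)
        g.add_edge("C", "D", sign=-1)
        g.add_edge("A", "C", sign=+1)
        net = SignedNetwork(g, stage="co-occupation", zone="LA")
        net.set_groups(labels)
        counts = np.array([[4, 2, 1, 1], [4, 2, 1, 0], [0, 2, 1, 0], [0, 2, 1, 1]])
        table = make_table(counts, zones=["LA"] * 4, belts=["B1", "B1", "B2", "B2"])
        table.otu_ids[:] = ["A", "B", "C", "D"]  # align ids with the toy network
        return net, toy_assignment(labels), table

    def test_hand_computed_rows(self):
        net, assignment, table = self._scene()
        df = summarize({"LA": net}, assignment, table).set_index("subgroup")
        both = df.loc["both"]
        assert both["n_nodes"] == 4
        assert both["n_edges_pos"] == 2 and both["n_edges_neg"] == 1
        assert both["connectance"] == pytest.approx(3 / 6)
        assert both["neg_pos_pct"] == pytest.approx(50.0)
        assert both["mean_degree"] == pytest.approx(1.5)
        common = df.loc["common"]
        assert common["connectance"] == pytest.approx(1.0)
        assert common["n_edges_neg"] == 0
        # A occupies only belt B1 (NW 1), B spread evenly over both belts (NW 2)
        assert common["mean_niche_width"] == pytest.approx(1.5)
        rare = df.loc["rare"]
        assert rare["n_edges_pos"] == 0 and rare["n_edges_neg"] == 1
        assert np.isnan(rare["neg_pos_pct"])  # no positive edges

    def test_subgroup_counts_partition_both(self):
        net, assignment, table = self._scene()
        df = summarize({"LA": net}, assignment, table).set_index("subgroup")
        assert df.loc["both", "n_nodes"] == df.loc["common", "n_nodes"] + df.loc["rare", "n_nodes"]

    def test_absent_subgroup_emits_na_row(self):
        labels = {"A": "common", "B": "common"}
        g = nx.Graph()
        g.add_nodes_from(labels)
        g.add_edge("A", "B", sign=+1)
        net = SignedNetwork(g, stage="co-occupation", zone="LA")
        net.set_groups(labels)
        counts = np.array([[1, 2], [3, 1]])
        table = make_table(counts, zones=["LA"] * 2, belts=["B1", "B2"])
        table.otu_ids[:] = ["A", "B"]
        df = summarize({"LA": net}, toy_assignment(labels), table).set_index("subgroup")
        assert df.loc["rare", "n_nodes"] == 0
        assert pd.isna(df.loc["rare", "connectance"])
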