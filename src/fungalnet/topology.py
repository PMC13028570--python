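"""Stability-related network topology: modularity, connectance,
negative:positive edge ratio, Levins niche width, clustering, degree —
reported per zone for the whole network and for the common and rare
subgroups separately.
"""

from __future__ import annotations

import warnings
from itertools import combinations

import networkx as nx
import numpy as np
import pandas as pd

from .commonness import CommonnessAssignment
from .datamodel import OtuTable
from .network import SignedNetwork

SUBGROUPS = ("both", "common", "rare")


def _as_graph(network: SignedNetwork | nx.Graph) -> nx.Graph:
    return network.graph if isinstance(network, SignedNetwork) else network


# -- modularity ----------------------------------------------------------


def modularity(network: SignedNetwork | nx.Graph, partition: dict) -> float:
    """Newman modularity of a node partition on the unsigned simple graph.

    ``M = (1/2m) * sum_ij (A_ij - k_i k_j / 2m) * delta(c_i, c_j)`` over
    ordered node pairs, with m the number of edges and k the unsigned
    degrees. Evaluated per module as ``(2 e_c - K_c^2 / 2m) / 2m`` with e_c
    the within-module edges and K_c the module's total degree.
    """
    g = _as_graph(network)
    missing = [n for n in g.nodes if n not in partition]
    if missing:
        raise ValueError(f"partition does not cover nodes: {missing[:5]}")
    m = g.number_of_edges()
    if m == 0:
        raise ValueError("modularity undefined for an empty edge set (m = 0)")
    e_c: dict = {}
    k_c: dict = {}
    for n in g.nodes:
        k_c[partition[n]] = k_c.get(partition[n], 0) + g.degree(n)
    for u, v in g.edges:
        if partition[u] == partition[v]:
            e_c[partition[u]] = e_c.get(partition[u], 0) + 1
    two_m = 2.0 * m
    return sum(
        (2.0 * e_c.get(c, 0) - k_c[c] ** 2 / two_m) / two_m for c in k_c
    )


def _set_partitions(items: list):
    """All set partitions of ``items`` (only ever called for tiny graphs)."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for smaller in _set_partitions(rest):
        for i in range(len(smaller)):
            yield smaller[:i] + [[first] + smaller[i]] + smaller[i + 1:]
        yield [[first]] + smaller


def detect_communities(
    network: SignedNetwork | nx.Graph,
    seed: int = 0,
    method: str = "auto",
    exact_max_nodes: int = 10,
) -> tuple[dict, float]:
    """Partition maximising modularity; returns (partition, M).

    Graphs whose non-isolated node set has at most ``exact_max_nodes`` nodes
    are solved exactly by enumerating all set partitions (Bell numbers stay
    tiny there); larger graphs use seeded greedy Louvain optimisation.
    Isolated nodes always form singleton modules (they cannot change M).
    """
    g = _as_graph(network)
    if g.number_of_edges() == 0:
        raise ValueError("community detection undefined for an empty edge set")
    active = [n for n in g.nodes if g.degree(n) > 0]
    isolated = [n for n in g.nodes if g.degree(n) == 0]
    if method == "auto":
        method = "exact" if len(active) <= exact_max_nodes else "louvain"
    if method == "exact":
        if len(active) > 14:
            raise ValueError("exact search is limited to small graphs")
        core = g.subgraph(active)
        best, best_m = None, -np.inf
        for blocks in _set_partitions(active):
            part = {n: b for b, block in enumerate(blocks) for n in block}
            val = modularity(core, part)
            if val > best_m + 1e-15:
                best, best_m = part, val
        partition = dict(best)
    elif method == "louvain":
        comms = nx.community.louvain_communities(g.subgraph(active), seed=seed)
        partition = {n: c for c, block in enumerate(comms) for n in block}
        if modularity(g.subgraph(active), partition) < 0.0:
            # never fall below the single-module baseline M = 0
            partition = {n: 0 for n in active}
    else:
        raise ValueError(f"unknown method {method!r}")
    next_id = max(partition.values(), default=-1) + 1
    for k, n in enumerate(isolated):
        partition[n] = next_id + k
    m_val = modularity(g, partition) if g.number_of_edges() else 0.0
    return partition, m_val


# -- closed-form metrics -------------------------------------------------


def connectance(network: SignedNetwork | nx.Graph, subset: list | None = None) -> float:
    """Realised edges over possible edges n(n-1)/2 on the (induced) graph."""
    g = _as_graph(network)
    if subset is not None:
        g = g.subgraph(subset)
    n = g.number_of_nodes()
    if n < 2:
        return np.nan
    return g.number_of_edges() / (n * (n - 1) / 2.0)


def neg_pos_ratio(network: SignedNetwork | nx.Graph, subset: list | None = None) -> float:
    """100 * negative edges / positive edges; NA when no positive edges."""
    g = _as_graph(network)
    if subset is not None:
        g = g.subgraph(subset)
    pos = sum(1 for _, _, d in g.edges(data=True) if d.get("sign", 1) > 0)
    neg = g.number_of_edges() - pos
    if pos == 0:
        if neg > 0:
            warnings.warn("no positive edges; negative:positive ratio undefined", stacklevel=2)
        return 0.0 if neg == 0 else np.nan
    return 100.0 * neg / pos


def clustering_coefficient(network: SignedNetwork | nx.Graph) -> float:
    """Mean local clustering on the unsigned graph; degree-<2 nodes count 0."""
    g = _as_graph(network)
    if g.number_of_nodes() < 3:
        return np.nan
    return nx.average_clustering(g, count_zeros=True)


# -- Levins niche width --------------------------------------------------


def _bin_labels(table: OtuTable, binning: str) -> np.ndarray:
    if binning == "plot":
        return np.asarray(table.plot_ids)
    if binning == "zone":
        return table.zones().to_numpy()
    if binning == "belt":
        if "belt" in table.metadata.columns:
            return table.metadata["belt"].to_numpy()
        return table.zones().to_numpy()  # fall back to zones when no belts
    raise ValueError(f"unknown binning {binning!r} (expected belt/zone/plot)")


def niche_width_all(table: OtuTable, binning: str = "belt") -> pd.Series:
    """Levins niche width ``NW = 1 / sum_j p_ij^2`` for every OTU.

    ``p_ij`` is the share of species i's total count that falls in resource
    bin j (altitudinal belts by default). NW is 1 for a single-bin
    specialist, r for a uniform generalist over r bins, and NA for an OTU
    with zero total count.
    """
    bins = _bin_labels(table, binning)
    frame = pd.DataFrame(table.counts, index=bins, columns=table.otu_ids)
    per_bin = frame.groupby(level=0).sum()
    totals = per_bin.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = per_bin / totals
        nw = 1.0 / (p**2).sum(axis=0)
    nw[totals == 0] = np.nan
    nw.name = "niche_width"
    return nw


def niche_width(table: OtuTable, species: str, binning: str = "belt") -> float:
    return float(niche_width_all(table, binning).loc[species])


# -- Table-shaped summary ------------------------------------------------


def _subgroup_nodes(net: SignedNetwork, labels: dict[str, str], subgroup: str) -> list:
    if subgroup == "both":
        return list(net.graph.nodes)
    return [n for n in net.graph.nodes if labels.get(n) == subgroup]


def _mean_togetherness(net: SignedNetwork, nodes: list) -> float:
    if net.tog_matrix is None or len(nodes) < 2:
        return np.nan
    idx = [net.node_order.index(n) for n in nodes]
    pairs = list(combinations(idx, 2))
    vals = [net.tog_matrix[i, j] for i, j in pairs]
    return float(np.mean(vals))


def summarize(
    networks: dict[str, SignedNetwork],
    assignment: CommonnessAssignment,
    table: OtuTable,
    binning: str = "belt",
    seed: int = 0,
) -> pd.DataFrame:
    """One row per zone x {both, common, rare} with all topology metrics.

    Subgroup metrics are computed on the induced subgraph; absent subgroups
    yield NA rows. Means (degree, togetherness, niche width) are averaged
    over the subgroup's nodes or node pairs; niche widths come from the
    zone's plots.
    """
    labels = assignment.labels
    rows = []
    for zone, net in networks.items():
        zone_tab = table.zone_table(zone) if zone in set(table.zones()) else table
        nw = niche_width_all(zone_tab, binning)
        for sub in SUBGROUPS:
            nodes = _subgroup_nodes(net, labels, sub)
            row = {"zone": zone, "subgroup": sub, "n_nodes": len(nodes)}
            if len(nodes) == 0:
                rows.append(row)
                continue
            sg = net.graph.subgraph(nodes)
            pos = sum(1 for _, _, d in sg.edges(data=True) if d["sign"] > 0)
            neg = sg.number_of_edges() - pos
            row["n_edges_pos"] = pos
            row["n_edges_neg"] = neg
            row["connectance"] = connectance(sg)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                row["neg_pos_pct"] = neg_pos_ratio(sg)
            if sg.number_of_edges() > 0:
                part, m_val = detect_communities(sg, seed=seed)
                row["modularity"] = m_val
                row["n_modules"] = len(set(part.values()))
            else:
                row["modularity"] = np.nan
                row["n_modules"] = np.nan
            row["clustering_coefficient"] = clustering_coefficient(sg)
            degs = [d for _, d in sg.degree()]
            row["mean_degree"] = float(np.mean(degs)) if degs else np.nan
            row["mean_togetherness"] = _mean_togetherness(net, nodes)
            member_nw = nw.reindex(nodes)
            row["mean_niche_width"] = (
                float(member_nw.mean()) if member_nw.notna().any() else np.nan
            )
            rows.append(row)
    cols = [
        "zone", "subgroup", "n_nodes", "n_edges_pos", "n_edges_neg",
        "connectance", "neg_pos_pct", "modularity", "n_modules",
        "clustering_coefficient", "mean_degree", "mean_togetherness",
        "mean_niche_width",
    ]
    return pd.DataFrame(rows, columns=cols)
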