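"""Co-occurrence networks: thresholded Spearman correlation of relative abundances.

Nodes are the OTUs present in at least half the plots (configurable); edges
are pairs with |rho| >= 0.65 and BH-adjusted p <= 0.01 by default, signed by
the direction of the correlation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.stats import spearmanr
from statsmodels.stats.multitest import multipletests

from .datamodel import OtuTable
from .network import SignedNetwork

log = logging.getLogger(__name__)


class NetworkRefused(ValueError):
    """Raised when a filter leaves too few OTUs to build a network."""


@dataclass
class PrevalenceReport:
    kept: list[str]
    dropped: list[str]
    min_plots: int


def prevalence_filter(
    table: OtuTable, min_fraction: float = 0.5
) -> tuple[OtuTable, PrevalenceReport]:
    """Keep OTUs present in at least ``ceil(min_fraction * n_plots)`` plots."""
    if not (0.0 < min_fraction <= 1.0):
        raise ValueError("min_fraction must lie in (0, 1]")
    need = math.ceil(min_fraction * table.n_plots)
    occ = (table.counts > 0).sum(axis=0)
    kept = [table.otu_ids[j] for j in np.flatnonzero(occ >= need)]
    dropped = [table.otu_ids[j] for j in np.flatnonzero(occ < need)]
    report = PrevalenceReport(kept, dropped, need)
    log.info(
        "prevalence filter (>= %d/%d plots): kept %d, dropped %d OTUs",
        need, table.n_plots, len(kept), len(dropped),
    )
    if len(kept) < 3:
        raise NetworkRefused(
            f"prevalence filter (>= {need} plots) left {len(kept)} OTUs; "
            "a correlation network needs at least 3"
        )
    return table.subset_otus(kept), report


def spearman_edges(
    table: OtuTable,
    rho_min: float = 0.65,
    q_max: float = 0.01,
    adjust: str = "fdr_bh",
    zone: str | None = None,
) -> SignedNetwork:
    """All-pairs Spearman on per-plot relative abundances, thresholded.

    Counts are converted to relative abundance (total-sum scaling per plot)
    and handed to :func:`edges_from_abundance`. Note the closure step itself
    is compositional: rank correlations are exactly invariant to strictly
    monotone transforms of the abundance columns they receive, but a
    monotone transform of one OTU's *raw counts* also perturbs every plot
    total and therefore, slightly, every other OTU's relative abundance.
    """
    return edges_from_abundance(
        table.relative_abundance(), table.otu_ids, rho_min, q_max, adjust, zone
    )


def edges_from_abundance(
    abundance: np.ndarray,
    otu_ids: list[str],
    rho_min: float = 0.65,
    q_max: float = 0.01,
    adjust: str = "fdr_bh",
    zone: str | None = None,
) -> SignedNetwork:
    """Thresholded rank-correlation network on a plots x OTUs abundance matrix.

    Average-rank tie handling and the two-sided t approximation come from the
    standard rank-correlation machinery; p-values are adjusted across all
    tested pairs (BH by default; 'holm', 'bonferroni' and 'none' accepted).
    An edge is emitted iff ``|rho| >= rho_min`` and adjusted p ``<= q_max``;
    the sign is the sign of rho and the weight is rho itself. Constant OTU
    vectors have no defined rank correlation: those pairs are skipped and
    logged.
    """
    if not (0.0 <= rho_min <= 1.0):
        raise ValueError("rho_min must lie in [0, 1]")
    if not (0.0 < q_max <= 1.0):
        raise ValueError("q_max must lie in (0, 1]")
    rel = np.asarray(abundance, dtype=float)
    n = len(otu_ids)
    if rel.shape[1] != n:
        raise ValueError("abundance matrix and otu_ids disagree")
    if n < 3:
        raise NetworkRefused("need at least 3 OTUs for a correlation network")
    rho, p_raw = spearmanr(rel, axis=0)
    rho = np.atleast_2d(rho)
    p_raw = np.atleast_2d(p_raw)

    constant = rel.std(axis=0) == 0
    if constant.any():
        log.warning(
            "skipping %d constant OTU vector(s): %s",
            constant.sum(),
            [otu_ids[j] for j in np.flatnonzero(constant)],
        )
    iu, ju = np.triu_indices(n, 1)
    valid = ~(constant[iu] | constant[ju]) & np.isfinite(rho[iu, ju])
    p_vec = p_raw[iu, ju]
    p_adj = np.full(p_vec.shape, np.nan)
    if valid.any():
        if adjust == "none":
            p_adj[valid] = p_vec[valid]
        else:
            p_adj[valid] = multipletests(p_vec[valid], method=adjust)[1]

    g = nx.Graph()
    g.add_nodes_from(otu_ids)
    hit = valid & (np.abs(rho[iu, ju]) >= rho_min) & (p_adj <= q_max)
    for k in np.flatnonzero(hit):
        a, b = otu_ids[iu[k]], otu_ids[ju[k]]
        r = float(rho[iu[k], ju[k]])
        g.add_edge(a, b, sign=1 if r > 0 else -1, weight=r, p=float(p_adj[k]))
    return SignedNetwork(g, stage="co-occurrence", zone=zone, node_order=list(otu_ids))


def cooccurrence_network(
    table: OtuTable,
    min_fraction: float = 0.5,
    rho_min: float = 0.65,
    q_max: float = 0.01,
    adjust: str = "fdr_bh",
    zone: str | None = None,
) -> tuple[SignedNetwork, PrevalenceReport]:
    """Full stage on one table: prevalence filter then thresholded Spearman."""
    filtered, report = prevalence_filter(table, min_fraction)
    net = spearman_edges(filtered, rho_min, q_max, adjust, zone=zone)
    return net, report
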