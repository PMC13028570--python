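"""Co-occupation networks: togetherness tested against a fixed-margin null.

For a species pair across plots, togetherness is
``T = S * A`` with S the number of plots where both are present and A the
number where both are absent; high T means the pair shares a spatial niche.
Observed T is compared with T under 999 randomisations of the integer count
table that preserve every plot total and every OTU total exactly (the
r2dtable / Patefield null, i.e. independence given margins). Pairs whose T
is significantly above the null are positive associations; significantly
below, negative.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.stats import random_table

from .datamodel import OtuTable, PresenceMatrix, binarize
from .network import SignedNetwork


@dataclass
class PairStatistic:
    """Togetherness bookkeeping for one OTU pair."""

    pair: tuple[str, str]
    S: int  # co-presence plots
    A: int  # co-absence plots
    togetherness: int  # S * A
    null_quantile: float | None = None  # fraction of null draws <= observed
    p_two_sided: float | None = None


@dataclass
class PairStatistics:
    """S, A and T for every OTU pair of one presence matrix."""

    otu_ids: list[str]
    S: np.ndarray
    A: np.ndarray
    T: np.ndarray
    n_plots: int


def togetherness(presence: PresenceMatrix, i: str, j: str) -> PairStatistic:
    """S, A and T = S*A for one pair, counted over plots."""
    if i == j:
        raise ValueError("togetherness is defined for distinct OTUs")
    ci = presence.presence[:, presence.otu_ids.index(i)]
    cj = presence.presence[:, presence.otu_ids.index(j)]
    s = int(np.sum((ci == 1) & (cj == 1)))
    a = int(np.sum((ci == 0) & (cj == 0)))
    return PairStatistic((i, j), s, a, s * a)


def pair_statistics(presence: PresenceMatrix) -> PairStatistics:
    """Vectorised S/A/T over all pairs (matrix products on the binary table)."""
    s, a, t = _tog_matrices(presence.presence)
    return PairStatistics(list(presence.otu_ids), s, a, t, presence.presence.shape[0])


def _tog_matrices(p: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    pf = p.astype(np.float64)
    s = pf.T @ pf
    q = 1.0 - pf
    a = q.T @ q
    return s, a, s * a


class NullEnsemble:
    """Lazy ensemble of fixed-margin randomisations of a count table.

    ``null_model='r2dtable'`` samples integer tables with the observed row
    (plot total) and column (OTU total) sums via Patefield's algorithm and
    binarises each draw; ``'curveball'`` instead randomises the binary
    presence matrix with fixed binary margins (swap-family alternative).
    Margin preservation is asserted on every draw.
    """

    def __init__(
        self,
        counts: np.ndarray,
        n_null: int = 999,
        seed: int = 0,
        null_model: str = "r2dtable",
        threshold: int = 0,
    ) -> None:
        counts = np.asarray(counts)
        if (counts < 0).any():
            raise ValueError("counts must be non-negative")
        if null_model not in ("r2dtable", "curveball"):
            raise ValueError(f"unknown null model {null_model!r}")
        self.counts = counts
        self.n_null = int(n_null)
        self.seed = int(seed)
        self.null_model = null_model
        self.threshold = int(threshold)
        self.row_sums = counts.sum(axis=1)
        self.col_sums = counts.sum(axis=0)

    def integer_draws(self, chunk: int = 111):
        """Yield raw fixed-margin integer tables (r2dtable model only)."""
        if self.null_model != "r2dtable":
            raise ValueError("integer tables exist only under the r2dtable null")
        rng = np.random.default_rng(self.seed)
        dist = random_table(self.row_sums, self.col_sums)
        done = 0
        while done < self.n_null:
            m = min(chunk, self.n_null - done)
            draws = dist.rvs(m, random_state=rng)
            if draws.ndim == 2:
                draws = draws[None, :, :]
            assert (draws.sum(axis=2) == self.row_sums).all()
            assert (draws.sum(axis=1) == self.col_sums).all()
            yield from draws
            done += m

    def presence_draws(self, chunk: int = 111):
        """Yield binarised null presence matrices in chunks of ``chunk``."""
        if self.null_model == "r2dtable":
            for d in self.integer_draws(chunk):
                yield (d > self.threshold).astype(np.int8)
        else:
            rng = np.random.default_rng(self.seed)
            p = (self.counts > self.threshold).astype(np.int8)
            rows = [set(np.flatnonzero(r)) for r in p]
            brow, bcol = p.sum(axis=1), p.sum(axis=0)
            for _ in range(self.n_null):
                _curveball_sweeps(rows, rng, n_sweeps=5)
                d = np.zeros_like(p)
                for ri, cols in enumerate(rows):
                    d[ri, list(cols)] = 1
                assert (d.sum(axis=1) == brow).all()
                assert (d.sum(axis=0) == bcol).all()
                yield d


def _curveball_sweeps(rows: list[set], rng: np.random.Generator, n_sweeps: int) -> None:
    """In-place curveball trades between random row pairs (binary margins fixed)."""
    n = len(rows)
    for _ in range(n_sweeps * n):
        i, j = rng.choice(n, 2, replace=False)
        shared = rows[i] & rows[j]
        pooled = list((rows[i] | rows[j]) - shared)
        if not pooled:
            continue
        ni = len(rows[i]) - len(shared)
        rng.shuffle(pooled)
        rows[i] = shared | set(pooled[:ni])
        rows[j] = shared | set(pooled[ni:])


def call_edges(
    observed: PairStatistics,
    ensemble: NullEnsemble,
    alpha: float = 0.05,
    zone: str | None = None,
) -> SignedNetwork:
    """Empirical two-sided permutation test per pair; emit significant edges.

    ``p = 2 * min(P(T_null >= T_obs), P(T_null <= T_obs))`` with the add-one
    rule ``(1 + #extreme) / (n_null + 1)``, capped at 1. Sign is + when the
    observed togetherness sits above the null's centre (the pair co-occupies
    more than expected), - when below.
    """
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must lie in (0, 1)")
    t_obs = observed.T
    n = len(observed.otu_ids)
    cge = np.zeros((n, n))
    cle = np.zeros((n, n))
    for pres in ensemble.presence_draws():
        _, _, t_null = _tog_matrices(pres)
        cge += t_null >= t_obs
        cle += t_null <= t_obs
    n_null = ensemble.n_null
    p_ge = (1.0 + cge) / (n_null + 1.0)
    p_le = (1.0 + cle) / (n_null + 1.0)
    p = np.minimum(1.0, 2.0 * np.minimum(p_ge, p_le))
    n_below, n_above = n_null - cge, n_null - cle  # null draws strictly below/above obs
    sign = np.where(n_below > n_above, 1, -1)

    g = nx.Graph()
    g.add_nodes_from(observed.otu_ids)
    iu, ju = np.triu_indices(n, 1)
    hit = p[iu, ju] <= alpha
    for a_idx, b_idx in zip(iu[hit], ju[hit]):
        g.add_edge(
            observed.otu_ids[a_idx],
            observed.otu_ids[b_idx],
            sign=int(sign[a_idx, b_idx]),
            weight=float(observed.T[a_idx, b_idx]),
            p=float(p[a_idx, b_idx]),
            S=int(observed.S[a_idx, b_idx]),
            A=int(observed.A[a_idx, b_idx]),
            togetherness=int(observed.T[a_idx, b_idx]),
        )
    net = SignedNetwork(
        g,
        stage="co-occupation",
        zone=zone,
        node_order=list(observed.otu_ids),
        tog_matrix=observed.T,
    )
    net.pair_p = p  # full per-pair p matrix, kept for calibration studies
    net.pair_sign = sign
    return net


def cooccupation_network(
    table: OtuTable,
    n_null: int = 999,
    alpha: float = 0.05,
    seed: int = 0,
    null_model: str = "r2dtable",
    threshold: int = 0,
    zone: str | None = None,
) -> SignedNetwork:
    """Full stage on one table (typically the plots of one zone)."""
    presence = binarize(table, threshold)
    stats = pair_statistics(presence)
    ensemble = NullEnsemble(table.counts, n_null, seed, null_model, threshold)
    return call_edges(stats, ensemble, alpha=alpha, zone=zone)
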