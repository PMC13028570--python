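"""Signed association networks shared by the co-occupation and co-occurrence stages."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd


@dataclass
class SignedNetwork:
    """Simple undirected graph whose edges carry a sign and a provenance stage.

    Nodes are OTU ids, optionally labelled with a ``group`` attribute
    (common/rare). Edge attributes: ``sign`` (+1/-1), ``weight``, ``p``,
    ``stage``. ``tog_matrix`` optionally holds the observed togetherness of
    every pair (stage ``co-occupation`` only), aligned to ``node_order``.
    """

    graph: nx.Graph
    stage: str  # "co-occupation" | "co-occurrence"
    zone: str | None = None
    node_order: list[str] = field(default_factory=list)
    tog_matrix: np.ndarray | None = None

    def __post_init__(self) -> None:
        if any(u == v for u, v in self.graph.edges):
            raise ValueError("signed network must be a simple graph (self-loop found)")
        for u, v, d in self.graph.edges(data=True):
            if d.get("sign") not in (+1, -1):
                raise ValueError(f"edge ({u}, {v}) has no +/- sign")
        if not self.node_order:
            self.node_order = list(self.graph.nodes)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edge_counts(self) -> tuple[int, int]:
        """(positive, negative) edge counts."""
        signs = [d["sign"] for _, _, d in self.graph.edges(data=True)]
        pos = sum(1 for s in signs if s > 0)
        return pos, len(signs) - pos

    def set_groups(self, labels: dict[str, str]) -> None:
        for n in self.graph.nodes:
            self.graph.nodes[n]["group"] = labels.get(n, "unknown")

    def subgraph_group(self, group: str) -> nx.Graph:
        nodes = [n for n, d in self.graph.nodes(data=True) if d.get("group") == group]
        return self.graph.subgraph(nodes)

    def to_edge_dataframe(self) -> pd.DataFrame:
        rows = [
            {
                "otu_i": u,
                "otu_j": v,
                "sign": "+" if d["sign"] > 0 else "-",
                "weight": d.get("weight", np.nan),
                "p": d.get("p", np.nan),
                "S": d.get("S", np.nan),
                "A": d.get("A", np.nan),
                "togetherness": d.get("togetherness", np.nan),
                "stage": self.stage,
                "zone": self.zone or "",
            }
            for u, v, d in self.graph.edges(data=True)
        ]
        return pd.DataFrame(
            rows,
            columns=[
                "otu_i", "otu_j", "sign", "weight", "p",
                "S", "A", "togetherness", "stage", "zone",
            ],
        )

    def write_tsv(self, path: str | Path) -> None:
        self.to_edge_dataframe().to_csv(path, sep="\t", index=False)

    def write_graphml(self, path: str | Path) -> None:
        g = self.graph.copy()
        for _, _, d in g.edges(data=True):
            for k, v in list(d.items()):
                if isinstance(v, (np.integer, np.floating)):
                    d[k] = v.item()
        nx.write_graphml(g, path)
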