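"""Community data model: the plot-by-OTU count table and its presence view.

The count matrix is stored plots x OTUs with non-negative integer entries;
relative abundances are derived views, never the primary matrix, because the
fixed-margin permutation null is defined on integer contingency tables.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

ZONES = ("LA", "MA", "HA")


class OtuTableError(ValueError):
    """Raised when a table violates the data-model invariants."""


@dataclass
class OtuTable:
    """Plot-by-OTU count matrix with aligned per-plot metadata.

    Parameters
    ----------
    counts
        Integer matrix, shape ``(n_plots, n_otus)``, no negative entries.
    otu_ids, plot_ids
        Ordered identifiers matching the matrix axes.
    metadata
        Per-plot records indexed by plot id. ``altitude`` (metres) and
        ``zone`` (categorical LA/MA/HA) are expected by the network stages;
        an optional ``belt`` column gives finer altitudinal bins.
    """

    counts: np.ndarray
    otu_ids: list[str]
    plot_ids: list[str]
    metadata: pd.DataFrame

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise OtuTableError("counts must be a 2-D matrix (plots x OTUs)")
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.allclose(self.counts, np.round(self.counts)):
                raise OtuTableError("counts must be integers")
            self.counts = self.counts.astype(np.int64)
        if (self.counts < 0).any():
            i, j = np.argwhere(self.counts < 0)[0]
            raise OtuTableError(
                f"negative count at plot {self.plot_ids[i]!r}, OTU {self.otu_ids[j]!r}"
            )
        self.otu_ids = [str(o) for o in self.otu_ids]
        self.plot_ids = [str(p) for p in self.plot_ids]
        n_plots, n_otus = self.counts.shape
        if len(self.plot_ids) != n_plots or len(self.otu_ids) != n_otus:
            raise OtuTableError(
                f"id lists ({len(self.plot_ids)} plots, {len(self.otu_ids)} OTUs) "
                f"do not match counts shape {self.counts.shape}"
            )
        meta_ids = set(map(str, self.metadata.index))
        table_ids = set(self.plot_ids)
        if meta_ids != table_ids:
            missing = sorted(table_ids - meta_ids)
            orphans = sorted(meta_ids - table_ids)
            raise OtuTableError(
                "plot ids in counts and metadata do not reconcile; "
                f"missing from metadata: {missing}; metadata orphans: {orphans}"
            )
        self.metadata = self.metadata.loc[self.plot_ids]

    # -- derived views ---------------------------------------------------
    @property
    def n_plots(self) -> int:
        return self.counts.shape[0]

    @property
    def n_otus(self) -> int:
        return self.counts.shape[1]

    def relative_abundance(self) -> np.ndarray:
        """Per-plot total-sum scaling; plots with zero total stay all-zero."""
        totals = self.counts.sum(axis=1, keepdims=True).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            rel = np.where(totals > 0, self.counts / totals, 0.0)
        return rel

    def zones(self) -> pd.Series:
        if "zone" not in self.metadata.columns:
            raise OtuTableError("metadata has no 'zone' column")
        z = self.metadata["zone"]
        bad = z.isna() | ~z.astype(str).isin(ZONES)
        if bad.any():
            raise OtuTableError(
                f"plots with missing/unknown zone label: {list(z.index[bad])}"
            )
        return z.astype(str)

    def subset_plots(self, plot_ids: list[str]) -> "OtuTable":
        idx = [self.plot_ids.index(p) for p in plot_ids]
        return OtuTable(
            counts=self.counts[idx],
            otu_ids=list(self.otu_ids),
            plot_ids=list(plot_ids),
            metadata=self.metadata.loc[plot_ids],
        )

    def subset_otus(self, otu_ids: list[str]) -> "OtuTable":
        idx = [self.otu_ids.index(o) for o in otu_ids]
        return OtuTable(
            counts=self.counts[:, idx],
            otu_ids=list(otu_ids),
            plot_ids=list(self.plot_ids),
            metadata=self.metadata,
        )

    def zone_table(self, zone: str) -> "OtuTable":
        """Restrict to the plots of one altitudinal zone."""
        z = self.zones()
        keep = [p for p in self.plot_ids if z.loc[p] == zone]
        if not keep:
            raise OtuTableError(f"no plots in zone {zone!r}")
        return self.subset_plots(keep)


@dataclass
class PresenceMatrix:
    """Binary occupancy view of a count table.

    ``presence[i, j] = 1`` iff ``counts[i, j] > threshold``.
    """

    presence: np.ndarray
    derived_from: OtuTable
    threshold: int = 0
    all_zero_otus: list[str] = field(default_factory=list)

    @property
    def otu_ids(self) -> list[str]:
        return self.derived_from.otu_ids

    @property
    def plot_ids(self) -> list[str]:
        return self.derived_from.plot_ids


def binarize(table: OtuTable, threshold: int = 0) -> PresenceMatrix:
    """Declare presence where the count strictly exceeds ``threshold``.

    OTUs that end up all-absent are flagged (never silently dropped).
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    presence = (table.counts > threshold).astype(np.int8)
    zero_cols = np.flatnonzero(presence.sum(axis=0) == 0)
    flagged = [table.otu_ids[j] for j in zero_cols]
    if flagged:
        warnings.warn(
            f"{len(flagged)} OTU(s) absent everywhere at threshold {threshold}",
            stacklevel=2,
        )
    return PresenceMatrix(presence, table, threshold, flagged)


# -- I/O -----------------------------------------------------------------


def _read_counts_tsv(path: Path, otus_as_rows: bool) -> tuple[np.ndarray, list, list]:
    df = pd.read_csv(path, sep="\t", index_col=0)
    num = df.apply(pd.to_numeric, errors="coerce")
    if num.isna().any().any():
        r, c = np.argwhere(num.isna().to_numpy())[0]
        raise OtuTableError(
            f"non-numeric count at row {df.index[r]!r}, column {df.columns[c]!r} in {path}"
        )
    arr = num.to_numpy()
    if (arr < 0).any():
        r, c = np.argwhere(arr < 0)[0]
        raise OtuTableError(
            f"negative count at row {df.index[r]!r}, column {df.columns[c]!r} in {path}"
        )
    if otus_as_rows:
        return arr.T.astype(np.int64), list(df.index), list(df.columns)
    return arr.astype(np.int64), list(df.columns), list(df.index)


def _read_biom_json(path: Path) -> tuple[np.ndarray, list, list]:
    """Minimal BIOM v1 (JSON) reader, dense or sparse matrices.

    BIOM orients the matrix observations(OTUs) x samples(plots).
    """
    with open(path) as fh:
        doc = json.load(fh)
    otu_ids = [r["id"] for r in doc["rows"]]
    plot_ids = [c["id"] for c in doc["columns"]]
    shape = tuple(doc["shape"])
    mat = np.zeros(shape, dtype=np.int64)
    if doc.get("matrix_type", "sparse") == "dense":
        mat[:] = np.asarray(doc["data"])
    else:
        for i, j, v in doc["data"]:
            mat[int(i), int(j)] = v
    return mat.T, otu_ids, plot_ids


def read_otu_table(
    counts_path: str | Path,
    metadata_path: str | Path,
    format: str = "tsv",
    otus_as_rows: bool = True,
) -> OtuTable:
    """Read a count table plus its per-plot metadata table.

    The TSV dialect defaults to OTUs-as-rows / plots-as-columns (the dominant
    amplicon convention). Orientation is an explicit flag: auto-detection is
    refused because silent transposition is the classic OTU-table bug.
    """
    counts_path, metadata_path = Path(counts_path), Path(metadata_path)
    if format == "tsv":
        counts, otu_ids, plot_ids = _read_counts_tsv(counts_path, otus_as_rows)
    elif format == "biom":
        counts, otu_ids, plot_ids = _read_biom_json(counts_path)
    else:
        raise ValueError(f"unknown format {format!r} (expected 'tsv' or 'biom')")
    meta = pd.read_csv(metadata_path, sep="\t", index_col=0)
    meta.index = meta.index.astype(str)
    return OtuTable(counts, otu_ids, plot_ids, meta)


def write_otu_table(table: OtuTable, counts_path: str | Path, metadata_path: str | Path) -> None:
    """Write counts (OTUs as rows) and metadata as TSV; round-trips exactly."""
    df = pd.DataFrame(table.counts.T, index=table.otu_ids, columns=table.plot_ids)
    df.index.name = "otu_id"
    df.to_csv(counts_path, sep="\t")
    meta = table.metadata.copy()
    meta.index.name = "plot_id"
    meta.to_csv(metadata_path, sep="\t")
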