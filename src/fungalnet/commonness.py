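"""Common/rare classification from joint abundance-frequency structure.

A fuzzy two-cluster partition of the OTUs in the (occupancy, log-abundance)
plane: common taxa are the few high-occupancy, high-abundance species; rare
taxa the many sparse ones. The partition is a standard fuzzy c-means with
c = 2 clusters, re-implemented here because the classifier is the core of
the commonness stage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datamodel import OtuTable


class ClassificationError(ValueError):
    pass


@dataclass
class CommonnessAssignment:
    """Per-OTU fuzzy membership and hard common/rare label.

    ``table`` columns: otu_id (index), occupancy, abundance_index,
    membership_common, label. ``separation`` is a silhouette-like score of
    how cleanly the two clusters split (mean silhouette over OTUs).
    """

    table: pd.DataFrame
    centroids: np.ndarray  # (2, 2) in z-scored feature space; row 0 = common
    separation: float

    @property
    def labels(self) -> dict[str, str]:
        return dict(self.table["label"])

    def write_tsv(self, path) -> None:
        out = self.table.copy()
        out.index.name = "otu_id"
        out.to_csv(path, sep="\t")


def abundance_occupancy_features(table: OtuTable) -> pd.DataFrame:
    """Per-OTU feature pair: occupancy fraction and log10(1 + mean nonzero count).

    All-zero OTUs are excluded with a warning — they carry no
    abundance-frequency information.
    """
    present = table.counts > 0
    occ_counts = present.sum(axis=0)
    keep = occ_counts > 0
    if (~keep).any():
        dropped = [table.otu_ids[j] for j in np.flatnonzero(~keep)]
        warnings.warn(
            f"excluding {len(dropped)} all-zero OTU(s) from classification",
            stacklevel=2,
        )
    ids = [table.otu_ids[j] for j in np.flatnonzero(keep)]
    if len(ids) < 2:
        raise ClassificationError("need at least 2 non-empty OTUs to classify")
    occupancy = occ_counts[keep] / table.n_plots
    mean_nonzero = table.counts[:, keep].sum(axis=0) / occ_counts[keep]
    abundance_index = np.log10(1.0 + mean_nonzero)
    return pd.DataFrame(
        {"occupancy": occupancy, "abundance_index": abundance_index}, index=ids
    )


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    return (x - x.mean(axis=0)) / sd


def _kmeanspp_init(x: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    c0 = x[rng.integers(len(x))]
    d2 = ((x - c0) ** 2).sum(axis=1)
    if d2.sum() == 0:  # callers guard against this; belt and braces
        raise ClassificationError("all feature points identical; no partition defined")
    c1 = x[rng.choice(len(x), p=d2 / d2.sum())]
    return np.vstack([c0, c1])


def fuzzy_two_means(
    features: pd.DataFrame,
    fuzzifier: float = 2.0,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> CommonnessAssignment:
    """Fuzzy c-means with c = 2 on z-scored abundance-occupancy features.

    Memberships follow the classic update
    ``u_ik proportional to (1 / d_ik^2)^(1/(m-1))`` normalised over the two
    clusters; iteration stops when the centroid shift drops below ``tol``.
    The cluster whose centroid has the larger occupancy is called "common";
    an OTU is labelled common iff its common-membership exceeds 0.5 (an exact
    tie goes to rare — the conservative choice that keeps the common set
    minimal).
    """
    if fuzzifier <= 1.0:
        raise ClassificationError("fuzzifier must exceed 1")
    x_raw = features[["occupancy", "abundance_index"]].to_numpy(float)
    if len(x_raw) < 2 or np.unique(x_raw, axis=0).shape[0] < 2:
        raise ClassificationError("all feature points identical; no partition defined")
    x = _zscore(x_raw)
    rng = np.random.default_rng(seed)
    c = _kmeanspp_init(x, rng)
    expo = 1.0 / (fuzzifier - 1.0)
    u = None
    for _ in range(max_iter):
        d2 = ((x[:, None, :] - c[None, :, :]) ** 2).sum(axis=2)
        d2 = np.maximum(d2, 1e-300)
        w = (1.0 / d2) ** expo
        u = w / w.sum(axis=1, keepdims=True)
        um = u**fuzzifier
        c_new = (um.T @ x) / um.sum(axis=0)[:, None]
        shift = np.abs(c_new - c).max()
        c = c_new
        if shift < tol:
            break
    # exact-tie / coincident-point cleanup: points identical to a centroid
    # get full membership there
    d2 = ((x[:, None, :] - c[None, :, :]) ** 2).sum(axis=2)
    hit = d2 < 1e-290
    if hit.any():
        u = np.where(hit.any(axis=1, keepdims=True), hit / hit.sum(axis=1, keepdims=True), u)

    # identify the common cluster by the larger centroid occupancy
    # (z-scored occupancy is monotone in occupancy, so comparison is safe)
    common_cluster = int(np.argmax(c[:, 0]))
    membership_common = u[:, common_cluster]
    labels = hard_labels(membership_common)

    sep = _mean_silhouette(x, labels)
    out = pd.DataFrame(
        {
            "occupancy": features["occupancy"].to_numpy(float),
            "abundance_index": features["abundance_index"].to_numpy(float),
            "membership_common": membership_common,
            "label": labels,
        },
        index=features.index,
    )
    centroids = c[[common_cluster, 1 - common_cluster]]
    return CommonnessAssignment(out, centroids, sep)


def hard_labels(membership_common: np.ndarray) -> np.ndarray:
    """Hard common/rare call from fuzzy membership.

    Common iff membership strictly exceeds 0.5; an exact tie goes to rare,
    the conservative choice that keeps the common set minimal.
    """
    return np.where(np.asarray(membership_common) > 0.5, "common", "rare")


def _mean_silhouette(x: np.ndarray, labels: np.ndarray) -> float:
    """Mean silhouette of the hard 2-cluster split (0 when one cluster empty)."""
    groups = np.unique(labels)
    if groups.size < 2:
        return 0.0
    d = np.sqrt(((x[:, None, :] - x[None, :, :]) ** 2).sum(axis=2))
    sil = np.zeros(len(x))
    for g in groups:
        mask = labels == g
        other = ~mask
        n_in = mask.sum()
        for i in np.flatnonzero(mask):
            a = d[i, mask].sum() / max(n_in - 1, 1)
            b = d[i, other].mean()
            sil[i] = (b - a) / max(a, b) if max(a, b) > 0 else 0.0
    return float(sil.mean())


def classify_common_rare(
    table: OtuTable,
    fuzzifier: float = 2.0,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> CommonnessAssignment:
    """Convenience chain: features -> fuzzy two-means."""
    feats = abundance_occupancy_features(table)
    return fuzzy_two_means(feats, fuzzifier=fuzzifier, seed=seed, tol=tol, max_iter=max_iter)
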