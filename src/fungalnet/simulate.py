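"""Synthetic altitudinal-gradient communities with known ground truth.

Emulates a temperate-forest sampling frame: ~119 plots along a 1020-1770 m
gradient (lapse rate -0.6 degC / 100 m), a species pool in which a minority of
common taxa face a majority of rare taxa, Gaussian niche responses to
altitude, negative-binomial counts, and pairwise associations planted through
a Gaussian copula on the abundance latents. Every stochastic quantity is
driven by one integer seed, so identical inputs give bit-identical tables.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import nbinom, norm, poisson

from .datamodel import OtuTable

SHAPES = ("monotone_decreasing", "monotone_increasing", "hump_backed", "flat")


class ConfigError(ValueError):
    pass


@dataclass
class GradientDesign:
    """Sampling frame of the altitudinal gradient."""

    n_plots: int = 119
    altitude_range: tuple[float, float] = (1020.0, 1770.0)
    lapse_rate: float = -0.6  # degC per 100 m
    base_temperature: float = 29.0  # degC extrapolated to sea level
    covariate_shapes: dict[str, str] = field(
        default_factory=lambda: {
            "soil_temperature": "monotone_decreasing",
            "soil_moisture": "hump_backed",
            "ph": "monotone_increasing",
        }
    )
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_plots < 4:
            raise ConfigError("need at least 4 plots")
        lo, hi = self.altitude_range
        if not lo < hi:
            raise ConfigError("altitude_range must satisfy low < high")
        for cov, shape in self.covariate_shapes.items():
            if shape not in SHAPES:
                raise ConfigError(f"unknown shape {shape!r} for covariate {cov!r}")

    def altitudes(self) -> np.ndarray:
        lo, hi = self.altitude_range
        return np.linspace(lo, hi, self.n_plots)

    def plot_ids(self) -> list[str]:
        return [f"P{i + 1:03d}" for i in range(self.n_plots)]


def assign_zones(altitudes: np.ndarray, low: float, high: float) -> np.ndarray:
    """Equal-altitude terciles: LA / MA / HA."""
    edges = np.linspace(low, high, 4)
    idx = np.clip(np.searchsorted(edges, altitudes, side="right") - 1, 0, 2)
    return np.array(["LA", "MA", "HA"])[idx]


def assign_belts(altitudes: np.ndarray, low: float, high: float, n_belts: int = 10) -> np.ndarray:
    """Equal-width altitudinal belts B01..B10 (the niche-resource bins)."""
    edges = np.linspace(low, high, n_belts + 1)
    idx = np.clip(np.searchsorted(edges, altitudes, side="right") - 1, 0, n_belts - 1)
    return np.array([f"B{i + 1:02d}" for i in range(n_belts)])[idx]


def generate_environment(design: GradientDesign) -> pd.DataFrame:
    """Per-plot covariate table realising the configured altitudinal shapes.

    Soil temperature follows the lapse-rate line
    ``base + lapse_rate * altitude / 100``; other covariates are generated on
    a unit scale. Gaussian noise with sd ``design.noise_sd`` is added to all.
    """
    rng = np.random.default_rng(design.seed)
    alt = design.altitudes()
    lo, hi = design.altitude_range
    rel = (alt - lo) / (hi - lo)
    out = pd.DataFrame({"altitude": alt}, index=design.plot_ids())
    out.index.name = "plot_id"
    for cov, shape in design.covariate_shapes.items():
        if cov == "soil_temperature":
            base = design.base_temperature + design.lapse_rate * alt / 100.0
        elif shape == "monotone_decreasing":
            base = 1.0 - rel
        elif shape == "monotone_increasing":
            base = rel
        elif shape == "hump_backed":
            base = np.exp(-((rel - 0.5) ** 2) / (2 * 0.18**2))
        else:  # flat
            base = np.ones_like(rel)
        out[cov] = base + rng.normal(0.0, design.noise_sd, size=alt.size)
    return out


@dataclass
class SpeciesPool:
    """Gaussian niche parameters of the simulated pool.

    Common species carry larger abundance scales and wider niches than rare
    species, so their realised occupancy and mean abundance stochastically
    dominate the rare group.
    """

    niche_optimum: np.ndarray  # metres
    niche_width: np.ndarray  # metres (sd of the Gaussian response)
    abundance_scale: np.ndarray  # expected count at the optimum
    dispersion: np.ndarray  # NB size parameter; np.inf means Poisson
    labels: np.ndarray  # "common" | "rare"
    otu_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if (self.niche_width <= 0).any():
            raise ConfigError("niche_width must be positive")
        if not self.otu_ids:
            self.otu_ids = [f"OTU{i + 1:04d}" for i in range(self.size)]

    @property
    def size(self) -> int:
        return self.niche_optimum.size


def default_pool(
    n_common: int = 50,
    n_rare: int = 450,
    design: GradientDesign | None = None,
    seed: int = 0,
    common_scale: float = 80.0,
    rare_scale: float = 4.0,
    dispersion: float = 2.0,
) -> SpeciesPool:
    """Separated default pool: few common (abundant, wide-niche, ubiquitous)
    versus many rare (sparse, narrow-niche) species."""
    design = design or GradientDesign()
    rng = np.random.default_rng(seed)
    lo, hi = design.altitude_range
    n = n_common + n_rare
    labels = np.array(["common"] * n_common + ["rare"] * n_rare)
    common = labels == "common"
    opt = rng.uniform(lo, hi, n)
    width = np.where(common, rng.uniform(300.0, 700.0, n), rng.uniform(80.0, 200.0, n))
    scale = np.where(
        common,
        rng.lognormal(np.log(common_scale), 0.4, n),
        rng.lognormal(np.log(rare_scale), 0.6, n),
    )
    return SpeciesPool(opt, width, scale, np.full(n, float(dispersion)), labels)


@dataclass(frozen=True)
class PlantedAssociation:
    """Ground-truth pairwise association induced through the latent copula."""

    pair: tuple[int, int]  # OTU column indices
    sign: int  # +1 / -1
    strength: float  # latent correlation magnitude in (0, 1]

    def __post_init__(self) -> None:
        if self.pair[0] == self.pair[1]:
            raise ConfigError("self-pair association")
        if not (0.0 < self.strength <= 1.0):
            raise ConfigError("association strength must lie in (0, 1]")
        if self.sign not in (+1, -1):
            raise ConfigError("association sign must be +1 or -1")


@dataclass
class SyntheticTruth:
    """Planted ground truth serialised alongside the generated table."""

    labels: dict[str, str]  # otu_id -> common/rare
    associations: list[dict]  # otu_i, otu_j, sign, strength
    module_membership: dict[str, int] | None = None

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "labels": self.labels,
                    "associations": self.associations,
                    "module_membership": self.module_membership,
                },
                fh,
                indent=1,
            )

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        with open(path) as fh:
            doc = json.load(fh)
        return cls(doc["labels"], doc["associations"], doc.get("module_membership"))


def plant_association_cohort(
    pool: SpeciesPool,
    n_positive: int,
    n_negative: int,
    strength: float = 0.9,
    occupancy_mu: float = 1.0,
    flat_width: float = 5000.0,
) -> list[PlantedAssociation]:
    """Reserve the last ``2*(n_positive+n_negative)`` pool members as
    association partners with flat, mid-occupancy niches.

    An association is only observable where both partners can occur, so the
    partners are made wide-niche generalists at roughly 50% occupancy — the
    operating point where presence-absence statistics are most informative.
    The partners' abundance scale is low, so they stay in the rare group.
    """
    n_pairs = n_positive + n_negative
    if 2 * n_pairs > pool.size:
        raise ConfigError("pool too small for the requested association cohort")
    first = pool.size - 2 * n_pairs
    assocs = []
    for t in range(n_pairs):
        i, j = first + 2 * t, first + 2 * t + 1
        sign = +1 if t < n_positive else -1
        for col in (i, j):
            pool.niche_width[col] = flat_width
            pool.abundance_scale[col] = occupancy_mu
            pool.niche_optimum[col] = sum(GradientDesign().altitude_range) / 2
        assocs.append(PlantedAssociation((i, j), sign, strength))
    return assocs


def sample_community(
    design: GradientDesign,
    pool: SpeciesPool,
    associations: list[PlantedAssociation] | None = None,
    seed: int = 0,
) -> tuple[OtuTable, SyntheticTruth]:
    """Draw one plot-by-OTU count table from the niche model.

    Expected count of species *s* at plot *p* is
    ``scale_s * exp(-(alt_p - opt_s)^2 / (2 width_s^2))``; counts are
    negative-binomial around that mean (Poisson when dispersion is inf).
    Planted associations are induced by correlating the standard-normal
    abundance latents of the pair before the quantile transform, which
    preserves each member's marginal while controlling the sign and strength
    of their rank dependence.
    """
    if pool.size == 0:
        raise ConfigError("empty species pool")
    associations = list(associations or [])
    used: set[int] = set()
    for a in associations:
        for col in a.pair:
            if col in used:
                raise ConfigError(f"OTU index {col} appears in more than one association")
            if not 0 <= col < pool.size:
                raise ConfigError(f"association index {col} outside pool")
            used.add(col)

    rng = np.random.default_rng(seed)
    alt = design.altitudes()
    mu = pool.abundance_scale[None, :] * np.exp(
        -((alt[:, None] - pool.niche_optimum[None, :]) ** 2)
        / (2.0 * pool.niche_width[None, :] ** 2)
    )
    z = rng.standard_normal((design.n_plots, pool.size))
    for a in associations:
        i, j = a.pair
        noise = rng.standard_normal(design.n_plots)
        z[:, j] = a.sign * (a.strength * z[:, i] + np.sqrt(1.0 - a.strength**2) * noise)
    u = norm.cdf(z)
    counts = np.empty_like(mu, dtype=np.int64)
    mu_safe = np.maximum(mu, 1e-12)
    for s in range(pool.size):
        k = pool.dispersion[s]
        if np.isinf(k):
            counts[:, s] = poisson.ppf(u[:, s], mu_safe[:, s]).astype(np.int64)
        else:
            counts[:, s] = nbinom.ppf(u[:, s], k, k / (k + mu_safe[:, s])).astype(np.int64)

    lo, hi = design.altitude_range
    meta = pd.DataFrame(
        {
            "altitude": alt,
            "zone": assign_zones(alt, lo, hi),
            "belt": assign_belts(alt, lo, hi),
        },
        index=design.plot_ids(),
    )
    meta.index.name = "plot_id"
    table = OtuTable(counts, list(pool.otu_ids), design.plot_ids(), meta)
    truth = SyntheticTruth(
        labels=dict(zip(pool.otu_ids, pool.labels)),
        associations=[
            {
                "otu_i": pool.otu_ids[a.pair[0]],
                "otu_j": pool.otu_ids[a.pair[1]],
                "sign": a.sign,
                "strength": a.strength,
            }
            for a in associations
        ],
    )
    return table, truth


def default_scene(
    seed: int = 0,
    n_common: int = 50,
    n_rare: int = 450,
    n_positive: int = 12,
    n_negative: int = 8,
    strength: float = 0.9,
    design: GradientDesign | None = None,
) -> tuple[OtuTable, SyntheticTruth]:
    """The standard demo scene: 119 plots, 1020-1770 m, three tercile zones,
    50 common + 450 rare OTUs, 20 planted associations at strength 0.9."""
    design = design or GradientDesign(seed=seed)
    pool = default_pool(n_common, n_rare, design, seed=seed)
    assocs = plant_association_cohort(pool, n_positive, n_negative, strength)
    return sample_community(design, pool, assocs, seed=seed)


def independence_scene(
    seed: int = 0,
    n_plots: int = 119,
    n_otus: int = 64,
    mean_abundance: float = 0.7,
    species_sdlog: float = 0.5,
    depth_sdlog: float = 0.3,
) -> OtuTable:
    """Null scene for type-I-error studies: independent Poisson counts from a
    plot-effect x species-effect independence model at ~50% occupancy.

    This is the data-generating model whose margin-conditional distribution
    the fixed-margin (r2dtable) null reproduces exactly, so association tests
    run on it measure their true false-positive rate.
    """
    rng = np.random.default_rng(seed)
    species = rng.lognormal(np.log(mean_abundance), species_sdlog, n_otus)
    depth = rng.lognormal(0.0, depth_sdlog, n_plots)
    counts = rng.poisson(np.outer(depth, species))
    design = GradientDesign(n_plots=n_plots, seed=seed)
    alt = design.altitudes()
    lo, hi = design.altitude_range
    meta = pd.DataFrame(
        {
            "altitude": alt,
            "zone": assign_zones(alt, lo, hi),
            "belt": assign_belts(alt, lo, hi),
        },
        index=design.plot_ids(),
    )
    meta.index.name = "plot_id"
    otu_ids = [f"OTU{i + 1:04d}" for i in range(n_otus)]
    return OtuTable(counts, otu_ids, design.plot_ids(), meta)
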