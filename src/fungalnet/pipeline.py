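"""End-to-end orchestration: classify -> co-occupation -> co-occurrence ->
topology, per altitudinal zone, with stage logging, a resolved-config
snapshot, and a one-command synthetic demo with a ground-truth recovery
report.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import cooccurrence
from .commonness import classify_common_rare
from .cooccupation import cooccupation_network
from .datamodel import OtuTable, read_otu_table, write_otu_table
from .simulate import SyntheticTruth, default_scene
from .topology import summarize

log = logging.getLogger(__name__)

ZONES = ("LA", "MA", "HA")


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage and entity."""


@dataclass
class RunConfig:
    """Resolved parameters of one analysis run. ``seed`` drives every
    stochastic stage (null ensembles, classifier init, community detection)."""

    seed: int
    counts_path: str | None = None
    metadata_path: str | None = None
    format: str = "tsv"
    otus_as_rows: bool = True
    fuzzifier: float = 2.0
    n_null: int = 999
    alpha: float = 0.05
    rho_min: float = 0.65
    q_max: float = 0.01
    min_fraction: float = 0.5
    adjust: str = "fdr_bh"
    null_model: str = "r2dtable"
    niche_binning: str = "belt"
    zones: tuple[str, ...] = ZONES
    extra: dict = field(default_factory=dict)

    def validate(self) -> None:
        checks = [
            (0.0 < self.alpha < 1.0, f"alpha {self.alpha} outside (0, 1)"),
            (0.0 <= self.rho_min <= 1.0, f"rho_min {self.rho_min} outside [0, 1]"),
            (0.0 < self.q_max <= 1.0, f"q_max {self.q_max} outside (0, 1]"),
            (0.0 < self.min_fraction <= 1.0, f"min_fraction {self.min_fraction} outside (0, 1]"),
            (self.fuzzifier > 1.0, f"fuzzifier {self.fuzzifier} must exceed 1"),
            (self.n_null >= 1, "n_null must be >= 1"),
            (self.null_model in ("r2dtable", "curveball"), f"unknown null model {self.null_model!r}"),
            (self.niche_binning in ("belt", "zone", "plot"), f"unknown binning {self.niche_binning!r}"),
        ]
        bad = [msg for ok, msg in checks if not ok]
        if bad:
            raise StageError("config validation failed: " + "; ".join(bad))


def _stage_seed(seed: int, stage: str, zone: str = "") -> int:
    """Deterministic per-stage sub-seed, kept below 2**31."""
    h = int(seed) & 0x7FFFFFFF
    for ch in f"{stage}:{zone}":
        h = (h * 31 + ord(ch)) % (2**31 - 1)
    return h


def _setup_run_logging(outdir: Path) -> logging.Handler:
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    root = logging.getLogger("fungalnet")
    root.setLevel(logging.INFO)
    root.addHandler(handler)
    return handler


def run(
    config: RunConfig,
    outdir: str | Path,
    table: OtuTable | None = None,
    include_global: bool = False,
) -> Path:
    """Execute the full per-zone analysis; returns the run directory.

    The directory layout is deterministic: classified labels, per-zone
    co-occupation and co-occurrence edge lists (TSV + GraphML), two
    topology-summary tables, the run log, and the resolved-config snapshot
    that suffices to replay the run bit-identically.
    """
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = _setup_run_logging(outdir)
    try:
        with open(outdir / "config.json", "w") as fh:
            json.dump(asdict(config), fh, indent=1, default=str)

        if table is None:
            if not config.counts_path or not config.metadata_path:
                raise StageError("stage load: no input table and no counts/metadata paths")
            try:
                table = read_otu_table(
                    config.counts_path, config.metadata_path,
                    format=config.format, otus_as_rows=config.otus_as_rows,
                )
            except Exception as exc:
                raise StageError(f"stage load failed: {exc}") from exc
        log.info("loaded table: %d plots x %d OTUs", table.n_plots, table.n_otus)

        try:
            zones_present = table.zones()
        except Exception as exc:
            raise StageError(f"stage zoning failed: {exc}") from exc

        try:
            assignment = classify_common_rare(
                table, fuzzifier=config.fuzzifier, seed=_stage_seed(config.seed, "classify")
            )
        except Exception as exc:
            raise StageError(f"stage classify failed: {exc}") from exc
        assignment.write_tsv(outdir / "commonness.tsv")
        n_common = int((assignment.table["label"] == "common").sum())
        log.info("classified %d common / %d rare OTUs (separation %.3f)",
                 n_common, len(assignment.table) - n_common, assignment.separation)

        occup_nets, cooc_nets = {}, {}
        zone_list = list(config.zones)
        if include_global:
            zone_list.append("ALL")
        for zone in zone_list:
            ztab = table if zone == "ALL" else table.zone_table(zone)
            if zone != "ALL" and zone not in set(zones_present):
                raise StageError(f"stage zoning: zone {zone} has no plots")
            try:
                net = cooccupation_network(
                    ztab,
                    n_null=config.n_null,
                    alpha=config.alpha,
                    seed=_stage_seed(config.seed, "cooccupation", zone),
                    null_model=config.null_model,
                    zone=zone,
                )
            except Exception as exc:
                raise StageError(f"stage co-occupation failed in zone {zone}: {exc}") from exc
            net.set_groups(assignment.labels)
            occup_nets[zone] = net
            pos, neg = net.edge_counts()
            log.info("co-occupation %s: %d nodes, %d+ / %d- edges", zone, net.n_nodes, pos, neg)
            net.write_tsv(outdir / f"cooccupation_{zone}.tsv")
            net.write_graphml(outdir / f"cooccupation_{zone}.graphml")

            if zone == "ALL":
                continue
            try:
                cnet, report = cooccurrence.cooccurrence_network(
                    ztab,
                    min_fraction=config.min_fraction,
                    rho_min=config.rho_min,
                    q_max=config.q_max,
                    adjust=config.adjust,
                    zone=zone,
                )
            except cooccurrence.NetworkRefused as exc:
                raise StageError(f"stage co-occurrence refused in zone {zone}: {exc}") from exc
            except Exception as exc:
                raise StageError(f"stage co-occurrence failed in zone {zone}: {exc}") from exc
            cnet.set_groups(assignment.labels)
            cooc_nets[zone] = cnet
            pos, neg = cnet.edge_counts()
            log.info(
                "co-occurrence %s: prevalence kept %d/%d OTUs; %d+ / %d- edges",
                zone, len(report.kept), ztab.n_otus, pos, neg,
            )
            cnet.write_tsv(outdir / f"cooccurrence_{zone}.tsv")
            cnet.write_graphml(outdir / f"cooccurrence_{zone}.graphml")

        try:
            topo_seed = _stage_seed(config.seed, "topology")
            per_zone_occup = {z: n for z, n in occup_nets.items() if z != "ALL"}
            summary_occ = summarize(per_zone_occup, assignment, table,
                                    binning=config.niche_binning, seed=topo_seed)
            summary_cor = summarize(cooc_nets, assignment, table,
                                    binning=config.niche_binning, seed=topo_seed)
        except Exception as exc:
            raise StageError(f"stage topology failed: {exc}") from exc
        summary_occ.to_csv(outdir / "topology_cooccupation.tsv", sep="\t", index=False)
        summary_cor.to_csv(outdir / "topology_cooccurrence.tsv", sep="\t", index=False)
        log.info("run complete: %s", outdir)
        return outdir
    finally:
        logging.getLogger("fungalnet").removeHandler(handler)
        handler.close()


def recovery_report(outdir: Path, truth: SyntheticTruth) -> dict:
    """Compare run outputs against the planted ground truth."""
    import pandas as pd

    assigned = pd.read_csv(outdir / "commonness.tsv", sep="\t", index_col=0)
    common_ids = set(assigned.index[assigned["label"] == "common"])
    correct = sum(
        1 for otu, lab in truth.labels.items()
        if (otu in common_ids) == (lab == "common")
    )
    label_acc = correct / len(truth.labels)

    edge_signs: dict[frozenset, int] = {}
    for path in sorted(outdir.glob("cooccupation_*.tsv")):
        df = pd.read_csv(path, sep="\t")
        for _, row in df.iterrows():
            key = frozenset((row["otu_i"], row["otu_j"]))
            edge_signs[key] = +1 if row["sign"] == "+" else -1

    n_planted = len(truth.associations)
    recovered = sign_ok = 0
    for a in truth.associations:
        key = frozenset((a["otu_i"], a["otu_j"]))
        if key in edge_signs:
            recovered += 1
            if edge_signs[key] == a["sign"]:
                sign_ok += 1
    return {
        "label_accuracy": label_acc,
        "n_otus": len(truth.labels),
        "n_planted_associations": n_planted,
        "planted_edge_recall": recovered / n_planted if n_planted else float("nan"),
        "planted_sign_accuracy": sign_ok / recovered if recovered else float("nan"),
    }


def demo(seed: int, outdir: str | Path, **scene_kwargs) -> Path:
    """Full pipeline on the default 119-plot synthetic scene.

    Generates the community, writes table + truth, runs every stage per zone
    plus a gradient-wide co-occupation network (zone ``ALL``, used for the
    planted-association recovery report), and writes ``recovery.json``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    table, truth = default_scene(seed=seed, **scene_kwargs)
    write_otu_table(table, outdir / "counts.tsv", outdir / "metadata.tsv")
    truth.to_json(outdir / "truth.json")
    config = RunConfig(seed=seed)
    run(config, outdir, table=table, include_global=True)
    report = recovery_report(outdir, truth)
    with open(outdir / "recovery.json", "w") as fh:
        json.dump(report, fh, indent=1)
    return outdir
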