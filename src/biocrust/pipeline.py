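"""Configuration-driven end-to-end orchestration.

Runs the full analysis shape on an ASV table (read from disk or simulated):
rarefaction -> diversity (Shannon, Bray-Curtis, PCoA, PERMANOVA) ->
per-group co-occurrence network + topology panel + Zi-Pi roles ->
per-group neutral-model fit -> composites + path model. Every stochastic
stage's seed goes into a manifest so a rerun of the same config reproduces
every output.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .abundance import (
    AbundanceTable,
    SampleMetadata,
    rarefy,
    read_abundance_table,
    read_metadata,
)
from .diversity import bray_curtis, pcoa, permanova, shannon_per_sample
from .network import (
    build_network,
    roles_to_dataframe,
    topology_panel,
    write_network,
    zipi,
)
from .neutral import fit_ncm, ncm_report
from .pathmodel import PathModel, PathSpec, composite_pc1
from .simulate import BlockSpec, SimulationConfig, simulate_neutral

logger = logging.getLogger("biocrust.pipeline")

__all__ = ["PipelineConfig", "run_pipeline", "derived_percent_change"]


def derived_percent_change(a: float, b: float) -> float:
    """Percent change of a relative to b, 100*(a-b)/b, rounded half-up to
    2 decimals for reporting."""
    if b == 0:
        raise ValueError("reference value must be nonzero")
    raw = 100.0 * (a - b) / b
    return float(Decimal(repr(raw)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass
class PipelineConfig:
    """All knobs of a pipeline run; round-trips losslessly through YAML."""

    # inputs: either file paths or a simulate block
    table_path: str | None = None
    metadata_path: str | None = None
    orientation: str = "samples-in-rows"
    simulate: dict | None = None  # keys: groups, n_replicates, + SimulationConfig knobs
    # stages
    rarefaction_depth: int = 20000
    rarefaction_seed: int = 1
    rho_threshold: float = 0.6
    q_threshold: float = 0.001
    top_n: int = 300
    n_null: int = 100
    network_seed: int = 1
    ncm_n_boot: int = 1000
    ncm_seed: int = 1
    permanova_permutations: int = 999
    permanova_seed: int = 1
    path_edges: list[str] = field(
        default_factory=lambda: [
            "inoculation -> community_axis",
            "community_axis -> growth",
        ]
    )
    output_dir: str = "pipeline_out"

    def __post_init__(self) -> None:
        if not (0 < self.rho_threshold <= 1 and 0 < self.q_threshold <= 1):
            raise ValueError("network thresholds must lie in (0, 1]")
        if self.rarefaction_depth < 1 or self.top_n < 1:
            raise ValueError("depth and top_n must be positive")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.__dict__, fh, sort_keys=True)


def _simulated_inputs(cfg: PipelineConfig) -> tuple[AbundanceTable, SampleMetadata]:
    """Build a multi-group table from the simulate block: one neutral
    community per group (group index perturbs the seed), stacked."""
    block = dict(cfg.simulate or {})
    groups = block.pop("groups", ["S", "SB", "SM", "SMB", "SL", "SLB"])
    n_rep = int(block.pop("n_replicates", 5))
    nm_by_group = block.pop("Nm_by_group", None)
    base_seed = int(block.pop("seed", cfg.rarefaction_seed))
    tables = []
    meta_rows = []
    for gi, group in enumerate(groups):
        sim = SimulationConfig(
            n_samples=n_rep, seed=base_seed + 1000 * gi, **block
        )
        if nm_by_group:
            sim.Nm = float(nm_by_group[gi])
        t = simulate_neutral(sim)
        ids = [f"{group}_{r + 1}" for r in range(n_rep)]
        tables.append(AbundanceTable(ids, t.asv_ids, t.counts))
        meta_rows += [
            {"sample_id": s, "group": group, "replicate": r + 1}
            for r, s in enumerate(ids)
        ]
    counts = np.vstack([t.counts for t in tables])
    sample_ids = [s for t in tables for s in t.sample_ids]
    table = AbundanceTable(sample_ids, tables[0].asv_ids, counts)
    return table, SampleMetadata(pd.DataFrame(meta_rows))


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis; returns a report bundle (dict of artifacts)
    and writes TSV/JSON outputs plus a manifest under config.output_dir."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "config": {k: v for k, v in config.__dict__.items()},
        "stages": {},
    }
    bundle: dict = {}

    def stage(name):
        logger.info("stage %s", name)
        manifest["stages"][name] = {"t_start": time.time()}
        return time.time()

    def done(name, t0, **extra):
        manifest["stages"][name].update(t_seconds=round(time.time() - t0, 3), **extra)

    # ---- inputs
    t0 = stage("input")
    if config.simulate is not None:
        table, meta = _simulated_inputs(config)
    else:
        if config.table_path is None or config.metadata_path is None:
            raise ValueError("need table_path+metadata_path or a simulate block")
        table = read_abundance_table(config.table_path, config.orientation)
        meta = read_metadata(config.metadata_path)
    done("input", t0, n_samples=table.n_samples, n_asvs=table.n_asvs)

    # ---- rarefaction
    t0 = stage("rarefy")
    depth = min(config.rarefaction_depth, int(table.sample_sums().min()))
    rare = rarefy(table, depth, seed=config.rarefaction_seed)
    done("rarefy", t0, depth=depth, seed=config.rarefaction_seed)

    # ---- diversity
    t0 = stage("diversity")
    alpha = shannon_per_sample(rare)
    pd.Series(alpha, name="shannon").to_csv(
        out / "alpha_diversity.tsv", sep="\t", index_label="sample_id"
    )
    dm = bray_curtis(rare)
    pd.DataFrame(dm.d, index=dm.ids, columns=dm.ids).to_csv(
        out / "bray_curtis.tsv", sep="\t", index_label="sample_id"
    )
    ordn = pcoa(dm, n_axes=2)
    coords = pd.DataFrame(
        ordn.coordinates,
        index=ordn.ids,
        columns=[f"PCo{i + 1}" for i in range(ordn.coordinates.shape[1])],
    )
    with open(out / "pcoa.tsv", "w") as fh:
        fh.write("# explained: " + ", ".join(f"{e:.4f}" for e in ordn.explained) + "\n")
        coords.to_csv(fh, sep="\t", index_label="sample_id")
    perm = permanova(
        dm, meta, n_permutations=config.permanova_permutations,
        seed=config.permanova_seed,
    )
    with open(out / "permanova.json", "w") as fh:
        json.dump(
            {"pseudo_F": perm.pseudo_F, "p_value": perm.p_value,
             "n_permutations": perm.n_permutations, "seed": perm.seed},
            fh, indent=2,
        )
    bundle.update(alpha=alpha, distance=dm, ordination=ordn, permanova=perm)
    done("diversity", t0, permanova_seed=config.permanova_seed)

    # ---- per-group networks and NCM
    t0 = stage("per_group")
    panels = {}
    roles = {}
    fits = {}
    networks = {}
    for group in meta.group_names:
        samples = [s for s in meta.samples_in_group(group) if s in rare.sample_ids]
        if len(samples) < 4:
            logger.warning("group %s has %d samples; skipping", group, len(samples))
            continue
        if len(samples) < 10:
            logger.warning(
                "group %s: correlations on n=%d samples are fragile", group, len(samples)
            )
        sub = rare.subset_samples(samples).drop_empty_asvs()
        net = build_network(
            sub,
            rho_threshold=config.rho_threshold,
            q_threshold=config.q_threshold,
            top_n=config.top_n,
            seed=config.network_seed,
        )
        networks[group] = net
        if net.n_edges > 0:
            panels[group] = topology_panel(
                net, n_null=config.n_null, seed=config.network_seed
            )
            roles[group] = zipi(net)
            write_network(net, out / f"network_{group}.graphml", format="graphml")
            write_network(net, out / f"network_{group}_edges.tsv", format="edgelist")
        else:
            logger.warning("group %s: empty network (flagged in panel table)", group)
        fits[group] = fit_ncm(
            sub, n_boot=config.ncm_n_boot, seed=config.ncm_seed, group=group
        )
        fits[group].write_json(out / f"ncm_{group}.json")
        fits[group].write_partition_tsv(out / f"ncm_partition_{group}.tsv")
    if panels:
        panel_df = pd.DataFrame(
            {g: p.to_series() for g, p in panels.items()}
        ).T.round(2)
        panel_df.to_csv(out / "topology_panel.tsv", sep="\t", index_label="group")
        role_df = pd.concat(
            {g: roles_to_dataframe(r) for g, r in roles.items()}, names=["group"]
        )
        role_df.to_csv(out / "node_roles.tsv", sep="\t")
        bundle.update(panels=panels, roles=roles)
    report = ncm_report(fits)
    report.round({"R2": 3}).to_csv(out / "ncm_report.tsv", sep="\t", index=False)
    bundle.update(networks=networks, ncm_fits=fits, ncm_report=report)
    done("per_group", t0, groups=list(fits), ncm_seed=config.ncm_seed,
         network_seed=config.network_seed)

    # ---- path model on composites
    t0 = stage("path_model")
    groups = meta.groups_for(rare.sample_ids)
    inoculation = np.array([0.0 if g in ("S", "SB") else 1.0 for g in groups])
    community_axis = composite_pc1(rare, method="pcoa-on-bray")
    # growth proxy from the community composition scale (no external
    # phenotype table in the generic pipeline); a real study would supply
    # measured OM/coverage here via the pathmodel API directly.
    growth = pd.DataFrame(
        {"inoculation": inoculation, "community_axis": community_axis},
        index=rare.sample_ids,
    )
    growth["growth"] = shannon_per_sample(rare).values()
    if inoculation.std() > 0:
        path_res = PathModel(growth, PathSpec.from_strings(config.path_edges)).fit()
        path_res.write_json(out / "path_model.json")
        bundle["path_model"] = path_res
    else:
        logger.warning("single inoculation level; path model skipped")
    done("path_model", t0)

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    bundle["manifest"] = manifest
    return bundle
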