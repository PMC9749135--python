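"""End-to-end orchestration: simulate/ingest -> preprocess -> diversity ->
EFS -> associations -> network -> regressions, with a reproducibility manifest."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .tables import (AbundanceTable, align_samples, read_abundance_table,
                     read_env_table, read_sample_frame, write_abundance_table,
                     write_frame)
from . import preprocess, diversity, efs, association, network, regress, simulate

log = logging.getLogger("ftstab")

# stage names hashed with the root seed for per-stage reproducibility
_STAGES = ("rarefy", "mantel", "simulate")


def _stage_seed(root_seed: int, stage: str) -> int:
    digest = hashlib.sha256(f"{root_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2 ** 31)


@dataclass
class RunConfig:
    """Serializable configuration of a full pipeline run."""

    out_dir: str = "ftstab_out"
    seed: int = 0
    # input: either generated...
    simulate: bool = True
    generator_preset: str = "pearl-river"  # or "small"
    # ...or ingested from the canonical TSV formats
    bacteria_path: str | None = None
    archaea_path: str | None = None
    genes_path: str | None = None
    genes_annotation_path: str | None = None
    meta_path: str | None = None
    env_path: str | None = None
    # analysis knobs
    rarefy_depth: str | int = "min"
    dominance_threshold: float = 0.01
    f_level: str = "pathway"  # or "gene"
    tmic_norm: str = "block"
    mantel_permutations: int = 999
    mantel_method: str = "pearson"
    network_r_threshold: float = 0.6
    network_alpha: float = 0.05
    env_variables: tuple[str, ...] = ("WT", "pH", "DO", "Chl_a", "DSi", "SO4")

    def validate(self) -> None:
        if self.f_level not in ("pathway", "gene"):
            raise ValueError("f_level must be 'pathway' or 'gene'")
        if self.tmic_norm not in ("block", "joint"):
            raise ValueError("tmic_norm must be 'block' or 'joint'")
        if not self.simulate:
            required = [self.bacteria_path, self.archaea_path, self.genes_path,
                        self.meta_path]
            if any(p is None for p in required):
                raise ValueError("non-simulated runs need bacteria/archaea/"
                                 "genes/meta paths")

    def to_yaml(self) -> str:
        return yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        raw = yaml.safe_load(text) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "env_variables" in raw:
            raw["env_variables"] = tuple(raw["env_variables"])
        return cls(**raw)

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]


def _load_inputs(config: RunConfig):
    if config.simulate:
        if config.generator_preset == "small":
            gcfg = simulate.small_config(seed=_stage_seed(config.seed, "simulate"))
        else:
            gcfg = simulate.GeneratorConfig(seed=_stage_seed(config.seed, "simulate"))
        ds = simulate.generate_dataset(gcfg)
        return ds.bacteria, ds.archaea, ds.genes, ds.meta, ds.env
    bac = read_abundance_table(config.bacteria_path, "bacteria", "counts")
    arc = read_abundance_table(config.archaea_path, "archaea", "counts")
    genes = read_abundance_table(config.genes_path, "function", "copies",
                                 annotation_path=config.genes_annotation_path)
    meta = read_sample_frame(config.meta_path)
    env = read_env_table(config.env_path) if config.env_path else None
    return bac, arc, genes, meta, env


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run(config: RunConfig) -> dict:
    """Execute every stage, write all outputs under ``out_dir``, return the manifest."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "inputs"
    try:
        bac, arc, genes, meta, env = _load_inputs(config)
        bundle = align_samples([bac, arc, genes], meta=meta, env=env)
        bac, arc, genes = bundle.tables
        meta, env = bundle.meta, bundle.env

        stage = "preprocess"
        bac_rare, _ = preprocess.rarefy(bac, config.rarefy_depth,
                                        seed=_stage_seed(config.seed, "rarefy"))
        arc_rare, _ = preprocess.rarefy(arc, config.rarefy_depth,
                                        seed=_stage_seed(config.seed, "rarefy") + 1)
        # rarefaction can drop shallow samples: re-align everything
        bundle = align_samples([bac_rare, arc_rare, genes], meta=meta, env=env)
        bac_rare, arc_rare, genes = bundle.tables
        meta, env = bundle.meta, bundle.env
        bac_rel = preprocess.aggregate_dominant(
            preprocess.to_relative(bac_rare), config.dominance_threshold)
        arc_rel = preprocess.aggregate_dominant(
            preprocess.to_relative(arc_rare), config.dominance_threshold)
        pathways = preprocess.map_genes_to_pathways(genes)
        func_table = pathways if config.f_level == "pathway" else genes
        func_rel = preprocess.to_relative(func_table)

        stage = "diversity"
        div = pd.concat([diversity.shannon(t)
                         for t in (bac_rare, arc_rare, genes)], ignore_index=True)

        stage = "efs"
        summaries = efs.distance_summaries(func_rel, bac_rel, arc_rel,
                                           tmic_norm=config.tmic_norm)
        efs_result = efs.ft_ratio(summaries)
        efs_result["CF:CD"] = preprocess.cf_cd_ratio(pathways)
        water_ratio = efs.paired_water_ratio(efs_result, meta)
        contrast = efs.group_contrast(
            efs_result.loc[meta["water_type"] != "released", "ft_mic"],
            meta.loc[meta["water_type"] != "released", "water_type"],
            labels=("inflow", "reservoir"))

        stage = "association"
        mantel_rows = []
        if env is not None:
            d_func = efs.euclidean_distance_matrix(func_rel, "function")
            d_bac = efs.euclidean_distance_matrix(bac_rel, "bacteria")
            d_arc = efs.euclidean_distance_matrix(arc_rel, "archaea")
            for var in config.env_variables:
                if var not in env.columns:
                    continue
                d_env = association.env_distance(env, var)
                for dm in (d_func, d_bac, d_arc):
                    res = association.mantel(
                        dm, d_env, n_perm=config.mantel_permutations,
                        method=config.mantel_method,
                        seed=_stage_seed(config.seed, f"mantel:{dm.source}:{var}"))
                    mantel_rows.append({"matrix": dm.source, "env_variable": var,
                                        "r": res.r, "p": res.p,
                                        "n_perm": res.n_perm, "method": res.method})
        mantel_report = pd.DataFrame(
            mantel_rows, columns=["matrix", "env_variable", "r", "p",
                                  "n_perm", "method"])

        stage = "network"
        bac_block = bac_rel.data.add_prefix("bac|").T
        arc_block = arc_rel.data.add_prefix("arc|").T
        stacked = pd.concat([bac_block, arc_block, func_rel.data.T])
        kinds = {v: "bacteria" for v in bac_block.index}
        kinds.update({v: "archaea" for v in arc_block.index})
        kinds.update({v: "gene" for v in func_rel.data.columns})
        if env is not None:
            env_block = env[list(config.env_variables)].T
            stacked = pd.concat([stacked, env_block])
            kinds.update({v: "env" for v in config.env_variables})
        graph = network.build_network(stacked, r_threshold=config.network_r_threshold,
                                      alpha=config.network_alpha, node_kinds=kinds)
        topo = network.topology(graph)

        stage = "regress"
        regress_rows = []
        if env is not None and "yield" in env.columns:
            mask = efs_result["t_bac_to_t_arc"].notna()
            if mask.sum() >= 3:
                fit = regress.linfit(efs_result.loc[mask, "t_bac_to_t_arc"],
                                     env.loc[mask, "yield"])
                regress_rows.append({"fit": "yield_vs_tbac_tarc",
                                     **dataclasses.asdict(fit)})
        deltas = regress.seasonal_ft_difference(efs_result, meta)
        h = meta.groupby("reservoir")["hydraulic_load"].first()
        if len(deltas.dropna()) >= 3:
            fit = regress.hydraulic_regression(deltas, h)
            regress_rows.append({"fit": "seasonal_dft_vs_log10H",
                                 **dataclasses.asdict(fit)})
        regress_report = pd.DataFrame(regress_rows)
    except Exception as err:
        raise RuntimeError(f"pipeline failed in stage {stage!r}: {err}") from err

    # ---- outputs ---------------------------------------------------------
    outputs: dict[str, Path] = {}

    def emit_frame(name: str, df: pd.DataFrame, index: bool = False) -> None:
        path = out / f"{name}.tsv"
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            df.to_csv(fh, sep="\t", index=index, lineterminator="\n")
        outputs[name] = path

    write_abundance_table(bac_rare, out / "bacteria_rarefied.tsv")
    outputs["bacteria_rarefied"] = out / "bacteria_rarefied.tsv"
    write_abundance_table(arc_rare, out / "archaea_rarefied.tsv")
    outputs["archaea_rarefied"] = out / "archaea_rarefied.tsv"
    write_abundance_table(func_rel, out / "function_relative.tsv")
    outputs["function_relative"] = out / "function_relative.tsv"
    emit_frame("diversity", div)
    emit_frame("efs_per_sample", efs_result.round(12), index=True)
    emit_frame("water_ratio", water_ratio.reset_index())
    emit_frame("mantel", mantel_report)
    emit_frame("network_edges", network.edge_table(graph))
    emit_frame("network_nodes", network.node_table(graph))
    if not regress_report.empty:
        emit_frame("regressions", regress_report)
    write_frame(meta.reset_index(drop=True), out / "meta_aligned.tsv")
    outputs["meta_aligned"] = out / "meta_aligned.tsv"

    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "config": yaml.safe_load(config.to_yaml()),
        "inflow_reservoir_contrast": {"t": contrast.t, "p": contrast.p,
                                      "mean_inflow": contrast.mean_a,
                                      "mean_reservoir": contrast.mean_b},
        "network_topology": dataclasses.asdict(topo),
        "stage_checksums": {k: _checksum(p) for k, p in sorted(outputs.items())},
    }
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
    log.info("pipeline complete: %d samples, outputs in %s",
             len(efs_result), out)
    return manifest
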