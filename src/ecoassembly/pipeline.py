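"""End-to-end orchestration of the full analysis workflow.

A flat key=value config file drives: rarefaction -> alpha diversity ->
Bray-Curtis -> PCoA -> PERMANOVA/ANOSIM/beta-dispersion -> betaNTI +
RC-Bray assembly partition -> co-occurrence network -> taxonomy
summaries -> Mantel/Procrustes/VPA/ordination regression. Every stage
writes tidy CSVs; a JSON report collects headline numbers; the manifest
echoes every effective parameter and seed so a re-run is byte-stable.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import assembly, diversity, io as eio, network, stats, taxonomy

logger = logging.getLogger("ecoassembly")


@dataclass
class RunConfig:
    """Validated, fully-explicit run configuration."""
    table: str = ""
    tree: str = ""
    metadata: str = ""
    soil: str = ""
    taxonomy: str = ""
    out_dir: str = "ecoassembly_out"
    orientation: str = "samples_as_rows"
    rarefy_depth: str = "min"
    rarefy_seed: int = 0
    group_col: str = "compartment"
    assembly_group_col: str = "region"
    reps: int = 999
    permutations: int = 999
    seed: int = 0
    network_rho_min: float = 0.6
    network_q_max: float = 0.05
    network_min_prevalence: float = 0.2

    _REQUIRED = ("table",)

    @classmethod
    def field_names(cls):
        return [f.name for f in dataclasses.fields(cls)]


def validate_config(path) -> RunConfig:
    """Parse a flat ``key = value`` config file.

    Unknown keys are rejected by name; every default that fills in is
    logged so the effective configuration is explicit.
    """
    known = RunConfig.field_names()
    raw: dict = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected key = value")
            key, val = (s.strip() for s in line.split("=", 1))
            if key not in known:
                raise ValueError(f"{path}:{lineno}: unknown key {key!r}")
            raw[key] = val
    for req in RunConfig._REQUIRED:
        if req not in raw:
            raise ValueError(f"missing required key {req!r}")
    cfg = RunConfig()
    for f in dataclasses.fields(RunConfig):
        if f.name in raw:
            val = raw[f.name]
            if f.type == "int":
                val = int(val)
            elif f.type == "float":
                val = float(val)
            setattr(cfg, f.name, val)
        else:
            logger.info("config: %s defaulted to %r", f.name,
                        getattr(cfg, f.name))
    return cfg


def dump_config(cfg: RunConfig, path) -> None:
    with open(path, "w") as fh:
        for f in dataclasses.fields(RunConfig):
            fh.write(f"{f.name} = {getattr(cfg, f.name)}\n")


def run_full_pipeline(cfg: RunConfig) -> dict:
    """Execute every stage the inputs support; return the report dict.

    Stages whose inputs are absent (no tree, no soil table, ...) are
    skipped and flagged in the report rather than failing the run.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_handler = logging.FileHandler(out / "run.log")
    log_handler.setFormatter(logging.Formatter(
        "%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(log_handler)
    report: dict = {"stages": {}, "skipped": []}

    def stage(name):
        logger.info("stage: %s", name)
        return report["stages"].setdefault(name, {})

    try:
        # ---- load & align -------------------------------------------
        table = eio.read_community_table(cfg.table,
                                         orientation=cfg.orientation)
        metadata = eio.read_metadata(cfg.metadata) if cfg.metadata else None
        soil = eio.read_soil(cfg.soil) if cfg.soil else None
        tree = eio.read_newick(cfg.tree) if cfg.tree else None
        taxo = (pd.read_csv(cfg.taxonomy, index_col=0, dtype=str)
                if cfg.taxonomy else None)
        bundle = eio.align_inputs(table, metadata=metadata, soil=soil,
                                  tree=tree, taxonomy=taxo)
        table = bundle.table

        # ---- rarefaction --------------------------------------------
        s = stage("rarefy")
        table = eio.rarefy(table, depth=cfg.rarefy_depth,
                           seed=cfg.rarefy_seed)
        s["depth"] = int(table.sample_totals().iloc[0])
        s["n_samples"], s["n_otus"] = table.shape
        if bundle.metadata is not None:
            bundle.metadata = bundle.metadata.loc[table.sample_ids]
        if bundle.soil is not None:
            bundle.soil = bundle.soil.loc[table.sample_ids]

        # ---- alpha diversity ----------------------------------------
        alpha = diversity.alpha_diversity(table)
        alpha.to_csv(out / "alpha_diversity.csv")
        stage("alpha")["mean_sobs"] = float(alpha["sobs"].mean())

        # ---- beta diversity / ordination ----------------------------
        dm = diversity.bray_curtis(table)
        dm.to_data_frame().to_csv(out / "bray_curtis.csv")
        ord_res = diversity.pcoa(dm)
        ord_df = ord_res.samples.iloc[:, :4]
        ord_df = ord_df.assign(
            **{"proportion_axis1": ord_res.proportion_explained.iloc[0]})
        ord_df.to_csv(out / "pcoa.csv")
        stage("pcoa")["proportion_explained_axis1"] = float(
            ord_res.proportion_explained.iloc[0])

        # ---- group statistics ---------------------------------------
        md = bundle.metadata
        if md is not None and cfg.group_col in md.columns \
                and md[cfg.group_col].nunique() > 1:
            groups = md[cfg.group_col]
            res = stats.permanova(dm, md, cfg.group_col,
                                  permutations=cfg.permutations,
                                  seed=cfg.seed)
            res.to_csv(out / "permanova.csv", index=False)
            s = stage("permanova")
            s["R2"] = float(res.loc[0, "R2"])
            s["p_value"] = float(res.loc[0, "p_value"])
            an = stats.anosim(dm, groups, permutations=cfg.permutations,
                              seed=cfg.seed)
            stage("anosim").update(R=an.statistic, p_value=an.p_value)
            if groups.value_counts().min() >= 2:
                disp = diversity.beta_dispersion(
                    dm, groups, permutations=cfg.permutations, seed=cfg.seed)
                disp["distances"].to_frame("dist_to_centroid").to_csv(
                    out / "beta_dispersion.csv")
                stage("beta_dispersion").update(F=disp["F"],
                                                p_value=disp["p_value"])
        else:
            report["skipped"].append("group_statistics")

        # ---- assembly null models -----------------------------------
        if bundle.tree is not None:
            groups = None
            if md is not None and cfg.assembly_group_col in md.columns:
                groups = md[cfg.assembly_group_col]
            phylo_table = table
            if bundle.otus_not_in_tree:
                keep = [o for o in table.otu_ids
                        if o not in set(bundle.otus_not_in_tree)]
                phylo_table = table.subset(otus=keep)
            ares = assembly.assembly_analysis(
                phylo_table, bundle.tree, groups=groups, reps=cfg.reps,
                seed=cfg.seed)
            ares.pairs.to_csv(out / "assembly_pairs.csv", index=False)
            ares.partition.to_csv(out / "assembly_partition.csv",
                                  index=False)
            s = stage("assembly")
            for _, row in ares.partition.iterrows():
                fr = {p: row[p] for p in assembly.PROCESSES}
                s[str(row["group"])] = {
                    "n_pairs": int(row["n_pairs"]),
                    "modal_process": max(fr, key=fr.get), **fr}
        else:
            report["skipped"].append("assembly")

        # ---- co-occurrence network ----------------------------------
        try:
            filt = network.filter_otus(
                table, min_prevalence=cfg.network_min_prevalence)
            net = network.build_network(
                filt, rho_min=cfg.network_rho_min, q_max=cfg.network_q_max,
                taxonomy=bundle.taxonomy, seed=cfg.seed)
            net.edges.to_csv(out / "network_edges.csv", index=False)
            net.nodes.to_csv(out / "network_nodes.csv")
            pd.DataFrame([net.metrics]).to_csv(out / "network_metrics.csv",
                                               index=False)
            network.write_graphml(net, out / "network.graphml")
            stage("network").update(net.metrics)
        except eio.ValidationError as exc:
            logger.warning("network stage skipped: %s", exc)
            report["skipped"].append("network")

        # ---- taxonomy summaries -------------------------------------
        if bundle.taxonomy is not None:
            comp = taxonomy.relative_abundance(
                taxonomy.collapse_rank(table, bundle.taxonomy, "phylum"),
                group_by=md[cfg.group_col] if md is not None else None)
            comp.to_csv(out / "composition_phylum.csv")
            stage("taxonomy")["n_phyla"] = int(comp.shape[1])
        else:
            report["skipped"].append("taxonomy")

        # ---- community-environment analyses -------------------------
        if bundle.soil is not None:
            soil_num = bundle.soil.select_dtypes(include=[np.number])
            soil_num = soil_num.loc[:, soil_num.std(ddof=0) > 0]
            env_dm = stats.DistanceMatrix(
                stats.squareform(stats.pdist(
                    (soil_num - soil_num.mean()) / soil_num.std(ddof=0))),
                ids=table.sample_ids)
            mt = stats.mantel(dm, env_dm, permutations=cfg.permutations,
                              seed=cfg.seed)
            stage("mantel").update(r=mt.statistic, p_value=mt.p_value)
            soil_pca = stats.pca_ordination(soil_num)
            pr = stats.procrustes(ord_res, soil_pca,
                                  permutations=cfg.permutations,
                                  seed=cfg.seed)
            stage("procrustes").update(M2=pr.statistic,
                                       p_value=pr.p_value,
                                       correlation=pr.extras["correlation"])
            reg = stats.ordination_regression(ord_res, soil_num)
            reg.to_csv(out / "ordination_regression.csv", index=False)
            stage("ordination_regression")["top_driver"] = str(
                reg.loc[0, "variable"])
            blocks = _default_blocks(soil_num)
            if len(blocks) >= 2:
                vres = stats.vpa(dm, blocks)
                rows = [{"fraction": "+".join(sorted(k)), "value": v}
                        for k, v in vres.fractions.items()]
                rows.append({"fraction": "residual", "value": vres.residual})
                pd.DataFrame(rows).to_csv(out / "vpa.csv", index=False)
                stage("vpa")["residual"] = vres.residual
        else:
            report["skipped"].append("environment")

        report["ok"] = True
    except Exception as exc:
        report["ok"] = False
        report["error"] = f"{type(exc).__name__}: {exc}"
        logger.error("pipeline aborted: %s", report["error"])
        raise
    finally:
        manifest = {"config": dataclasses.asdict(cfg),
                    "version": _version()}
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True, default=float)
        logger.removeHandler(log_handler)
        log_handler.close()
    return report


#: soil variables grouped the way community-environment variance is
#: usually partitioned: edaphic chemistry, geography, climate
BLOCK_DEFS = {
    "edaphic": ["TN", "TP", "AN", "AP", "AK", "OC", "C/N", "pH", "EC",
                "ALP", "SUC", "UR", "SM"],
    "geographic": ["altitude"],
    "climatic": ["MAT", "MAP"],
}


def _default_blocks(soil: pd.DataFrame) -> dict:
    blocks = {}
    n = len(soil)
    for name, cols in BLOCK_DEFS.items():
        cols = [c for c in cols if c in soil.columns]
        # keep the block fittable: fewer predictors than residual df
        cols = cols[:max(1, n - 3 - 1) // 2]
        if cols:
            blocks[name] = soil[cols]
    return blocks


def _version() -> str:
    from . import __version__
    return __version__


def summarize_report(out_dir) -> str:
    """Human-readable digest of a finished run's report.json."""
    with open(Path(out_dir) / "report.json") as fh:
        report = json.load(fh)
    lines = []
    for name, vals in report.get("stages", {}).items():
        lines.append(f"[{name}]")
        for k, v in vals.items():
            lines.append(f"  {k}: {v}")
    if report.get("skipped"):
        lines.append("skipped: " + ", ".join(report["skipped"]))
    return "\n".join(lines)
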