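"""End-to-end orchestration of the synthetic radiation-response analysis.

Stages (in dependency order): simulate -> de -> earlylate -> gan ->
centrality -> enrichment -> integration.  Every stage reads/writes only
declared files inside the output directory; a manifest with the config
hash and per-file checksums is written last, so re-running an identical
config reproduces identical checksums for all deterministic stages.
"""

from __future__ import annotations

import hashlib
import json
import time
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as rio
from .synthetic import (
    SimulationConfig,
    default_gene_annotation,
    gen_cna_profile,
    gen_gene_sets,
    gen_timecourse,
)
from .timecourse import classify_early_late, static_de, timecourse_de, validate_design
from .gan import reconstruct_network
from .centrality import compute_centralities, top_fraction
from .enrichment import GeneSetCollection, filter_sets, fisher_enrichment, write_gmt, read_gmt
from .integration import concordant_genes, map_genes_to_calls

ALL_STAGES = ("simulate", "de", "earlylate", "gan", "centrality", "enrichment", "integration")


@dataclass
class PipelineConfig:
    """Thresholds, seed and stage toggles for a full run.

    Threshold defaults are the analysis defaults used throughout the
    package: DE FDR 0.05, static |log2FC| 0.5, early/late fold-change
    window 2.0/0.5, edge posterior 0.95, top 5 % centrality cut, set
    sizes 20..600, enrichment reporting FDR 0.1.
    """

    outdir: str = "radpipe_run"
    seed: int = 0
    de_fdr: float = 0.05
    static_lfc: float = 0.5
    fc_hi: float = 2.0
    fc_lo: float = 0.5
    edge_prob: float = 0.95
    top_fraction: float = 0.05
    set_min: int = 20
    set_max: int = 600
    enrich_fdr: float = 0.1
    max_network_genes: int = 300
    n_genes: int = 1000
    n_gene_sets: int = 30
    n_cna_segments: int = 5
    stages: tuple = ALL_STAGES
    sim: dict = field(default_factory=dict)

    def __post_init__(self):
        for name, lo, hi in [
            ("de_fdr", 0, 1), ("edge_prob", 0, 1), ("top_fraction", 0, 1),
            ("enrich_fdr", 0, 1),
        ]:
            v = getattr(self, name)
            if not lo < v <= hi:
                raise ValueError(f"{name}={v} outside ({lo}, {hi}]")
        if self.fc_lo >= self.fc_hi:
            raise ValueError("fc_lo must be below fc_hi")
        if not 0 < self.set_min <= self.set_max:
            raise ValueError("need 0 < set_min <= set_max")
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return cls(**raw)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def validate_inputs(expr: pd.DataFrame, design: pd.DataFrame) -> list[str]:
    """Schema/consistency report for a time-course expression bundle.

    Returns a list of blocking issues (empty = clean).
    """
    issues = []
    missing = set(expr.columns) - set(design.index)
    if missing:
        issues.append(f"samples missing from design: {sorted(missing)[:5]}")
    if expr.isna().any().any():
        issues.append("expression matrix contains missing values")
    if not issues:
        try:
            validate_design(expr, design)
        except ValueError as err:
            issues.append(str(err))
    return issues


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the enabled stages; returns the run manifest (also written
    to ``<outdir>/manifest.json``)."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": config.config_hash(),
        "config": asdict(config),
        "stages_run": [],
        "checksums": {},
        "warnings": [],
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    stages = set(config.stages)
    files: dict[str, Path] = {}

    def declare(name: str, path: Path):
        files[name] = path
        manifest["checksums"][name] = _checksum(path)

    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        state: dict = {}
        try:
            if "simulate" in stages:
                sim = SimulationConfig(
                    n_genes=config.n_genes, seed=config.seed, **config.sim
                )
                expr, design, truth = gen_timecourse(sim)
                rio.write_expression(expr, out / "expr.tsv")
                rio.write_design(design, out / "design.tsv")
                pd.Series(sorted(truth.de_genes)).to_csv(
                    out / "truth_de_genes.tsv", sep="\t", index=False, header=["gene"]
                )
                annot = default_gene_annotation(expr.index)
                rio.write_table(annot, out / "gene_annotation.tsv")
                segments, cna_truth = gen_cna_profile(annot, config.n_cna_segments, sim.seed)
                rio.write_table(segments, out / "cna_segments.tsv")
                sets, set_truth = gen_gene_sets(
                    list(expr.index),
                    n_sets=config.n_gene_sets,
                    size_range=(config.set_min, min(config.set_max, max(config.set_min, config.n_genes // 4))),
                    enriched_in=sorted(truth.de_genes),
                    seed=sim.seed,
                )
                write_gmt(GeneSetCollection.from_dict(sets), out / "gene_sets.gmt")
                state.update(expr=expr, design=design, truth=truth)
                manifest["stages_run"].append("simulate")
                for n, f in [
                    ("expr", "expr.tsv"), ("design", "design.tsv"),
                    ("truth_de", "truth_de_genes.tsv"), ("annot", "gene_annotation.tsv"),
                    ("segments", "cna_segments.tsv"), ("gmt", "gene_sets.gmt"),
                ]:
                    declare(n, out / f)

            if "de" in stages:
                expr = state["expr"] if "expr" in state else rio.read_expression(out / "expr.tsv")
                design = state["design"] if "design" in state else rio.read_design(out / "design.tsv")
                issues = validate_inputs(expr, design)
                if issues:
                    raise RuntimeError(f"stage de: invalid inputs: {issues}")
                de = timecourse_de(expr, design, fdr_threshold=config.de_fdr)
                rio.write_table(de, out / "de.tsv", index=True, index_label="gene")
                state.update(expr=expr, design=design, de=de)
                manifest["stages_run"].append("de")
                declare("de", out / "de.tsv")

            if "earlylate" in stages:
                de = state["de"]
                de_genes = list(de.index[de["de"]])
                resp = classify_early_late(
                    state["expr"], state["design"], de_genes,
                    fc_high=config.fc_hi, fc_low=config.fc_lo,
                )
                rio.write_table(resp, out / "earlylate.tsv", index=True, index_label="gene")
                state["earlylate"] = resp
                manifest["stages_run"].append("earlylate")
                declare("earlylate", out / "earlylate.tsv")

            if "gan" in stages:
                de = state["de"]
                de_genes = de[de["de"]].sort_values("F", ascending=False).index
                net_genes = list(de_genes[: config.max_network_genes])
                if len(net_genes) < 5:
                    raise RuntimeError("stage gan: fewer than 5 DE genes for the network")
                G, P, lam, model = reconstruct_network(
                    state["expr"].loc[net_genes], state["design"],
                    condition="treated", threshold=config.edge_prob,
                )
                rio.write_edges(G, out / "edges.tsv")
                state.update(network=G)
                manifest["lambda_star"] = lam
                manifest["eta0"] = model.eta0
                manifest["stages_run"].append("gan")
                declare("edges", out / "edges.tsv")

            if "centrality" in stages:
                table = compute_centralities(state["network"])
                top = top_fraction(table, fraction=config.top_fraction)
                table["selected"] = table.index.isin(top)
                rio.write_table(table, out / "centrality.tsv", index=True, index_label="gene")
                state["top_genes"] = top
                manifest["stages_run"].append("centrality")
                declare("centrality", out / "centrality.tsv")

            if "enrichment" in stages:
                collection = read_gmt(out / "gene_sets.gmt")
                universe = list(state["expr"].index)
                filtered = filter_sets(collection, universe, config.set_min, config.set_max)
                query = state.get("top_genes") or list(state["de"].index[state["de"]["de"]])
                enr = fisher_enrichment(query, universe, filtered)
                enr["significant"] = enr["fdr"] < config.enrich_fdr
                rio.write_table(enr, out / "enrichment.tsv")
                manifest["stages_run"].append("enrichment")
                declare("enrichment", out / "enrichment.tsv")

            if "integration" in stages:
                design = state["design"]
                expr = state["expr"]
                trt = design.index[design["condition"] == "treated"]
                ctl = design.index[design["condition"] == "control"]
                static = static_de(expr[trt], expr[ctl], lfc_threshold=config.static_lfc,
                                   fdr_threshold=config.de_fdr)
                rio.write_table(static, out / "static_de.tsv", index=True, index_label="gene")
                annot = rio.read_table(out / "gene_annotation.tsv")
                segments = rio.read_table(out / "cna_segments.tsv")
                calls = map_genes_to_calls(annot, segments)
                rio.write_table(calls, out / "cna_calls.tsv")
                conc = concordant_genes(static, calls)
                rio.write_table(conc, out / "concordance.tsv", index=True, index_label="gene")
                manifest["status_counts"] = conc["status"].value_counts().to_dict()
                manifest["stages_run"].append("integration")
                for n, f in [("static_de", "static_de.tsv"), ("cna_calls", "cna_calls.tsv"),
                             ("concordance", "concordance.tsv")]:
                    declare(n, out / f)
        except Exception as err:
            manifest["failed_stage"] = _current_stage(manifest)
            manifest["error"] = str(err)
            (out / "manifest.partial.json").write_text(json.dumps(manifest, indent=2, default=str))
            raise
        manifest["warnings"] = sorted({str(w.message) for w in caught})

    manifest["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest


def _current_stage(manifest: dict) -> str:
    done = manifest["stages_run"]
    for stage in ALL_STAGES:
        if stage not in done:
            return stage
    return "unknown"
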