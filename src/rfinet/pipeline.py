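"""End-to-end orchestration: simulate -> expression -> DE/TS -> RIF -> PCIT
-> network -> report, driven by a single configuration mapping.

Every stage threshold lives in :class:`RunConfig`; the shipped defaults are
the analysis defaults (min 10 M reads, RPKM 0.2, 2/3 tissue share, 2-SD DE
rule, 2-SD edge rule, enrichment alpha 0.05).  A fixed seed makes reruns
byte-identical.
"""
from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import expression, io, mixed_model, network, pcit, phenotypes, rif
from .datatypes import CountMatrix, GeneAnnotation, ValidationError
from .simulate import (ExperimentDesign, GroundTruth, PhenoParams, SimParams,
                       simulate_expression, simulate_phenotypes)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    outdir: str = "run"
    seed: int = 0
    # simulation (used when no input paths are given)
    simulate: bool = True
    design: dict = field(default_factory=dict)
    sim_params: dict = field(default_factory=dict)
    pheno_params: dict = field(default_factory=dict)
    # input paths (used when simulate is False)
    counts: Optional[str] = None
    gene_lengths: Optional[str] = None
    samples: Optional[str] = None
    annotation: Optional[str] = None
    phenotypes_csv: Optional[str] = None
    events_csv: Optional[str] = None
    # stage thresholds
    min_reads: float = expression.DEFAULT_MIN_READS
    rpkm_threshold: float = expression.DEFAULT_RPKM_THRESHOLD
    ts_threshold: float = expression.DEFAULT_TS_THRESHOLD
    log2_offset: float = expression.DEFAULT_LOG2_OFFSET
    de_k: float = 2.0
    rif_z: float = 2.0
    pcit_k: float = 2.0
    pcit_stat: str = "raw"
    enrichment_alpha: float = 0.05
    # stage toggles
    run_rif: bool = True
    run_pcit: bool = True
    run_phenotypes: bool = True

    @classmethod
    def from_mapping(cls, mapping: dict) -> "RunConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(mapping) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**mapping)


@dataclass
class RunReport:
    seed: int
    counts: dict = field(default_factory=dict)
    timings: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {"seed": self.seed, "counts": self.counts, "timings": self.timings}


class _StageTimer:
    def __init__(self, report: RunReport, name: str):
        self.report, self.name = report, name

    def __enter__(self):
        self.t0 = time.perf_counter()
        logger.info("stage %s: start", self.name)
        return self

    def __exit__(self, exc_type, exc, tb):
        self.report.timings[self.name] = round(time.perf_counter() - self.t0, 3)
        if exc_type is not None:
            logger.error("stage %s failed: %s", self.name, exc)
        else:
            logger.info("stage %s: done (%.2fs)", self.name, self.report.timings[self.name])
        return False


def run_pipeline(config: RunConfig) -> RunReport:
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = RunReport(seed=config.seed)
    truth: Optional[GroundTruth] = None

    with _StageTimer(report, "inputs"):
        if config.simulate:
            design = ExperimentDesign(seed=config.seed, **config.design)
            sim_params = SimParams(**config.sim_params)
            cm, meta, annotation, truth = simulate_expression(design, sim_params)
            io.write_counts(cm, outdir)
            io.write_samples(meta, outdir)
            io.write_annotation(annotation, outdir)
            io.write_truth(truth, outdir)
            pheno = simulate_phenotypes(design, PhenoParams(**config.pheno_params)) \
                if config.run_phenotypes else None
            if pheno is not None:
                io.write_phenotypes(pheno, outdir)
        else:
            if not (config.counts and config.gene_lengths and config.samples):
                raise ValidationError("counts, gene_lengths and samples paths are required")
            cm = io.read_counts(Path(config.counts), Path(config.gene_lengths))
            meta = io.read_samples(Path(config.samples))
            annotation = io.read_annotation(Path(config.annotation)) if config.annotation \
                else GeneAnnotation(table=pd.DataFrame(index=cm.genes))
            pheno = io.read_phenotypes(
                Path(config.phenotypes_csv),
                Path(config.events_csv) if config.events_csv else None,
            ) if (config.run_phenotypes and config.phenotypes_csv) else None

    with _StageTimer(report, "expression"):
        min_reads = config.min_reads
        if config.simulate:
            # simulated depths default below 10 M; scale the QC threshold to
            # half the simulated target depth so the rule stays exercised
            min_reads = min(min_reads, 0.5 * SimParams(**config.sim_params).depth_mean)
        cm_qc = expression.qc_samples(cm, min_reads=min_reads)
        meta_qc = meta.loc[cm_qc.samples]
        expr = expression.compute_rpkm(cm_qc, meta=meta_qc)
        expressed, not_expressed = expression.filter_expressed(expr, config.rpkm_threshold)
        expr_kept = type(expr)(rpkm=expr.rpkm.loc[expressed], meta=expr.meta)
        shares = expression.tissue_share(expr_kept)
        ts_calls = expression.classify_tissue_specific(shares, config.ts_threshold)
        Y = expression.log2_transform(expr_kept, offset=config.log2_offset)
        expr.rpkm.loc[expressed].to_csv(outdir / "rpkm.tsv", sep="\t", index_label="gene")
        ts_calls.to_csv(outdir / "ts_calls.tsv", sep="\t", index_label="gene")
        report.counts.update(
            samples_kept=int(cm_qc.counts.shape[1]),
            genes_expressed=int(len(expressed)),
            genes_not_expressed=int(len(not_expressed)),
            ts_genes=int(ts_calls["is_ts"].sum()),
        )

    with _StageTimer(report, "mixed_model"):
        fit = mixed_model.fit_variance_components(Y, meta_qc)
        sols = mixed_model.solve_blups(Y, meta_qc, fit)
        tissue_fc = mixed_model.tissue_fold_changes(Y, meta_qc)
        de_results = mixed_model.call_de(sols, k=config.de_k, tissue_fc=tissue_fc)
        with open(outdir / "varcomp.json", "w") as fh:
            json.dump(fit.as_dict(), fh, indent=1, sort_keys=True)
        de_results.to_csv(outdir / "de_results.tsv", sep="\t", index_label="gene")
        report.counts["de_genes"] = int(de_results["is_de"].sum())

    de_genes = de_results.index[de_results["is_de"]]
    ts_genes = ts_calls.index[ts_calls["is_ts"]]
    tf_genes = annotation.tf_genes.intersection(Y.index)
    snp_genes = annotation.snp_genes.intersection(Y.index)

    if config.run_rif:
        with _StageTimer(report, "rif"):
            targets = de_genes.union(ts_genes)
            if len(tf_genes) and len(targets.difference(tf_genes)):
                scores = rif.compute_rif(Y, meta_qc, tf_genes, targets)
                selected = rif.select_tf(scores, z_cut=config.rif_z)
                scores.assign(selected=scores.index.isin(selected)).to_csv(
                    outdir / "rif_scores.tsv", sep="\t"
                )
                report.counts["tf_selected"] = int(len(selected))
            else:
                logger.warning("skipping RIF: no TFs or no targets")
                report.counts["tf_selected"] = 0

    net = None
    if config.run_pcit:
        with _StageTimer(report, "pcit"):
            node_union = de_genes.union(ts_genes).union(tf_genes).union(snp_genes)
            node_union = node_union.intersection(Y.index)
            edges = pcit.infer_network(Y.loc[node_union], k=config.pcit_k, stat=config.pcit_stat)
            edges.to_csv(outdir / "edges.tsv", sep="\t", index=False)
        with _StageTimer(report, "network"):
            tissue_of_max = expression.classify_tissue_specific(shares, threshold=2.0)[
                "dominant_tissue"
            ]  # argmax share for every gene (threshold 2 never fires)
            net = network.build_network(
                edges, de_genes, ts_genes, tf_genes, snp_genes, tissue_of_max,
                provenance={"seed": config.seed, "pcit_k": config.pcit_k,
                            "de_k": config.de_k, "ts_threshold": config.ts_threshold},
            )
            network.export_network(net, outdir / "network_edges.tsv", fmt="tsv")
            network.export_network(net, outdir / "network.sif", fmt="sif")
            network.export_network(net, outdir / "network.graphml", fmt="graphml")
            summary = network.tissue_edge_summary(net)
            degrees = network.degree_table(net)
            degrees.to_csv(outdir / "degree_table.tsv", sep="\t")
            report.counts.update(
                nodes=int(net.n_nodes),
                edges=int(net.n_edges),
                within_tissue_fraction=(
                    None if np.isnan(summary["within_fraction"])
                    else round(float(summary["within_fraction"]), 4)
                ),
            )

    if config.run_phenotypes and pheno is not None:
        with _StageTimer(report, "phenotypes"):
            rows = {}
            for animal, sub in pheno.weights.groupby("animal"):
                rows[animal] = {
                    "adg": phenotypes.compute_adg(sub["day"], sub["weight_kg"]),
                    "mmw": phenotypes.compute_mmw(sub["weight_kg"]),
                }
            per_animal = pd.DataFrame(rows).T
            per_animal["dmi"] = pheno.dmi.groupby("animal")["dmi_kg"].mean()
            fit_rfi = phenotypes.compute_rfi(
                per_animal["dmi"], per_animal["adg"], per_animal["mmw"], period=pheno.period
            )
            out = fit_rfi.table.copy()
            out["sire_group"] = pheno.animals["sire_group"]
            out.to_csv(outdir / "rfi.csv", index_label="animal")
            report.counts["rfi_mean"] = round(float(fit_rfi.rfi.mean()), 10)

    manifest = {
        "config": asdict(config),
        "seed": config.seed,
        "report": report.as_dict(),
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return report
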