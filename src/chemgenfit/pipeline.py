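"""End-to-end orchestration: simulate -> count -> fit -> antagonism ->
profiles -> enrich -> report, driven by a validated YAML/dict configuration.

Every stage writes plain-text outputs under the run directory and records
them (with SHA-256 hashes) in ``manifest.json``; rerunning an unchanged
configuration reproduces byte-identical non-log outputs.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field

from . import antagonism as antag
from . import barcodes as bc
from . import diffit, enrichment, profiles, synthpool
from . import io as cgio


class SimulateConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_strains: int = 500
    n_compounds: int = 6
    compounds: list[str] | None = None
    unpaired: list[str] = Field(default_factory=list)
    n_replicates: int = 3
    depth: int = 200_000
    barcode_length: int = 20
    dispersion: float = 0.05
    batch_sigma: float = 0.3
    fractions: dict[str, float] | None = None
    effect_low: float = 0.1
    effect_high: float = 0.5
    n_compound_classes: int = 2
    fastq: bool = False
    error_rate: float = 0.0
    n_gene_sets: int = 20
    planted_set_size: int = 0


class FitConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    fdr: float = 0.05
    trim_m: float = 0.30
    trim_a: float = 0.05
    trend_weight: float = 0.4
    prior_count: float = 0.5
    global_fdr: bool = False


class AntagonismConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    rule: str = "both-significant"
    focal: str | None = None


class ProfilesConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    k: int = 8
    n_starts: int = 5
    tol: float = 1e-6
    cut_height: float | None = None


class EnrichConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    p_cutoff: float = 1e-4
    universe: str = "tested"
    min_size: int = 3


class RunConfig(BaseModel):
    """Whole-run configuration; unknown keys are rejected up front."""

    model_config = ConfigDict(extra="forbid")
    seed: int = 0
    outdir: str = "run"
    counts: str | None = None     # precomputed counts TSV (skips simulate)
    design: str | None = None
    genesets: str | None = None   # GMT path; simulated when absent
    simulate: SimulateConfig = Field(default_factory=SimulateConfig)
    fit: FitConfig = Field(default_factory=FitConfig)
    antagonism: AntagonismConfig = Field(default_factory=AntagonismConfig)
    profiles: ProfilesConfig = Field(default_factory=ProfilesConfig)
    enrich: EnrichConfig = Field(default_factory=EnrichConfig)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.model_validate(yaml.safe_load(Path(path).read_text()) or {})


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_all(config: RunConfig) -> dict:
    """Execute the configured stages; returns the manifest (also written to
    ``manifest.json`` in the run directory)."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": config.model_dump(), "outputs": {}, "stages": []}
    outputs: dict[str, Path] = {}

    def _record(name: str, path: Path):
        outputs[name] = path

    stage = "simulate"
    try:
        if config.counts is not None:
            counts = cgio.read_counts(config.counts)
            design = cgio.read_design(config.design)
            truth = None
            sets = (cgio.read_gmt(config.genesets)
                    if config.genesets else None)
        else:
            sc = config.simulate
            compounds = sc.compounds or [f"cmpd_{i:02d}"
                                         for i in range(sc.n_compounds)]
            catalog = synthpool.generate_catalog(
                sc.n_strains, sc.barcode_length, seed=config.seed)
            tcfg = synthpool.TruthConfig(
                effect_low=sc.effect_low, effect_high=sc.effect_high,
                n_compound_classes=sc.n_compound_classes,
                dispersion=sc.dispersion)
            if sc.fractions:
                tcfg.fractions = sc.fractions
            truth = synthpool.generate_truth(catalog, compounds, tcfg,
                                             seed=config.seed + 1)
            design = synthpool.generate_design(
                compounds, n_replicates=sc.n_replicates,
                unpaired=tuple(sc.unpaired), seed=config.seed + 2)
            cm = synthpool.simulate_counts(
                catalog, design, truth, depth=sc.depth,
                seed=config.seed + 3, batch_sigma=sc.batch_sigma)
            counts = cm.counts
            cgio.write_catalog(catalog, outdir / "catalog.tsv")
            cgio.write_design(design, outdir / "design.tsv")
            cgio.write_counts(counts, outdir / "counts.tsv")
            truth.write(outdir)
            _record("catalog", outdir / "catalog.tsv")
            _record("design", outdir / "design.tsv")
            _record("counts", outdir / "counts.tsv")
            _record("truth_s", outdir / "truth_s.tsv")
            _record("truth_gene_class", outdir / "truth_gene_class.tsv")
            _record("truth_compound_class", outdir / "truth_compound_class.tsv")
            if sc.fastq:
                fq = synthpool.emit_fastq(cm, catalog, outdir / "fastq",
                                          error_rate=sc.error_rate,
                                          seed=config.seed + 4)
                recount, report = bc.count_uptags(
                    {s: str(p) for s, p in fq.items()}, catalog)
                counts = recount
                report.per_sample.to_csv(outdir / "counting_report.tsv",
                                         sep="\t")
                _record("counting_report", outdir / "counting_report.tsv")
            planted = []
            if sc.planted_set_size > 0:
                planted = [("planted_beneficial", "beneficial-only",
                            sc.planted_set_size),
                           ("planted_deleterious", "deleterious-only",
                            sc.planted_set_size)]
            sets = synthpool.generate_genesets(
                catalog, sc.n_gene_sets, seed=config.seed + 5,
                truth=truth, planted=planted)
            cgio.write_gmt(sets, outdir / "genesets.gmt")
            _record("genesets", outdir / "genesets.gmt")
        manifest["stages"].append(stage)

        stage = "fit"
        fc = config.fit
        fitness = diffit.fit_all(
            counts, design, fdr=fc.fdr, trim_m=fc.trim_m, trim_a=fc.trim_a,
            trend_weight=fc.trend_weight, prior_count=fc.prior_count,
            global_fdr=fc.global_fdr,
            unpaired=tuple(design.loc[design["pair_id"].isna(),
                                      "compound"].unique()))
        fitness.table.to_csv(outdir / "fitness.tsv", sep="\t", index=False,
                             float_format=cgio.FLOAT_FMT)
        fitness.per_inhibitor.to_csv(outdir / "per_inhibitor.tsv", sep="\t",
                                     index=False)
        (outdir / "significant_union.txt").write_text(
            "\n".join(fitness.significant_union) + "\n")
        _record("fitness", outdir / "fitness.tsv")
        _record("per_inhibitor", outdir / "per_inhibitor.tsv")
        _record("significant_union", outdir / "significant_union.txt")
        manifest["stages"].append(stage)

        stage = "antagonism"
        ac = config.antagonism
        summary = antag.gene_direction_profile(fitness)
        summary.per_gene.to_csv(outdir / "gene_directions.tsv", sep="\t",
                                float_format=cgio.FLOAT_FMT)
        summary.cumulative.to_csv(outdir / "direction_cumulative.tsv",
                                  sep="\t", index=False)
        _record("gene_directions", outdir / "gene_directions.tsv")
        _record("direction_cumulative", outdir / "direction_cumulative.tsv")
        if design["compound"].nunique() >= 2:
            pair_mat, _ = antag.pairwise_antagonistic_proportion(
                fitness, rule=ac.rule)
            cgio.write_matrix(pair_mat, outdir / "pairwise_antagonism.tsv",
                              index_label="inhibitor")
            _record("pairwise_antagonism", outdir / "pairwise_antagonism.tsv")
            focal = ac.focal or sorted(design["compound"].unique())[0]
            others = [c for c in sorted(design["compound"].unique())
                      if c != focal]
            inter = antag.focal_intersections(fitness, focal, others)
            inter.to_csv(outdir / "focal_intersections.tsv", sep="\t",
                         index=False)
            _record("focal_intersections", outdir / "focal_intersections.tsv")
        manifest["stages"].append(stage)

        stage = "profiles"
        pc = config.profiles
        pm = fitness.profile_matrix(union_only=True)
        if pm.shape[0] >= max(3, pc.k) and pm.shape[1] >= 2:
            corr = profiles.correlation_matrix(pm)
            cgio.write_matrix(corr.corr, outdir / "inhibitor_correlation.tsv",
                              index_label="inhibitor")
            (outdir / "inhibitor_dendrogram.nwk").write_text(corr.newick + "\n")
            clustering = profiles.cluster_genes_eii(
                pm, k=min(pc.k, pm.shape[0]), n_starts=pc.n_starts,
                seed=config.seed + 6, tol=pc.tol)
            pd.DataFrame({"cluster": clustering.labels}).to_csv(
                outdir / "gene_clusters.tsv", sep="\t", index_label="gene")
            orders = profiles.order_within_clusters(pm, clustering)
            profiles.export_cdt(pm, clustering, orders,
                                outdir / "profiles.cdt")
            _record("inhibitor_correlation",
                    outdir / "inhibitor_correlation.tsv")
            _record("inhibitor_dendrogram",
                    outdir / "inhibitor_dendrogram.nwk")
            _record("gene_clusters", outdir / "gene_clusters.tsv")
            _record("profiles_cdt", outdir / "profiles.cdt")
        manifest["stages"].append(stage)

        stage = "enrich"
        ec = config.enrich
        if sets:
            enr = enrichment.enrich_all(fitness, sets,
                                        universe_mode=ec.universe,
                                        p_cutoff=ec.p_cutoff,
                                        min_size=ec.min_size)
            enr.to_csv(outdir / "enrichment.tsv", sep="\t", index=False,
                       float_format=cgio.FLOAT_FMT)
            _record("enrichment", outdir / "enrichment.tsv")
            em = enrichment.signed_matrix_and_cluster(enr,
                                                      p_cutoff=ec.p_cutoff)
            if not em.scores.empty:
                cgio.write_matrix(em.scores, outdir / "enrichment_matrix.tsv",
                                  index_label="category")
                _record("enrichment_matrix", outdir / "enrichment_matrix.tsv")
        manifest["stages"].append(stage)

        stage = "report"
        report_text = build_report(outdir, fitness, summary, truth)
        (outdir / "report.txt").write_text(report_text)
        _record("report", outdir / "report.txt")
        manifest["stages"].append(stage)
    except Exception as exc:
        (outdir / "FAILED").write_text(f"stage={stage}\nerror={exc}\n")
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    manifest["outputs"] = {name: {"path": str(p.relative_to(outdir)),
                                  "sha256": _sha256(p)}
                           for name, p in sorted(outputs.items())}
    cfg_ser = json.dumps(manifest["config"], sort_keys=True)
    manifest["config_hash"] = hashlib.sha256(cfg_ser.encode()).hexdigest()
    cgio.write_json(manifest, outdir / "manifest.json")
    return manifest


def build_report(outdir: Path, fitness: diffit.FitnessTable,
                 summary: "antag.GeneDirectionSummary",
                 truth: synthpool.SimulationTruth | None) -> str:
    """Human-readable run summary: per-inhibitor significant counts, the
    directional histogram, and class recovery against truth when planted
    truth is available."""
    lines = ["# chemgenfit run report", ""]
    lines.append("## Significant genes per inhibitor (FDR < "
                 f"{fitness.fdr:g})")
    lines.append(fitness.per_inhibitor.to_string(index=False))
    lines.append("")
    lines.append(f"## Significant union: {len(fitness.significant_union)} genes")
    lines.append("")
    lines.append("## Gene direction classes")
    lines.append(summary.per_gene["gene_class"].value_counts().to_string())
    if truth is not None:
        lines.append("")
        lines.append("## Class recovery vs planted truth")
        detected = summary.per_gene["gene_class"]
        planted = truth.gene_class.reindex(detected.index)
        tab = pd.crosstab(planted, detected)
        tab.index.name = "planted"
        tab.columns.name = "detected"
        lines.append(tab.to_string())
    lines.append("")
    return "\n".join(lines)
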