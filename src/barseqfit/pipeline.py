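"""End-to-end pipeline: simulate → count → filter → test → cluster → enrich.

Runs the whole pooled-competition analysis on synthetic data from one
seedable configuration, writing every stage's output as TSV/JSON beside a
manifest of SHA-256 checksums. Reruns with the same config are
byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__, cluster, counting, enrich, filters, io, simulate, stats
from .core import ReadLayout

log = logging.getLogger("barseqfit")

CONTRASTS = [("basal", "glucose"), ("basal", "sorbitol"), ("sorbitol", "glucose")]


@dataclass
class PipelineConfig:
    """All pipeline parameters; defaults are the experiment's constants."""

    outdir: str = "barseqfit_out"
    seed: int = 0
    # synthetic data
    n_strains: int = 1000
    depth_per_sample: int = 17000
    n_replicates: int = 3
    generations_hom: float = 10.0
    generations_het: float = 20.0
    error_rate: float = 0.002
    dispersion: float = 0.05
    tag_bias_sigma: float = 0.3
    frac_impaired: float = 0.05
    frac_advantaged: float = 0.03
    frac_artifact: float = 0.12
    effect_scale: float = 0.2
    n_terms: int = 50
    planted_term_size: int = 20
    planted_overlap: int = 15
    read_length: int = 50
    # counting
    max_mismatch: int = 2
    max_index_mismatch: int = 0
    # filters
    threshold_frac: float = 0.10
    hom_lfc_min: float = 0.0
    het_lfc_max: float = -3.0
    het_fdr_max: float = 0.05
    # hit calling
    alpha: float = 0.05
    lfc_threshold: float = 1.0
    # clustering
    diameter: float = 0.25
    min_size: int = 25
    cluster_metric: str = "pearson"
    # optional external inputs (skip simulation when all are given)
    fastq_hom: str | None = None
    fastq_het: str | None = None
    catalog_hom: str | None = None
    catalog_het: str | None = None
    samples_hom: str | None = None
    samples_het: str | None = None
    annotation: str | None = None

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _stage(name):
    def wrap(fn):
        def inner(*args, **kwargs):
            log.info("stage %s: start", name)
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") from exc
        return inner
    return wrap


@_stage("simulate")
def stage_simulate(cfg: PipelineConfig, out: Path) -> dict:
    layout = ReadLayout(read_length=cfg.read_length)
    seed = cfg.seed
    arts: dict = {"layout": layout}
    genes = [f"GENE{i + 1:04d}" for i in range(cfg.n_strains)]
    for k, coll in enumerate(("homozygous", "heterozygous")):
        short = "hom" if coll == "homozygous" else "het"
        catalog = simulate.generate_catalog(cfg.n_strains, seed + k, collection=coll,
                                            genes=genes)
        truth = simulate.generate_truth(
            catalog, frac_impaired=cfg.frac_impaired,
            frac_advantaged=cfg.frac_advantaged, frac_artifact=cfg.frac_artifact,
            effect_scale=cfg.effect_scale, seed=seed + 2)
        G = cfg.generations_hom if short == "hom" else cfg.generations_het
        sheet = simulate.make_samplesheet(coll, cfg.n_replicates, G, seed=seed + 3 + k)
        tag_counts = {}
        for c, cond in enumerate(("t0", "basal", "glucose", "sorbitol")):
            sim = simulate.simulate_competition(
                catalog, truth, cond, 0.0 if cond == "t0" else G,
                cfg.depth_per_sample, cfg.n_replicates,
                seed=seed + 100 + 10 * k + c,
                dispersion=cfg.dispersion, tag_bias_sigma=cfg.tag_bias_sigma)
            for r in range(1, cfg.n_replicates + 1):
                tag_counts[f"{short}_{cond}_{r}"] = sim.tag_counts[f"rep{r}"]
        tag_counts = pd.DataFrame(tag_counts)
        fastq = out / f"{short}.fastq.gz"
        simulate.simulate_reads(tag_counts, catalog, sheet, fastq, layout,
                                error_rate=cfg.error_rate, seed=seed + 200 + k)
        io.write_tsv(catalog, out / f"catalog_{short}.tsv")
        io.write_tsv(sheet, out / f"samples_{short}.tsv")
        io.write_tsv(truth, out / f"truth_{short}.tsv")
        io.write_tsv(tag_counts, out / f"true_tag_counts_{short}.tsv", index=True)
        arts[short] = {"catalog": catalog, "sheet": sheet, "truth": truth,
                       "fastq": fastq, "true_tag_counts": tag_counts}
    annotation = simulate.generate_annotation(
        arts["hom"]["catalog"], arts["hom"]["truth"], n_terms=cfg.n_terms,
        planted_term_size=cfg.planted_term_size, planted_overlap=cfg.planted_overlap,
        seed=seed + 5)
    io.write_tsv(annotation, out / "annotation.tsv")
    arts["annotation"] = annotation
    return arts


@_stage("count")
def stage_count(cfg: PipelineConfig, out: Path, arts: dict) -> dict:
    for short in ("hom", "het"):
        a = arts[short]
        tag_cm = counting.count_tags(a["fastq"], a["catalog"], a["sheet"],
                                     arts["layout"], max_mismatch=cfg.max_mismatch,
                                     max_index_mismatch=cfg.max_index_mismatch)
        strain_cm = counting.aggregate_strains(tag_cm, a["catalog"])
        io.write_count_matrix(tag_cm, out / f"tag_counts_{short}.tsv",
                              out / f"ledger_{short}.tsv")
        io.write_count_matrix(strain_cm, out / f"strain_counts_{short}.tsv")
        a["tag_cm"], a["strain_cm"] = tag_cm, strain_cm
        log.info("count[%s]: %d reads, %d assigned", short, tag_cm.total_reads,
                 int(tag_cm.ledger["assigned"].sum()))
    return arts


def _condition_samples(sheet: pd.DataFrame, condition: str) -> list[str]:
    return list(sheet.loc[sheet["condition"] == condition, "sample_id"])


@_stage("filter")
def stage_filter(cfg: PipelineConfig, out: Path, arts: dict) -> dict:
    basal_tables = {}
    for short in ("hom", "het"):
        a = arts[short]
        t0 = _condition_samples(a["sheet"], "t0")
        basal = _condition_samples(a["sheet"], "basal")
        table = stats.fitness_table(a["strain_cm"].counts, t0, basal,
                                    alpha=cfg.alpha, lfc_threshold=cfg.lfc_threshold)
        gene_map = a["catalog"].set_index("strain_id")["gene"]
        table_g = table.copy()
        table_g.index = gene_map.loc[table.index].to_numpy()
        basal_tables[short] = table_g
        io.write_fitness_table(table, out / f"fitness_basal_vs_t0_{short}.tsv")

    hom = arts["hom"]
    ref = _condition_samples(hom["sheet"], "t0") + _condition_samples(hom["sheet"], "basal")
    low = filters.low_abundance_filter(hom["strain_cm"].counts, ref,
                                       threshold_frac=cfg.threshold_frac)
    unreliable_genes = filters.reliability_filter(
        basal_tables["hom"], basal_tables["het"], hom_lfc_min=cfg.hom_lfc_min,
        het_lfc_max=cfg.het_lfc_max, het_fdr_max=cfg.het_fdr_max)
    gene_to_strain = hom["catalog"].set_index("gene")["strain_id"]
    unreliable = {gene_to_strain[g] for g in unreliable_genes if g in gene_to_strain.index}
    report = filters.combine_filters(low, unreliable, hom["catalog"]["strain_id"])
    report_df = pd.DataFrame({"strain_id": sorted(hom["catalog"]["strain_id"])})
    report_df["low_abundance"] = report_df["strain_id"].isin(report.removed_low_abundance)
    report_df["unreliable"] = report_df["strain_id"].isin(report.removed_unreliable)
    report_df["retained"] = report_df["strain_id"].isin(report.retained)
    io.write_tsv(report_df, out / "filter_report.tsv")
    io.write_json(report.summary(), out / "filter_summary.json")
    arts["filter_report"] = report
    log.info("filter: %s", report.summary())
    return arts


@_stage("test")
def stage_test(cfg: PipelineConfig, out: Path, arts: dict) -> dict:
    hom = arts["hom"]
    retained = [s for s in hom["strain_cm"].counts.index
                if s in arts["filter_report"].retained]
    counts = hom["strain_cm"].counts.loc[retained]
    arts["retained_counts"] = counts
    arts["tables"] = {}
    arts["hits"] = {}
    for cond_a, cond_b in CONTRASTS:
        sa = _condition_samples(hom["sheet"], cond_a)
        sb = _condition_samples(hom["sheet"], cond_b)
        table = stats.fitness_table(counts, sa, sb, alpha=cfg.alpha,
                                    lfc_threshold=cfg.lfc_threshold)
        up, down = stats.call_hits(table, cfg.lfc_threshold, cfg.alpha)
        name = f"{cond_b}_vs_{cond_a}"
        io.write_fitness_table(table, out / f"fitness_{name}.tsv")
        arts["tables"][name] = table
        arts["hits"][name] = {"UP": up, "DOWN": down}
        log.info("test[%s]: phi=%.4f, %d UP, %d DOWN", name,
                 table.attrs["dispersion"], len(up), len(down))
    return arts


@_stage("cluster")
def stage_cluster(cfg: PipelineConfig, out: Path, arts: dict) -> dict:
    hom = arts["hom"]
    profiles = cluster.profile_matrix(arts["retained_counts"], hom["sheet"])
    assignment = cluster.qt_cluster(profiles, diameter=cfg.diameter,
                                    min_size=cfg.min_size, metric=cfg.cluster_metric)
    labels = assignment.labels().rename_axis("strain_id").reset_index()
    io.write_tsv(labels.sort_values(["cluster", "strain_id"]), out / "clusters.tsv")
    io.write_json(
        {
            "n_clusters": assignment.n_clusters,
            "sizes": [len(c) for c in assignment.clusters],
            "diameters": assignment.diameters,
            "n_unclustered": len(assignment.unclustered),
        },
        out / "cluster_summary.json",
    )
    arts["clusters"] = assignment
    log.info("cluster: %d clusters, %d unclustered", assignment.n_clusters,
             len(assignment.unclustered))
    return arts


@_stage("enrich")
def stage_enrich(cfg: PipelineConfig, out: Path, arts: dict) -> dict:
    hom = arts["hom"]
    strain_to_gene = hom["catalog"].set_index("strain_id")["gene"]
    universe = [strain_to_gene[s] for s in arts["filter_report"].retained]
    for name in ("glucose_vs_basal", "sorbitol_vs_basal"):
        for direction in ("DOWN", "UP"):
            hit_genes = [strain_to_gene[s] for s in arts["hits"][name][direction]]
            res = enrich.hypergeometric_enrichment(hit_genes, universe,
                                                   arts["annotation"])
            io.write_tsv(res, out / f"enrichment_{name}_{direction}.tsv")
    arts["universe_genes"] = universe
    return arts


@_stage("overlap")
def stage_overlap(cfg: PipelineConfig, out: Path, arts: dict) -> dict:
    hom = arts["hom"]
    strain_to_gene = hom["catalog"].set_index("strain_id")["gene"]
    result = {}
    for direction in ("DOWN", "UP"):
        a = [strain_to_gene[s] for s in arts["hits"]["glucose_vs_basal"][direction]]
        b = [strain_to_gene[s] for s in arts["hits"]["sorbitol_vs_basal"][direction]]
        result[direction] = enrich.overlap_test(a, b, arts["universe_genes"]).to_dict()
    io.write_json(result, out / "overlap.json")
    arts["overlap"] = result
    return arts


def run_all(cfg: PipelineConfig) -> dict:
    """Run every stage and write a checksum manifest; returns the artifacts."""
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    io.write_json(cfg.to_dict(), out / "config.json")
    arts = stage_simulate(cfg, out)
    arts = stage_count(cfg, out, arts)
    arts = stage_filter(cfg, out, arts)
    arts = stage_test(cfg, out, arts)
    arts = stage_cluster(cfg, out, arts)
    arts = stage_enrich(cfg, out, arts)
    arts = stage_overlap(cfg, out, arts)
    manifest = {
        "package_version": __version__,
        "seed": cfg.seed,
        "checksums": {
            p.name: _sha256(p)
            for p in sorted(out.iterdir())
            if p.is_file() and p.name != "manifest.json"
        },
    }
    io.write_json(manifest, out / "manifest.json")
    arts["manifest"] = manifest
    return arts
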