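"""End-to-end orchestration: preprocess -> annotate -> hairpin -> diffexpr ->
targets -> enrich, with a manifest of outputs.

``run_stages`` is the in-memory core; ``run_pipeline`` wraps it with file I/O,
per-stage logging and an output manifest (file hashes + parameters), so a
rerun with an identical configuration is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

from . import annotate, diffexpr, enrich, hairpin, preprocess, target_scan
from .formats import (
    ReferenceSet,
    SmallRNARead,
    read_fasta,
    read_fastq,
    read_gff3,
    write_tsv,
)
from .simdata import DEFAULT_ADAPTER

logger = logging.getLogger("mirddr")

_KNOWN_KEYS = {
    "fastq_ck",
    "fastq_tr",
    "genome",
    "mirna_mature",
    "mirna_hairpin",
    "transcripts",
    "gene_models",
    "class_refs",
    "go_map",
    "pathway_map",
    "outdir",
    "seed",
    "adapter",
    "min_len",
    "max_len",
    "flank",
    "min_read_support",
    "max_expectation",
    "fdr_method",
    "floor_value",
    "exclusion_threshold",
    "lfc_cutoff",
    "q_cutoff",
    "nd_min_reads",
}


@dataclass
class PipelineConfig:
    """Strictly validated pipeline settings; defaults mirror the published
    analysis (18-30 nt window, 0.01 floor, |log2FC| > 1, FDR < 0.05, ND < 5)."""

    fastq_ck: str
    fastq_tr: str
    genome: str
    mirna_mature: str
    transcripts: str
    outdir: str
    mirna_hairpin: str | None = None
    gene_models: str | None = None
    class_refs: dict[str, str] = field(default_factory=dict)
    go_map: str | None = None
    pathway_map: str | None = None
    seed: int = 0
    adapter: str = DEFAULT_ADAPTER
    min_len: int = 18
    max_len: int = 30
    flank: int = 120
    min_read_support: int = 2
    max_expectation: float = 4.0
    fdr_method: str = "bh"
    floor_value: float = diffexpr.FLOOR
    exclusion_threshold: float = diffexpr.EXCLUSION_THRESHOLD
    lfc_cutoff: float = diffexpr.LFC_CUTOFF
    q_cutoff: float = diffexpr.Q_CUTOFF
    nd_min_reads: int = diffexpr.ND_MIN_READS

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - _KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate_inputs(self) -> None:
        for key in ("fastq_ck", "fastq_tr", "genome", "mirna_mature", "transcripts"):
            path = getattr(self, key)
            if not Path(path).exists():
                raise FileNotFoundError(f"config key {key}: missing file {path}")


@dataclass
class PipelineResult:
    qc_reports: dict[str, preprocess.QCReport]
    length_dists: dict[str, dict[int, float]]
    tags: list[annotate.UniqueTag]
    class_table: pd.DataFrame
    known: list[annotate.KnownMiRNA]
    novel: list[hairpin.NovelLocus]
    records: list[diffexpr.ExpressionRecord]
    families: list[diffexpr.FamilySummary]
    sites: list[target_scan.TargetSite]
    genes_per_mirna: dict[str, set[str]]
    enrichment: dict[str, list[enrich.EnrichmentResult]]
    n1: int = 0
    n2: int = 0


def run_stages(
    refs: ReferenceSet,
    reads_ck: list[SmallRNARead],
    reads_tr: list[SmallRNARead],
    config: PipelineConfig | None = None,
    annotations: Mapping[str, list[enrich.TermAnnotation]] | None = None,
) -> PipelineResult:
    """The whole analysis on in-memory inputs."""
    cfg = config or PipelineConfig(
        fastq_ck="", fastq_tr="", genome="", mirna_mature="", transcripts="", outdir=""
    )
    qc_reports: dict[str, preprocess.QCReport] = {}
    clean: dict[str, list[SmallRNARead]] = {}
    for name, reads in (("ck", reads_ck), ("tr", reads_tr)):
        t0 = time.perf_counter()
        result = preprocess.preprocess_library(reads, cfg.adapter)
        selected = preprocess.length_select(result.clean, cfg.min_len, cfg.max_len)
        qc_reports[name] = result.report
        clean[name] = selected
        logger.info(
            "stage=preprocess lib=%s wall=%.2fs raw=%d clean=%d selected=%d",
            name, time.perf_counter() - t0, len(reads), len(result.clean), len(selected),
        )
    length_dists = {
        name: preprocess.length_distribution(reads) for name, reads in clean.items()
    }

    t0 = time.perf_counter()
    tags = annotate.collapse_tags(clean["ck"], clean["tr"])
    annotate.annotate_tags(tags, refs)
    class_table = annotate.class_count_table(tags)
    known = annotate.known_mirna_table(tags, refs)
    logger.info(
        "stage=annotate wall=%.2fs tags=%d known=%d",
        time.perf_counter() - t0, len(tags), len(known),
    )

    t0 = time.perf_counter()
    hp_params = hairpin.HairpinParams(
        flank=cfg.flank, min_read_support=cfg.min_read_support
    )
    novel = hairpin.discover_novel(tags, refs.genome, hp_params)
    logger.info(
        "stage=hairpin wall=%.2fs candidates=%d", time.perf_counter() - t0, len(novel)
    )

    # library totals for normalization: clean-read counts after size selection
    n1 = sum(r.count_ck for r in tags)
    n2 = sum(r.count_tr for r in tags)
    counts = [(k.name, k.count_ck, k.count_tr) for k in known]
    counts += [(l.name, l.tag.count_ck, l.tag.count_tr) for l in novel]
    t0 = time.perf_counter()
    records = diffexpr.differential_expression(
        counts, n1, n2,
        floor=cfg.floor_value,
        exclusion_threshold=cfg.exclusion_threshold,
        lfc_cutoff=cfg.lfc_cutoff,
        q_cutoff=cfg.q_cutoff,
        fdr_method=cfg.fdr_method,
    )
    families = diffexpr.family_table(known, n1, n2, cfg.floor_value, cfg.nd_min_reads)
    logger.info(
        "stage=diffexpr wall=%.2fs tested=%d de=%d",
        time.perf_counter() - t0,
        sum(r.status != "EXCLUDED" for r in records),
        sum(r.status in {"UP", "DOWN"} for r in records),
    )

    de_ids = {r.mirna_id for r in records if r.status in {"UP", "DOWN"}}
    queries = {k.name: k.mature_seq for k in known if k.name in de_ids}
    queries.update(
        {
            l.name: l.candidate.precursor_seq[
                l.candidate.mature_arm[0] : l.candidate.mature_arm[0]
                + l.candidate.mature_arm[1]
            ]
            for l in novel
            if l.name in de_ids
        }
    )
    t0 = time.perf_counter()
    sites = target_scan.scan_all(
        queries, refs.transcripts, target_scan.ScanParams(max_expectation=cfg.max_expectation)
    )
    genes_per_mirna = target_scan.collapse_to_genes(
        sites, refs.gene_models.transcript_to_gene or None
    )
    logger.info(
        "stage=targets wall=%.2fs queries=%d sites=%d",
        time.perf_counter() - t0, len(queries), len(sites),
    )

    enrichment: dict[str, list[enrich.EnrichmentResult]] = {}
    if annotations:
        target_genes = sorted({g for gs in genes_per_mirna.values() for g in gs})
        for label, ann in annotations.items():
            enrichment[label] = enrich.enrich(target_genes, ann)

    return PipelineResult(
        qc_reports=qc_reports,
        length_dists=length_dists,
        tags=tags,
        class_table=class_table,
        known=known,
        novel=novel,
        records=records,
        families=families,
        sites=sites,
        genes_per_mirna=genes_per_mirna,
        enrichment=enrichment,
        n1=n1,
        n2=n2,
    )


def load_references(config: PipelineConfig) -> ReferenceSet:
    refs = ReferenceSet()
    refs.genome = read_fasta(config.genome)
    refs.mirna_mature = read_fasta(config.mirna_mature)
    if config.mirna_hairpin:
        refs.mirna_hairpin = read_fasta(config.mirna_hairpin)
    refs.transcripts = read_fasta(config.transcripts)
    if config.gene_models:
        refs.gene_models = read_gff3(config.gene_models)
    for label, path in config.class_refs.items():
        refs.class_refs[label] = read_fasta(path)
    refs.validate()
    return refs


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """File-based run; returns the manifest (also written to the outdir)."""
    config.validate_inputs()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    refs = load_references(config)
    reads_ck = read_fastq(config.fastq_ck)
    reads_tr = read_fastq(config.fastq_tr)
    annotations: dict[str, list[enrich.TermAnnotation]] = {}
    if config.go_map:
        annotations["go"] = enrich.read_annotation_map(config.go_map)
    if config.pathway_map:
        annotations["pathway"] = enrich.read_annotation_map(config.pathway_map)

    result = run_stages(refs, reads_ck, reads_tr, config, annotations)

    stage_outputs: dict[str, list[Path]] = {}

    qc = preprocess.qc_summary(result.qc_reports)
    p = outdir / "qc.tsv"
    write_tsv(qc, p)
    lengths = pd.DataFrame(
        [
            {"library": lib, "length": length, "proportion": prop}
            for lib, dist in result.length_dists.items()
            for length, prop in dist.items()
        ]
    )
    p2 = outdir / "lengths.tsv"
    write_tsv(lengths, p2)
    stage_outputs["preprocess"] = [p, p2]

    p = outdir / "tags.tsv"
    write_tsv(annotate.tags_to_frame(result.tags), p)
    p2 = outdir / "class_table.tsv"
    write_tsv(result.class_table, p2)
    stage_outputs["annotate"] = [p, p2]

    p = outdir / "novel.tsv"
    write_tsv(hairpin.novel_table(result.novel), p)
    stage_outputs["hairpin"] = [p]

    p = outdir / "de.tsv"
    write_tsv(diffexpr.expression_frame(result.records), p)
    p2 = outdir / "families.tsv"
    write_tsv(diffexpr.family_frame(result.families), p2)
    p3 = outdir / "logtpm.tsv"
    write_tsv(diffexpr.log_tpm_matrix(result.records), p3)
    stage_outputs["diffexpr"] = [p, p2, p3]

    p = outdir / "targets.tsv"
    write_tsv(target_scan.sites_frame(result.sites), p)
    stage_outputs["targets"] = [p]

    enrich_paths = []
    for label, res in result.enrichment.items():
        p = outdir / f"enrich_{label}.tsv"
        write_tsv(enrich.enrichment_frame(res), p)
        enrich_paths.append(p)
    stage_outputs["enrich"] = enrich_paths

    manifest = {
        "config": {k: v for k, v in vars(config).items()},
        "stages": [
            {
                "stage": stage,
                "outputs": {str(path): _sha256(path) for path in paths},
            }
            for stage, paths in stage_outputs.items()
        ],
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest


__all__ = [
    "PipelineConfig",
    "PipelineResult",
    "run_stages",
    "load_references",
    "run_pipeline",
]
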