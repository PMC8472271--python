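"""Synthetic two-condition small-RNA libraries with known ground truth.

The generator emulates the composition of a plant root small-RNA experiment
comparing a control (CK) and a genotoxin-treated library:

* known miRNA hairpins embedded in dedicated genome contigs, with mature tags
  whose abundance carries planted log2 fold changes (including forced
  dropouts);
* novel miRNA loci built as perfect inverted repeats (stem >= 16 bp, loop >=
  3 nt) so the hairpin stage can rediscover them, a subset with sequenced
  star tags in proper duplex geometry;
* degradation-fragment contaminants for each annotation class (rRNA, tRNA,
  snRNA, snoRNA, repeat, NAT), exon/intron tags on an annotated gene contig,
  mapped-but-unannotated tags and unmapped tags;
* a transcriptome with planted target sites (perfect, one-mismatch and G:U
  variants) plus annotation maps with one deliberately enriched term.

Counts follow a per-tag negative binomial (Poisson when the dispersion is 0,
matching the sampling model the two-library exact test assumes); per-tag mean
counts are log-uniform. Reads are exact tag copies with the 3' adapter
appended; optional planted defects (N-rich, homopolymer, adapterless reads)
are constructed non-overlapping so QC category counts can be checked exactly.
A fixed seed yields byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .formats import (
    Exon,
    GeneModels,
    ReferenceSet,
    SmallRNARead,
    revcomp,
    write_fasta,
    write_fastq,
    write_gff3,
    write_tsv,
)

#: Illumina TruSeq small-RNA 3' adapter.
DEFAULT_ADAPTER = "TGGAATTCTCGGGTGCCAAGG"

CONTAMINANT_CLASSES = ("rRNA", "tRNA", "snRNA", "snoRNA", "repeat", "NAT")


class SimConfigError(ValueError):
    pass


@dataclass
class SimConfig:
    """All knobs of the generator; the defaults are the study conditions the
    pipeline is validated under (20 known miRNAs, 5 of them planted at
    |log2FC| = 2, two libraries of 2e5 reads, Poisson counts)."""

    seed: int = 0
    n_known_mirnas: int = 20
    n_novel_loci: int = 5
    n_star_supported: int = 3
    n_class_contaminant_tags: int = 8
    n_exon_intron_tags: int = 2  # per exon/intron x sense/antisense cell
    n_other_tags: int = 8
    n_unmapped_tags: int = 4
    library_sizes: tuple[int, int] = (200_000, 200_000)
    planted_log2fc: dict[str, float] = field(default_factory=dict)
    dropout_mirnas: set[str] = field(default_factory=set)  # zero in treated
    adapter: str = DEFAULT_ADAPTER
    dispersion: float = 0.0  # NB overdispersion; 0 -> Poisson
    mature_length: int = 21
    novel_arm_length: int = 60
    loop_length: int = 8
    known_mean_range: tuple[float, float] = (50.0, 2000.0)
    novel_mean_range: tuple[float, float] = (5.0, 40.0)
    contaminant_mean_range: tuple[float, float] = (100.0, 5000.0)
    star_fraction: float = 0.3  # star mean relative to its mature mean
    n_rich_rate: float = 0.0
    homopolymer_rate: float = 0.0
    adapterless_rate: float = 0.0
    n_target_mirnas: int = 5  # miRNAs given planted transcript target sites
    n_background_transcripts: int = 10

    def validate(self) -> None:
        if min(self.library_sizes) <= 0:
            raise SimConfigError("library_sizes must be positive")
        if self.loop_length < 3:
            raise SimConfigError("hairpin loop must be at least 3 nt")
        if self.novel_arm_length < max(16, self.mature_length):
            raise SimConfigError(
                "novel_arm_length must allow a >=16 bp stem containing the mature tag"
            )
        if len(self.adapter) < 6:
            raise SimConfigError("adapter must be at least 6 nt")
        if self.dispersion < 0:
            raise SimConfigError("dispersion must be non-negative")


def default_config(seed: int = 0) -> SimConfig:
    """The standard validation scenario: 20 known miRNAs, the first five
    planted at log2FC +2/+2/-2/-2/+2, everything else null."""
    cfg = SimConfig(seed=seed)
    names = known_mirna_names(cfg.n_known_mirnas)
    for name, fc in zip(names, (2.0, 2.0, -2.0, -2.0, 2.0)):
        cfg.planted_log2fc[name] = fc
    return cfg


def known_mirna_names(n: int) -> list[str]:
    """Species-prefixed names; the first two share a family (miR101a/b) so the
    family summary has a multi-member row."""
    names = []
    for i in range(n):
        if i == 0:
            names.append("osa-miR101a")
        elif i == 1:
            names.append("osa-miR101b-3p")
        else:
            names.append(f"osa-miR{100 + i}")
    return names


@dataclass
class PlantedTag:
    tag_id: str
    sequence: str
    class_label: str
    log2fc: float
    mean_ck: float = 0.0
    mean_tr: float = 0.0
    count_ck: int = 0
    count_tr: int = 0
    contig: str = ""
    star_of: str | None = None


@dataclass
class NovelTruth:
    name: str
    contig: str
    mature: str
    star: str
    precursor_start: int  # 0-based on the contig
    precursor_end: int
    star_supported: bool


@dataclass
class SimTruth:
    """Everything the generator knows that the pipeline must rediscover."""

    tags: list[PlantedTag] = field(default_factory=list)
    novel_loci: list[NovelTruth] = field(default_factory=list)
    target_sites: list[tuple[str, str, str]] = field(default_factory=list)
    # (mirna name, transcript id, kind: perfect/mismatch/gu)
    enriched_term: str = "T:repair"

    def frame(self) -> pd.DataFrame:
        star_by_name = {n.name: n.star_supported for n in self.novel_loci}
        rows = []
        for t in self.tags:
            rows.append(
                {
                    "tag_id": t.tag_id,
                    "sequence": t.sequence,
                    "class": t.class_label,
                    "count_ck": t.count_ck,
                    "count_tr": t.count_tr,
                    "planted_log2fc": t.log2fc,
                    "contig": t.contig,
                    "star_of": t.star_of or "",
                    "star_supported": star_by_name.get(t.tag_id, ""),
                }
            )
        return pd.DataFrame(rows)


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


# ---------------------------------------------------------------------------
# References
# ---------------------------------------------------------------------------

def build_references(config: SimConfig) -> tuple[ReferenceSet, SimTruth]:
    """Genome, class references, miRNA references, annotated gene models,
    transcriptome with planted target sites, plus the ground truth."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    refs = ReferenceSet()
    truth = SimTruth()

    # --- known miRNA hairpins, one contig each -----------------------------
    names = known_mirna_names(config.n_known_mirnas)
    unknown = set(config.planted_log2fc) - set(names)
    if unknown:
        raise SimConfigError(f"planted_log2fc names not generated: {sorted(unknown)}")
    if not set(config.dropout_mirnas) <= set(names):
        raise SimConfigError("dropout_mirnas must be generated miRNA names")
    for name in names:
        mature = _random_seq(rng, config.mature_length)
        arm = mature + _random_seq(rng, 15)
        precursor = arm + _random_seq(rng, config.loop_length) + revcomp(arm)
        contig = f"chr_kmir_{name}"
        refs.genome[contig] = (
            _random_seq(rng, 25) + precursor + _random_seq(rng, 25)
        )
        refs.mirna_mature[name] = mature
        refs.mirna_hairpin[name] = precursor
        truth.tags.append(
            PlantedTag(
                name,
                mature,
                "known_miRNA",
                config.planted_log2fc.get(name, 0.0),
                contig=contig,
            )
        )

    # --- novel loci: perfect inverted repeats on dedicated contigs ---------
    arm_len = config.novel_arm_length
    for j in range(config.n_novel_loci):
        name = f"novel_{j + 1}"
        mature = _random_seq(rng, config.mature_length)
        arm = mature + _random_seq(rng, arm_len - config.mature_length)
        precursor = arm + _random_seq(rng, config.loop_length) + revcomp(arm)
        # short flanks: stray genomic bases inside the excision window can
        # displace stem pairs under max-pairing folding; 2 nt bounds the
        # resulting duplex asymmetry to the tolerated bulge size
        flank = 2
        contig = f"chr_novel_{j + 1}"
        refs.genome[contig] = (
            _random_seq(rng, flank) + precursor + _random_seq(rng, flank)
        )
        # star 5' end = pairing partner of the mature 3' end in the perfect stem
        partner_of_mature_end = len(precursor) - 1 - (config.mature_length - 1)
        star = precursor[partner_of_mature_end : partner_of_mature_end + config.mature_length]
        supported = j < config.n_star_supported
        truth.novel_loci.append(
            NovelTruth(
                name, contig, mature, star, flank, flank + len(precursor), supported
            )
        )
        truth.tags.append(PlantedTag(name, mature, "other", 0.0, contig=contig))
        if supported:
            truth.tags.append(
                PlantedTag(f"{name}_star", star, "other", 0.0, contig=contig, star_of=name)
            )

    # --- class contaminants -------------------------------------------------
    for cls in CONTAMINANT_CLASSES:
        refs.class_refs[cls] = {}
        parents = []
        for k in range(config.n_class_contaminant_tags):
            tag_len = int(rng.integers(20, 27))
            tag = _random_seq(rng, tag_len)
            parent = _random_seq(rng, 30) + tag + _random_seq(rng, 30)
            pname = f"{cls}_src_{k + 1}"
            refs.class_refs[cls][pname] = parent
            parents.append(parent)
            truth.tags.append(
                PlantedTag(f"{cls}_{k + 1}", tag, cls, 0.0, contig=f"chr_{cls}")
            )
        spacer = _random_seq(rng, 20)
        refs.genome[f"chr_{cls}"] = spacer.join(parents)

    # --- annotated gene contig: exon/intron sense/antisense tags -----------
    gene_contig = "chr_gene"
    gene_seq = _random_seq(rng, 1100)
    refs.genome[gene_contig] = gene_seq
    refs.gene_models = GeneModels(
        exons=[
            Exon(gene_contig, 100, 400, "+", "gene_models_1"),
            Exon(gene_contig, 700, 1000, "+", "gene_models_1"),
        ]
    )
    regions = {"exon": (100, 400), "intron": (400, 700)}
    for kind, (lo, hi) in regions.items():
        for sense in (True, False):
            for k in range(config.n_exon_intron_tags):
                tag_len = int(rng.integers(20, 27))
                start = int(rng.integers(lo, hi - tag_len))
                sub = gene_seq[start : start + tag_len]
                tag = sub if sense else revcomp(sub)
                label = f"{kind}_{'sense' if sense else 'antisense'}"
                truth.tags.append(
                    PlantedTag(f"{label}_{k + 1}", tag, label, 0.0, contig=gene_contig)
                )

    # --- mapped-but-unannotated and unmapped tags ---------------------------
    other_contig = "chr_other"
    other_seq = _random_seq(rng, 300 + 60 * config.n_other_tags)
    refs.genome[other_contig] = other_seq
    for k in range(config.n_other_tags):
        tag_len = int(rng.integers(20, 27))
        start = 150 + 60 * k
        tag = other_seq[start : start + tag_len]
        truth.tags.append(PlantedTag(f"other_{k + 1}", tag, "other", 0.0, contig=other_contig))
    genome_blob = " ".join(refs.genome.values())
    for k in range(config.n_unmapped_tags):
        while True:
            tag = _random_seq(rng, 25)
            if tag not in genome_blob and revcomp(tag) not in genome_blob:
                break
        truth.tags.append(PlantedTag(f"unmapped_{k + 1}", tag, "unmapped", 0.0))

    # --- transcriptome with planted target sites ----------------------------
    target_names = names[: config.n_target_mirnas]
    for name in target_names:
        mature = refs.mirna_mature[name]
        site = revcomp(mature)  # perfect cleavage-style site
        tx = f"tx_{name}_perfect"
        refs.transcripts[tx] = _random_seq(rng, 20) + site + _random_seq(rng, 20)
        truth.target_sites.append((name, tx, "perfect"))

        # one mismatch at miRNA position 15 (outside the seed)
        pos = 15
        site_idx = len(mature) - pos  # 0-based site base opposite position 15
        old = site[site_idx]
        new = {"A": "C", "C": "A", "G": "T", "T": "G"}[old]
        mm_site = site[:site_idx] + new + site[site_idx + 1 :]
        tx = f"tx_{name}_mismatch"
        refs.transcripts[tx] = _random_seq(rng, 20) + mm_site + _random_seq(rng, 20)
        truth.target_sites.append((name, tx, "mismatch"))

        # one G:U wobble in the 3' half, when the mature sequence allows it
        gu_pos = next(
            (p for p in range(14, len(mature) + 1) if mature[p - 1] in "GT"), None
        )
        if gu_pos is not None:
            site_idx = len(mature) - gu_pos
            wobble_base = "T" if mature[gu_pos - 1] == "G" else "G"
            gu_site = site[:site_idx] + wobble_base + site[site_idx + 1 :]
            tx = f"tx_{name}_gu"
            refs.transcripts[tx] = _random_seq(rng, 20) + gu_site + _random_seq(rng, 20)
            truth.target_sites.append((name, tx, "gu"))
    for k in range(config.n_background_transcripts):
        refs.transcripts[f"tx_bg_{k + 1}"] = _random_seq(rng, 200)

    refs.validate()
    return refs, truth


def annotation_maps(
    config: SimConfig, refs: ReferenceSet, truth: SimTruth
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """GO-style and pathway-style gene->term maps over the transcriptome.

    Every transcript gets a generic term; the transcripts carrying planted
    target sites share one 'repair' term per map, so enrichment has a planted
    positive."""
    rng = np.random.default_rng(config.seed + 1)
    site_txs = sorted({tx for _, tx, _ in truth.target_sites})
    all_txs = sorted(refs.transcripts)
    rows_go, rows_pw = [], []
    for tx in all_txs:
        rows_go.append((tx, "GO:0008150", "biological_process", "BP"))
        rows_pw.append((tx, "path:osa01100", "metabolic pathways", "pathway"))
    for tx in site_txs:
        rows_go.append((tx, "GO:0006281", "DNA repair", "BP"))
        rows_pw.append((tx, "path:osa03430", "mismatch repair", "pathway"))
    # a scattering of unenriched terms
    for i, tx in enumerate(all_txs):
        if i % 3 == 0:
            rows_go.append((tx, "GO:0003674", "molecular_function", "MF"))
        if i % 4 == 0:
            rows_go.append((tx, "GO:0005575", "cellular_component", "CC"))
    cols = ["gene", "term_id", "term_name", "category"]
    return pd.DataFrame(rows_go, columns=cols), pd.DataFrame(rows_pw, columns=cols)


# ---------------------------------------------------------------------------
# Libraries
# ---------------------------------------------------------------------------

def _draw_counts(
    rng: np.random.Generator, means: np.ndarray, dispersion: float
) -> np.ndarray:
    if dispersion <= 0:
        return rng.poisson(means)
    n = 1.0 / dispersion
    p = n / (n + means)
    return rng.negative_binomial(n, p)


@dataclass
class SimLibraries:
    reads_ck: list[SmallRNARead]
    reads_tr: list[SmallRNARead]
    truth: SimTruth

    def truth_frame(self) -> pd.DataFrame:
        return self.truth.frame()


def simulate_libraries(
    config: SimConfig, refs: ReferenceSet, truth: SimTruth
) -> SimLibraries:
    """Draw per-tag counts and emit adapter-ligated reads for both libraries.

    CK means are log-uniform per tag class; treated means are CK means scaled
    by 2^planted_log2fc (zeroed for dropouts); each library's means are then
    scaled to its configured size, which leaves fold changes intact on the
    reads-per-million scale.
    """
    config.validate()
    rng = np.random.default_rng(config.seed + 2)
    ranges = {
        "known_miRNA": config.known_mean_range,
        "novel": config.novel_mean_range,
        "contaminant": config.contaminant_mean_range,
    }
    mature_mean: dict[str, float] = {}
    for tag in truth.tags:
        if tag.class_label == "known_miRNA":
            lo, hi = ranges["known_miRNA"]
        elif tag.tag_id.startswith("novel_"):
            lo, hi = ranges["novel"]
        else:
            lo, hi = ranges["contaminant"]
        if tag.star_of is not None:
            base = mature_mean[tag.star_of] * config.star_fraction
            tag.mean_ck = max(2.0, base)
        else:
            tag.mean_ck = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
            if tag.tag_id.startswith("novel_"):
                mature_mean[tag.tag_id] = tag.mean_ck
        tag.mean_tr = tag.mean_ck * 2.0 ** tag.log2fc
        if tag.tag_id in config.dropout_mirnas:
            tag.mean_tr = 0.0

    mu_ck = np.array([t.mean_ck for t in truth.tags])
    mu_tr = np.array([t.mean_tr for t in truth.tags])
    mu_ck *= config.library_sizes[0] / mu_ck.sum()
    mu_tr *= config.library_sizes[1] / mu_tr.sum()
    counts_ck = _draw_counts(rng, mu_ck, config.dispersion)
    counts_tr = _draw_counts(rng, mu_tr, config.dispersion)
    for tag, ck, tr in zip(truth.tags, counts_ck, counts_tr):
        tag.count_ck = int(ck)
        tag.count_tr = int(tr)

    libs = []
    for lib, attr in (("ck", "count_ck"), ("tr", "count_tr")):
        reads: list[SmallRNARead] = []
        serial = 0
        for tag in truth.tags:
            seq = tag.sequence + config.adapter
            qual = tuple([40] * len(seq))
            for _ in range(getattr(tag, attr)):
                serial += 1
                reads.append(SmallRNARead(f"{lib}_{serial}_{tag.tag_id}", seq, qual))
        reads.extend(_defect_reads(config, rng, lib))
        libs.append(reads)
    return SimLibraries(libs[0], libs[1], truth)


def _defect_reads(
    config: SimConfig, rng: np.random.Generator, lib: str
) -> list[SmallRNARead]:
    """Planted QC-failure reads; each defect trips exactly one filter."""
    out: list[SmallRNARead] = []
    size = config.library_sizes[0 if lib == "ck" else 1]
    n_rich = int(round(config.n_rich_rate * size))
    homo = int(round(config.homopolymer_rate * size))
    noadapt = int(round(config.adapterless_rate * size))
    for i in range(n_rich):
        insert = "ACGTACGTACGTACGTACGT" + "NNNNN"  # 5/25 N = 20%
        seq = insert + config.adapter
        out.append(SmallRNARead(f"{lib}_nrich_{i + 1}", seq, tuple([40] * len(seq))))
    for i in range(homo):
        seq = "A" * 24 + config.adapter
        out.append(SmallRNARead(f"{lib}_homo_{i + 1}", seq, tuple([40] * len(seq))))
    seed8 = config.adapter[:8]
    for i in range(noadapt):
        while True:
            seq = _random_seq(rng, 40)
            if seed8 not in seq:
                break
        out.append(SmallRNARead(f"{lib}_noadapt_{i + 1}", seq, tuple([40] * len(seq))))
    return out


def simulate_null_tag_counts(
    n_tags: int,
    library_size: int,
    seed: int,
    dispersion: float = 0.0,
    mean_range: tuple[float, float] = (10.0, 200.0),
) -> tuple[np.ndarray, np.ndarray, int, int]:
    """Count-level null simulation for test calibration: paired Poisson (or
    NB) draws with equal means for ``n_tags`` tags. Returns (x, y, N1, N2)."""
    rng = np.random.default_rng(seed)
    mu = np.exp(rng.uniform(np.log(mean_range[0]), np.log(mean_range[1]), n_tags))
    mu *= library_size / mu.sum()
    x = _draw_counts(rng, mu, dispersion)
    y = _draw_counts(rng, mu, dispersion)
    return x, y, int(x.sum()), int(y.sum())


# ---------------------------------------------------------------------------
# On-disk outputs
# ---------------------------------------------------------------------------

def write_simulation(config: SimConfig, outdir: str | Path) -> dict[str, Path]:
    """Materialise a full simulated experiment under ``outdir``."""
    outdir = Path(outdir)
    refdir = outdir / "refs"
    refdir.mkdir(parents=True, exist_ok=True)
    refs, truth = build_references(config)
    libs = simulate_libraries(config, refs, truth)
    go_map, pathway_map = annotation_maps(config, refs, truth)

    paths = {
        "reads_ck": outdir / "reads_ck.fastq.gz",
        "reads_tr": outdir / "reads_tr.fastq.gz",
        "truth": outdir / "truth.tsv",
        "go_map": outdir / "go_map.tsv",
        "pathway_map": outdir / "pathway_map.tsv",
        "genome": refdir / "genome.fasta",
        "mature": refdir / "mirna_mature.fasta",
        "hairpin": refdir / "mirna_hairpin.fasta",
        "transcripts": refdir / "transcripts.fasta",
        "gene_models": refdir / "gene_models.gff3",
    }
    write_fastq(libs.reads_ck, paths["reads_ck"])
    write_fastq(libs.reads_tr, paths["reads_tr"])
    write_tsv(libs.truth_frame(), paths["truth"])
    write_tsv(go_map, paths["go_map"])
    write_tsv(pathway_map, paths["pathway_map"])
    write_fasta(refs.genome, paths["genome"])
    write_fasta(refs.mirna_mature, paths["mature"])
    write_fasta(refs.mirna_hairpin, paths["hairpin"])
    write_fasta(refs.transcripts, paths["transcripts"])
    write_gff3(refs.gene_models, paths["gene_models"])
    for cls, seqs in refs.class_refs.items():
        p = refdir / f"{cls}.fasta"
        write_fasta(seqs, p)
        paths[f"class_{cls}"] = p
    return paths


__all__ = [
    "DEFAULT_ADAPTER",
    "CONTAMINANT_CLASSES",
    "SimConfig",
    "SimConfigError",
    "SimTruth",
    "SimLibraries",
    "PlantedTag",
    "NovelTruth",
    "default_config",
    "known_mirna_names",
    "build_references",
    "annotation_maps",
    "simulate_libraries",
    "simulate_null_tag_counts",
    "write_simulation",
]
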