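"""Readers and writers for the on-disk formats the pipeline touches.

Conventions
-----------
* FASTQ is 4-line, Phred+33 only. ``U`` is normalized to ``T`` on ingest so
  that all internal sequence comparison happens in the DNA alphabet; the RNA
  alphabet is restored only where hairpin structures are reported.
* All interval coordinates are 0-based half-open internally and 1-based
  inclusive on any file we emit (GFF3 convention on input).
* Ambiguity codes other than ``N`` are rejected.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import pandas as pd
from Bio import SeqIO

VALID_BASES = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class FormatError(ValueError):
    """Malformed input file."""


def normalize_sequence(seq: str) -> str:
    """Uppercase, U->T. Raises on ambiguity codes other than N."""
    s = seq.strip().upper().replace("U", "T")
    bad = set(s) - VALID_BASES
    if bad:
        raise FormatError(f"invalid sequence characters: {sorted(bad)}")
    return s


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class SmallRNARead:
    """One sequencing read: identifier, sequence, per-base Phred scores."""

    read_id: str
    sequence: str
    quality: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.sequence) == 0:
            raise ValueError(f"read {self.read_id!r}: empty sequence")
        if len(self.quality) != len(self.sequence):
            raise ValueError(
                f"read {self.read_id!r}: quality length {len(self.quality)} "
                f"!= sequence length {len(self.sequence)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class Exon:
    """Gene-model interval, 0-based half-open on ``contig``."""

    contig: str
    start: int
    end: int
    strand: str
    gene_id: str
    transcript_id: str | None = None
    kind: str = "exon"  # exon or intron


@dataclass
class GeneModels:
    """Exon intervals per gene; introns are the gaps between a gene's exons."""

    exons: list[Exon] = field(default_factory=list)
    transcript_to_gene: dict[str, str] = field(default_factory=dict)

    def introns(self) -> list[Exon]:
        by_gene: dict[str, list[Exon]] = {}
        for ex in self.exons:
            by_gene.setdefault(ex.gene_id, []).append(ex)
        out: list[Exon] = []
        for gene_id, exs in by_gene.items():
            exs = sorted(exs, key=lambda e: e.start)
            for a, b in zip(exs, exs[1:]):
                if b.start > a.end and a.contig == b.contig:
                    out.append(
                        Exon(a.contig, a.end, b.start, a.strand, gene_id, kind="intron")
                    )
        return out


@dataclass
class ReferenceSet:
    """All reference material the annotation cascade consults.

    ``class_refs`` maps a class label (rRNA, tRNA, snRNA, snoRNA, repeat, NAT)
    to named reference sequences; tags are classified by exact substring
    membership in either orientation.
    """

    genome: dict[str, str] = field(default_factory=dict)
    class_refs: dict[str, dict[str, str]] = field(default_factory=dict)
    mirna_mature: dict[str, str] = field(default_factory=dict)
    mirna_hairpin: dict[str, str] = field(default_factory=dict)
    transcripts: dict[str, str] = field(default_factory=dict)
    gene_models: GeneModels = field(default_factory=GeneModels)

    def validate(self) -> None:
        for name, seq in self.mirna_mature.items():
            if not seq:
                raise ValueError(f"empty mature sequence for {name}")
        for pool in (self.genome, self.mirna_hairpin, self.transcripts):
            for name, seq in pool.items():
                if not seq:
                    raise ValueError(f"empty reference sequence {name}")


# ---------------------------------------------------------------------------
# FASTQ
# ---------------------------------------------------------------------------

class _GzipTextWriter(io.TextIOWrapper):
    """Gzip text writer with a zeroed mtime header so identical content gives
    identical bytes (the determinism contract of the simulator)."""

    def __init__(self, path: Path):
        self._raw = open(path, "wb")
        self._gz = gzip.GzipFile(filename="", mode="wb", fileobj=self._raw, mtime=0)
        super().__init__(self._gz)

    def close(self) -> None:
        super().close()
        if not self._raw.closed:
            self._raw.close()


def _open_text(path: str | Path, mode: str = "rt") -> io.TextIOBase:
    path = Path(path)
    if path.suffix == ".gz":
        if "w" in mode:
            return _GzipTextWriter(path)
        return gzip.open(path, mode)  # type: ignore[return-value]
    return open(path, mode)


def read_fastq(path: str | Path) -> list[SmallRNARead]:
    """Parse a 4-line-record Phred+33 FASTQ file.

    Malformed records raise :class:`FormatError` naming the offending line.
    """
    reads: list[SmallRNARead] = []
    with _open_text(path) as fh:
        lineno = 0
        while True:
            header = fh.readline()
            if not header:
                break
            lineno += 1
            if not header.startswith("@"):
                raise FormatError(f"{path}: line {lineno}: expected '@' header")
            seq_line = fh.readline()
            plus = fh.readline()
            qual_line = fh.readline()
            if not qual_line:
                raise FormatError(f"{path}: truncated record at line {lineno}")
            seq = normalize_sequence(seq_line)
            if not plus.startswith("+"):
                raise FormatError(f"{path}: line {lineno + 2}: expected '+' separator")
            qual_str = qual_line.strip()
            if len(qual_str) != len(seq):
                raise FormatError(
                    f"{path}: line {lineno + 3}: quality length {len(qual_str)} "
                    f"!= sequence length {len(seq)}"
                )
            quality = tuple(ord(c) - 33 for c in qual_str)
            if any(q < 0 for q in quality):
                raise FormatError(f"{path}: line {lineno + 3}: quality below Phred+33 range")
            reads.append(SmallRNARead(header[1:].strip(), seq, quality))
            lineno += 3
    return reads


def write_fastq(reads: Iterable[SmallRNARead], path: str | Path) -> None:
    with _open_text(path, "wt") as fh:
        for r in reads:
            qual = "".join(chr(q + 33) for q in r.quality)
            fh.write(f"@{r.read_id}\n{r.sequence}\n+\n{qual}\n")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    """FASTA -> {name: sequence}; name is the first whitespace token.

    Duplicate names are an error.
    """
    out: dict[str, str] = {}
    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            name = rec.id
            if name in out:
                raise FormatError(f"{path}: duplicate FASTA name {name!r}")
            out[name] = normalize_sequence(str(rec.seq))
    return out


def write_fasta(seqs: Mapping[str, str], path: str | Path) -> None:
    with _open_text(path, "wt") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n{seq}\n")


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

def _gff3_attributes(raw: str) -> dict[str, str]:
    attrs = {}
    for chunk in raw.strip().split(";"):
        if not chunk:
            continue
        key, _, value = chunk.partition("=")
        attrs[key.strip()] = value.strip()
    return attrs


def read_gff3(path: str | Path) -> GeneModels:
    """Parse exon features from GFF3 into 0-based half-open gene models.

    A missing strand on an exon feature is an error (classification needs it).
    Gene identity comes from ``gene_id``, else ``Parent``, else ``ID``.
    """
    models = GeneModels()
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise FormatError(f"{path}: line {lineno}: expected 9 GFF3 columns")
            contig, _src, ftype, start, end, _score, strand, _frame, attr_raw = fields
            attrs = _gff3_attributes(attr_raw)
            if ftype == "mRNA" or ftype == "transcript":
                tx = attrs.get("ID")
                gene = attrs.get("Parent") or attrs.get("gene_id") or tx
                if tx and gene:
                    models.transcript_to_gene[tx] = gene
                continue
            if ftype != "exon":
                continue
            if strand not in {"+", "-"}:
                raise FormatError(f"{path}: line {lineno}: exon feature missing strand")
            gene = attrs.get("gene_id") or attrs.get("Parent") or attrs.get("ID")
            if gene is None:
                raise FormatError(f"{path}: line {lineno}: exon has no gene attribute")
            models.exons.append(
                Exon(
                    contig=contig,
                    start=int(start) - 1,  # 1-based inclusive -> 0-based half-open
                    end=int(end),
                    strand=strand,
                    gene_id=gene,
                    transcript_id=attrs.get("Parent"),
                )
            )
    return models


def write_gff3(models: GeneModels, path: str | Path) -> None:
    with _open_text(path, "wt") as fh:
        fh.write("##gff-version 3\n")
        for ex in models.exons:
            fh.write(
                f"{ex.contig}\tmirddr\texon\t{ex.start + 1}\t{ex.end}\t.\t"
                f"{ex.strand}\t.\tgene_id={ex.gene_id}\n"
            )


# ---------------------------------------------------------------------------
# TSV
# ---------------------------------------------------------------------------

def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_tsv(table: pd.DataFrame, path: str | Path) -> None:
    """TSV with a header row, UTF-8, '.' as the decimal separator."""
    table.to_csv(path, sep="\t", index=False, encoding="utf-8")


__all__ = [
    "FormatError",
    "SmallRNARead",
    "ReferenceSet",
    "GeneModels",
    "Exon",
    "normalize_sequence",
    "revcomp",
    "read_fastq",
    "write_fastq",
    "read_fasta",
    "write_fasta",
    "read_gff3",
    "write_gff3",
    "read_tsv",
    "write_tsv",
]
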