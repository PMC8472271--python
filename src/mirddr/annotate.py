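"""Tag collapsing, genome mapping and the class-assignment cascade.

Clean reads are collapsed to unique 18-30 nt tags with per-library counts,
mapped exactly (both strands, all hits) to the genome, and assigned a single
class by a fixed priority cascade:

    known_miRNA > rRNA > tRNA > snRNA > snoRNA > repeat > NAT
    > exon_sense > exon_antisense > intron_sense > intron_antisense > other

Unmapped tags stay outside the cascade. Known-miRNA identification allows a
small number of substitutions and end offsets against the mature reference
(cross-species matches are common in small-RNA studies), with deterministic
tie-breaking.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .formats import GeneModels, ReferenceSet, SmallRNARead, revcomp

#: Cascade order for mapped tags (after the known-miRNA check).
CLASS_PRIORITY = ("rRNA", "tRNA", "snRNA", "snoRNA", "repeat", "NAT")

CLASS_LABELS = (
    "known_miRNA",
    *CLASS_PRIORITY,
    "novel_miRNA_candidate",
    "exon_sense",
    "exon_antisense",
    "intron_sense",
    "intron_antisense",
    "other",
    "unmapped",
)


@dataclass
class UniqueTag:
    """A distinct tag sequence with per-library counts and one class label."""

    sequence: str
    count_ck: int = 0
    count_tr: int = 0
    genome_hits: list[tuple[str, int, str]] = field(default_factory=list)
    class_label: str = "unmapped"
    matched_feature: str | None = None

    @property
    def total(self) -> int:
        return self.count_ck + self.count_tr


@dataclass(frozen=True)
class MatchParams:
    """Known-miRNA matching tolerance (substitutions / summed end offsets)."""

    max_substitutions: int = 2
    max_offset: int = 2


def collapse_tags(
    clean_ck: Iterable[SmallRNARead], clean_tr: Iterable[SmallRNARead]
) -> list[UniqueTag]:
    """One UniqueTag per distinct sequence; counts conserve read counts."""
    tags: dict[str, UniqueTag] = {}
    for read in clean_ck:
        tag = tags.setdefault(read.sequence, UniqueTag(read.sequence))
        tag.count_ck += 1
    for read in clean_tr:
        tag = tags.setdefault(read.sequence, UniqueTag(read.sequence))
        tag.count_tr += 1
    return list(tags.values())


def _find_all(haystack: str, needle: str) -> Iterable[int]:
    start = 0
    while True:
        pos = haystack.find(needle, start)
        if pos < 0:
            return
        yield pos
        start = pos + 1


def map_tags(tags: Sequence[UniqueTag], genome: Mapping[str, str]) -> None:
    """Exact full-length matching on both strands; all hits recorded in place.

    Hit strand is the tag's orientation relative to the contig; the start is
    always the leftmost contig coordinate of the match (0-based).
    """
    for tag in tags:
        hits: list[tuple[str, int, str]] = []
        rc = revcomp(tag.sequence)
        for contig in sorted(genome):
            seq = genome[contig]
            for pos in _find_all(seq, tag.sequence):
                hits.append((contig, pos, "+"))
            if rc != tag.sequence:
                for pos in _find_all(seq, rc):
                    hits.append((contig, pos, "-"))
            else:  # palindromic tag: a forward hit is also a reverse hit
                for pos in _find_all(seq, rc):
                    hits.append((contig, pos, "-"))
        tag.genome_hits = hits
        if not hits:
            tag.class_label = "unmapped"


def match_known_mirna(
    tag_seq: str, mirna_mature: Mapping[str, str], params: MatchParams = MatchParams()
) -> str | None:
    """Best mature-miRNA match for a tag, or None.

    An ungapped alignment at shift ``s`` (tag start relative to the mature
    5' end) is admissible when |s| plus the 3'-end overhang totals at most
    ``max_offset``; substitutions are counted over the overlap. Best match =
    fewest substitutions, then smallest offset, then lexicographic name.
    """
    best: tuple[int, int, str] | None = None
    for name in sorted(mirna_mature):
        mature = mirna_mature[name]
        for shift in range(-params.max_offset, params.max_offset + 1):
            # tag[i] aligns to mature[i + shift]
            left_off = abs(shift)
            right_off = abs((shift + len(tag_seq)) - len(mature))
            offset = left_off + right_off
            if offset > params.max_offset:
                continue
            lo = max(0, -shift)
            hi = min(len(tag_seq), len(mature) - shift)
            if hi <= lo:
                continue
            subs = sum(
                1 for i in range(lo, hi) if tag_seq[i] != mature[i + shift]
            )
            if subs > params.max_substitutions:
                continue
            key = (subs, offset, name)
            if best is None or key < best:
                best = key
    return best[2] if best else None


def _in_class_refs(tag_seq: str, refs: Mapping[str, str]) -> str | None:
    """Exact full-length substring membership, either strand."""
    rc = revcomp(tag_seq)
    for name in sorted(refs):
        seq = refs[name]
        if tag_seq in seq or rc in seq:
            return name
    return None


def _gene_model_class(
    hits: Sequence[tuple[str, int, str]],
    tag_len: int,
    models: GeneModels,
) -> tuple[str, str] | None:
    """Exon/intron overlap classification: exon before intron, sense before
    antisense within each (Table-2 column order)."""
    exons = models.exons
    introns = models.introns()
    for kind, intervals in (("exon", exons), ("intron", introns)):
        for sense in (True, False):
            for contig, start, strand in hits:
                end = start + tag_len
                for iv in intervals:
                    if iv.contig != contig:
                        continue
                    if start < iv.end and iv.start < end:
                        if (strand == iv.strand) == sense:
                            suffix = "sense" if sense else "antisense"
                            return f"{kind}_{suffix}", iv.gene_id
    return None


def classify_tag(
    tag: UniqueTag,
    refs: ReferenceSet,
    params: MatchParams = MatchParams(),
) -> None:
    """Assign the first matching class in the fixed priority order (in place)."""
    if not tag.genome_hits:
        tag.class_label = "unmapped"
        return
    name = match_known_mirna(tag.sequence, refs.mirna_mature, params)
    if name is not None:
        tag.class_label = "known_miRNA"
        tag.matched_feature = name
        return
    for label in CLASS_PRIORITY:
        pool = refs.class_refs.get(label, {})
        feature = _in_class_refs(tag.sequence, pool)
        if feature is not None:
            tag.class_label = label
            tag.matched_feature = feature
            return
    gm = _gene_model_class(tag.genome_hits, len(tag.sequence), refs.gene_models)
    if gm is not None:
        tag.class_label, tag.matched_feature = gm
        return
    tag.class_label = "other"


def annotate_tags(
    tags: Sequence[UniqueTag],
    refs: ReferenceSet,
    params: MatchParams = MatchParams(),
) -> None:
    map_tags(tags, refs.genome)
    for tag in tags:
        classify_tag(tag, refs, params)


def family_of(mirna_name: str) -> str:
    """Family from a (possibly species-prefixed) miRNA name.

    'ath-miR166a-3p' -> 'miR166'; names without a miR+digits token are
    'unassigned'.
    """
    if not mirna_name:
        raise ValueError("empty miRNA name")
    m = re.search(r"miR(\d+)", mirna_name, flags=re.IGNORECASE)
    if m is None:
        return "unassigned"
    return f"miR{m.group(1)}"


@dataclass
class KnownMiRNA:
    """A mature known miRNA observed in the libraries, with family."""

    name: str
    family: str
    mature_seq: str
    count_ck: int = 0
    count_tr: int = 0


def known_mirna_table(tags: Sequence[UniqueTag], refs: ReferenceSet) -> list[KnownMiRNA]:
    """Aggregate known-miRNA tag counts per matched mature name."""
    agg: dict[str, KnownMiRNA] = {}
    for tag in tags:
        if tag.class_label != "known_miRNA" or tag.matched_feature is None:
            continue
        name = tag.matched_feature
        rec = agg.setdefault(
            name, KnownMiRNA(name, family_of(name), refs.mirna_mature[name])
        )
        rec.count_ck += tag.count_ck
        rec.count_tr += tag.count_tr
    return [agg[name] for name in sorted(agg)]


def class_count_table(tags: Sequence[UniqueTag]) -> pd.DataFrame:
    """Table-2-shaped summary: per-library READ counts and percentages per
    class; total row covers mapped reads only."""
    mapped = [t for t in tags if t.class_label != "unmapped"]
    counts: dict[str, list[int]] = {}
    for t in mapped:
        label = t.class_label
        row = counts.setdefault(label, [0, 0])
        row[0] += t.count_ck
        row[1] += t.count_tr
    total_ck = sum(v[0] for v in counts.values())
    total_tr = sum(v[1] for v in counts.values())
    order = [c for c in CLASS_LABELS if c in counts]
    rows = [
        {
            "class": "Total",
            "reads_ck": total_ck,
            "reads_tr": total_tr,
            "pct_ck": 100.0,
            "pct_tr": 100.0,
        }
    ]
    for label in order:
        ck, tr = counts[label]
        rows.append(
            {
                "class": label,
                "reads_ck": ck,
                "reads_tr": tr,
                "pct_ck": 100.0 * ck / total_ck if total_ck else 0.0,
                "pct_tr": 100.0 * tr / total_tr if total_tr else 0.0,
            }
        )
    return pd.DataFrame(rows)


def tags_to_frame(tags: Sequence[UniqueTag]) -> pd.DataFrame:
    """TSV-ready view of annotated tags (1-based hit coordinates)."""
    rows = []
    for t in tags:
        hits = ";".join(f"{c}:{s + 1}:{st}" for c, s, st in t.genome_hits)
        rows.append(
            {
                "sequence": t.sequence,
                "count_ck": t.count_ck,
                "count_tr": t.count_tr,
                "class": t.class_label,
                "matched_feature": t.matched_feature or "",
                "genome_hits": hits,
            }
        )
    return pd.DataFrame(rows)


__all__ = [
    "CLASS_LABELS",
    "UniqueTag",
    "KnownMiRNA",
    "MatchParams",
    "collapse_tags",
    "map_tags",
    "match_known_mirna",
    "classify_tag",
    "annotate_tags",
    "family_of",
    "known_mirna_table",
    "class_count_table",
    "tags_to_frame",
]
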