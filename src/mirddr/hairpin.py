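"""Novel-miRNA candidate discovery from unannotated mapped tags.

Candidate precursors are excised around each genome hit, folded with a
base-pair-maximization dynamic program (Nussinov-style, pairs A:U, G:C and the
G:U wobble, minimum hairpin loop 3 nt), and screened with structural stem-loop
criteria of the kind used for annotating plant miRNAs: the mature tag and its
star partner must sit on opposite arms of a single hairpin, form a duplex with
few unpaired mature bases and no large asymmetric bulges, inside a well-paired
precursor. A candidate gains star support when an independently sequenced tag
maps onto the star arm with miRNA/miRNA* duplex geometry (2-nt 3' overhang,
small tolerance).

Base-pair maximization stands in for a thermodynamic folding energy; the
screening criteria here are structural, not energetic, and a pairing-fraction
threshold plays the role of a free-energy cut-off.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .annotate import UniqueTag
from .formats import revcomp

#: Allowed base pairs in the DNA alphabet (U normalized to T at ingest).
_PAIRS = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G"), ("G", "T"), ("T", "G")}

MIN_LOOP = 3


def can_pair(a: str, b: str) -> bool:
    return (a, b) in _PAIRS


@dataclass(frozen=True)
class HairpinParams:
    """Stem-loop screening thresholds (all config-exposed)."""

    flank: int = 120
    min_precursor: int = 60
    max_precursor: int = 300
    max_duplex_mismatches: int = 4
    max_asym_bulge: int = 2
    min_pairing_fraction: float = 0.55
    mature_length_range: tuple[int, int] = (20, 24)
    min_read_support: int = 2
    star_tolerance: int = 2


@dataclass
class HairpinCandidate:
    """A folded candidate precursor with criteria verdicts."""

    contig: str
    start: int  # 0-based half-open window on the contig
    end: int
    strand: str
    precursor_seq: str
    structure: str
    n_pairs: int
    mature_arm: tuple[int, int]  # (offset, length) within the precursor
    star_arm: tuple[int, int] | None = None
    star_expected_start: int | None = None
    duplex_mismatches: int = 0
    max_asym_bulge: int = 0
    pairing_fraction: float = 0.0
    star_supported: bool = False
    verdict: bool = False
    reasons: list[str] = field(default_factory=list)

    @property
    def mfe_proxy(self) -> int:
        """Pseudo-energy: paired-base count with a negative sign."""
        return -self.n_pairs

    def structure_rna(self) -> str:
        """Precursor in the RNA alphabet with its dot-bracket, for reports."""
        return self.precursor_seq.replace("T", "U") + "\n" + self.structure


# ---------------------------------------------------------------------------
# Folding
# ---------------------------------------------------------------------------

def fold(seq: str) -> tuple[str, int]:
    """Maximum base-pairing secondary structure of ``seq``.

    Returns ``(dot_bracket, n_pairs)``. Deterministic traceback: an end that
    can stay unpaired without losing a pair does so, then pairing (i, j) is
    preferred over bifurcation, and bifurcation splits at the leftmost optimal
    point. Consuming free ends first keeps co-optimal structures local
    (stems), which is what the downstream duplex criteria expect.
    """
    n = len(seq)
    if not (1 <= n <= 400):
        raise ValueError(f"fold: sequence length {n} outside [1, 400]")
    P = np.zeros((n, n), dtype=bool)
    for i in range(n):
        for j in range(i + MIN_LOOP + 1, n):
            P[i, j] = can_pair(seq[i], seq[j])
    M = np.zeros((n, n), dtype=np.int32)
    for l in range(MIN_LOOP + 1, n):
        i = np.arange(0, n - l)
        j = i + l
        best = np.maximum(M[i + 1, j], M[i, j - 1])
        paired = np.where(P[i, j], M[i + 1, j - 1] + 1, -1)
        best = np.maximum(best, paired)
        for t in range(1, l):
            best = np.maximum(best, M[i, i + t] + M[i + t + 1, j])
        M[i, j] = best

    structure = ["."] * n
    pairs = 0
    stack = [(0, n - 1)]
    while stack:
        i, j = stack.pop()
        if j - i <= MIN_LOOP:
            continue
        m = M[i, j]
        if m == 0:
            continue
        if m == M[i + 1, j]:
            stack.append((i + 1, j))
        elif m == M[i, j - 1]:
            stack.append((i, j - 1))
        elif P[i, j] and m == M[i + 1, j - 1] + 1:
            structure[i] = "("
            structure[j] = ")"
            pairs += 1
            stack.append((i + 1, j - 1))
        else:
            for k in range(i + 1, j):
                if M[i, k] + M[k + 1, j] == m:
                    stack.append((i, k))
                    stack.append((k + 1, j))
                    break
    return "".join(structure), pairs


def pair_table(structure: str) -> list[int]:
    """Partner index per position (-1 when unpaired); raises on imbalance."""
    partner = [-1] * len(structure)
    stack: list[int] = []
    for i, c in enumerate(structure):
        if c == "(":
            stack.append(i)
        elif c == ")":
            if not stack:
                raise ValueError("unbalanced dot-bracket")
            j = stack.pop()
            partner[i] = j
            partner[j] = i
    if stack:
        raise ValueError("unbalanced dot-bracket")
    return partner


# ---------------------------------------------------------------------------
# Precursor excision
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PrecursorWindow:
    contig: str
    start: int
    end: int
    strand: str
    seq: str
    mature_offset: int
    mature_length: int


def excise_precursors(
    tag: UniqueTag, genome: Mapping[str, str], flank: int = 120
) -> list[PrecursorWindow]:
    """Two candidate windows per genome hit: tag with upstream flank and tag
    with downstream flank (clipped at contig ends), strand-oriented."""
    windows: list[PrecursorWindow] = []
    tlen = len(tag.sequence)
    for contig, hit_start, strand in tag.genome_hits:
        contig_seq = genome[contig]
        hit_end = hit_start + tlen
        for w_start, w_end in (
            (max(0, hit_start - flank), hit_end),
            (hit_start, min(len(contig_seq), hit_end + flank)),
        ):
            seq = contig_seq[w_start:w_end]
            if strand == "-":
                seq = revcomp(seq)
                mature_offset = w_end - hit_end
            else:
                mature_offset = hit_start - w_start
            windows.append(
                PrecursorWindow(contig, w_start, w_end, strand, seq, mature_offset, tlen)
            )
    return windows


# ---------------------------------------------------------------------------
# Criteria
# ---------------------------------------------------------------------------

def check_criteria(
    cand: HairpinCandidate, params: HairpinParams = HairpinParams()
) -> HairpinCandidate:
    """Apply the stem-loop criteria; fills verdict, reasons and duplex stats.

    (a) mature and star arms on opposite sides of a single stem;
    (b) at most ``max_duplex_mismatches`` unpaired mature bases in the duplex;
    (c) no asymmetric bulge wider than ``max_asym_bulge`` nt in the duplex;
    (d) precursor pairing fraction at least ``min_pairing_fraction``;
    (e) mature length within ``mature_length_range``.
    """
    m0, mlen = cand.mature_arm
    m1 = m0 + mlen
    n = len(cand.precursor_seq)
    if m0 < 0 or m1 > n:
        raise ValueError("mature arm outside precursor")
    partner = pair_table(cand.structure)
    reasons: list[str] = []

    paired = [(p, partner[p]) for p in range(m0, m1) if partner[p] >= 0]
    outside = [(p, q) for p, q in paired if q < m0 or q >= m1]
    intra = len(paired) - len(outside)
    one_side = bool(outside) and (
        all(q >= m1 for _, q in outside) or all(q < m0 for _, q in outside)
    )
    if not one_side or intra > 0:
        reasons.append("arms_not_opposite")
        duplex = []
    else:
        duplex = outside

    mismatches = mlen - len(duplex)
    cand.duplex_mismatches = mismatches
    if mismatches > params.max_duplex_mismatches:
        reasons.append("duplex_mismatches")

    max_bulge = 0
    for (p, q), (p2, q2) in zip(duplex, duplex[1:]):
        gap_m = p2 - p - 1
        gap_s = abs(q - q2) - 1
        max_bulge = max(max_bulge, abs(gap_m - gap_s))
    cand.max_asym_bulge = max_bulge
    if max_bulge > params.max_asym_bulge:
        reasons.append("asymmetric_bulge")

    cand.pairing_fraction = 2.0 * cand.n_pairs / n if n else 0.0
    if cand.pairing_fraction < params.min_pairing_fraction:
        reasons.append("pairing_fraction")

    lo, hi = params.mature_length_range
    if not (lo <= mlen <= hi):
        reasons.append("mature_length")

    if duplex:
        star_positions = [q for _, q in duplex]
        s_lo, s_hi = min(star_positions), max(star_positions) + 1
        cand.star_arm = (s_lo, s_hi - s_lo)
        # 2-nt 3' overhang geometry: the star 5' end sits at the pairing
        # partner of the mature 3' end; extrapolate from the last paired base.
        p_last, q_last = duplex[-1]
        cand.star_expected_start = q_last - ((m1 - 1) - p_last)
    cand.verdict = not reasons
    cand.reasons = reasons
    return cand


def star_support(
    cand: HairpinCandidate,
    tags: Sequence[UniqueTag],
    params: HairpinParams = HairpinParams(),
) -> bool:
    """True when some tag maps onto the star arm with duplex geometry
    (tag 5' end within ``star_tolerance`` nt of the expected star start)."""
    if cand.star_expected_start is None:
        return False
    mature_seq = cand.precursor_seq[
        cand.mature_arm[0] : cand.mature_arm[0] + cand.mature_arm[1]
    ]
    for tag in tags:
        if tag.sequence == mature_seq:
            continue
        for contig, start, strand in tag.genome_hits:
            if contig != cand.contig or strand != cand.strand:
                continue
            if cand.strand == "+":
                offset = start - cand.start
            else:
                offset = cand.end - (start + len(tag.sequence))
            if abs(offset - cand.star_expected_start) <= params.star_tolerance:
                return True
    return False


# ---------------------------------------------------------------------------
# Locus-level discovery
# ---------------------------------------------------------------------------

@dataclass
class NovelLocus:
    name: str
    candidate: HairpinCandidate
    tag: UniqueTag
    star_supported: bool


def discover_novel(
    tags: Sequence[UniqueTag],
    genome: Mapping[str, str],
    params: HairpinParams = HairpinParams(),
) -> list[NovelLocus]:
    """Run excision + folding + criteria over unannotated tags and collapse
    passing candidates into loci (overlapping windows on one contig are one
    locus; the most abundant tag represents it)."""
    passing: list[tuple[UniqueTag, HairpinCandidate]] = []
    for tag in tags:
        if tag.class_label != "other" or tag.total < params.min_read_support:
            continue
        best: HairpinCandidate | None = None
        for win in excise_precursors(tag, genome, params.flank):
            if not (params.min_precursor <= len(win.seq) <= params.max_precursor):
                continue
            structure, n_pairs = fold(win.seq)
            cand = HairpinCandidate(
                contig=win.contig,
                start=win.start,
                end=win.end,
                strand=win.strand,
                precursor_seq=win.seq,
                structure=structure,
                n_pairs=n_pairs,
                mature_arm=(win.mature_offset, win.mature_length),
            )
            check_criteria(cand, params)
            if cand.verdict and (best is None or cand.n_pairs > best.n_pairs):
                best = cand
        if best is not None:
            passing.append((tag, best))

    # merge overlapping windows on the same contig into loci
    passing.sort(key=lambda tc: (tc[1].contig, tc[1].start, tc[0].sequence))
    loci: list[list[tuple[UniqueTag, HairpinCandidate]]] = []
    for tag, cand in passing:
        placed = False
        for group in loci:
            g = group[0][1]
            if g.contig == cand.contig and cand.start < g.end and g.start < cand.end:
                group.append((tag, cand))
                placed = True
                break
        if not placed:
            loci.append([(tag, cand)])

    result: list[NovelLocus] = []
    for idx, group in enumerate(sorted(loci, key=lambda g: (g[0][1].contig, g[0][1].start))):
        tag, cand = max(group, key=lambda tc: (tc[0].total, tc[0].sequence))
        cand.star_supported = star_support(cand, tags, params)
        result.append(NovelLocus(f"novel_{idx + 1}", cand, tag, cand.star_supported))
    return result


def novel_table(loci: Iterable[NovelLocus]) -> "pd.DataFrame":
    import pandas as pd

    rows = []
    for locus in loci:
        c = locus.candidate
        rows.append(
            {
                "name": locus.name,
                "sequence": locus.tag.sequence,
                "count_ck": locus.tag.count_ck,
                "count_tr": locus.tag.count_tr,
                "contig": c.contig,
                "start": c.start + 1,  # 1-based inclusive on output
                "end": c.end,
                "strand": c.strand,
                "n_pairs": c.n_pairs,
                "pairing_fraction": c.pairing_fraction,
                "duplex_mismatches": c.duplex_mismatches,
                "star_supported": locus.star_supported,
            }
        )
    return pd.DataFrame(rows)


__all__ = [
    "HairpinParams",
    "HairpinCandidate",
    "PrecursorWindow",
    "NovelLocus",
    "can_pair",
    "fold",
    "pair_table",
    "excise_precursors",
    "check_criteria",
    "star_support",
    "discover_novel",
    "novel_table",
]
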