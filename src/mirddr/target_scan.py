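"""Plant miRNA target prediction by complementarity expectation scoring.

A miRNA is aligned antiparallel against every transcript window and penalised
per position: 1.0 for a mismatch, 0.5 for a G:U wobble, 2.0 for a gap (at most
one single-nucleotide gap on either strand), with penalties doubled at miRNA
positions 2-13 (5' seed region, positions counted 1..L from the miRNA 5'
end). The total is the expectation score; sites at or below the cutoff
(default 4.0) are reported. Optional structural constraints of the
Schwab style can additionally be enforced: no mismatch at positions 10-11,
no more than two consecutive mismatches, and at most one mismatch within
positions 2-12 (a gap or wobble counts as a mismatch for these rules).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .formats import revcomp

SEED_START = 2  # 1-based, inclusive
SEED_END = 13

MISMATCH_PENALTY = 1.0
GU_PENALTY = 0.5
GAP_PENALTY = 2.0

#: (miRNA base, reverse-complemented site base) combinations that are G:U
#: wobbles: miRNA G opposite target U, or miRNA U opposite target G.
_WOBBLE_RC = {("G", "A"), ("T", "C")}


@dataclass(frozen=True)
class ScanParams:
    max_expectation: float = 4.0
    max_gaps: int = 1
    schwab: bool = True  # position 10-11 / consecutive / seed-mismatch rules
    max_consecutive_mismatches: int = 2
    max_seed_mismatches: int = 1


@dataclass
class TargetSite:
    mirna_id: str
    transcript_id: str
    site_start: int  # 0-based on the transcript
    site_end: int
    alignment: tuple[str, str, str]  # miRNA 5'->3', pairing row, site 3'->5'
    expectation: float
    n_mismatch: int = 0
    n_gu: int = 0
    n_gap: int = 0


def _position_weight(pos: int) -> float:
    return 2.0 if SEED_START <= pos <= SEED_END else 1.0


def _score_alignment(
    mirna: str, site_rc: str, gap: tuple[str, int] | None
) -> tuple[float, int, int, int, list[str]] | None:
    """Score one ungapped-or-single-gap alignment.

    ``site_rc`` is the site reverse-complemented, so a perfect target reads
    identically to the miRNA. ``gap`` is None, or ("mirna", k): miRNA position
    k (0-based) has no site partner, or ("site", k): an extra site base sits
    between miRNA positions k-1 and k. Returns (expectation, n_mismatch, n_gu,
    n_gap, per-position states) or None for an inadmissible geometry.
    """
    states: list[str] = []  # one per miRNA position: match/gu/mismatch/gap
    expectation = 0.0
    n_mm = n_gu = n_gap = 0
    si = 0
    for mi in range(len(mirna)):
        pos1 = mi + 1
        if gap is not None and gap[0] == "mirna" and gap[1] == mi:
            expectation += GAP_PENALTY * _position_weight(pos1)
            n_gap += 1
            states.append("gap")
            continue
        if gap is not None and gap[0] == "site" and gap[1] == mi:
            # unpaired site base: gap penalty charged at the flanking position
            expectation += GAP_PENALTY * _position_weight(pos1)
            n_gap += 1
            si += 1
        if si >= len(site_rc):
            return None
        m, s = mirna[mi], site_rc[si]
        if m == s:
            states.append("match")
        elif (m, s) in _WOBBLE_RC:
            expectation += GU_PENALTY * _position_weight(pos1)
            n_gu += 1
            states.append("gu")
        else:
            expectation += MISMATCH_PENALTY * _position_weight(pos1)
            n_mm += 1
            states.append("mismatch")
        si += 1
    if si != len(site_rc):
        return None
    return expectation, n_mm, n_gu, n_gap, states


def _violates_schwab(states: Sequence[str], params: ScanParams) -> bool:
    """Structural constraints; anything that is not a perfect pair counts as
    a mismatch here."""
    bad = [s != "match" for s in states]
    if any(bad[9:11]):  # miRNA positions 10-11 (1-based)
        return True
    run = 0
    for b in bad:
        run = run + 1 if b else 0
        if run > params.max_consecutive_mismatches:
            return True
    if sum(bad[1:12]) > params.max_seed_mismatches:  # positions 2-12
        return True
    return False


def site_expectation(
    mirna: str, site: str, gap: tuple[str, int] | None = None
) -> tuple[float, int, int, int]:
    """Expectation score of one miRNA/site duplex (site given 5'->3' on the
    transcript). Returns (expectation, n_mismatch, n_gu, n_gap)."""
    scored = _score_alignment(mirna, revcomp(site), gap)
    if scored is None:
        raise ValueError("inadmissible alignment geometry")
    e, mm, gu, g, _ = scored
    return e, mm, gu, g


def _alignment_strings(
    mirna: str, site_rc: str, states: Sequence[str], gap: tuple[str, int] | None
) -> tuple[str, str, str]:
    top, mid, bot = [], [], []
    si = 0
    for mi, state in enumerate(states):
        if state == "gap":
            top.append(mirna[mi])
            mid.append(" ")
            bot.append("-")
            continue
        if gap is not None and gap[0] == "site" and gap[1] == mi:
            top.append("-")
            mid.append(" ")
            bot.append(site_rc[si])
            si += 1
        top.append(mirna[mi])
        mid.append("|" if state == "match" else ("o" if state == "gu" else " "))
        bot.append(site_rc[si])
        si += 1
    # bottom row shown 3'->5' relative to the transcript (it is the reverse
    # complement of the genomic site)
    return "".join(top), "".join(mid), "".join(bot)


def scan(
    mirna_id: str,
    mirna: str,
    transcripts: Mapping[str, str],
    params: ScanParams = ScanParams(),
) -> list[TargetSite]:
    """All target sites of one miRNA across the transcriptome.

    Every window is evaluated ungapped and, when allowed, with each possible
    single-nucleotide gap on either strand; the best-scoring admissible
    alignment per (transcript, start) is kept if it passes the cutoff and the
    structural constraints.
    """
    L = len(mirna)
    sites: list[TargetSite] = []
    for tx_id in sorted(transcripts):
        seq = transcripts[tx_id]
        for start in range(0, len(seq) - L + 1 + params.max_gaps):
            best = None
            geometries: list[tuple[int, tuple[str, int] | None]] = [(L, None)]
            if params.max_gaps >= 1:
                # gap in miRNA: site window one shorter; gap in site: one longer
                geometries += [(L - 1, ("mirna", k)) for k in range(1, L - 1)]
                geometries += [(L + 1, ("site", k)) for k in range(1, L)]
            for width, gap in geometries:
                if start + width > len(seq):
                    continue
                window = seq[start : start + width]
                scored = _score_alignment(mirna, revcomp(window), gap)
                if scored is None:
                    continue
                e, mm, gu, g, states = scored
                if e > params.max_expectation:
                    continue
                if params.schwab and _violates_schwab(states, params):
                    continue
                if best is None or e < best[0]:
                    best = (e, mm, gu, g, states, gap, width)
            if best is not None:
                e, mm, gu, g, states, gap, width = best
                window = seq[start : start + width]
                sites.append(
                    TargetSite(
                        mirna_id=mirna_id,
                        transcript_id=tx_id,
                        site_start=start,
                        site_end=start + width,
                        alignment=_alignment_strings(mirna, revcomp(window), states, gap),
                        expectation=e,
                        n_mismatch=mm,
                        n_gu=gu,
                        n_gap=g,
                    )
                )
    return sites


def scan_all(
    mirnas: Mapping[str, str],
    transcripts: Mapping[str, str],
    params: ScanParams = ScanParams(),
) -> list[TargetSite]:
    out: list[TargetSite] = []
    for mirna_id in sorted(mirnas):
        out.extend(scan(mirna_id, mirnas[mirna_id], transcripts, params))
    return out


def collapse_to_genes(
    sites: Iterable[TargetSite], transcript_to_gene: Mapping[str, str] | None = None
) -> dict[str, set[str]]:
    """Distinct target genes per miRNA (transcript id when no map is given)."""
    out: dict[str, set[str]] = {}
    for s in sites:
        gene = (
            transcript_to_gene.get(s.transcript_id, s.transcript_id)
            if transcript_to_gene
            else s.transcript_id
        )
        out.setdefault(s.mirna_id, set()).add(gene)
    return out


def targets_per_mirna_histogram(
    genes_per_mirna: Mapping[str, set[str]], bin_width: int = 20
) -> dict[str, int]:
    """Histogram of distinct-target-gene counts per miRNA; default bins
    1-20, 21-40, ... plus a '0' bin for target-less miRNAs."""
    bins: dict[str, int] = {}
    for _mirna, genes in genes_per_mirna.items():
        n = len(genes)
        if n == 0:
            key = "0"
        else:
            lo = ((n - 1) // bin_width) * bin_width + 1
            key = f"{lo}-{lo + bin_width - 1}"
        bins[key] = bins.get(key, 0) + 1
    return dict(sorted(bins.items(), key=lambda kv: (kv[0] != "0", int(kv[0].split("-")[0]))))


def sites_frame(sites: Iterable[TargetSite]) -> pd.DataFrame:
    rows = []
    for s in sites:
        rows.append(
            {
                "mirna_id": s.mirna_id,
                "transcript_id": s.transcript_id,
                "site_start": s.site_start + 1,  # 1-based inclusive on output
                "site_end": s.site_end,
                "expectation": s.expectation,
                "n_mismatch": s.n_mismatch,
                "n_gu": s.n_gu,
                "n_gap": s.n_gap,
            }
        )
    return pd.DataFrame(rows)


__all__ = [
    "ScanParams",
    "TargetSite",
    "site_expectation",
    "scan",
    "scan_all",
    "collapse_to_genes",
    "targets_per_mirna_histogram",
    "sites_frame",
]
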