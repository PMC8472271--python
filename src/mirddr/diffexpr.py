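"""Two-library differential expression for miRNA counts.

The comparison is one pooled library per condition, so significance comes from
the Audic-Claverie exact test: conditional on a count x in library 1 (total N1
clean reads), the count y in library 2 (total N2) follows

    p(y | x) = (N2/N1)^y * (x + y)! / (x! y!) / (1 + N2/N1)^(x + y + 1),

a negative-binomial tail-friendly form evaluated here in log space with
log-gamma. Tails are inclusive of the observed count; the two-sided p-value is
2 * min(lower tail, upper tail), capped at 1.

The test runs on raw integer counts. Normalized expression (reads per million,
"TPM") is used only for fold changes: zeros are floored to 0.01 and entries
where both libraries sit below 1 TPM are excluded as too lowly expressed.
A record is called UP when log2FC > 1 with BH q < 0.05, DOWN for the mirror.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .annotate import KnownMiRNA, family_of
from .preprocess import round_half_up

#: Default thresholds; match the published analysis settings.
FLOOR = 0.01
EXCLUSION_THRESHOLD = 1.0
LFC_CUTOFF = 1.0
Q_CUTOFF = 0.05
ND_MIN_READS = 5


@dataclass
class ExpressionRecord:
    """Per-miRNA counts, normalized expression and test results."""

    mirna_id: str
    x_count: int  # control raw count
    y_count: int  # treated raw count
    n1: int  # control library total clean reads
    n2: int  # treated library total clean reads
    tpm_ck: float = 0.0
    tpm_tr: float = 0.0
    log2fc: float | None = None
    p_value: float | None = None
    q_value: float | None = None
    status: str = "NS"  # UP / DOWN / NS / ND / EXCLUDED


def tpm(count: int, total: int) -> float:
    """Reads-per-million normalization: count / total * 1e6, full precision."""
    if total <= 0:
        raise ValueError(f"library total must be positive, got {total}")
    if count < 0:
        raise ValueError(f"negative count {count}")
    return count / total * 1_000_000


def apply_floor(pair: tuple[float, float], floor: float = FLOOR) -> tuple[float, float]:
    """Replace exact zeros by the floor; other values pass unchanged."""
    a, b = pair
    return (floor if a == 0 else a, floor if b == 0 else b)


def exclusion_rule(
    pair: tuple[float, float], threshold: float = EXCLUSION_THRESHOLD
) -> bool:
    """True (EXCLUDED) when both normalized values are strictly below the
    threshold; requiring both keeps strong on/off cases in the analysis."""
    a, b = pair
    return a < threshold and b < threshold


def log2fc(tpm_tr: float, tpm_ck: float) -> float:
    """log2(treated / control); callers floor zeros first."""
    if tpm_tr <= 0 or tpm_ck <= 0:
        raise ValueError("log2fc requires positive inputs (apply the floor first)")
    return math.log2(tpm_tr / tpm_ck)


# ---------------------------------------------------------------------------
# Audic-Claverie exact test
# ---------------------------------------------------------------------------

def ac_log_pmf(y, x: int, n1: int, n2: int):
    """log p(y | x) for scalar or array y."""
    if n1 <= 0 or n2 <= 0:
        raise ValueError("library totals must be positive")
    if x < 0 or np.any(np.asarray(y) < 0):
        raise ValueError("counts must be non-negative")
    rho = n2 / n1
    y = np.asarray(y, dtype=np.float64)
    return (
        y * math.log(rho)
        + gammaln(x + y + 1)
        - gammaln(x + 1)
        - gammaln(y + 1)
        - (x + y + 1) * math.log1p(rho)
    )


def ac_pmf(y: int, x: int, n1: int, n2: int) -> float:
    """p(y | x): probability of count y in library 2 given x in library 1."""
    return float(np.exp(ac_log_pmf(y, x, n1, n2)))


def _lower_tail(x: int, y: int, n1: int, n2: int) -> float:
    """C = sum_{y'=0..y} p(y' | x), inclusive, via a log-sum-exp cumulation."""
    ys = np.arange(0, y + 1)
    logs = ac_log_pmf(ys, x, n1, n2)
    m = logs.max()
    return float(np.exp(m) * np.exp(logs - m).sum())


def ac_pvalue(x: int, y: int, n1: int, n2: int) -> float:
    """Two-sided exact p-value: 2 * min(lower tail, upper tail), capped at 1.

    Both tails include the observed y; the upper tail is computed as
    1 - (lower tail below y) and clamped to [0, 1].
    """
    c = _lower_tail(x, y, n1, n2)
    below = _lower_tail(x, y - 1, n1, n2) if y > 0 else 0.0
    d = min(1.0, max(0.0, 1.0 - below))
    c = min(1.0, c)
    return min(1.0, 2.0 * min(c, d))


def bh_fdr(p_values: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up q-values, order-preserving on input index."""
    p = np.asarray(p_values, dtype=np.float64)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values outside [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q.tolist()


def by_fdr(p_values: Sequence[float]) -> list[float]:
    """Benjamini-Yekutieli variant (BH scaled by the harmonic sum)."""
    p = np.asarray(p_values, dtype=np.float64)
    if p.size == 0:
        return []
    c_m = float(np.sum(1.0 / np.arange(1, p.size + 1)))
    return bh_fdr(np.minimum(p * c_m, 1.0))


def call_de(
    record: ExpressionRecord,
    lfc_cutoff: float = LFC_CUTOFF,
    q_cutoff: float = Q_CUTOFF,
) -> str:
    """UP / DOWN / NS from the thresholds (strict inequalities both sides)."""
    if record.log2fc is None or record.q_value is None:
        raise ValueError(f"{record.mirna_id}: log2fc/q not computed")
    if record.log2fc > lfc_cutoff and record.q_value < q_cutoff:
        return "UP"
    if record.log2fc < -lfc_cutoff and record.q_value < q_cutoff:
        return "DOWN"
    return "NS"


def differential_expression(
    counts: Sequence[tuple[str, int, int]],
    n1: int,
    n2: int,
    floor: float = FLOOR,
    exclusion_threshold: float = EXCLUSION_THRESHOLD,
    lfc_cutoff: float = LFC_CUTOFF,
    q_cutoff: float = Q_CUTOFF,
    fdr_method: str = "bh",
) -> list[ExpressionRecord]:
    """Full DE analysis over (mirna_id, count_ck, count_tr) triples.

    Excluded records (both normalized values below the threshold) keep their
    TPM values but get no test; q-values are computed across tested records.
    """
    records: list[ExpressionRecord] = []
    for mirna_id, x, y in counts:
        rec = ExpressionRecord(mirna_id, x, y, n1, n2)
        rec.tpm_ck, rec.tpm_tr = apply_floor((tpm(x, n1), tpm(y, n2)), floor)
        if exclusion_rule((rec.tpm_ck, rec.tpm_tr), exclusion_threshold):
            rec.status = "EXCLUDED"
        else:
            rec.log2fc = log2fc(rec.tpm_tr, rec.tpm_ck)
            rec.p_value = ac_pvalue(x, y, n1, n2)
        records.append(rec)
    tested = [r for r in records if r.status != "EXCLUDED"]
    fdr = {"bh": bh_fdr, "by": by_fdr}[fdr_method]
    qs = fdr([r.p_value for r in tested])
    for rec, q in zip(tested, qs):
        rec.q_value = q
        rec.status = call_de(rec, lfc_cutoff, q_cutoff)
    return records


# ---------------------------------------------------------------------------
# Family summaries
# ---------------------------------------------------------------------------

@dataclass
class FamilySummary:
    family: str
    n_members: int
    reads_ck: int
    reads_tr: int
    norm_ck: float
    norm_tr: float
    log2fc: float | None  # None <=> ND


def family_table(
    known: Sequence[KnownMiRNA],
    n1: int,
    n2: int,
    floor: float = FLOOR,
    nd_min_reads: int = ND_MIN_READS,
) -> list[FamilySummary]:
    """Per-family member counts, summed reads, normalized reads and fold
    change; ND (None) when the summed reads are below ``nd_min_reads`` in both
    libraries."""
    groups: dict[str, list[KnownMiRNA]] = {}
    for rec in known:
        groups.setdefault(rec.family, []).append(rec)
    out: list[FamilySummary] = []
    for family in sorted(groups):
        members = groups[family]
        ck = sum(m.count_ck for m in members)
        tr = sum(m.count_tr for m in members)
        norm_ck, norm_tr = apply_floor((tpm(ck, n1), tpm(tr, n2)), floor)
        fc = None
        if not (ck < nd_min_reads and tr < nd_min_reads):
            fc = log2fc(norm_tr, norm_ck)
        out.append(FamilySummary(family, len(members), ck, tr, norm_ck, norm_tr, fc))
    out.sort(key=lambda s: (-s.n_members, s.family))
    return out


def family_frame(summaries: Iterable[FamilySummary]) -> pd.DataFrame:
    rows = []
    for s in summaries:
        rows.append(
            {
                "family": s.family,
                "n_members": s.n_members,
                "reads_ck": s.reads_ck,
                "reads_tr": s.reads_tr,
                "norm_ck": round_half_up(s.norm_ck, 2),
                "norm_tr": round_half_up(s.norm_tr, 2),
                "log2fc": "ND" if s.log2fc is None else round_half_up(s.log2fc, 2),
            }
        )
    return pd.DataFrame(rows)


def expression_frame(records: Iterable[ExpressionRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append(
            {
                "mirna_id": r.mirna_id,
                "count_ck": r.x_count,
                "count_tr": r.y_count,
                "tpm_ck": round_half_up(r.tpm_ck, 2),
                "tpm_tr": round_half_up(r.tpm_tr, 2),
                "log2fc": "" if r.log2fc is None else round_half_up(r.log2fc, 2),
                "p_value": "" if r.p_value is None else r.p_value,
                "q_value": "" if r.q_value is None else r.q_value,
                "status": r.status,
            }
        )
    return pd.DataFrame(rows)


def log_tpm_matrix(records: Sequence[ExpressionRecord], de_only: bool = True) -> pd.DataFrame:
    """Per-miRNA log10(TPM) per library, heatmap-export shaped."""
    chosen = [r for r in records if r.status in {"UP", "DOWN"}] if de_only else list(records)
    return pd.DataFrame(
        {
            "mirna_id": [r.mirna_id for r in chosen],
            "log10_tpm_ck": [math.log10(r.tpm_ck) for r in chosen],
            "log10_tpm_tr": [math.log10(r.tpm_tr) for r in chosen],
        }
    )


__all__ = [
    "ExpressionRecord",
    "FamilySummary",
    "tpm",
    "apply_floor",
    "exclusion_rule",
    "log2fc",
    "ac_pmf",
    "ac_log_pmf",
    "ac_pvalue",
    "bh_fdr",
    "by_fdr",
    "call_de",
    "differential_expression",
    "family_table",
    "family_frame",
    "expression_frame",
    "log_tpm_matrix",
]
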