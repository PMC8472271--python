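"""Relative quantification from RT-qPCR Ct tables by the 2^-ddCt method.

dCt_group = mean(Ct_target, group) - mean(Ct_reference, group);
ddCt = dCt_treated - dCt_control; relative expression = 2^-ddCt.
Per-replicate values (replicates paired by index) give the dispersion
(SD, with SE = SD / sqrt(n) reported alongside).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from statistics import mean, stdev
from typing import Sequence

import pandas as pd

GROUPS = ("CK", "treated")


@dataclass
class CtTable:
    """Rows of (group, gene, role, replicate Ct values)."""

    frame: pd.DataFrame  # columns: group, gene, role, ct (list) exploded

    @classmethod
    def from_tsv(cls, path) -> "CtTable":
        """ct.tsv columns: group, gene, role, ct1..ctN."""
        df = pd.read_csv(path, sep="\t")
        ct_cols = [c for c in df.columns if c.startswith("ct")]
        if not ct_cols:
            raise ValueError("Ct table has no ct columns")
        return cls(df)

    def replicates(self, group: str, gene: str) -> list[float]:
        sel = self.frame[(self.frame.group == group) & (self.frame.gene == gene)]
        if sel.empty:
            raise KeyError(f"missing Ct cell for (group={group!r}, gene={gene!r})")
        ct_cols = [c for c in self.frame.columns if c.startswith("ct")]
        vals = [float(v) for v in sel.iloc[0][ct_cols] if pd.notna(v)]
        if not vals:
            raise KeyError(f"no replicate Ct values for (group={group!r}, gene={gene!r})")
        return vals


@dataclass
class DdctResult:
    relative_expression: float
    ddct: float
    per_replicate: list[float]
    sd: float
    se: float


def ddct(
    table: CtTable,
    target: str,
    reference: str,
    treated: str = "treated",
    control: str = "CK",
) -> DdctResult:
    """2^-ddCt of ``target`` against ``reference`` between the two groups."""
    ct = {
        (g, gene): table.replicates(g, gene)
        for g in (control, treated)
        for gene in (target, reference)
    }
    dct_ck = mean(ct[(control, target)]) - mean(ct[(control, reference)])
    dct_tr = mean(ct[(treated, target)]) - mean(ct[(treated, reference)])
    dd = dct_tr - dct_ck
    rel = 2.0 ** (-dd)

    # per-replicate spread: pair replicates by index against the control means
    n = min(len(ct[(treated, target)]), len(ct[(treated, reference)]))
    per_rep = [
        2.0 ** (-((ct[(treated, target)][i] - ct[(treated, reference)][i]) - dct_ck))
        for i in range(n)
    ]
    sd = stdev(per_rep) if len(per_rep) > 1 else 0.0
    return DdctResult(rel, dd, per_rep, sd, sd / math.sqrt(len(per_rep)) if per_rep else 0.0)


def concordance(
    mirna_lfc: float, qpcr_rel: float, dead_zone: float = 0.1
) -> str:
    """SAME / OPPOSITE / NULL direction agreement between sequencing log2FC
    and a qPCR relative-expression ratio (|log2| at or below the dead zone on
    either side gives NULL)."""
    if qpcr_rel <= 0:
        raise ValueError("relative expression must be positive")
    q = math.log2(qpcr_rel)
    if abs(q) <= dead_zone or abs(mirna_lfc) <= dead_zone:
        return "NULL"
    return "SAME" if (q > 0) == (mirna_lfc > 0) else "OPPOSITE"


__all__ = ["CtTable", "DdctResult", "ddct", "concordance", "GROUPS"]
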