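"""Bundled reference table and its arithmetic reproduction.

``data/family_abundance.tsv`` is the published known-miRNA family abundance
table from a two-library rice root small-RNA study (control vs bleomycin
treatment): per family, the member count, summed raw reads per library, the
normalized reads (reads per million against library totals of 12,819,498 and
4,736,578 mapped reads, zeros floored to 0.01) and the printed log2 fold
change, with ND marking families below 5 reads in both libraries.

The reproduction functions feed those printed columns back through the
pipeline's own normalization and fold-change operations. Because the printed
normalized columns are rounded to 2 decimals (and derive from replicate
averaging upstream), the recomputed fold change can differ from the printed
one by the propagated input precision; ``fc_tolerance`` gives that
interval-arithmetic bound per row.
"""

from __future__ import annotations

import math
from importlib import resources

import pandas as pd

from .diffexpr import apply_floor, log2fc, tpm
from .preprocess import round_half_up

#: Library totals printed with the table (mapped reads, CK / treated).
TOTAL_CK = 12_819_498
TOTAL_TR = 4_736_578


def load_family_abundance() -> pd.DataFrame:
    with resources.files("mirddr.data").joinpath("family_abundance.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")


def fc_tolerance(norm_ck: float, norm_tr: float) -> float:
    """Worst-case |log2fc| shift when both inputs are rounded to 2 decimals,
    plus the half-ulp of the printed fold change itself."""
    return (0.005 / norm_ck + 0.005 / norm_tr) / math.log(2) + 0.005


def reproduce_fold_changes(table: pd.DataFrame | None = None) -> pd.DataFrame:
    """Recompute every row's fold change two ways: from the printed normalized
    columns and from the raw read counts via the TPM formula."""
    if table is None:
        table = load_family_abundance()
    rows = []
    for r in table.itertuples(index=False):
        norm_pair = apply_floor((float(r.norm_ck), float(r.norm_tr)))
        fc_from_norm = log2fc(norm_pair[1], norm_pair[0])
        tpm_pair = apply_floor((tpm(int(r.reads_ck), TOTAL_CK), tpm(int(r.reads_tr), TOTAL_TR)))
        fc_from_counts = log2fc(tpm_pair[1], tpm_pair[0])
        nd = int(r.reads_ck) < 5 and int(r.reads_tr) < 5
        rows.append(
            {
                "family": r.family,
                "printed_fc": None if r.log2fc == "ND" else float(r.log2fc),
                "printed_nd": r.log2fc == "ND",
                "nd_rule": nd,
                "fc_from_norm": fc_from_norm,
                "fc_from_norm_2dp": round_half_up(fc_from_norm, 2),
                "fc_from_counts": fc_from_counts,
                "tpm_ck": tpm_pair[0],
                "tpm_tr": tpm_pair[1],
                "tolerance": fc_tolerance(*norm_pair),
            }
        )
    return pd.DataFrame(rows)


__all__ = [
    "TOTAL_CK",
    "TOTAL_TR",
    "load_family_abundance",
    "fc_tolerance",
    "reproduce_fold_changes",
]
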