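"""GO / pathway over-representation analysis of predicted target genes.

One hypergeometric upper-tail test per term (equivalent to one-sided Fisher):
with N background genes of which K carry the term, and n query (DE-target)
genes of which k carry it, p = P(X >= k). q-values are Benjamini-Hochberg
within each annotation category; the rich factor is k / K, the fraction of a
term's genes hit by the query set. No term-graph propagation is performed:
the annotation map is taken as given.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd
from scipy.stats import hypergeom

from .diffexpr import bh_fdr


@dataclass(frozen=True)
class TermAnnotation:
    gene: str
    term_id: str
    term_name: str
    category: str  # BP / CC / MF / pathway


@dataclass
class EnrichmentResult:
    term_id: str
    term_name: str
    category: str
    k: int  # query genes in term
    n: int  # annotated query genes
    K: int  # background genes in term
    N: int  # background annotated genes
    p_value: float
    q_value: float | None = None

    @property
    def rich_factor(self) -> float:
        return self.k / self.K


def hypergeom_upper(k: int, n: int, K: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n)."""
    if not (0 <= k <= n <= N and k <= K <= N):
        raise ValueError(f"inconsistent counts k={k} n={n} K={K} N={N}")
    if k == 0:
        return 1.0
    return float(hypergeom.sf(k - 1, N, K, n))


def read_annotation_map(path) -> list[TermAnnotation]:
    """TSV columns: gene, term_id, term_name, category."""
    df = pd.read_csv(path, sep="\t")
    required = {"gene", "term_id", "term_name", "category"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"annotation map missing columns: {sorted(missing)}")
    return [
        TermAnnotation(r.gene, r.term_id, r.term_name, r.category)
        for r in df.itertuples(index=False)
    ]


def enrich(
    target_genes: Iterable[str],
    annotations: Sequence[TermAnnotation],
    background: Iterable[str] | None = None,
) -> list[EnrichmentResult]:
    """Over-representation of target genes per annotated term.

    Background defaults to all annotated genes. One result per term with at
    least one query gene; q-values computed per category.
    """
    ann_genes = sorted({a.gene for a in annotations})
    if not ann_genes:
        raise ValueError("empty annotation map")
    bg = sorted(set(background)) if background is not None else ann_genes
    if not bg:
        raise ValueError("empty background")
    bg_set = set(bg) & set(ann_genes) if background is not None else set(ann_genes)
    if not bg_set:
        raise ValueError("background shares no genes with the annotation map")
    query = sorted(set(target_genes) & bg_set)

    terms: dict[str, tuple[str, str, set[str]]] = {}
    for a in annotations:
        if a.gene not in bg_set:
            continue
        entry = terms.setdefault(a.term_id, (a.term_name, a.category, set()))
        entry[2].add(a.gene)

    N = len(bg_set)
    n = len(query)
    results: list[EnrichmentResult] = []
    for term_id in sorted(terms):
        name, category, genes = terms[term_id]
        k = len(genes & set(query))
        if k == 0:
            continue
        K = len(genes)
        p = hypergeom_upper(k, n, K, N)
        results.append(EnrichmentResult(term_id, name, category, k, n, K, N, p))

    for category in sorted({r.category for r in results}):
        group = [r for r in results if r.category == category]
        qs = bh_fdr([r.p_value for r in group])
        for r, q in zip(group, qs):
            r.q_value = q
    results.sort(key=lambda r: (r.q_value, r.p_value, r.term_id))
    return results


def top_terms(results: Sequence[EnrichmentResult], n: int = 20) -> list[EnrichmentResult]:
    """Top-n view sorted by q then p (the results list is already sorted)."""
    return list(results[:n])


def enrichment_frame(results: Iterable[EnrichmentResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        rows.append(
            {
                "term_id": r.term_id,
                "term_name": r.term_name,
                "category": r.category,
                "k": r.k,
                "n": r.n,
                "K": r.K,
                "N": r.N,
                "rich_factor": r.rich_factor,
                "p_value": r.p_value,
                "q_value": r.q_value,
            }
        )
    return pd.DataFrame(rows)


__all__ = [
    "TermAnnotation",
    "EnrichmentResult",
    "hypergeom_upper",
    "read_annotation_map",
    "enrich",
    "top_terms",
    "enrichment_frame",
]
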