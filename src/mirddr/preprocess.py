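"""Raw-read QC: adapter trimming, quality/composition filters, length selection.

The stage turns raw FASTQ into clean 18-30 nt tags and produces the per-library
QC summary and length distribution. Filter definitions that the underlying
study leaves implicit (what counts as "low quality", what counts as a
poly-A/T/G/C read) are explicit, documented parameters here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Sequence

from .formats import SmallRNARead

#: Removal reasons, in reporting order.
REASONS = ("n_content", "low_quality", "adapter_only_or_missing", "polyx")


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class FilterParams:
    """Tunable QC thresholds.

    max_n_fraction: remove when count(N)/length is strictly above this.
    min_phred / max_low_quality_fraction: remove when more than this fraction
        of bases is below ``min_phred``.
    polyx_fraction: remove when any single nucleotide makes up at least this
        fraction of the read.
    """

    max_n_fraction: float = 0.10
    min_phred: int = 20
    max_low_quality_fraction: float = 0.50
    polyx_fraction: float = 0.80
    adapter_seed_length: int = 8


@dataclass
class QCReport:
    """Per-library read accounting; every raw read lands in exactly one row."""

    raw_reads: int = 0
    n_filtered: int = 0
    low_quality: int = 0
    adapter_only_or_missing: int = 0
    polyx: int = 0
    clean_reads: int = 0

    def category_counts(self) -> dict[str, int]:
        return {
            "n_content": self.n_filtered,
            "low_quality": self.low_quality,
            "adapter_only_or_missing": self.adapter_only_or_missing,
            "polyx": self.polyx,
            "clean": self.clean_reads,
        }

    def validate(self) -> None:
        removed = (
            self.n_filtered + self.low_quality + self.adapter_only_or_missing + self.polyx
        )
        if self.raw_reads != removed + self.clean_reads:
            raise RuntimeError(
                f"QC accounting broken: raw {self.raw_reads} != "
                f"removed {removed} + clean {self.clean_reads}"
            )

    def percentages(self) -> dict[str, float]:
        if self.raw_reads == 0:
            return {k: 0.0 for k in self.category_counts()}
        return {
            k: round_half_up(100.0 * v / self.raw_reads, 2)
            for k, v in self.category_counts().items()
        }


def round_half_up(value: float, ndigits: int = 2) -> float:
    """Decimal round-half-up (report presentation convention)."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def trim_adapter(
    read: SmallRNARead, adapter: str, seed_length: int = 8
) -> SmallRNARead | None:
    """Cut at the leftmost exact occurrence of the adapter's first ``seed_length``
    bases and return the insert; None when the adapter is absent or the insert
    is empty (read begins with the adapter).
    """
    if len(adapter) < 6:
        raise ConfigError("adapter must be at least 6 nt")
    seed = adapter[:seed_length] if len(read.sequence) >= seed_length else adapter
    pos = read.sequence.find(seed)
    if pos < 0:
        return None
    if pos == 0:
        return None  # empty insert
    return SmallRNARead(read.read_id, read.sequence[:pos], read.quality[:pos])


def filter_read(read: SmallRNARead, params: FilterParams = FilterParams()) -> str | None:
    """Return a removal reason or None (PASS) for an adapter-trimmed read.

    Evaluation order: n_content, low_quality, polyx; the first failure wins.
    """
    n = len(read.sequence)
    if read.sequence.count("N") / n > params.max_n_fraction:
        return "n_content"
    low = sum(1 for q in read.quality if q < params.min_phred)
    if low / n > params.max_low_quality_fraction:
        return "low_quality"
    for base in "ACGT":
        if read.sequence.count(base) / n >= params.polyx_fraction:
            return "polyx"
    return None


def length_select(
    reads: Iterable[SmallRNARead], min_len: int = 18, max_len: int = 30
) -> list[SmallRNARead]:
    """Retain reads with min_len <= length <= max_len (inclusive)."""
    if min_len > max_len:
        raise ConfigError(f"min_len {min_len} > max_len {max_len}")
    return [r for r in reads if min_len <= len(r) <= max_len]


@dataclass
class PreprocessResult:
    clean: list[SmallRNARead]
    report: QCReport


def preprocess_library(
    reads: Sequence[SmallRNARead],
    adapter: str,
    params: FilterParams = FilterParams(),
) -> PreprocessResult:
    """Adapter-trim then filter a library; length selection is a separate step
    (the QC summary mirrors the published accounting, which precedes size
    selection)."""
    report = QCReport(raw_reads=len(reads))
    clean: list[SmallRNARead] = []
    for read in reads:
        trimmed = trim_adapter(read, adapter, params.adapter_seed_length)
        if trimmed is None:
            report.adapter_only_or_missing += 1
            continue
        reason = filter_read(trimmed, params)
        if reason == "n_content":
            report.n_filtered += 1
        elif reason == "low_quality":
            report.low_quality += 1
        elif reason == "polyx":
            report.polyx += 1
        else:
            clean.append(trimmed)
    report.clean_reads = len(clean)
    report.validate()
    return PreprocessResult(clean=clean, report=report)


def qc_summary(reports: dict[str, QCReport]) -> "pd.DataFrame":
    """Table-1-shaped summary: per-library counts and percentages plus an
    across-library arithmetic-mean column."""
    import pandas as pd

    rows = []
    names = list(reports)
    categories = [
        ("Raw reads", lambda r: r.raw_reads),
        ("N% > 10% reads", lambda r: r.n_filtered),
        ("Low quality reads", lambda r: r.low_quality),
        ("Adaptor reads", lambda r: r.adapter_only_or_missing),
        ("polyA/T/G/C reads", lambda r: r.polyx),
        ("Clean reads", lambda r: r.clean_reads),
    ]
    for label, getter in categories:
        row: dict[str, object] = {"read_type": label}
        vals = []
        for name in names:
            rep = reports[name]
            count = getter(rep)
            pct = (
                round_half_up(100.0 * count / rep.raw_reads, 2)
                if rep.raw_reads
                else 0.0
            )
            row[f"{name}_count"] = count
            row[f"{name}_pct"] = pct
            vals.append(count)
        row["average"] = sum(vals) / len(vals) if vals else 0.0
        rows.append(row)
    return pd.DataFrame(rows)


def length_distribution(clean_reads: Sequence[SmallRNARead]) -> dict[int, float]:
    """Proportion of clean reads at each observed length; sums to 1."""
    counts: dict[int, int] = {}
    for r in clean_reads:
        counts[len(r)] = counts.get(len(r), 0) + 1
    total = sum(counts.values())
    if total == 0:
        return {}
    return {length: c / total for length, c in sorted(counts.items())}


__all__ = [
    "ConfigError",
    "FilterParams",
    "QCReport",
    "PreprocessResult",
    "round_half_up",
    "trim_adapter",
    "filter_read",
    "length_select",
    "preprocess_library",
    "qc_summary",
    "length_distribution",
]
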