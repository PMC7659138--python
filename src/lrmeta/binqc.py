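"""Draft-genome quality triage and assembly summary statistics.

Contig bins are classified into quality tiers using completeness,
contamination, rRNA presence and tRNA count:

* high quality: completeness > 90 %, contamination < 5 %, all of the 5S,
  16S and 23S rRNAs present, and at least 18 tRNAs;
* medium quality: completeness >= 50 % and contamination < 10 %;
* low quality: completeness < 50 % and contamination < 10 %;
* other: everything else (in particular any bin with contamination >= 10 %).

The tiers are evaluated in that order, so a 95 %-complete, 3 %-contaminated
bin missing an rRNA is medium quality, and every high-quality bin also
satisfies the medium-quality numeric thresholds.  A bin counts as a draft
genome when it lands in any of the three named tiers.

Bin abundance is ``size(bin) * depth(bin) / (read_length * total aligned
reads)``.  ``compute_n50`` provides the standard N50/NG50 contig statistics.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .config import round_half_up
from .errors import ConfigError

__all__ = [
    "QualityTier",
    "BinRecord",
    "classify_bin",
    "bin_abundance",
    "compute_n50",
    "summarize_assembly",
    "summarize_tier_counts",
    "read_bins_tsv",
    "write_bins_tsv",
]

BIN_TSV_COLUMNS = (
    "bin_id",
    "size_bp",
    "depth",
    "completeness",
    "contamination",
    "has_5S",
    "has_16S",
    "has_23S",
    "n_tRNA",
)

SUMMARY_COLUMNS = (
    "config",
    "n_bins",
    "total_length_mb",
    "high",
    "medium",
    "low",
    "other",
    "high_pct",
    "medium_pct",
    "low_pct",
    "other_pct",
    "draft_pct",
)


class QualityTier(str, enum.Enum):
    HIGH = "HIGH"
    MEDIUM = "MEDIUM"
    LOW = "LOW"
    OTHER = "OTHER"

    @property
    def is_draft_genome(self) -> bool:
        return self is not QualityTier.OTHER


@dataclass
class BinRecord:
    """One contig bin with the annotations needed for quality triage."""

    bin_id: str
    size_bp: int
    depth: float
    completeness: float
    contamination: float
    has_5s: bool = False
    has_16s: bool = False
    has_23s: bool = False
    n_trna: int = 0
    contig_lengths: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (0.0 <= self.completeness <= 100.0):
            raise ConfigError(
                f"bin {self.bin_id!r}: completeness must be in [0, 100]"
            )
        if self.contamination < 0:
            raise ConfigError(f"bin {self.bin_id!r}: contamination must be >= 0")
        if self.n_trna < 0:
            raise ConfigError(f"bin {self.bin_id!r}: n_tRNA must be >= 0")
        if self.contig_lengths and self.size_bp != sum(self.contig_lengths):
            raise ConfigError(
                f"bin {self.bin_id!r}: size_bp does not match contig lengths"
            )


def classify_bin(b: BinRecord) -> QualityTier:
    """Assign a bin to its quality tier (see module docstring for rules)."""
    if (
        b.completeness > 90.0
        and b.contamination < 5.0
        and b.has_5s
        and b.has_16s
        and b.has_23s
        and b.n_trna >= 18
    ):
        return QualityTier.HIGH
    if b.completeness >= 50.0 and b.contamination < 10.0:
        return QualityTier.MEDIUM
    if b.completeness < 50.0 and b.contamination < 10.0:
        return QualityTier.LOW
    return QualityTier.OTHER


def bin_abundance(
    size_bp: float, depth: float, read_length: float, total_aligned_reads: float
) -> float:
    """Relative abundance of a bin: size x depth / (read length x reads)."""
    if size_bp < 0 or depth < 0:
        raise ConfigError("size and depth must be non-negative")
    denom = read_length * total_aligned_reads
    if denom <= 0:
        raise ConfigError("read_length and total_aligned_reads must be positive")
    return size_bp * depth / denom


def compute_n50(
    contig_lengths: Sequence[int], reference_size: int | None = None
) -> dict:
    """N50 (and NG50 when a reference size is given) of a contig set.

    N50 is the largest length L such that contigs of length >= L sum to at
    least half the assembly; NG50 replaces half the assembly with half the
    reference, and is reported as 0 when the assembly does not reach half
    the reference.
    """
    if not contig_lengths:
        raise ConfigError("cannot compute N50 of an empty contig set")
    if any(l <= 0 for l in contig_lengths):
        raise ConfigError("contig lengths must be positive")
    ordered = sorted(contig_lengths, reverse=True)
    total = sum(ordered)

    def _nx(target: float) -> int:
        cum = 0
        for l in ordered:
            cum += l
            if cum >= target:
                return l
        return 0

    result = {"N50": _nx(total / 2.0)}
    if reference_size is not None:
        if reference_size <= 0:
            raise ConfigError("reference_size must be positive")
        result["NG50"] = _nx(reference_size / 2.0) if total >= reference_size / 2.0 else 0
    return result


def summarize_tier_counts(
    counts: Mapping[QualityTier | str, int],
    total_length_mb: float = float("nan"),
    config: str = "",
) -> dict:
    """Assembly summary from per-tier bin counts.

    Percentages (of total bins) are rounded half-up to two decimals; the
    draft-genome proportion is the share of bins in the high, medium or low
    tier.
    """
    norm = {QualityTier(k): int(v) for k, v in counts.items()}
    n_bins = sum(norm.values())
    row: dict = {
        "config": config,
        "n_bins": n_bins,
        "total_length_mb": total_length_mb,
    }
    for tier in QualityTier:
        n = norm.get(tier, 0)
        row[tier.value.lower()] = n
        row[f"{tier.value.lower()}_pct"] = (
            round_half_up(100.0 * n / n_bins, 2) if n_bins else 0.0
        )
    n_draft = sum(norm.get(t, 0) for t in QualityTier if t.is_draft_genome)
    row["draft_pct"] = round_half_up(100.0 * n_draft / n_bins, 2) if n_bins else 0.0
    return row


def summarize_assembly(
    bins: Sequence[BinRecord], config: str = ""
) -> dict:
    """Classify bins and summarise the assembly (counts, percentages,
    total length in Mb, draft-genome proportion)."""
    counts = {tier: 0 for tier in QualityTier}
    for b in bins:
        counts[classify_bin(b)] += 1
    total_mb = sum(b.size_bp for b in bins) / 1e6
    return summarize_tier_counts(counts, total_length_mb=total_mb, config=config)


def _as_bool(value) -> bool:
    if isinstance(value, str):
        return value.strip().lower() in ("1", "true", "yes", "y")
    return bool(value)


def read_bins_tsv(path: str | Path) -> list[BinRecord]:
    """Read the neutral bin-report TSV (see ``BIN_TSV_COLUMNS``)."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in BIN_TSV_COLUMNS if c not in df.columns]
    if missing:
        raise ConfigError(f"{path}: missing bin columns {missing}")
    return [
        BinRecord(
            bin_id=str(r.bin_id),
            size_bp=int(r.size_bp),
            depth=float(r.depth),
            completeness=float(r.completeness),
            contamination=float(r.contamination),
            has_5s=_as_bool(r.has_5S),
            has_16s=_as_bool(r.has_16S),
            has_23s=_as_bool(r.has_23S),
            n_trna=int(r.n_tRNA),
        )
        for r in df.itertuples(index=False)
    ]


def write_bins_tsv(bins: Iterable[BinRecord], path: str | Path) -> None:
    rows = [
        (
            b.bin_id,
            b.size_bp,
            b.depth,
            b.completeness,
            b.contamination,
            int(b.has_5s),
            int(b.has_16s),
            int(b.has_23s),
            b.n_trna,
        )
        for b in bins
    ]
    pd.DataFrame(rows, columns=list(BIN_TSV_COLUMNS)).to_csv(
        path, sep="\t", index=False
    )


def write_summary_tsv(rows: Sequence[dict], path: str | Path) -> None:
    pd.DataFrame(rows, columns=list(SUMMARY_COLUMNS)).to_csv(
        path, sep="\t", index=False
    )
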