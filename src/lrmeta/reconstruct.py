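"""Greedy reconstruction of long DNA fragments from co-barcoded alignments.

Reads are grouped by barcode, then by reference, and scanned in mapping
order.  A growing fragment is extended while the next co-barcoded read
starts within ``max_gap`` (default 50 kb) of the fragment's current right
edge; a larger gap terminates the fragment and starts a new one.  Reads of
one barcode on different references never join the same fragment.  After
clustering, fragments with fewer than ``min_pairs`` distinct read pairs
(default 2) or spanning less than ``min_length`` (default 2 kb) are
discarded.

With right-edge anchoring, greedy clustering is exactly the connected
components of the reads on the line where two reads are connected when the
gap between their intervals is at most ``max_gap``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import ConfigError
from .seqio import AlignmentRecord

__all__ = [
    "ReconstructionParams",
    "ReconstructedFragment",
    "reconstruct_fragments",
    "cluster_alignments",
    "reconstruction_recall",
    "write_reconstructed_tsv",
    "read_reconstructed_tsv",
]

RECONSTRUCTED_TSV_COLUMNS = (
    "barcode",
    "reference_id",
    "start",
    "end",
    "length",
    "n_read_pairs",
)


@dataclass(frozen=True)
class ReconstructionParams:
    """Termination and filtering rules for fragment reconstruction."""

    max_gap: int = 50_000
    min_pairs: int = 2
    min_length: int = 2_000

    def __post_init__(self) -> None:
        if self.max_gap <= 0 or self.min_pairs <= 0 or self.min_length <= 0:
            raise ConfigError("reconstruction parameters must be positive")


@dataclass
class ReconstructedFragment:
    """A fragment inferred from co-barcoded read coordinates."""

    barcode: str
    reference_id: str
    start: int  # leftmost aligned base
    end: int  # rightmost aligned base + 1
    n_read_pairs: int
    read_ids: list[str]

    @property
    def length(self) -> int:
        return self.end - self.start


def cluster_alignments(
    alignments: Iterable[AlignmentRecord], max_gap: int
) -> list[ReconstructedFragment]:
    """Greedy gap clustering without the pair-count / length filters.

    Returns one candidate fragment per cluster, sorted by
    (reference, start, barcode).  Exposed separately because the raw cluster
    count is monotone in ``max_gap`` while the filtered count is not.
    """
    groups: dict[tuple[str, str], list[AlignmentRecord]] = {}
    for rec in alignments:
        groups.setdefault((rec.barcode, rec.reference_id), []).append(rec)

    fragments: list[ReconstructedFragment] = []
    for (barcode, ref), records in groups.items():
        records.sort(key=lambda r: (r.start, r.end, r.pair_id))
        cluster: list[AlignmentRecord] = []
        cur_end = -1
        for rec in records:
            if cluster and rec.start - cur_end > max_gap:
                fragments.append(_finish(barcode, ref, cluster))
                cluster = []
                cur_end = -1
            cluster.append(rec)
            cur_end = max(cur_end, rec.end)
        if cluster:
            fragments.append(_finish(barcode, ref, cluster))
    fragments.sort(key=lambda f: (f.reference_id, f.start, f.barcode))
    return fragments


def _finish(
    barcode: str, ref: str, cluster: Sequence[AlignmentRecord]
) -> ReconstructedFragment:
    pair_ids = sorted({r.pair_id for r in cluster})
    return ReconstructedFragment(
        barcode=barcode,
        reference_id=ref,
        start=min(r.start for r in cluster),
        end=max(r.end for r in cluster),
        n_read_pairs=len(pair_ids),
        read_ids=pair_ids,
    )


def reconstruct_fragments(
    alignments: Iterable[AlignmentRecord],
    params: ReconstructionParams | None = None,
) -> list[ReconstructedFragment]:
    """Reconstruct fragments from alignments and apply the quality filters.

    A fragment must contain at least ``params.min_pairs`` distinct read pairs
    (a pair whose mates fall in different clusters counts in both) and span
    at least ``params.min_length``.  Empty input yields empty output.
    """
    params = params or ReconstructionParams()
    return [
        f
        for f in cluster_alignments(alignments, params.max_gap)
        if f.n_read_pairs >= params.min_pairs and f.length >= params.min_length
    ]


def _reciprocal_overlap(
    a_start: int, a_end: int, b_start: int, b_end: int, fraction: float
) -> bool:
    ov = min(a_end, b_end) - max(a_start, b_start)
    if ov <= 0:
        return False
    return ov >= fraction * (a_end - a_start) and ov >= fraction * (b_end - b_start)


def reconstruction_recall(
    truth: pd.DataFrame,
    reconstructed: Sequence[ReconstructedFragment],
    overlap_fraction: float = 0.8,
) -> dict:
    """Score reconstructed fragments against simulation ground truth.

    A truth fragment counts as recovered when some reconstructed fragment
    with the same barcode on the same reference overlaps it reciprocally by
    at least ``overlap_fraction``.  Returns recall, precision, and the mean
    reconstructed/truth length ratio over recovered fragments (reconstruction
    can only span out to the outermost reads, so this ratio is typically
    slightly below one).
    """
    ref_col = "record_id" if "record_id" in truth.columns else "reference_id"
    index: dict[tuple[str, str], list[ReconstructedFragment]] = {}
    for frag in reconstructed:
        index.setdefault((frag.barcode, frag.reference_id), []).append(frag)

    n_recovered = 0
    ratios: list[float] = []
    for row in truth.itertuples(index=False):
        t_start, t_end = int(row.start), int(row.end)
        best = None
        for frag in index.get((row.barcode, getattr(row, ref_col)), []):
            if _reciprocal_overlap(
                t_start, t_end, frag.start, frag.end, overlap_fraction
            ):
                ov = min(t_end, frag.end) - max(t_start, frag.start)
                if best is None or ov > best[0]:
                    best = (ov, frag)
        if best is not None:
            n_recovered += 1
            ratios.append(best[1].length / (t_end - t_start))
    n_truth = len(truth)
    n_recon = len(reconstructed)
    # precision: reconstructed fragments that match some truth fragment
    truth_index: dict[tuple[str, str], list[tuple[int, int]]] = {}
    for row in truth.itertuples(index=False):
        truth_index.setdefault(
            (row.barcode, getattr(row, ref_col)), []
        ).append((int(row.start), int(row.end)))
    n_true_recon = 0
    for frag in reconstructed:
        for t_start, t_end in truth_index.get((frag.barcode, frag.reference_id), []):
            if _reciprocal_overlap(
                t_start, t_end, frag.start, frag.end, overlap_fraction
            ):
                n_true_recon += 1
                break
    return {
        "recall": n_recovered / n_truth if n_truth else 0.0,
        "precision": n_true_recon / n_recon if n_recon else 0.0,
        "length_bias": sum(ratios) / len(ratios) if ratios else float("nan"),
        "n_truth": n_truth,
        "n_reconstructed": n_recon,
    }


def write_reconstructed_tsv(
    fragments: Iterable[ReconstructedFragment], path
) -> None:
    with open(path, "w", encoding="ascii", newline="") as out:
        out.write("\t".join(RECONSTRUCTED_TSV_COLUMNS) + "\n")
        for f in fragments:
            out.write(
                f"{f.barcode}\t{f.reference_id}\t{f.start}\t{f.end}\t"
                f"{f.length}\t{f.n_read_pairs}\n"
            )


def read_reconstructed_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
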