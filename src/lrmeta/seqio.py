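"""Readers and writers for the sequence formats the toolkit touches.

FASTA is read through Biopython; SAM/BAM through pysam (the barcode is taken
from the ``BX`` tag, as written by barcode-aware aligners).  A plain TSV
alignment dialect is also supported so that fragment reconstruction can be
exercised without running an aligner.  FASTQ output supports two barcode
dialects:

``bx``
    the barcode travels in the read description as ``BX:Z:<barcode>-1``
    (both mates), the way barcode-aware pipelines emit processed reads;
``raw10x``
    the barcode is the first 16 bases of R1 followed by a 7 bp spacer,
    mimicking an unprocessed Chromium v1 library.

All coordinates are 0-based half-open.  All readers stream their input.
"""

from __future__ import annotations

import csv
import gzip
import io
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterable, Iterator

from Bio import SeqIO
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .community import GenomeEntry
from .errors import ParseError

__all__ = [
    "AlignmentRecord",
    "AlignmentStream",
    "FastqPair",
    "read_fasta",
    "write_fasta",
    "read_alignments",
    "read_fastq_pair",
    "write_fastq_pair",
]

BARCODE_LENGTH = 16
RAW10X_SPACER = "ACGACTC"  # constant 7 bp spacer after the barcode on R1
RAW10X_TRIM = BARCODE_LENGTH + len(RAW10X_SPACER)
_AUX_QUAL = "I"  # quality symbol for barcode+spacer bases on raw10x R1

FASTQ_DIALECTS = ("bx", "raw10x")
ALIGNMENT_DIALECTS = ("sam", "bam", "tsv")

ALIGNMENT_TSV_COLUMNS = (
    "barcode",
    "reference_id",
    "start",
    "end",
    "pair_id",
    "mate_index",
)


def _open_text(path: str | Path, mode: str) -> IO[str]:
    """gzip-aware text open; writes use a fixed mtime so output is
    byte-reproducible for identical inputs."""
    path = Path(path)
    if path.suffix == ".gz":
        if "w" in mode:
            raw = gzip.GzipFile(
                filename="", mode="wb", fileobj=open(path, "wb"), mtime=0
            )
            return io.TextIOWrapper(raw, encoding="ascii", newline="")
        return io.TextIOWrapper(
            gzip.GzipFile(filename=str(path), mode="rb"), encoding="ascii"
        )
    return open(path, mode, encoding="ascii", newline="" if "w" in mode else None)


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> list[GenomeEntry]:
    """Read a (possibly gzipped) FASTA file into one entry per record.

    Sequences are uppercased; record ids are taken up to the first whitespace.
    """
    path = Path(path)
    entries: list[GenomeEntry] = []
    with _open_text(path, "r") as handle:
        for rec in SeqIO.parse(handle, "fasta"):
            seq = str(rec.seq).upper()
            if not seq:
                raise ParseError(f"{path}: empty sequence for record {rec.id!r}")
            entries.append(GenomeEntry(id=rec.id, length_bp=len(seq), sequence=seq))
    if not entries:
        raise ParseError(f"{path}: no FASTA records found")
    return entries


def write_fasta(path: str | Path, records: Iterable[tuple[str, str]]) -> None:
    """Write ``(record_id, sequence)`` pairs as 80-column FASTA."""
    with _open_text(path, "w") as out:
        for rec_id, seq in records:
            out.write(f">{rec_id}\n")
            for i in range(0, len(seq), 80):
                out.write(seq[i : i + 80] + "\n")


# ---------------------------------------------------------------------------
# Alignments


@dataclass(frozen=True)
class AlignmentRecord:
    """One aligned read (mate) carrying a partition barcode."""

    barcode: str
    reference_id: str
    start: int  # 0-based inclusive
    end: int  # exclusive
    pair_id: str
    mate_index: int = 1

    def __post_init__(self) -> None:
        if not self.barcode:
            raise ParseError("alignment record without barcode")
        if self.start >= self.end:
            raise ParseError(
                f"inverted coordinates {self.start}..{self.end} for {self.pair_id!r}"
            )


class AlignmentStream:
    """Iterable over :class:`AlignmentRecord` with a drop counter.

    Unmapped, secondary and supplementary records are skipped silently;
    mapped records without a barcode are dropped and counted in
    ``n_missing_barcode``.
    """

    def __init__(self, path: str | Path, dialect: str = "tsv") -> None:
        if dialect not in ALIGNMENT_DIALECTS:
            raise ParseError(f"unknown alignment dialect {dialect!r}")
        self.path = Path(path)
        self.dialect = dialect
        self.n_missing_barcode = 0

    def __iter__(self) -> Iterator[AlignmentRecord]:
        if self.dialect == "tsv":
            yield from self._iter_tsv()
        else:
            yield from self._iter_sam()

    def _iter_tsv(self) -> Iterator[AlignmentRecord]:
        with _open_text(self.path, "r") as handle:
            reader = csv.DictReader(handle, delimiter="\t")
            if reader.fieldnames is None or any(
                c not in reader.fieldnames for c in ALIGNMENT_TSV_COLUMNS
            ):
                raise ParseError(
                    f"{self.path}: alignment TSV must have columns "
                    f"{list(ALIGNMENT_TSV_COLUMNS)}"
                )
            for lineno, row in enumerate(reader, start=2):
                barcode = (row["barcode"] or "").strip()
                if not barcode:
                    self.n_missing_barcode += 1
                    continue
                try:
                    start = int(row["start"])
                    end = int(row["end"])
                    mate = int(row["mate_index"])
                except (TypeError, ValueError) as exc:
                    raise ParseError(f"{self.path}: line {lineno}: {exc}") from exc
                if start >= end:
                    raise ParseError(
                        f"{self.path}: line {lineno}: inverted coordinates "
                        f"{start}..{end}"
                    )
                yield AlignmentRecord(
                    barcode=barcode,
                    reference_id=row["reference_id"],
                    start=start,
                    end=end,
                    pair_id=row["pair_id"],
                    mate_index=mate,
                )

    def _iter_sam(self) -> Iterator[AlignmentRecord]:
        import pysam

        mode = "rb" if self.dialect == "bam" else "r"
        with pysam.AlignmentFile(str(self.path), mode) as af:
            for aln in af:
                if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                    continue
                if not aln.has_tag("BX"):
                    self.n_missing_barcode += 1
                    continue
                end = aln.reference_end
                if end is None:
                    continue
                yield AlignmentRecord(
                    barcode=str(aln.get_tag("BX")),
                    reference_id=aln.reference_name,
                    start=aln.reference_start,
                    end=end,
                    pair_id=aln.query_name,
                    mate_index=2 if aln.is_read2 else 1,
                )


def read_alignments(path: str | Path, dialect: str = "tsv") -> AlignmentStream:
    """Open an alignment source (``sam``, ``bam`` or ``tsv`` dialect)."""
    return AlignmentStream(path, dialect)


def write_alignments_tsv(
    records: Iterable[AlignmentRecord], path: str | Path
) -> None:
    with _open_text(path, "w") as out:
        out.write("\t".join(ALIGNMENT_TSV_COLUMNS) + "\n")
        for r in records:
            out.write(
                f"{r.barcode}\t{r.reference_id}\t{r.start}\t{r.end}\t"
                f"{r.pair_id}\t{r.mate_index}\n"
            )


# ---------------------------------------------------------------------------
# FASTQ


@dataclass(frozen=True)
class FastqPair:
    """A paired read with its partition barcode (biological bases only)."""

    read_id: str
    barcode: str
    seq1: str
    qual1: str
    seq2: str
    qual2: str


def write_fastq_pair(
    pairs: Iterable[FastqPair],
    dialect: str,
    path1: str | Path,
    path2: str | Path,
) -> int:
    """Write mate streams to two (gzipped when ``.gz``) FASTQ files.

    Returns the number of pairs written.
    """
    if dialect not in FASTQ_DIALECTS:
        raise ParseError(f"unknown FASTQ dialect {dialect!r}")
    n = 0
    with _open_text(path1, "w") as out1, _open_text(path2, "w") as out2:
        for p in pairs:
            if dialect == "bx":
                head = f"{p.read_id} BX:Z:{p.barcode}-1"
                out1.write(f"@{head}\n{p.seq1}\n+\n{p.qual1}\n")
                out2.write(f"@{head}\n{p.seq2}\n+\n{p.qual2}\n")
            else:  # raw10x
                aux = _AUX_QUAL * RAW10X_TRIM
                out1.write(
                    f"@{p.read_id}\n{p.barcode}{RAW10X_SPACER}{p.seq1}\n+\n"
                    f"{aux}{p.qual1}\n"
                )
                out2.write(f"@{p.read_id}\n{p.seq2}\n+\n{p.qual2}\n")
            n += 1
    return n


def _parse_bx_title(title: str, path: Path) -> tuple[str, str]:
    fields = title.split()
    read_id = fields[0]
    for f in fields[1:]:
        if f.startswith("BX:Z:"):
            barcode = f[5:]
            if barcode.endswith("-1"):
                barcode = barcode[:-2]
            return read_id, barcode
    raise ParseError(f"{path}: read {read_id!r} has no BX:Z tag")


def read_fastq_pair(
    path1: str | Path, path2: str | Path, dialect: str
) -> Iterator[FastqPair]:
    """Stream pairs back from two FASTQ files written by :func:`write_fastq_pair`."""
    if dialect not in FASTQ_DIALECTS:
        raise ParseError(f"unknown FASTQ dialect {dialect!r}")
    path1, path2 = Path(path1), Path(path2)
    with _open_text(path1, "r") as h1, _open_text(path2, "r") as h2:
        it1 = FastqGeneralIterator(h1)
        it2 = FastqGeneralIterator(h2)
        from itertools import zip_longest

        for rec1, rec2 in zip_longest(it1, it2):
            if rec1 is None or rec2 is None:
                raise ParseError("mate files have different numbers of reads")
            (t1, s1, q1), (t2, s2, q2) = rec1, rec2
            if dialect == "bx":
                read_id, barcode = _parse_bx_title(t1, path1)
            else:
                read_id = t1.split()[0]
                if len(s1) <= RAW10X_TRIM:
                    raise ParseError(f"{path1}: R1 shorter than barcode+spacer")
                barcode = s1[:BARCODE_LENGTH]
                s1, q1 = s1[RAW10X_TRIM:], q1[RAW10X_TRIM:]
            if t2.split()[0] != read_id:
                raise ParseError(
                    f"mate order mismatch: {read_id!r} vs {t2.split()[0]!r}"
                )
            yield FastqPair(read_id, barcode, s1, q1, s2, q2)
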