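"""Community abundance model for microbial mixtures with uneven abundance.

A community is a set of reference genomes mixed at known molarities.
Normalising the molarities gives relative abundances ``A_i`` (``sum A_i = 1``).
Together with a global long-fragment physical depth ``C_F`` they determine how
much long-fragment DNA each genome contributes to a linked-read library::

    C_Fi = C_F * A_i * G      per-genome physical depth (G genomes)
    M_i  = C_Fi * L_i         fragment-length budget for genome i, in bp

where ``L_i`` is the genome size.  Uniform abundance recovers ``C_Fi = C_F``
for every genome, and ``mean(C_Fi) = C_F`` holds for any abundance vector.

Two abundance-class presets are provided: a molarity-threshold scheme
(low / medium / high, cut at 1e-15 and 1e-14 molar) used for staggered
simulated communities, and a percentage scheme (ultra-high / high / medium /
low, cut at 18 / 1.8 / 0.18 percent) matching staggered mock communities.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

from .errors import CommunityError, ConfigError

__all__ = [
    "AbundanceClass",
    "GenomeEntry",
    "CommunityProfile",
    "DepthBudget",
    "normalize_abundance",
    "per_genome_physical_depth",
    "fragment_budget",
    "estimated_input_nucleotides",
    "classify_abundance",
    "classify_percent_abundance",
    "read_community_table",
    "load_community",
]

#: molarity below which a genome counts as low-abundance (mol/L)
LOW_MOLARITY = 1e-15
#: molarity above which a genome counts as high-abundance (mol/L)
HIGH_MOLARITY = 1e-14

#: percentage thresholds for the mock-community preset
ULTRA_HIGH_PERCENT = 18.0
HIGH_PERCENT = 1.8
MEDIUM_PERCENT = 0.18


class AbundanceClass(str, enum.Enum):
    """Discrete abundance tier of a community member."""

    LOW = "LOW"
    MEDIUM = "MEDIUM"
    HIGH = "HIGH"
    ULTRA_HIGH = "ULTRA_HIGH"


@dataclass
class GenomeEntry:
    """One genome (or one FASTA record of a genome).

    ``length_bp`` is the total size.  For a multi-replicon genome (chromosome
    plus plasmids) ``records`` holds one single-record :class:`GenomeEntry`
    per replicon and ``length_bp`` is their sum; fragments are later allocated
    to records proportionally to record length and never span records.
    """

    id: str
    length_bp: int
    sequence: str | None = None
    records: tuple["GenomeEntry", ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.length_bp < 1:
            raise CommunityError(f"genome {self.id!r}: length_bp must be >= 1")
        if self.sequence is not None and len(self.sequence) != self.length_bp:
            raise CommunityError(
                f"genome {self.id!r}: length_bp={self.length_bp} does not match "
                f"sequence length {len(self.sequence)}"
            )
        if self.records:
            total = sum(r.length_bp for r in self.records)
            if total != self.length_bp:
                raise CommunityError(
                    f"genome {self.id!r}: record lengths sum to {total}, "
                    f"expected {self.length_bp}"
                )

    def iter_records(self) -> Iterator["GenomeEntry"]:
        """Yield the sequence-bearing records of this genome."""
        if self.records:
            yield from self.records
        else:
            yield self


def normalize_abundance(molarities: Sequence[float]) -> np.ndarray:
    """Normalise molarities to relative abundances summing to one.

    Raises :class:`CommunityError` if any molarity is negative or all are zero.
    """
    mol = np.asarray(molarities, dtype=float)
    if mol.size == 0:
        raise CommunityError("empty molarity vector")
    if np.any(mol < 0):
        raise CommunityError("molarities must be non-negative")
    total = mol.sum()
    if total <= 0:
        raise CommunityError("at least one molarity must be positive")
    return mol / total


def per_genome_physical_depth(
    c_f: float, abundances: Sequence[float], g: int
) -> np.ndarray:
    """Per-genome physical depth ``C_Fi = C_F * A_i * G``.

    The mean of the result over genomes equals ``C_F`` for any normalized
    abundance vector.
    """
    ab = np.asarray(abundances, dtype=float)
    if c_f < 0:
        raise ConfigError("C_F must be non-negative")
    if g != ab.size:
        raise ConfigError(f"G={g} does not match {ab.size} abundances")
    return c_f * ab * g


def fragment_budget(c_fi: Sequence[float], lengths: Sequence[float]) -> np.ndarray:
    """Fragment-length budget ``M_i = C_Fi * L_i`` in bp."""
    c = np.asarray(c_fi, dtype=float)
    l = np.asarray(lengths, dtype=float)
    if c.size != l.size:
        raise ConfigError("C_Fi and lengths differ in size")
    if np.any(c < 0) or np.any(l < 0):
        raise ConfigError("depths and lengths must be non-negative")
    return c * l


def estimated_input_nucleotides(
    abundances: Sequence[float], lengths: Sequence[float], g: int
) -> float:
    """Estimated input nucleotides ``sum_i A_i * L_i * G`` in bp."""
    ab = np.asarray(abundances, dtype=float)
    l = np.asarray(lengths, dtype=float)
    if ab.size != l.size:
        raise ConfigError("abundances and lengths differ in size")
    if g != ab.size:
        raise ConfigError(f"G={g} does not match {ab.size} abundances")
    return float(np.sum(ab * l) * g)


def classify_abundance(molarity: float) -> AbundanceClass:
    """Classify a molarity into low / medium / high abundance.

    Cuts are at 1e-15 and 1e-14; a molarity exactly on a cut is assigned the
    lower class.
    """
    if molarity < 0:
        raise CommunityError("molarity must be non-negative")
    if molarity <= LOW_MOLARITY:
        return AbundanceClass.LOW
    if molarity <= HIGH_MOLARITY:
        return AbundanceClass.MEDIUM
    return AbundanceClass.HIGH


def classify_percent_abundance(percent: float) -> AbundanceClass:
    """Mock-community preset: classify a mixture percentage.

    ``>= 18`` percent is ultra-high, ``>= 1.8`` high, ``>= 0.18`` medium,
    anything lower is low.
    """
    if percent < 0:
        raise CommunityError("percentage must be non-negative")
    if percent >= ULTRA_HIGH_PERCENT:
        return AbundanceClass.ULTRA_HIGH
    if percent >= HIGH_PERCENT:
        return AbundanceClass.HIGH
    if percent >= MEDIUM_PERCENT:
        return AbundanceClass.MEDIUM
    return AbundanceClass.LOW


@dataclass
class CommunityProfile:
    """Genomes plus their molarities and normalised abundances."""

    genomes: list[GenomeEntry]
    molarity: np.ndarray
    abundance: np.ndarray

    def __post_init__(self) -> None:
        self.molarity = np.asarray(self.molarity, dtype=float)
        self.abundance = np.asarray(self.abundance, dtype=float)
        n = len(self.genomes)
        if self.molarity.size != n or self.abundance.size != n:
            raise CommunityError("molarity/abundance size does not match genomes")
        if n == 0:
            raise CommunityError("community has no genomes")
        if abs(self.abundance.sum() - 1.0) > 1e-9:
            raise CommunityError("abundances must sum to 1")
        if not np.any(self.molarity > 0):
            raise CommunityError("at least one molarity must be positive")

    @classmethod
    def from_molarities(
        cls, genomes: list[GenomeEntry], molarities: Sequence[float]
    ) -> "CommunityProfile":
        mol = np.asarray(molarities, dtype=float)
        return cls(genomes=genomes, molarity=mol, abundance=normalize_abundance(mol))

    @property
    def g(self) -> int:
        """Number of genomes in the community."""
        return len(self.genomes)

    @property
    def lengths(self) -> np.ndarray:
        return np.array([g.length_bp for g in self.genomes], dtype=float)

    @property
    def total_length(self) -> int:
        return int(sum(g.length_bp for g in self.genomes))

    def abundance_classes(self) -> list[AbundanceClass]:
        return [classify_abundance(m) for m in self.molarity]


@dataclass
class DepthBudget:
    """Per-genome physical depths and fragment budgets for a community."""

    c_f_global: float
    c_fi: np.ndarray
    m_i: np.ndarray
    input_nucleotides: float

    @classmethod
    def for_community(cls, community: CommunityProfile, c_f: float) -> "DepthBudget":
        c_fi = per_genome_physical_depth(c_f, community.abundance, community.g)
        m_i = fragment_budget(c_fi, community.lengths)
        inp = estimated_input_nucleotides(
            community.abundance, community.lengths, community.g
        )
        return cls(c_f_global=float(c_f), c_fi=c_fi, m_i=m_i, input_nucleotides=inp)


COMMUNITY_COLUMNS = ("genome_id", "fasta_path")


def read_community_table(path: str | Path) -> pd.DataFrame:
    """Read a community TSV (``genome_id, fasta_path, molarity`` with header).

    An ``abundance`` column is accepted instead of (or in addition to)
    ``molarity``; when both are present molarity wins and is renormalised.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in COMMUNITY_COLUMNS if c not in df.columns]
    if missing:
        raise CommunityError(f"{path}: missing community columns {missing}")
    if "molarity" not in df.columns:
        if "abundance" not in df.columns:
            raise CommunityError(f"{path}: need a 'molarity' or 'abundance' column")
        df = df.assign(molarity=df["abundance"].astype(float))
    df["molarity"] = df["molarity"].astype(float)
    if df["genome_id"].duplicated().any():
        raise CommunityError(f"{path}: duplicated genome_id")
    return df


def load_community(
    path: str | Path, load_sequences: bool = True
) -> CommunityProfile:
    """Load a community TSV and its referenced FASTA files.

    Relative FASTA paths are resolved against the directory of the TSV.
    A genome's ``L_i`` is the sum of its FASTA record lengths.
    """
    from . import seqio  # deferred: seqio imports GenomeEntry from here

    path = Path(path)
    df = read_community_table(path)
    genomes: list[GenomeEntry] = []
    for row in df.itertuples(index=False):
        fasta = Path(row.fasta_path)
        if not fasta.is_absolute():
            fasta = path.parent / fasta
        records = seqio.read_fasta(fasta)
        if not load_sequences:
            records = [GenomeEntry(id=r.id, length_bp=r.length_bp) for r in records]
        total = sum(r.length_bp for r in records)
        genomes.append(
            GenomeEntry(
                id=str(row.genome_id),
                length_bp=total,
                records=tuple(records),
            )
        )
    return CommunityProfile.from_molarities(genomes, df["molarity"].to_numpy())


def write_community_table(
    path: str | Path,
    entries: Iterable[tuple[str, str, float]],
) -> None:
    """Write a community TSV from ``(genome_id, fasta_path, molarity)`` rows."""
    df = pd.DataFrame(entries, columns=["genome_id", "fasta_path", "molarity"])
    df.to_csv(path, sep="\t", index=False)
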