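"""Linked-read simulator for microbial communities with uneven abundance.

The generative model has four library parameters:

``C_F``
    physical depth of each genome by long DNA fragments (scaled per genome
    by relative abundance, ``C_Fi = C_F * A_i * G``);
``C_R``
    average short-read depth sequenced per fragment (typically 0.1-0.4X);
``mu_FL``
    mean (unweighted) fragment length.  Lengths follow a truncated
    (shifted) exponential with lower bound ``min_fragment_length`` by
    default, matching the short-fragment-dominated profiles of real
    metagenomic DNA extractions; a lognormal family is available;
``N_F/P``
    mean number of fragments per barcode partition.  Fragments are thrown
    uniformly at random into ``round(n_fragments / N_F/P)`` partitions, so
    occupancy is approximately Poisson(N_F/P); every partition carries a
    distinct random 16-mer barcode.

For genome ``i`` fragments are sampled until their cumulative length reaches
the budget ``M_i = C_Fi * L_i`` (the final fragment may overshoot and is kept
whole).  Each fragment is then sequenced into ``Poisson(C_R * length /
(2 * read_length))`` paired-end reads with a truncated-normal insert size,
uniform placement inside the fragment, and iid substitution errors at a
constant rate (``N`` reference bases pass through unchanged).  The total read
depth realised per genome therefore converges to ``C = C_R * C_Fi``.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .community import CommunityProfile, DepthBudget, GenomeEntry
from .config import make_rng, round_half_up
from .errors import ConfigError
from .seqio import (
    BARCODE_LENGTH,
    AlignmentRecord,
    FastqPair,
    write_fastq_pair,
)

logger = logging.getLogger(__name__)

__all__ = [
    "SimulationConfig",
    "SimulatedFragment",
    "Partition",
    "SimulatedReadPair",
    "draw_fragments",
    "assign_partitions",
    "partition_space",
    "generate_reads",
    "simulate_community",
    "simulate",
    "truth_alignments",
    "write_fragments_tsv",
    "read_fragments_tsv",
    "write_read_origins_tsv",
    "read_read_origins_tsv",
]

FRAGMENT_LENGTH_DISTS = ("exponential", "lognormal")

FRAGMENT_TSV_COLUMNS = (
    "fragment_id",
    "genome_id",
    "record_id",
    "start",
    "end",
    "partition_id",
    "barcode",
)
READ_ORIGIN_TSV_COLUMNS = ("read_id", "fragment_id", "mate1_start", "mate2_start")


@dataclass
class SimulationConfig:
    """Parameter vector of one simulated linked-read library."""

    c_f: float = 30.0
    c_r: float = 0.3
    mu_fl: float = 10_000.0
    n_fp: float = 10.0
    read_length: int = 150
    insert_mean: int = 400
    insert_sd: float = 50.0
    error_rate: float = 0.001
    min_fragment_length: int = 1_000
    fragment_length_dist: str = "exponential"
    lognormal_sigma: float = 0.5
    barcode_dialect: str = "bx"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.c_f < 0 or self.c_r < 0:
            raise ConfigError("depths must be non-negative")
        if self.read_length < 1:
            raise ConfigError("read_length must be >= 1")
        if not (0 <= self.error_rate < 1):
            raise ConfigError("error_rate must be in [0, 1)")
        if self.n_fp < 1:
            raise ConfigError("n_fp must be >= 1")
        if self.min_fragment_length < 1:
            raise ConfigError("min_fragment_length must be >= 1")
        if self.mu_fl <= self.min_fragment_length:
            raise ConfigError(
                f"mu_fl={self.mu_fl} must exceed min_fragment_length="
                f"{self.min_fragment_length}"
            )
        if self.fragment_length_dist not in FRAGMENT_LENGTH_DISTS:
            raise ConfigError(
                f"fragment_length_dist must be one of {FRAGMENT_LENGTH_DISTS}"
            )
        if self.insert_sd < 0:
            raise ConfigError("insert_sd must be non-negative")

    @property
    def implied_c(self) -> float:
        """Total read depth implied by the configured C_R and C_F."""
        return self.c_r * self.c_f

    @property
    def quality_char(self) -> str:
        """Constant Phred symbol matching the substitution rate (capped Q41)."""
        if self.error_rate <= 0:
            q = 41
        else:
            q = min(41, int(round(-10.0 * math.log10(self.error_rate))))
        return chr(q + 33)


@dataclass
class SimulatedFragment:
    """A sampled long DNA molecule (0-based half-open span on one record)."""

    fragment_id: str
    genome_id: str
    record_id: str
    start: int
    end: int
    partition_id: str = ""
    barcode: str = ""

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class Partition:
    """A droplet: one barcode holding one or more fragments."""

    partition_id: str
    barcode: str
    fragment_ids: list[str] = field(default_factory=list)


@dataclass
class SimulatedReadPair:
    """A paired-end read sequenced from a fragment (mate2 on reverse strand)."""

    read_id: str
    fragment_id: str
    mate1_start: int
    mate2_start: int
    seq1: str
    qual1: str
    seq2: str
    qual2: str
    barcode: str


# ---------------------------------------------------------------------------
# sequence helpers (uint8 views keep per-read work vectorised)

_COMP = np.full(256, ord("N"), dtype=np.uint8)
for _a, _b in (("A", "T"), ("T", "A"), ("C", "G"), ("G", "C"), ("N", "N")):
    _COMP[ord(_a)] = ord(_b)

_BASE_INDEX = np.full(256, 255, dtype=np.uint8)
for _i, _a in enumerate("ACGT"):
    _BASE_INDEX[ord(_a)] = _i
_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def encode_sequence(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def _revcomp(arr: np.ndarray) -> np.ndarray:
    return _COMP[arr][::-1]


def _mutate(arr: np.ndarray, error_rate: float, rng: np.random.Generator) -> np.ndarray:
    """Apply iid substitutions; non-ACGT positions (N) are left unchanged."""
    if error_rate <= 0:
        return arr
    n_err = rng.binomial(arr.size, error_rate)
    if n_err == 0:
        return arr
    out = arr.copy()
    pos = rng.choice(arr.size, size=n_err, replace=False)
    idx = _BASE_INDEX[out[pos]]
    valid = idx != 255
    if np.any(valid):
        shift = rng.integers(1, 4, size=int(valid.sum()))
        out[pos[valid]] = _BASES[(idx[valid] + shift) % 4]
    return out


# ---------------------------------------------------------------------------
# fragment sampling


def _draw_length(
    rng: np.random.Generator,
    mu_fl: float,
    min_len: int,
    dist: str,
    lognormal_sigma: float,
) -> int:
    if dist == "exponential":
        # shifted exponential == exponential truncated below at min_len,
        # with overall mean exactly mu_fl
        return int(min_len + rng.exponential(mu_fl - min_len))
    mu_log = math.log(mu_fl) - lognormal_sigma**2 / 2.0
    return int(max(min_len, rng.lognormal(mu_log, lognormal_sigma)))


def draw_fragments(
    genome: GenomeEntry,
    c_fi: float,
    mu_fl: float,
    min_len: int,
    rng: np.random.Generator,
    dist: str = "exponential",
    lognormal_sigma: float = 0.5,
) -> list[SimulatedFragment]:
    """Sample fragments from a genome until the budget ``M_i = C_Fi * L_i``
    is reached.

    The budget is allocated to the genome's records proportionally to record
    length (each record's budget is ``C_Fi * record_length``); fragments never
    span records.  Fragment starts are uniform, fragments may overlap, and the
    final fragment of a record may overshoot its budget and is kept whole.
    """
    if mu_fl <= min_len:
        raise ConfigError(f"mu_fl={mu_fl} must exceed min_len={min_len}")
    if c_fi < 0:
        raise ConfigError("C_Fi must be non-negative")
    fragments: list[SimulatedFragment] = []
    if c_fi == 0:
        return fragments
    for record in genome.iter_records():
        rec_len = record.length_bp
        if rec_len < min_len:
            logger.warning(
                "record %s (%d bp) shorter than min fragment length %d; skipped",
                record.id,
                rec_len,
                min_len,
            )
            continue
        budget = c_fi * rec_len
        cum = 0.0
        k = 0
        while cum < budget:
            length = min(rec_len, _draw_length(rng, mu_fl, min_len, dist, lognormal_sigma))
            start = int(rng.integers(0, rec_len - length + 1))
            fragments.append(
                SimulatedFragment(
                    fragment_id=f"F:{genome.id}:{record.id}:{k}",
                    genome_id=genome.id,
                    record_id=record.id,
                    start=start,
                    end=start + length,
                )
            )
            cum += length
            k += 1
    return fragments


def partition_space(n_fragments: int, n_fp: float) -> int:
    """Number of partitions allocated for ``n_fragments`` at mean load N_F/P."""
    if n_fp < 1:
        raise ConfigError("n_fp must be >= 1")
    if n_fragments == 0:
        return 0
    return max(1, int(round(n_fragments / n_fp)))


def _random_barcodes(n: int, rng: np.random.Generator) -> list[str]:
    """``n`` distinct random 16-mers over ACGT."""
    letters = np.frombuffer(b"ACGT", dtype=np.uint8)
    seen: set[str] = set()
    out: list[str] = []
    while len(out) < n:
        batch = letters[rng.integers(0, 4, size=(n - len(out), BARCODE_LENGTH))]
        for row in batch:
            bc = row.tobytes().decode("ascii")
            if bc not in seen:
                seen.add(bc)
                out.append(bc)
    return out


def assign_partitions(
    fragments: Sequence[SimulatedFragment],
    n_fp: float,
    rng: np.random.Generator,
) -> list[Partition]:
    """Throw fragments uniformly into ``round(n / N_F/P)`` barcoded partitions.

    Assignment is multinomial, so occupancy is approximately Poisson(N_F/P);
    partitions that receive no fragment are unobservable and are not
    returned.  Fragments are annotated in place with their partition id and
    barcode.  Returns the non-empty partitions.
    """
    if not fragments:
        return []
    space = partition_space(len(fragments), n_fp)
    barcodes = _random_barcodes(space, rng)
    slots = rng.integers(0, space, size=len(fragments))
    members: dict[int, list[str]] = {}
    for frag, slot in zip(fragments, slots):
        pid = f"P{slot:06d}"
        frag.partition_id = pid
        frag.barcode = barcodes[slot]
        members.setdefault(int(slot), []).append(frag.fragment_id)
    return [
        Partition(partition_id=f"P{slot:06d}", barcode=barcodes[slot],
                  fragment_ids=ids)
        for slot, ids in sorted(members.items())
    ]


# ---------------------------------------------------------------------------
# read generation


def generate_reads(
    fragment: SimulatedFragment,
    record_seq: np.ndarray,
    cfg: SimulationConfig,
    rng: np.random.Generator,
) -> list[SimulatedReadPair]:
    """Sequence one fragment into paired-end reads at per-fragment depth C_R.

    The number of pairs is Poisson with mean ``C_R * length / (2 *
    read_length)``; inserts are Normal(insert_mean, insert_sd) truncated to
    ``[2 * read_length, fragment length]``; both mates always lie inside the
    fragment span.  A fragment too short for a single pair yields no reads.
    """
    R = cfg.read_length
    L = fragment.length
    if cfg.c_r == 0:
        return []
    if L < 2 * R + 1:
        logger.warning(
            "fragment %s (%d bp) too short for a read pair", fragment.fragment_id, L
        )
        return []
    n_pairs = int(rng.poisson(cfg.c_r * L / (2.0 * R)))
    if n_pairs == 0:
        return []
    lo, hi = 2 * R, L
    qual = cfg.quality_char * R
    pairs: list[SimulatedReadPair] = []
    for k in range(n_pairs):
        insert = 0
        for _ in range(20):
            insert = int(round(rng.normal(cfg.insert_mean, cfg.insert_sd)))
            if lo <= insert <= hi:
                break
        else:
            insert = min(hi, max(lo, insert))
        offset = int(rng.integers(0, L - insert + 1))
        s1 = fragment.start + offset
        s2 = s1 + insert - R
        fwd = _mutate(record_seq[s1 : s1 + R], cfg.error_rate, rng)
        rev = _mutate(_revcomp(record_seq[s2 : s2 + R]), cfg.error_rate, rng)
        pairs.append(
            SimulatedReadPair(
                read_id=f"{fragment.fragment_id}/{k}",
                fragment_id=fragment.fragment_id,
                mate1_start=s1,
                mate2_start=s2,
                seq1=fwd.tobytes().decode("ascii"),
                qual1=qual,
                seq2=rev.tobytes().decode("ascii"),
                qual2=qual,
                barcode=fragment.barcode,
            )
        )
    return pairs


# ---------------------------------------------------------------------------
# whole-library simulation


def simulate_community(
    community: CommunityProfile, cfg: SimulationConfig
) -> tuple[list[SimulatedFragment], list[Partition], list[SimulatedReadPair]]:
    """Run the full generative model in memory.

    Three named random substreams (fragments, partitions, reads) are derived
    from ``cfg.seed`` so each stage is independently reproducible.
    """
    budget = DepthBudget.for_community(community, cfg.c_f)
    frag_rng = make_rng(cfg.seed, "fragments")
    part_rng = make_rng(cfg.seed, "partitions")
    read_rng = make_rng(cfg.seed, "reads")

    fragments: list[SimulatedFragment] = []
    for genome, c_fi in zip(community.genomes, budget.c_fi):
        fragments.extend(
            draw_fragments(
                genome,
                float(c_fi),
                cfg.mu_fl,
                cfg.min_fragment_length,
                frag_rng,
                dist=cfg.fragment_length_dist,
                lognormal_sigma=cfg.lognormal_sigma,
            )
        )
    partitions = assign_partitions(fragments, cfg.n_fp, part_rng)

    seq_cache: dict[str, np.ndarray] = {}
    for genome in community.genomes:
        for record in genome.iter_records():
            if record.sequence is None:
                raise ConfigError(f"record {record.id!r} has no sequence loaded")
            seq_cache[record.id] = encode_sequence(record.sequence)

    pairs: list[SimulatedReadPair] = []
    for frag in fragments:
        pairs.extend(generate_reads(frag, seq_cache[frag.record_id], cfg, read_rng))
    return fragments, partitions, pairs


def truth_alignments(
    fragments: Sequence[SimulatedFragment],
    pairs: Sequence[SimulatedReadPair],
    read_length: int,
) -> list[AlignmentRecord]:
    """Turn ground-truth read coordinates into alignment records.

    This is the error-free 'perfect aligner' used to validate fragment
    reconstruction against simulation truth.
    """
    by_id = {f.fragment_id: f for f in fragments}
    records: list[AlignmentRecord] = []
    for p in pairs:
        frag = by_id[p.fragment_id]
        for mate_index, start in ((1, p.mate1_start), (2, p.mate2_start)):
            records.append(
                AlignmentRecord(
                    barcode=frag.barcode,
                    reference_id=frag.record_id,
                    start=start,
                    end=start + read_length,
                    pair_id=p.read_id,
                    mate_index=mate_index,
                )
            )
    return records


def write_fragments_tsv(
    fragments: Iterable[SimulatedFragment], path: str | Path
) -> None:
    with open(path, "w", encoding="ascii", newline="") as out:
        out.write("\t".join(FRAGMENT_TSV_COLUMNS) + "\n")
        for f in fragments:
            out.write(
                f"{f.fragment_id}\t{f.genome_id}\t{f.record_id}\t{f.start}\t"
                f"{f.end}\t{f.partition_id}\t{f.barcode}\n"
            )


def read_fragments_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in FRAGMENT_TSV_COLUMNS if c not in df.columns]
    if missing:
        raise ConfigError(f"{path}: missing fragment columns {missing}")
    return df


def write_read_origins_tsv(
    pairs: Iterable[SimulatedReadPair], path: str | Path
) -> None:
    with open(path, "w", encoding="ascii", newline="") as out:
        out.write("\t".join(READ_ORIGIN_TSV_COLUMNS) + "\n")
        for p in pairs:
            out.write(
                f"{p.read_id}\t{p.fragment_id}\t{p.mate1_start}\t{p.mate2_start}\n"
            )


def read_read_origins_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def simulate(
    community: CommunityProfile, cfg: SimulationConfig, out_dir: str | Path
) -> dict:
    """Simulate a library and write FASTQ, ground truth and a manifest.

    Outputs under ``out_dir``: ``reads_R1.fastq.gz`` / ``reads_R2.fastq.gz``
    (barcode dialect per config), ``fragments.tsv`` and ``read_origins.tsv``
    ground truth, and ``manifest.json`` echoing the configuration together
    with the realised parameter values.  Identical seed, config and inputs
    give byte-identical outputs.
    """
    fragments, partitions, pairs = simulate_community(community, cfg)
    return write_library(community, cfg, fragments, partitions, pairs, out_dir)


def write_library(
    community: CommunityProfile,
    cfg: SimulationConfig,
    fragments: Sequence[SimulatedFragment],
    partitions: Sequence[Partition],
    pairs: Sequence[SimulatedReadPair],
    out_dir: str | Path,
) -> dict:
    """Write a simulated library (FASTQ, truth tables, manifest) to disk."""
    from .linkstats import estimate_stats, fragment_observations

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    r1 = out_dir / "reads_R1.fastq.gz"
    r2 = out_dir / "reads_R2.fastq.gz"
    write_fastq_pair(
        (
            FastqPair(p.read_id, p.barcode, p.seq1, p.qual1, p.seq2, p.qual2)
            for p in pairs
        ),
        cfg.barcode_dialect,
        r1,
        r2,
    )
    write_fragments_tsv(fragments, out_dir / "fragments.tsv")
    write_read_origins_tsv(pairs, out_dir / "read_origins.tsv")

    obs = fragment_observations(fragments, pairs)
    stats = estimate_stats(obs, cfg.read_length, community.total_length)

    frag_by_id = {f.fragment_id: f for f in fragments}
    genome_bases: dict[str, int] = {g.id: 0 for g in community.genomes}
    for p in pairs:
        genome_bases[frag_by_id[p.fragment_id].genome_id] += 2 * cfg.read_length
    per_genome_depth = {
        g.id: genome_bases[g.id] / g.length_bp for g in community.genomes
    }

    budget = DepthBudget.for_community(community, cfg.c_f)
    manifest = {
        "tool": "lrmeta",
        "version": __version__,
        "seed": cfg.seed,
        "config": asdict(cfg),
        "implied_c": round_half_up(cfg.implied_c, 2),
        "barcode_dialect": cfg.barcode_dialect,
        "community": {
            "n_genomes": community.g,
            "total_length_bp": community.total_length,
            "abundance": community.abundance.tolist(),
            "c_fi": budget.c_fi.tolist(),
            "m_i": budget.m_i.tolist(),
            "estimated_input_nucleotides": budget.input_nucleotides,
        },
        "realized": {
            **stats.to_dict(),
            "per_genome_depth": per_genome_depth,
            "n_partitions": len(partitions),
        },
        "outputs": {
            "fastq_r1": r1.name,
            "fastq_r2": r2.name,
            "fragments": "fragments.tsv",
            "read_origins": "read_origins.tsv",
        },
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
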