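"""Linked-read parameter estimation and the two subsampling schemes.

Given a set of fragments (simulation truth or reconstructed) carrying read
pair counts, the estimators are::

    mu_FL   = mean(length)                        unweighted mean length
    Wmu_FL  = sum(length^2) / sum(length)         length-weighted mean
    C_F     = sum(length) / genome_size           physical depth
    C       = total read bases / genome_size      total read depth
    C_R     = mean over fragments of              per-fragment read depth
              n_read_pairs * 2 * read_length / length

``C_R`` is reported both unweighted (the average per-fragment depth) and
length-weighted (total read bases / total fragment bases).  The weighted
variant satisfies ``C = C_R_weighted * C_F`` as an algebraic identity on any
fragment set; the unweighted variant matches it only up to the covariance
between fragment length and depth.  ``Wmu_FL >= mu_FL`` always
(Cauchy-Schwarz), with equality iff all lengths are equal.

Two subsampling modes generate depth series from one library:

* read subsampling keeps each read *pair* independently with probability
  ``f`` (mates are never separated), scaling expected ``C_R`` by ``f`` while
  leaving the fragment population — hence ``C_F`` — essentially unchanged
  (fragments that lose all reads become unobservable);
* barcode subsampling keeps whole barcodes with probability ``f``, scaling
  expected ``C_F`` by ``f`` while leaving per-fragment depth untouched.

Composing the two scales expected total depth ``C`` by the product of the
fractions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Protocol, Sequence, TypeVar

import numpy as np

from .config import make_rng
from .errors import ConfigError
from .seqio import FastqPair, read_fastq_pair, write_fastq_pair

__all__ = [
    "LinkedReadStats",
    "FragmentObs",
    "fragment_observations",
    "estimate_stats",
    "subsample_read_pairs",
    "subsample_barcodes",
    "subsample_fastq",
]


class _FragmentLike(Protocol):
    barcode: str
    n_read_pairs: int

    @property
    def length(self) -> int: ...


@dataclass(frozen=True)
class FragmentObs:
    """Minimal fragment observation used by the estimators."""

    barcode: str
    length: int
    n_read_pairs: int


def fragment_observations(fragments, pairs) -> list[FragmentObs]:
    """Pair simulation-truth fragments with their read counts.

    Fragments that received no reads are kept with a zero count so that
    truth-based statistics describe the physical library, not only its
    sequenced part.
    """
    counts: dict[str, int] = {}
    for p in pairs:
        counts[p.fragment_id] = counts.get(p.fragment_id, 0) + 1
    return [
        FragmentObs(
            barcode=f.barcode,
            length=f.length,
            n_read_pairs=counts.get(f.fragment_id, 0),
        )
        for f in fragments
    ]


@dataclass
class LinkedReadStats:
    """Estimated linked-read parameter vector."""

    c: float
    c_r: float
    c_r_weighted: float
    c_f: float
    mu_fl: float
    w_mu_fl: float
    n_fp: float
    n_fragments: int
    n_read_pairs: int
    n_barcodes: int

    def to_dict(self) -> dict:
        return {
            "c": self.c,
            "c_r": self.c_r,
            "c_r_weighted": self.c_r_weighted,
            "c_f": self.c_f,
            "mu_fl": self.mu_fl,
            "w_mu_fl": self.w_mu_fl,
            "n_fp": self.n_fp,
            "n_fragments": self.n_fragments,
            "n_read_pairs": self.n_read_pairs,
            "n_barcodes": self.n_barcodes,
        }


def estimate_stats(
    fragments: Sequence[_FragmentLike], read_length: int, genome_size: float
) -> LinkedReadStats:
    """Estimate the parameter vector from a fragment set.

    An empty fragment set yields zero counts with NaN means so that callers
    can tell 'no signal' apart from 'zero depth'.
    """
    if genome_size <= 0:
        raise ConfigError("genome_size must be positive")
    if not fragments:
        nan = float("nan")
        return LinkedReadStats(0.0, nan, nan, nan, nan, nan, nan, 0, 0, 0)
    lengths = np.array([f.length for f in fragments], dtype=float)
    npairs = np.array([f.n_read_pairs for f in fragments], dtype=float)
    barcodes = {f.barcode for f in fragments}
    read_bases = npairs * 2.0 * read_length
    total_len = float(lengths.sum())
    return LinkedReadStats(
        c=float(read_bases.sum() / genome_size),
        c_r=float(np.mean(read_bases / lengths)),
        c_r_weighted=float(read_bases.sum() / total_len),
        c_f=float(total_len / genome_size),
        mu_fl=float(lengths.mean()),
        w_mu_fl=float(np.sum(lengths**2) / total_len),
        n_fp=len(fragments) / len(barcodes),
        n_fragments=len(fragments),
        n_read_pairs=int(npairs.sum()),
        n_barcodes=len(barcodes),
    )


T = TypeVar("T")


def _check_fraction(fraction: float) -> None:
    if not (0.0 <= fraction <= 1.0) or math.isnan(fraction):
        raise ConfigError(f"fraction must be in [0, 1], got {fraction}")


def subsample_read_pairs(
    pairs: Sequence[T], fraction: float, rng: np.random.Generator
) -> list[T]:
    """Keep each read pair independently with probability ``fraction``."""
    _check_fraction(fraction)
    if fraction == 1.0:
        return list(pairs)
    if fraction == 0.0:
        return []
    keep = rng.random(len(pairs)) < fraction
    return [p for p, k in zip(pairs, keep) if k]


def subsample_barcodes(
    pairs: Sequence[T], fraction: float, rng: np.random.Generator
) -> list[T]:
    """Keep whole barcodes with probability ``fraction``.

    All reads of a kept barcode are retained; all reads of a dropped barcode
    are removed.  The keep/drop decision is made per distinct barcode in
    order of first appearance, so the result is deterministic for a given
    input order and seed.
    """
    _check_fraction(fraction)
    if fraction == 1.0:
        return list(pairs)
    if fraction == 0.0:
        return []
    decision: dict[str, bool] = {}
    out: list[T] = []
    for p in pairs:
        bc = p.barcode  # type: ignore[attr-defined]
        if bc not in decision:
            decision[bc] = bool(rng.random() < fraction)
        if decision[bc]:
            out.append(p)
    return out


def subsample_fastq(
    in1: str | Path,
    in2: str | Path,
    out1: str | Path,
    out2: str | Path,
    mode: str,
    fraction: float,
    seed: int,
    dialect: str = "bx",
) -> dict:
    """Stream-subsample a FASTQ pair by reads or by barcodes.

    Returns a small summary dict (pairs in/out, barcodes kept for barcode
    mode).
    """
    _check_fraction(fraction)
    if mode not in ("reads", "barcodes"):
        raise ConfigError(f"mode must be 'reads' or 'barcodes', got {mode!r}")
    rng = make_rng(seed, f"subsample-{mode}")
    n_in = 0
    n_out = 0
    decision: dict[str, bool] = {}

    def _kept() -> Iterable[FastqPair]:
        nonlocal n_in, n_out
        for pair in read_fastq_pair(in1, in2, dialect):
            n_in += 1
            if mode == "reads":
                keep = fraction == 1.0 or rng.random() < fraction
            else:
                if pair.barcode not in decision:
                    decision[pair.barcode] = (
                        fraction == 1.0 or bool(rng.random() < fraction)
                    )
                keep = decision[pair.barcode]
            if keep:
                n_out += 1
                yield pair

    write_fastq_pair(_kept(), dialect, out1, out2)
    summary = {
        "mode": mode,
        "fraction": fraction,
        "seed": seed,
        "pairs_in": n_in,
        "pairs_out": n_out,
    }
    if mode == "barcodes":
        summary["barcodes_seen"] = len(decision)
        summary["barcodes_kept"] = sum(decision.values())
    return summary
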