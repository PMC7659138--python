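"""Generative model: fragment sampling, partitioning, read generation."""

import json
from pathlib import Path

import numpy as np
import pytest
import scipy.stats

from lrmeta import (
    GenomeEntry,
    SimulationConfig,
    assign_partitions,
    draw_fragments,
    generate_reads,
    simulate,
)
from lrmeta.config import make_rng
from lrmeta.errors import ConfigError
from lrmeta.linkstats import estimate_stats, fragment_observations
from lrmeta.simulate import (
    SimulatedFragment,
    encode_sequence,
    partition_space,
)

from conftest import make_community, random_sequence


def _dummy_fragments(n):
    return [
        SimulatedFragment(f"F{i}", "g", "g", 0, 10_000) for i in range(n)
    ]


# ---------------------------------------------------------------------------
# fragment sampling


def test_zero_depth_draws_no_fragments():
    genome = GenomeEntry(id="g", length_bp=100_000, sequence="A" * 100_000)
    assert draw_fragments(genome, 0.0, 10_000, 1_000, make_rng(0, "f")) == []


def test_budget_stopping_rule():
    # cumulative fragment length must land within one overshoot of M_i
    genome = GenomeEntry(id="g", length_bp=1_000_000)
    frags = draw_fragments(genome, 10.0, 10_000, 1_000, make_rng(1, "f"))
    total = sum(f.length for f in frags)
    assert total >= 1e7
    assert total == pytest.approx(1e7, rel=0.02)


def test_fragment_length_mean_matches_mu_fl():
    genome = GenomeEntry(id="g", length_bp=10_000_000)
    # budget 1e8 at mean 10 kb -> ~10k fragments
    frags = draw_fragments(genome, 10.0, 10_000, 1_000, make_rng(2, "f"))
    assert len(frags) > 5_000
    mean_len = np.mean([f.length for f in frags])
    assert mean_len == pytest.approx(10_000, rel=0.05)


def test_fragments_stay_inside_record():
    genome = GenomeEntry(id="g", length_bp=50_000)
    frags = draw_fragments(genome, 5.0, 10_000, 1_000, make_rng(3, "f"))
    assert all(0 <= f.start < f.end <= 50_000 for f in frags)
    assert all(f.length >= 1_000 for f in frags)


def test_multi_record_budget_is_proportional():
    records = (
        GenomeEntry(id="chr", length_bp=900_000),
        GenomeEntry(id="plasmid", length_bp=100_000),
    )
    genome = GenomeEntry(id="g", length_bp=1_000_000, records=records)
    frags = draw_fragments(genome, 20.0, 10_000, 1_000, make_rng(4, "f"))
    by_rec = {
        rec: sum(f.length for f in frags if f.record_id == rec)
        for rec in ("chr", "plasmid")
    }
    assert by_rec["chr"] == pytest.approx(18e6, rel=0.02)
    assert by_rec["plasmid"] == pytest.approx(2e6, rel=0.05)


def test_mu_fl_must_exceed_min_length():
    genome = GenomeEntry(id="g", length_bp=100_000)
    with pytest.raises(ConfigError):
        draw_fragments(genome, 1.0, 500, 1_000, make_rng(0, "f"))


# ---------------------------------------------------------------------------
# partition assignment


def test_partition_space_examples():
    assert partition_space(1_000, 1.0) == 1_000
    assert partition_space(10_000, 10.0) == 1_000
    assert partition_space(3, 10.0) == 1  # floor case
    assert partition_space(0, 10.0) == 0


def test_three_fragments_low_space_all_cobarcoded():
    frags = _dummy_fragments(3)
    parts = assign_partitions(frags, 10.0, make_rng(5, "p"))
    assert len(parts) == 1
    assert len({f.barcode for f in frags}) == 1


def test_partitions_conserve_fragments_and_barcodes_unique():
    frags = _dummy_fragments(2_000)
    parts = assign_partitions(frags, 10.0, make_rng(6, "p"))
    assigned = [fid for p in parts for fid in p.fragment_ids]
    assert sorted(assigned) == sorted(f.fragment_id for f in frags)
    barcodes = [p.barcode for p in parts]
    assert len(set(barcodes)) == len(barcodes)
    assert all(len(b) == 16 and set(b) <= set("ACGT") for b in barcodes)


def test_occupancy_is_approximately_poisson():
    n, n_fp = 10_000, 10.0
    frags = _dummy_fragments(n)
    parts = assign_partitions(frags, n_fp, make_rng(7, "p"))
    space = partition_space(n, n_fp)
    occ = np.zeros(space, dtype=int)
    occ[: len(parts)] = sorted((len(p.fragment_ids) for p in parts), reverse=True)
    counts = np.bincount(occ, minlength=25)[:25]
    expected = scipy.stats.poisson.pmf(np.arange(25), n_fp) * space
    # lump sparse tail bins so the chi-square approximation is valid
    keep = expected >= 5
    obs = np.append(counts[keep], counts[~keep].sum())
    exp = np.append(expected[keep], expected[~keep].sum())
    exp *= obs.sum() / exp.sum()
    stat, p = scipy.stats.chisquare(obs, exp)
    assert p > 0.01


def test_empty_fragment_list_gives_empty_partitions():
    assert assign_partitions([], 10.0, make_rng(0, "p")) == []


# ---------------------------------------------------------------------------
# read generation


def _fragment_on(seq: str, start: int, end: int) -> SimulatedFragment:
    return SimulatedFragment("F0", "g", "g", start, end, "P0", "A" * 16)


def test_zero_read_depth_yields_no_pairs():
    cfg = SimulationConfig(c_r=0.0)
    seq = "A" * 20_000
    frag = _fragment_on(seq, 0, 10_000)
    assert generate_reads(frag, encode_sequence(seq), cfg, make_rng(0, "r")) == []


def test_short_fragment_yields_no_pairs():
    cfg = SimulationConfig(min_fragment_length=1, mu_fl=10_000)
    seq = "A" * 1_000
    frag = _fragment_on(seq, 0, 250)  # < 2 * read_length + 1
    assert generate_reads(frag, encode_sequence(seq), cfg, make_rng(0, "r")) == []


def test_pair_count_is_poisson_with_expected_mean():
    # C_R=0.3 on a 10 kb fragment at 2x150 bp -> mean 10 pairs
    cfg = SimulationConfig(c_r=0.3, error_rate=0.0)
    rng_seq = np.random.default_rng(0)
    seq = random_sequence(rng_seq, 10_000)
    frag = _fragment_on(seq, 0, 10_000)
    arr = encode_sequence(seq)
    rng = make_rng(8, "r")
    n_rep = 3_000
    counts = [len(generate_reads(frag, arr, cfg, rng)) for _ in range(n_rep)]
    mean = np.mean(counts)
    se = np.sqrt(10.0 / n_rep)
    assert abs(mean - 10.0) < 3 * se
    # Poisson: variance matches the mean
    assert np.var(counts) == pytest.approx(10.0, rel=0.15)


def test_mates_contained_in_fragment_and_correct_bases():
    rng_seq = np.random.default_rng(1)
    seq = random_sequence(rng_seq, 30_000)
    arr = encode_sequence(seq)
    cfg = SimulationConfig(c_r=0.4, error_rate=0.0)
    frag = _fragment_on(seq, 5_000, 25_000)
    comp = str.maketrans("ACGTN", "TGCAN")
    pairs = generate_reads(frag, arr, cfg, make_rng(9, "r"))
    assert pairs
    for p in pairs:
        assert frag.start <= p.mate1_start <= p.mate1_start + 150 <= frag.end
        assert frag.start <= p.mate2_start <= p.mate2_start + 150 <= frag.end
        # error-free reads reproduce the reference (mate2 reverse strand)
        assert p.seq1 == seq[p.mate1_start : p.mate1_start + 150]
        assert p.seq2 == seq[p.mate2_start : p.mate2_start + 150].translate(comp)[::-1]


def test_substitution_rate_matches_configuration():
    rng_seq = np.random.default_rng(2)
    seq = random_sequence(rng_seq, 50_000)
    arr = encode_sequence(seq)
    cfg = SimulationConfig(c_r=0.77, error_rate=0.02)
    frag = _fragment_on(seq, 0, 50_000)
    comp = str.maketrans("ACGTN", "TGCAN")
    pairs = generate_reads(frag, arr, cfg, make_rng(10, "r"))
    mismatches = bases = 0
    for p in pairs:
        ref1 = seq[p.mate1_start : p.mate1_start + 150]
        ref2 = seq[p.mate2_start : p.mate2_start + 150].translate(comp)[::-1]
        mismatches += sum(a != b for a, b in zip(p.seq1, ref1))
        mismatches += sum(a != b for a, b in zip(p.seq2, ref2))
        bases += 300
    rate = mismatches / bases
    se = np.sqrt(0.02 * 0.98 / bases)
    assert abs(rate - 0.02) < 3 * se


def test_n_bases_pass_through_unchanged():
    seq = "A" * 500 + "N" * 500 + "C" * 500
    arr = encode_sequence(seq)
    cfg = SimulationConfig(
        c_r=0.77, error_rate=0.5, min_fragment_length=1, mu_fl=10_000
    )
    frag = _fragment_on(seq, 0, 1_500)
    pairs = generate_reads(frag, arr, cfg, make_rng(11, "r"))
    assert pairs
    for p in pairs:
        ref1 = seq[p.mate1_start : p.mate1_start + 150]
        for got, ref in zip(p.seq1, ref1):
            if ref == "N":
                assert got == "N"


def test_quality_symbol_tracks_error_rate():
    assert SimulationConfig(error_rate=0.001).quality_char == chr(30 + 33)
    assert SimulationConfig(error_rate=0.0).quality_char == chr(41 + 33)


# ---------------------------------------------------------------------------
# whole-library properties


def test_realized_depth_near_c_r_times_c_f(toy_sim):
    # toy community: C_Fi = 30 each, C_R = 0.3 -> ~9X per genome
    obs = fragment_observations(toy_sim["fragments"], toy_sim["pairs"])
    stats = estimate_stats(obs, 150, toy_sim["community"].total_length)
    assert stats.c == pytest.approx(9.0, rel=0.15)
    assert stats.c_f == pytest.approx(30.0, rel=0.1)
    assert stats.w_mu_fl >= stats.mu_fl


def test_fragment_physical_depth_per_genome(toy_sim):
    for genome in toy_sim["community"].genomes:
        total = sum(
            f.length for f in toy_sim["fragments"] if f.genome_id == genome.id
        )
        # within one mean fragment length of C_Fi * L_i
        assert abs(total - 30.0 * genome.length_bp) <= 60_000


def test_simulate_writes_reproducible_outputs(tmp_path, toy_community):
    cfg = SimulationConfig(c_f=8.0, c_r=0.3, seed=12)
    m1 = simulate(toy_community, cfg, tmp_path / "a")
    m2 = simulate(toy_community, cfg, tmp_path / "b")
    for name in ("reads_R1.fastq.gz", "reads_R2.fastq.gz", "fragments.tsv",
                 "read_origins.tsv", "manifest.json"):
        assert (tmp_path / "a" / name).read_bytes() == (
            tmp_path / "b" / name
        ).read_bytes(), name
    assert m1 == m2
    assert m1["realized"]["n_barcodes"] == m1["realized"]["n_partitions"]


def test_manifest_records_implied_c(tmp_path, toy_community):
    cfg = SimulationConfig(c_f=28.0, c_r=0.36, seed=3)
    manifest = simulate(toy_community, cfg, tmp_path / "sim")
    assert manifest["implied_c"] == pytest.approx(10.08)
    saved = json.loads((tmp_path / "sim" / "manifest.json").read_text())
    assert saved["implied_c"] == pytest.approx(10.08)
    # per-genome realized depth close to C_R * C_Fi = 0.36 * 28
    for depth in manifest["realized"]["per_genome_depth"].values():
        assert depth == pytest.approx(10.08, rel=0.2)


def test_distinct_barcodes_match_partition_space(toy_sim):
    n_frags = len(toy_sim["fragments"])
    barcodes = {f.barcode for f in toy_sim["fragments"]}
    # at N_F/P = 10 the chance of an unoccupied partition is ~e^-10
    assert len(barcodes) == partition_space(n_frags, toy_sim["cfg"].n_fp)
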