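"""Masking, recruitment, coverage normalization and replication skew."""

import numpy as np
import pytest

from cprlib import (
    PipelineError,
    ValidationError,
    coverage_per_gbp,
    mask_rrna,
    merge_intervals,
    recruit,
    recruitment_result,
    replication_index,
    subsample_reads,
    window_coverages,
)
from cprlib import synthetic_data as sd
from cprlib.recruitment import ReadHit


class TestMaskRrna:
    def test_effective_length_subtracts_masked_span(self):
        seq = "A" * 1_000_000
        masked, eff = mask_rrna(seq, [(100_001, 105_000)])
        assert eff == 995_000
        assert masked[100_000:105_000] == "N" * 5000
        assert len(masked) == len(seq)

    def test_no_intervals_is_identity(self):
        seq = "ACGT" * 100
        masked, eff = mask_rrna(seq, [])
        assert (masked, eff) == (seq, 400)

    def test_overlapping_intervals_merged_first(self):
        seq = "A" * 400
        masked, eff = mask_rrna(seq, [(100, 200), (150, 250)])
        assert masked.count("N") == 151
        assert eff == 400 - 151

    def test_out_of_bounds_interval_rejected(self):
        with pytest.raises(ValidationError):
            mask_rrna("ACGT", [(2, 10)])

    def test_merge_intervals_handles_adjacency(self):
        assert merge_intervals([(1, 5), (6, 10), (20, 25)]) == \
            [(1, 10), (20, 25)]


class TestSubsampleReads:
    def test_requesting_more_than_available_returns_all(self):
        reads = [(f"r{i}", "ACGT") for i in range(100)]
        assert subsample_reads(reads, 20_000_000, seed=1) == reads

    def test_zero_returns_empty(self):
        reads = [("r0", "ACGT")]
        assert subsample_reads(reads, 0, seed=1) == []

    def test_deterministic_and_order_preserving(self):
        reads = [(f"r{i}", "ACGT") for i in range(1000)]
        a = subsample_reads(reads, 100, seed=7)
        b = subsample_reads(reads, 100, seed=7)
        assert a == b
        ids = [int(r[0][1:]) for r in a]
        assert ids == sorted(ids)
        assert len(a) == 100


class TestRecruit:
    def test_verbatim_read_hits_once(self):
        genome = sd.make_genome(1, 10_000)
        read = genome[2000:2150]
        hits = recruit([("r1", read)], genome)
        assert len(hits) == 1
        assert hits[0].position == 2001
        assert hits[0].identity == 1.0

    def test_reverse_complement_read_hits(self):
        genome = sd.make_genome(2, 10_000)
        comp = str.maketrans("ACGT", "TGCA")
        read = genome[500:650].translate(comp)[::-1]
        hits = recruit([("r1", read)], genome)
        assert len(hits) == 1 and hits[0].strand == "-"

    def test_read_from_masked_region_misses(self):
        genome = sd.make_genome(3, 10_000)
        read = genome[4000:4150]
        masked, _ = mask_rrna(genome, [(3900, 4300)])
        assert recruit([("r1", read)], masked) == []

    def test_identity_floor_is_enforced(self):
        genome = sd.make_genome(4, 10_000)
        read = list(genome[1000:1150])
        for i in range(0, 24, 3):        # 8 mismatches -> 94.7% identity
            read[i] = {"A": "C", "C": "A", "G": "T", "T": "G"}[read[i]]
        assert recruit([("r1", "".join(read))], genome, 0.95) == []
        # 7 mismatches (95.3%) pass the same floor
        read7 = list(genome[1000:1150])
        for i in range(0, 21, 3):
            read7[i] = {"A": "C", "C": "A", "G": "T", "T": "G"}[read7[i]]
        assert len(recruit([("r1", "".join(read7))], genome, 0.95)) == 1

    def test_read_longer_than_genome_is_not_an_error(self):
        assert recruit([("r1", "A" * 100)], "ACGTACGT") == []


class TestCoveragePerGbp:
    def test_documented_arithmetic(self):
        res = coverage_per_gbp("b", "m", n_hits=2000,
                               mapped_bases=2000 * 150,
                               effective_genome_len=10**6,
                               sampled_bases=20 * 10**6 * 151)
        assert res.coverage == pytest.approx(0.3)
        assert res.coverage_per_gbp == pytest.approx(0.3 / 3.02)

    def test_zero_hits_zero_coverage(self):
        res = coverage_per_gbp("b", "m", 0, 0, 10**6, 10**9)
        assert res.coverage == 0 and res.coverage_per_gbp == 0

    def test_doubling_sampled_bases_halves_normalized_value(self):
        a = coverage_per_gbp("b", "m", 100, 15000, 10**6, 10**9)
        b = coverage_per_gbp("b", "m", 100, 15000, 10**6, 2 * 10**9)
        assert a.coverage_per_gbp == pytest.approx(2 * b.coverage_per_gbp)

    def test_zero_effective_length_rejected(self):
        with pytest.raises(PipelineError):
            coverage_per_gbp("b", "m", 0, 0, 0, 10**9)

    def test_matches_analytic_depth_on_simulated_reads(self):
        genome = sd.make_genome(5, 100_000)
        depth = 3.0
        reads, _ = sd.simulate_reads(5, genome, depth=depth)
        hits = recruit(reads, genome)
        sampled = sum(len(s) for _, s in reads)
        res = recruitment_result("b", "m", hits, len(genome), sampled)
        assert res.n_hits >= 1000
        assert res.coverage == pytest.approx(depth, rel=0.05)
        assert res.coverage_per_gbp == pytest.approx(
            depth / (sampled / 1e9), rel=0.05)

    def test_stable_under_subsampling(self):
        """Normalized abundance is invariant in expectation when the read
        pool is subsampled (relative spread < 10% at >= 1000 hits)."""
        genome = sd.make_genome(6, 100_000)
        reads, _ = sd.simulate_reads(6, genome, depth=6.0)
        values = []
        for seed in range(10):
            sub = subsample_reads(reads, len(reads) // 2, seed)
            hits = recruit(sub, genome)
            sampled = sum(len(s) for _, s in sub)
            values.append(recruitment_result("b", "m", hits, len(genome),
                                             sampled).coverage_per_gbp)
        spread = (max(values) - min(values)) / np.mean(values)
        assert spread < 0.10


class TestWindowCoverages:
    def test_single_full_window_read_coverage(self):
        hits = [ReadHit("r", 1, "+", 1.0, 5000)]
        cov = window_coverages(hits, 100_000, 5000)
        assert cov[0] == pytest.approx(1.0)
        assert np.all(cov[1:] == 0)

    def test_genome_shorter_than_window_rejected(self):
        with pytest.raises(PipelineError):
            window_coverages([], 1000, 5000)


class TestReplicationIndex:
    def test_uniform_windows_give_exactly_one(self):
        idx = replication_index([10.0] * 40)
        assert idx.index == 1.0

    def test_low_coverage_is_undefined(self):
        idx = replication_index([0.05] * 40)
        assert idx.index is None

    def test_all_zero_coverage_is_undefined(self):
        idx = replication_index([0.0] * 40, coverage_floor=0.0)
        assert idx.index is None

    def test_too_few_windows_rejected(self):
        with pytest.raises(PipelineError):
            replication_index([1.0] * 19)

    def test_planted_gradient_recovered(self):
        genome = sd.make_genome(11, 150_000)
        reads, _ = sd.simulate_reads(11, genome, depth=20, ptr=2.0)
        hits = recruit(reads, genome)
        cov = window_coverages(hits, len(genome))
        idx = replication_index(cov)
        assert 1.7 <= idx.index <= 2.3

    def test_monotone_in_planted_ptr(self):
        genome = sd.make_genome(12, 100_000)
        estimates = []
        for ptr in (1.0, 1.5, 2.0, 3.0):
            reads, _ = sd.simulate_reads(12, genome, depth=20, ptr=ptr)
            cov = window_coverages(recruit(reads, genome), len(genome))
            estimates.append(replication_index(cov).index)
        assert estimates == sorted(estimates)
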