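"""Fragment recruitment: normalized abundance and replication skew.

Abundance of a genome in a metagenome is expressed as *coverage per Gbp*:
the fold coverage achieved by recruited reads (mapped bases over the
rRNA-masked effective genome length) divided by the gigabases of metagenome
sampled.  This makes abundances comparable across genomes of different sizes
and metagenomes of different depths.

Replication skew is summarized by an origin-to-terminus coverage ratio
(peak-to-trough style): actively replicating populations over-represent the
replication origin, so the ratio of the best-covered to the worst-covered
genomic windows exceeds 1.  The index here is the mean of the top decile of
window coverages over the mean of the bottom decile, after discarding the
extreme 2% of windows on each side; it is floored at 1.0 and reported as
undefined below a minimum mean coverage (default 0.2x), where the ratio is
dominated by sampling noise.

The built-in read mapper is a deliberately simple k-mer-seeded ungapped
matcher sufficient for desk-scale genomes; recruitment from an external
mapper can be supplied as a precomputed hit table instead.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .core_model import PipelineError, ValidationError


@dataclass
class RecruitmentResult:
    bin_id: str
    metagenome_id: str
    n_hits: int
    mapped_bases: int
    effective_genome_len: int
    sampled_bases: int
    coverage: float
    coverage_per_gbp: float


@dataclass
class ReplicationIndex:
    bin_id: str
    metagenome_id: str
    index: float | None        # None = undefined (reported NA)
    mean_coverage: float
    window_size: int


@dataclass(frozen=True)
class ReadHit:
    read_id: str
    position: int              # 1-based start on the genome
    strand: str
    identity: float
    length: int


# ---------------------------------------------------------------------------
# rRNA masking
# ---------------------------------------------------------------------------

def merge_intervals(intervals: Iterable[tuple[int, int]]
                    ) -> list[tuple[int, int]]:
    """Merge overlapping/adjacent 1-based inclusive intervals."""
    ivs = sorted(intervals)
    merged: list[tuple[int, int]] = []
    for s, e in ivs:
        if merged and s <= merged[-1][1] + 1:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def mask_rrna(sequence: str,
              intervals: Sequence[tuple[int, int]],
              ) -> tuple[str, int]:
    """Replace rRNA intervals (1-based inclusive) with N and return the
    masked sequence plus the effective (unmasked) length."""
    L = len(sequence)
    for s, e in intervals:
        if not 1 <= s <= e <= L:
            raise ValidationError(
                f"interval {s}..{e} outside sequence of length {L}")
    merged = merge_intervals(intervals)
    masked = 0
    parts: list[str] = []
    prev = 0
    for s, e in merged:
        parts.append(sequence[prev:s - 1])
        parts.append("N" * (e - s + 1))
        masked += e - s + 1
        prev = e
    parts.append(sequence[prev:])
    return "".join(parts), L - masked


# ---------------------------------------------------------------------------
# Read subsampling
# ---------------------------------------------------------------------------

def subsample_reads(reads: Sequence[tuple[str, str]], n: int, seed: int,
                    ) -> list[tuple[str, str]]:
    """Reservoir-sample exactly min(n, len(reads)) reads, preserving the
    original read order; deterministic under a fixed seed."""
    if n < 0:
        raise PipelineError("subsample size must be >= 0")
    if n >= len(reads):
        return list(reads)
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(len(reads), size=n, replace=False))
    return [reads[i] for i in idx]


# ---------------------------------------------------------------------------
# Naive ungapped recruitment
# ---------------------------------------------------------------------------

_SEED_K = 15


def _index_genome(genome: str, k: int) -> dict[str, list[int]]:
    index: dict[str, list[int]] = {}
    for i in range(len(genome) - k + 1):
        kmer = genome[i:i + k]
        if "N" in kmer:
            continue
        index.setdefault(kmer, []).append(i)
    return index


_COMP = str.maketrans("ACGTN", "TGCAN")


def recruit(reads: Sequence[tuple[str, str]],
            genome: str,
            min_identity: float = 0.95,
            ) -> list[ReadHit]:
    """Recruit reads to a (masked) genome by ungapped full-length alignment.

    A read is a hit if an ungapped alignment at >= ``min_identity`` over the
    whole read exists anywhere on either strand; masked (N) positions count
    as mismatches.  One hit is kept per read (highest identity, leftmost on
    a tie).  Reads longer than the genome simply never hit.

    Seeding uses non-overlapping 15-mers, which by pigeonhole finds every
    alignment with fewer mismatches than the number of seeds — ample for a
    95% identity floor on 150 bp reads.
    """
    if not 0 < min_identity <= 1:
        raise PipelineError("min_identity must lie in (0, 1]")
    L = len(genome)
    index = _index_genome(genome, _SEED_K)
    garr = np.frombuffer(genome.encode(), dtype=np.uint8)
    hits: list[ReadHit] = []
    for read_id, seq in reads:
        rlen = len(seq)
        if rlen > L:
            continue
        best: tuple[float, int, str] | None = None
        for strand, oriented in (("+", seq),
                                 ("-", seq.translate(_COMP)[::-1])):
            rarr = np.frombuffer(oriented.encode(), dtype=np.uint8)
            seen: set[int] = set()
            for off in range(0, rlen - _SEED_K + 1, _SEED_K):
                for pos in index.get(oriented[off:off + _SEED_K], ()):
                    start = pos - off
                    if start < 0 or start + rlen > L or start in seen:
                        continue
                    seen.add(start)
                    window = garr[start:start + rlen]
                    matches = int(np.sum((window == rarr)
                                         & (window != ord("N"))))
                    ident = matches / rlen
                    if ident >= min_identity and (
                            best is None or ident > best[0]
                            or (ident == best[0] and start < best[1]
                                and strand == best[2])):
                        best = (ident, start, strand)
        if best is not None:
            hits.append(ReadHit(read_id=read_id, position=best[1] + 1,
                                strand=best[2], identity=best[0],
                                length=rlen))
    return hits


# ---------------------------------------------------------------------------
# Coverage and abundance
# ---------------------------------------------------------------------------

def coverage_per_gbp(bin_id: str,
                     metagenome_id: str,
                     n_hits: int,
                     mapped_bases: int,
                     effective_genome_len: int,
                     sampled_bases: int) -> RecruitmentResult:
    """Normalized abundance: fold coverage per gigabase of metagenome.

    coverage = mapped_bases / effective_genome_len;
    coverage_per_gbp = coverage / (sampled_bases / 1e9).
    """
    if effective_genome_len <= 0:
        raise PipelineError("effective genome length must be > 0")
    if sampled_bases <= 0:
        raise PipelineError("sampled bases must be > 0")
    if min(n_hits, mapped_bases) < 0:
        raise PipelineError("hit counts and mapped bases must be >= 0")
    coverage = mapped_bases / effective_genome_len
    return RecruitmentResult(
        bin_id=bin_id, metagenome_id=metagenome_id,
        n_hits=n_hits, mapped_bases=mapped_bases,
        effective_genome_len=effective_genome_len,
        sampled_bases=sampled_bases,
        coverage=coverage,
        coverage_per_gbp=coverage / (sampled_bases / 1e9),
    )


def recruitment_result(bin_id: str, metagenome_id: str,
                       hits: Sequence[ReadHit],
                       effective_genome_len: int,
                       sampled_bases: int) -> RecruitmentResult:
    """Convenience wrapper building a result from a recruited hit list."""
    return coverage_per_gbp(
        bin_id, metagenome_id,
        n_hits=len(hits),
        mapped_bases=sum(h.length for h in hits),
        effective_genome_len=effective_genome_len,
        sampled_bases=sampled_bases)


def window_coverages(hits: Sequence[ReadHit], genome_len: int,
                     window_size: int = 5000) -> np.ndarray:
    """Mean per-base coverage in consecutive fixed-size windows (the trailing
    partial window, if any, is dropped)."""
    if genome_len < window_size:
        raise PipelineError("genome shorter than one window")
    depth_delta = np.zeros(genome_len + 1)
    for h in hits:
        start0 = h.position - 1
        depth_delta[start0] += 1
        depth_delta[min(start0 + h.length, genome_len)] -= 1
    depth = np.cumsum(depth_delta[:-1])
    n_win = genome_len // window_size
    return depth[:n_win * window_size].reshape(n_win, window_size).mean(axis=1)


# ---------------------------------------------------------------------------
# Replication skew index
# ---------------------------------------------------------------------------

def replication_index(coverages: Sequence[float],
                      coverage_floor: float = 0.2,
                      trim_frac: float = 0.02,
                      window_size: int = 5000,
                      bin_id: str = "",
                      metagenome_id: str = "") -> ReplicationIndex:
    """Origin/terminus coverage skew from sorted window coverages.

    Windows are sorted; the extreme ``trim_frac`` of windows on each side is
    discarded; the index is the mean of the top decile over the mean of the
    bottom decile, floored at 1.0.  Undefined (NA) when the overall mean
    coverage is below ``coverage_floor`` or the bottom decile is empty of
    coverage.
    """
    cov = np.asarray(coverages, dtype=float)
    if cov.size < 20:
        raise PipelineError(
            f"need >= 20 coverage windows, got {cov.size}")
    if np.any(cov < 0):
        raise ValidationError("window coverages must be >= 0")
    mean_cov = float(cov.mean())
    if mean_cov < coverage_floor:
        return ReplicationIndex(bin_id, metagenome_id, None, mean_cov,
                                window_size)
    s = np.sort(cov)
    k = int(trim_frac * s.size)
    if k:
        s = s[k:-k]
    d = max(1, s.size // 10)
    bottom = float(s[:d].mean())
    top = float(s[-d:].mean())
    if bottom == 0.0:
        return ReplicationIndex(bin_id, metagenome_id, None, mean_cov,
                                window_size)
    return ReplicationIndex(bin_id, metagenome_id, max(1.0, top / bottom),
                            mean_cov, window_size)
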