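"""Bin decontamination and quality gating from single-copy marker genes.

Two filters clean a bin before quality estimation:

1. **Taxonomy vote** — every gene receives the taxonomy class of its best
   alignment hit (subject to e-value, identity, coverage and bitscore
   floors); the class with the most assigned genes bin-wide is the bin's
   dominant class, and any contig whose assigned genes fall below 30%
   dominant-class membership is discarded as a contaminant.
2. **Viral fraction** — contigs with more than 25% virus-flagged genes are
   discarded as phage sequence.

Quality is then estimated from a 43-marker single-copy-gene (SCG) profile:
completeness is the fraction of markers present, contamination the fraction
of surplus copies, and strain heterogeneity the share of multi-copy markers
whose extra copies are near-identical (>= 90% amino-acid identity) to the
first copy.  A bin passes when completeness > 40% and contamination < 5%
(both strict, matching the study's gate).

The vote denominator counts taxonomically *assigned* genes only: CPR genes
frequently have no database hit at all, and counting unassigned genes would
purge exactly the novel contigs the analysis is after.  Contigs with zero
assigned genes are therefore retained and flagged rather than removed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .core_model import (
    Bin,
    Hit,
    PipelineConfig,
    PipelineError,
    ValidationError,
    ConfigError,
)


@dataclass
class SCGProfile:
    """Copy counts over the 43-marker set, optionally with amino-acid
    identities of each extra copy against the first copy of its marker."""

    counts: dict[str, int]
    copy_identities: dict[str, list[float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.counts.values()):
            raise ValidationError("marker copy counts must be >= 0")


@dataclass
class QualityReport:
    bin_id: str
    completeness: float
    contamination: float
    strain_heterogeneity: float
    n_contigs_removed_taxonomy: int = 0
    n_contigs_removed_viral: int = 0
    passed: bool = False


# ---------------------------------------------------------------------------
# Gene taxonomy and the contig vote
# ---------------------------------------------------------------------------

def hit_passes(hit: Hit, config: PipelineConfig) -> bool:
    return (hit.evalue <= config.hit_evalue_max
            and hit.similarity >= config.hit_min_similarity
            and hit.coverage >= config.hit_min_coverage
            and hit.bitscore >= config.hit_min_bitscore)


def assign_gene_taxonomy(hits: Mapping[str, Sequence[Hit]],
                         config: PipelineConfig) -> dict[str, str | None]:
    """Map each gene to the class of its best surviving hit.

    Hits failing any of the four alignment criteria are discarded; among
    survivors the hit with the highest bitscore wins (first-listed hit on an
    exact tie).  Genes with no surviving hit map to ``None`` (unassigned).
    """
    out: dict[str, str | None] = {}
    for gene_id, gene_hits in hits.items():
        survivors = [h for h in gene_hits if hit_passes(h, config)]
        if not survivors:
            out[gene_id] = None
        else:
            out[gene_id] = max(survivors, key=lambda h: h.bitscore).subject_class
    return out


def dominant_class(bin_: Bin, taxonomy: Mapping[str, str | None]) -> str:
    """The taxonomy class with the most assigned genes bin-wide.

    Ties break to the lexicographically smallest class label.  A bin with no
    assigned gene at all cannot be voted on and raises.
    """
    counts: dict[str, int] = {}
    for gene_id in bin_.genes:
        cls = taxonomy.get(gene_id)
        if cls is not None:
            counts[cls] = counts.get(cls, 0) + 1
    if not counts:
        raise PipelineError(
            f"bin {bin_.id}: no taxonomically assigned genes; cannot vote")
    return min(counts, key=lambda c: (-counts[c], c))


def _subset_bin(bin_: Bin, keep: set[str]) -> Bin:
    contigs = {cid: c for cid, c in bin_.contigs.items() if cid in keep}
    genes = {g.id: g for g in bin_.genes.values() if g.contig_id in keep}
    return Bin(id=bin_.id, contigs=contigs, genes=genes,
               lake=bin_.lake, metagenome=bin_.metagenome)


def decontaminate(bin_: Bin,
                  taxonomy: Mapping[str, str | None],
                  config: PipelineConfig,
                  ) -> tuple[Bin, list[str], list[str]]:
    """Remove contigs whose assigned genes are <30% dominant-class.

    The dominant class and every contig's fraction are computed once, on the
    unfiltered bin (single pass, no re-voting).  Returns the filtered bin,
    removed contig ids, and the ids of retained contigs that carried zero
    assigned genes (flagged, not removed).
    """
    dom = dominant_class(bin_, taxonomy)
    removed: list[str] = []
    flagged: list[str] = []
    keep: set[str] = set()
    for cid, contig in bin_.contigs.items():
        assigned = [taxonomy.get(g) for g in contig.gene_ids
                    if taxonomy.get(g) is not None]
        if not assigned:
            flagged.append(cid)
            keep.add(cid)
            continue
        frac = sum(1 for c in assigned if c == dom) / len(assigned)
        if frac < config.dominant_class_min_frac:
            removed.append(cid)
        else:
            keep.add(cid)
    return _subset_bin(bin_, keep), removed, flagged


def viral_filter(bin_: Bin, config: PipelineConfig) -> tuple[Bin, list[str]]:
    """Remove contigs on which virus-flagged genes exceed 25% of all
    predicted genes.  Contigs without genes carry no evidence and stay."""
    removed: list[str] = []
    keep: set[str] = set()
    for cid, contig in bin_.contigs.items():
        genes = [bin_.genes[g] for g in contig.gene_ids]
        if genes:
            frac = sum(1 for g in genes if g.viral) / len(genes)
            if frac > config.viral_max_frac:
                removed.append(cid)
                continue
        keep.add(cid)
    return _subset_bin(bin_, keep), removed


# ---------------------------------------------------------------------------
# SCG profile and quality estimation
# ---------------------------------------------------------------------------

def scg_profile(marker_annotations: Mapping[str, str],
                config: PipelineConfig,
                copy_identities: Mapping[str, Sequence[float]] | None = None,
                ) -> SCGProfile:
    """Count marker copies from a gene_id -> marker_id annotation table.

    Annotations for markers outside the configured 43-marker set are
    ignored; every configured marker appears in the profile (count 0 when
    absent).
    """
    marker_set = set(config.scg_marker_ids)
    counts = {m: 0 for m in config.scg_marker_ids}
    for marker in marker_annotations.values():
        if marker in marker_set:
            counts[marker] += 1
    identities = {m: list(v) for m, v in (copy_identities or {}).items()}
    unknown = set(identities) - marker_set
    if unknown:
        raise ConfigError(f"copy identities for unknown markers: {sorted(unknown)}")
    return SCGProfile(counts=counts, copy_identities=identities)


def estimate_quality(profile: SCGProfile,
                     config: PipelineConfig,
                     bin_id: str = "",
                     n_removed_taxonomy: int = 0,
                     n_removed_viral: int = 0) -> QualityReport:
    """Completeness, contamination and strain heterogeneity from an SCG
    profile, plus the strict pass/fail quality gate.

    * completeness   = 100 x (markers with >= 1 copy) / 43
    * contamination  = 100 x sum of surplus copies / 43
    * strain heterogeneity = 100 x (multi-copy markers whose extra copies
      are all >= 90% identical to the first copy) / (multi-copy markers);
      0 when there is no multi-copy marker.  Markers without recorded copy
      identities are counted as divergent (not heterogeneous).
    """
    n = len(config.scg_marker_ids)
    if set(profile.counts) != set(config.scg_marker_ids):
        raise ValidationError(
            f"profile keys do not match the configured {n}-marker set")
    present = sum(1 for c in profile.counts.values() if c >= 1)
    surplus = sum(max(0, c - 1) for c in profile.counts.values())
    completeness = 100.0 * present / n
    contamination = 100.0 * surplus / n
    multi = [m for m, c in profile.counts.items() if c > 1]
    if multi:
        het = sum(
            1 for m in multi
            if profile.copy_identities.get(m)
            and all(i >= config.strain_het_identity_min
                    for i in profile.copy_identities[m]))
        strain_het = 100.0 * het / len(multi)
    else:
        strain_het = 0.0
    passed = (completeness > config.completeness_min
              and contamination < config.contamination_max)
    return QualityReport(
        bin_id=bin_id,
        completeness=completeness,
        contamination=contamination,
        strain_heterogeneity=strain_het,
        n_contigs_removed_taxonomy=n_removed_taxonomy,
        n_contigs_removed_viral=n_removed_viral,
        passed=passed,
    )


def qc_bin(bin_: Bin,
           taxonomy: Mapping[str, str | None],
           marker_annotations: Mapping[str, str],
           config: PipelineConfig,
           ) -> tuple[Bin, QualityReport]:
    """Full per-bin QC: taxonomy-vote decontamination, viral filter, then
    SCG quality estimation on the surviving genes."""
    decon, removed_tax, _ = decontaminate(bin_, taxonomy, config)
    clean, removed_vir = viral_filter(decon, config)
    surviving_markers = {g: m for g, m in marker_annotations.items()
                         if g in clean.genes}
    profile = scg_profile(surviving_markers, config)
    report = estimate_quality(profile, config, bin_id=bin_.id,
                              n_removed_taxonomy=len(removed_tax),
                              n_removed_viral=len(removed_vir))
    return clean, report
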