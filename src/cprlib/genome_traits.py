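"""Genome streamlining traits and lifestyle-group comparison.

Per-genome traits capture the hallmarks of genome streamlining in the
candidate phyla radiation: small assemblies, high coding density, low GC.
Because MAGs are incomplete, the estimated genome size extrapolates the
assembly length by completeness:

    estimated_genome_size = assembly_length * 100 / completeness

Coding density is the union of gene spans over the assembly length, so
overlapping genes are counted once.  Traits are compared across lifestyle
categories (CPR classes, free-living bacteria, symbionts/parasites) by
per-category median and range.

KEGG-module completeness is the fraction of a module's KOs a genome encodes;
group values are two-step unweighted means: first an average per genome over
modules, then an average of those over the group.  CAZy tabulation reports
per-genome totals, each family's share of all hits, and its prevalence
(fraction of genomes encoding it).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .core_model import Bin, ConfigError, PipelineError
from .bin_qc import QualityReport


@dataclass(frozen=True)
class ModuleDef:
    module_id: str
    kos: frozenset[str]

    def __post_init__(self) -> None:
        if not self.kos:
            raise ConfigError(f"module {self.module_id}: empty KO set")


TRAIT_COLUMNS = ("assembly_length", "estimated_genome_size", "gc",
                 "coding_density", "n_genes", "completeness")


# ---------------------------------------------------------------------------
# Per-genome traits
# ---------------------------------------------------------------------------

def _union_length(intervals: Iterable[tuple[int, int]]) -> int:
    """Total length of the union of 1-based inclusive intervals."""
    total, cur_s, cur_e = 0, None, None
    for s, e in sorted(intervals):
        if cur_e is None or s > cur_e + 1:
            if cur_e is not None:
                total += cur_e - cur_s + 1
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    if cur_e is not None:
        total += cur_e - cur_s + 1
    return total


def compute_traits(bin_: Bin, quality: QualityReport,
                   category: str = "") -> dict:
    """One trait-table row for a bin: sizes, GC, coding density, gene count."""
    assembly_length = bin_.assembly_length
    if assembly_length == 0:
        raise PipelineError(f"bin {bin_.id}: empty assembly")
    gc = at = 0
    for contig in bin_.contigs.values():
        if contig.sequence is None:
            raise PipelineError(f"contig {contig.id}: sequence required")
        gc += sum(contig.sequence.count(b) for b in "GC")
        at += sum(contig.sequence.count(b) for b in "AT")
    gc_pct = 100.0 * gc / (gc + at) if gc + at else 0.0
    coding = sum(
        _union_length((g.start, g.end) for g in bin_.genes_on(cid))
        for cid in bin_.contigs)
    estimated = (assembly_length * 100.0 / quality.completeness
                 if quality.completeness > 0 else None)
    return {
        "genome_id": bin_.id,
        "category": category,
        "assembly_length": assembly_length,
        "estimated_genome_size": estimated,
        "gc": gc_pct,
        "coding_density": 100.0 * coding / assembly_length,
        "n_genes": len(bin_.genes),
        "completeness": quality.completeness,
    }


# ---------------------------------------------------------------------------
# Group comparison
# ---------------------------------------------------------------------------

def summarize_groups(table: pd.DataFrame,
                     traits: Sequence[str] = TRAIT_COLUMNS) -> pd.DataFrame:
    """Median, min and max of each trait per lifestyle category.

    Categories without any genome are omitted (pandas groupby drops them);
    the output is order-invariant in the input rows.
    """
    if "category" not in table.columns:
        raise PipelineError("trait table needs a 'category' column")
    present = [t for t in traits if t in table.columns]
    rows = []
    for cat, sub in sorted(table.groupby("category")):
        row: dict = {"category": cat, "n": len(sub)}
        for t in present:
            vals = sub[t].dropna().astype(float)
            row[f"{t}_median"] = float(vals.median()) if len(vals) else None
            row[f"{t}_min"] = float(vals.min()) if len(vals) else None
            row[f"{t}_max"] = float(vals.max()) if len(vals) else None
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# KEGG module completeness
# ---------------------------------------------------------------------------

def module_completeness(genome_kos: Mapping[str, set[str] | frozenset[str]],
                        modules: Sequence[ModuleDef],
                        groups: Mapping[str, str] | None = None,
                        ) -> tuple[pd.DataFrame, pd.Series, dict[str, float]]:
    """Per-genome per-module completeness plus two-step group averages.

    Returns the genome x module fraction matrix, the per-genome average over
    modules, and (if ``groups`` maps genome -> category) the unweighted mean
    of per-genome averages for each category.
    """
    if not modules:
        raise ConfigError("no module definitions supplied")
    data = {
        m.module_id: {
            g: len(set(kos) & m.kos) / len(m.kos)
            for g, kos in genome_kos.items()
        }
        for m in modules
    }
    matrix = pd.DataFrame(data, index=list(genome_kos))
    per_genome = matrix.mean(axis=1)
    group_avg: dict[str, float] = {}
    if groups is not None:
        by_cat: dict[str, list[float]] = {}
        for g, avg in per_genome.items():
            if g not in groups:
                raise PipelineError(f"genome {g} has no category label")
            by_cat.setdefault(groups[g], []).append(float(avg))
        group_avg = {c: float(np.mean(v)) for c, v in sorted(by_cat.items())}
    return matrix, per_genome, group_avg


# ---------------------------------------------------------------------------
# CAZy tabulation
# ---------------------------------------------------------------------------

def cazy_summary(genome_families: Mapping[str, Sequence[str]],
                 ) -> tuple[pd.Series, pd.DataFrame]:
    """Per-genome CAZy gene totals and per-family share/prevalence.

    ``share`` is a family's percentage of all identified CAZy genes;
    ``prevalence`` the percentage of genomes encoding at least one copy.
    """
    totals = pd.Series({g: len(fams) for g, fams in genome_families.items()},
                       dtype=int, name="n_cazy")
    n_genomes = len(genome_families)
    counts: dict[str, int] = {}
    presence: dict[str, int] = {}
    for fams in genome_families.values():
        for f in fams:
            counts[f] = counts.get(f, 0) + 1
        for f in set(fams):
            presence[f] = presence.get(f, 0) + 1
    total_hits = sum(counts.values())
    fam_rows = [{
        "family": f,
        "n_hits": counts[f],
        "share": 100.0 * counts[f] / total_hits if total_hits else 0.0,
        "prevalence": 100.0 * presence[f] / n_genomes if n_genomes else 0.0,
    } for f in sorted(counts, key=lambda f: (-counts[f], f))]
    families = pd.DataFrame(
        fam_rows, columns=["family", "n_hits", "share", "prevalence"])
    return totals, families
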