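"""Synthetic inputs with planted ground truth for every pipeline stage.

Each generator plants a known truth (contamination fraction, single-copy-gene
profile, origin-to-terminus coverage gradient, rhodopsin class, ANI cluster
membership, group trait distributions) and returns it alongside the data, so
the downstream stage can be tested closed-loop without any external download.

Design notes
------------
* Everything is driven by ``numpy.random.default_rng(seed)``; the same seed
  reproduces byte-identical files.
* Membrane proteins are built to be solvable by a hydropathy/positive-inside
  topology predictor *by construction*: helices use strongly hydrophobic
  residues (I/V/L/F), loops use strongly hydrophilic ones (N/Q/E) so helix
  boundaries cannot bleed across loops, and arginines are placed only on the
  intended cytoplasmic side.  Serine, aspartate and lysine appear exclusively
  in the planted retinal-binding motif, so no spurious motif can arise.
* Read simulation is ungapped and error-free by default, mirroring strict
  ungapped recruitment; an optional substitution rate exists for robustness
  tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core_model import (
    Bin,
    Contig,
    Gene,
    PipelineError,
    DEFAULT_SCG_MARKERS,
    N_SCG_MARKERS,
)

NUCS = np.array(list("ACGT"))


@dataclass
class TruthRecord:
    """Planted ground truth accompanying one synthetic artifact."""

    foreign_contigs: list[str] = field(default_factory=list)
    viral_contigs: list[str] = field(default_factory=list)
    dominant_class: str | None = None
    completeness: float | None = None       # percent on the 43-marker grid
    contamination: float | None = None      # percent on the 43-marker grid
    ptr: float | None = None                # planted ori:ter density ratio
    rhodopsin_class: str | None = None      # ion_pump | heliorhodopsin | rejected
    clusters: list[list[str]] = field(default_factory=list)
    group_medians: dict[str, dict[str, float]] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Bins with planted foreign and viral contigs
# ---------------------------------------------------------------------------

def make_bin(seed: int,
             n_contigs: int = 10,
             genes_per_contig: int = 10,
             dominant_class: str = "Paceibacteria",
             foreign_frac: float = 0.0,
             viral_frac: float = 0.0,
             foreign_class: str = "Gammaproteobacteria",
             bin_id: str | None = None) -> tuple[Bin, TruthRecord]:
    """Build a multi-contig bin with planted foreign-class and viral contigs.

    Clean contigs carry 80% dominant-class genes; foreign contigs carry only
    10% (below the 30% vote threshold); viral contigs carry 50% virus-flagged
    genes (above the 25% viral threshold).  ``round(frac * n_contigs)``
    contigs of each kind are planted, disjointly.
    """
    if n_contigs < 1:
        raise PipelineError("n_contigs must be >= 1")
    if not (0 <= foreign_frac <= 1 and 0 <= viral_frac <= 1):
        raise PipelineError("fractions must lie in [0, 1]")
    n_foreign = round(foreign_frac * n_contigs)
    n_viral = round(viral_frac * n_contigs)
    if n_foreign + n_viral > n_contigs:
        raise PipelineError("foreign_frac + viral_frac exceed the bin")

    rng = np.random.default_rng(seed)
    bin_id = bin_id or f"bin{seed:05d}"
    contigs: dict[str, Contig] = {}
    genes: dict[str, Gene] = {}
    truth = TruthRecord(dominant_class=dominant_class)

    gene_len, gap = 900, 100
    for ci in range(n_contigs):
        cid = f"{bin_id}_c{ci:03d}"
        length = genes_per_contig * (gene_len + gap) + gap
        seq = "".join(rng.choice(NUCS, size=length))
        contig = Contig(id=cid, length=length, sequence=seq)
        is_foreign = ci < n_foreign
        is_viral = n_foreign <= ci < n_foreign + n_viral
        if is_foreign:
            truth.foreign_contigs.append(cid)
        if is_viral:
            truth.viral_contigs.append(cid)
        dom_share = 0.10 if is_foreign else 0.80
        n_dom = round(dom_share * genes_per_contig)
        n_viral_genes = round(0.50 * genes_per_contig) if is_viral else 0
        viral_idx = set(
            rng.choice(genes_per_contig, size=n_viral_genes, replace=False))
        for gi in range(genes_per_contig):
            gid = f"{cid}_g{gi:03d}"
            start = gap + gi * (gene_len + gap) + 1
            gene = Gene(
                id=gid, contig_id=cid, start=start, end=start + gene_len - 1,
                strand="+" if rng.random() < 0.5 else "-",
                protein_length=gene_len // 3,
                best_hit_class=(dominant_class if gi < n_dom else foreign_class),
                viral=gi in viral_idx,
            )
            genes[gid] = gene
            contig.gene_ids.append(gid)
        contigs[cid] = contig
    return Bin(id=bin_id, contigs=contigs, genes=genes), truth


# ---------------------------------------------------------------------------
# Single-copy marker profiles
# ---------------------------------------------------------------------------

def make_scg_profile(seed: int,
                     completeness_pct: float,
                     contamination_pct: float,
                     markers: Sequence[str] = DEFAULT_SCG_MARKERS,
                     ) -> tuple[dict[str, int], TruthRecord]:
    """Plant a 43-marker copy-count profile at given completeness and
    contamination, rounded to the nearest representable grid point
    (multiples of 100/43 percent)."""
    if not 0 <= completeness_pct <= 100:
        raise PipelineError("completeness must lie in [0, 100]")
    if contamination_pct < 0:
        raise PipelineError("contamination must be >= 0")
    n = len(markers)
    n_present = round(completeness_pct / 100 * n)
    n_dup = round(contamination_pct / 100 * n)
    if n_dup > n_present:
        raise PipelineError(
            "contamination requires more duplicated markers than are present")
    rng = np.random.default_rng(seed)
    present = rng.choice(n, size=n_present, replace=False)
    dup = rng.choice(present, size=n_dup, replace=False) if n_dup else []
    profile = {m: 0 for m in markers}
    for i in present:
        profile[markers[i]] = 1
    for i in dup:
        profile[markers[i]] = 2
    truth = TruthRecord(completeness=100.0 * n_present / n,
                        contamination=100.0 * n_dup / n)
    return profile, truth


# ---------------------------------------------------------------------------
# Read simulation with an ori->ter coverage gradient
# ---------------------------------------------------------------------------

def simulate_reads(seed: int,
                   genome: str,
                   depth: float,
                   read_len: int = 150,
                   ptr: float = 1.0,
                   error_rate: float = 0.0,
                   ) -> tuple[list[tuple[str, str]], TruthRecord]:
    """Draw reads whose start density follows an exponential ori->ter
    gradient with density ratio ``ptr`` (``ptr=1`` is uniform coverage).

    The origin sits at position 0 and the terminus at the end of the genome.
    Expected total bases equal ``depth * len(genome)``.  Returns
    ``(read_id, sequence)`` pairs; use :func:`write_fastq` to serialize.
    """
    L = len(genome)
    if read_len > L:
        raise PipelineError(f"read_len {read_len} exceeds genome length {L}")
    if ptr < 1:
        raise PipelineError("ptr must be >= 1")
    if depth <= 0:
        raise PipelineError("depth must be > 0")
    rng = np.random.default_rng(seed)
    n_reads = int(round(depth * L / read_len))
    span = L - read_len + 1
    u = rng.random(n_reads)
    if ptr == 1.0:
        starts = (u * span).astype(np.int64)
    else:
        lam = math.log(ptr) / span
        starts = (-np.log1p(-u * (1.0 - 1.0 / ptr)) / lam).astype(np.int64)
        starts = np.minimum(starts, span - 1)
    strands = rng.random(n_reads) < 0.5
    comp = str.maketrans("ACGT", "TGCA")
    reads: list[tuple[str, str]] = []
    for i, (s, rc) in enumerate(zip(starts, strands)):
        seq = genome[s:s + read_len]
        if error_rate > 0:
            arr = list(seq)
            for j in np.flatnonzero(rng.random(read_len) < error_rate):
                arr[j] = rng.choice(NUCS[NUCS != arr[j]])
            seq = "".join(arr)
        if rc:
            seq = seq.translate(comp)[::-1]
        reads.append((f"read{i:07d}", seq))
    return reads, TruthRecord(ptr=float(ptr))


def write_fastq(reads: Sequence[tuple[str, str]], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for rid, seq in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")
    return path


def read_fastq(path: str | Path) -> list[tuple[str, str]]:
    reads = []
    with open(path) as fh:
        while True:
            header = fh.readline()
            if not header:
                break
            seq = fh.readline().strip()
            fh.readline()
            fh.readline()
            reads.append((header[1:].strip().split()[0], seq))
    return reads


def make_genome(seed: int, length: int = 200_000) -> str:
    """A random nucleotide genome for read-simulation tests."""
    rng = np.random.default_rng(seed)
    return "".join(rng.choice(NUCS, size=length))


# ---------------------------------------------------------------------------
# Seven-transmembrane-helix proteins
# ---------------------------------------------------------------------------

# Helices: strongly hydrophobic (Kyte-Doolittle I 4.5, V 4.2, L 3.8, F 2.8).
# Loops: strongly hydrophilic (N/Q/E, all -3.5), long enough (18) that a
# 19-residue hydropathy window can never bridge two helices even for an
# all-isoleucine helix edge.  R (-4.5) carries the positive-inside signal;
# S, D and K are reserved for the retinal-binding motif.
_HELIX_RES = "IVLF"
_LOOP_RES = "NQE"
_HELIX_LEN = 21
_MOTIF_HELIX_LEN = 23
_LOOP_LEN = 18
_BASIC_PER_LOOP = 3


def make_rhodopsin_protein(seed: int,
                           kind: str,
                           n_helices: int | None = None,
                           motif: str | None = None,
                           ) -> tuple[str, TruthRecord]:
    """Build a membrane protein with a planted topology and TM7 motif.

    kind='pump'  -> 7 helices, extracellular N-terminus (positive charges on
                    the even-numbered cytoplasmic loops), DxxxK in helix 7.
    kind='helio' -> 7 helices, cytoplasmic N-terminus (inverted charge
                    placement), SxxxK in helix 7.
    kind='decoy' -> same architecture but ``n_helices`` helices (default 6)
                    and no retinal-binding motif.

    ``motif`` optionally fixes the exact 5-residue retinal-binding motif
    (e.g. the observed heliorhodopsin motifs SLVAK, SLIAK, SFVAK); by
    default the three interior residues are random hydrophobics.
    """
    if kind not in ("pump", "helio", "decoy"):
        raise PipelineError(f"unknown kind {kind!r}")
    if n_helices is None:
        n_helices = 7 if kind in ("pump", "helio") else 6
    if n_helices < 0:
        raise PipelineError("n_helices must be >= 0")
    if kind in ("pump", "helio"):
        if n_helices != 7:
            raise PipelineError(f"{kind} proteins require 7 helices")
    elif n_helices == 7:
        raise PipelineError("a 7-helix decoy would not be rejected; use != 7")
    if motif is not None:
        if kind == "decoy":
            raise PipelineError("decoy proteins carry no motif")
        expected_lead = "D" if kind == "pump" else "S"
        if (len(motif) != 5 or motif[0] != expected_lead or motif[4] != "K"):
            raise PipelineError(
                f"motif must be {expected_lead}xxxK, got {motif!r}")
    rng = np.random.default_rng(seed)

    # Loop parity: loop i precedes helix i+1 (loop 0 is the N-terminal tail,
    # loop n_helices the C-terminal tail).  With the N-terminus outside, the
    # odd-numbered loops are cytoplasmic; with it inside, the even ones are.
    n_in = kind == "helio"          # cytoplasmic N-terminus
    cytoplasmic_parity = 0 if n_in else 1

    def loop() -> list[str]:
        return list(rng.choice(list(_LOOP_RES), size=_LOOP_LEN))

    def helix(length: int) -> list[str]:
        return list(rng.choice(list(_HELIX_RES), size=length))

    parts: list[str] = []
    for i in range(n_helices):
        seg = loop()
        if i % 2 == cytoplasmic_parity:
            for p in rng.choice(_LOOP_LEN, size=_BASIC_PER_LOOP, replace=False):
                seg[p] = "R"
        parts.extend(seg)
        is_last = i == n_helices - 1
        h = helix(_MOTIF_HELIX_LEN if (is_last and kind != "decoy") else _HELIX_LEN)
        if is_last and kind != "decoy":
            # plant D/S-x-x-x-K in the middle of the final helix
            pos = _MOTIF_HELIX_LEN // 2 - 2
            planted = motif or (
                ("D" if kind == "pump" else "S") + "".join(h[pos + 1:pos + 4])
                + "K")
            h[pos:pos + 5] = list(planted)
        parts.extend(h)
    tail = loop()
    if n_helices % 2 == cytoplasmic_parity:
        for p in rng.choice(_LOOP_LEN, size=_BASIC_PER_LOOP, replace=False):
            tail[p] = "R"
    parts.extend(tail)
    seq = "".join(parts)
    truth = TruthRecord(rhodopsin_class={
        "pump": "ion_pump", "helio": "heliorhodopsin", "decoy": "rejected",
    }[kind])
    return seq, truth


# ---------------------------------------------------------------------------
# ANI matrices with planted clusters
# ---------------------------------------------------------------------------

def make_ani_matrix(seed: int,
                    cluster_sizes: Sequence[int],
                    intra_ani_range: tuple[float, float] = (99.2, 99.9),
                    inter_ani_range: tuple[float, float] = (90.0, 98.0),
                    ) -> tuple[pd.DataFrame, TruthRecord]:
    """A symmetric pairwise-ANI matrix whose single-linkage clusters at any
    threshold between the two ranges are exactly ``cluster_sizes``."""
    if min(cluster_sizes, default=0) < 1:
        raise PipelineError("cluster sizes must be >= 1")
    ilo, ihi = intra_ani_range
    olo, ohi = inter_ani_range
    if not (olo <= ohi < ilo <= ihi):
        raise PipelineError(
            "intra range must lie entirely above the inter range "
            f"(got intra {intra_ani_range}, inter {inter_ani_range})")
    rng = np.random.default_rng(seed)
    labels: list[str] = []
    membership: list[int] = []
    for k, size in enumerate(cluster_sizes):
        for j in range(size):
            labels.append(f"g{k:03d}_{j:03d}")
            membership.append(k)
    n = len(labels)
    mat = np.empty((n, n))
    for a in range(n):
        mat[a, a] = 100.0
        for b in range(a + 1, n):
            lo, hi = (ilo, ihi) if membership[a] == membership[b] else (olo, ohi)
            v = rng.uniform(lo, hi)
            mat[a, b] = mat[b, a] = v
    truth = TruthRecord(clusters=[
        [labels[i] for i in range(n) if membership[i] == k]
        for k in range(len(cluster_sizes))])
    return pd.DataFrame(mat, index=labels, columns=labels), truth


# ---------------------------------------------------------------------------
# Lifestyle trait tables
# ---------------------------------------------------------------------------

#: Emulated study conditions: CPR genomes are small, AT-rich-ish and densely
#: coded (median coding density 89.47%, GC 42.04%, estimated size ~1.02 Mbp);
#: free-living bacteria carry larger, GC-richer genomes; obligate symbionts
#: sit between on size with lower GC and coding density.
DEFAULT_GROUP_PARAMS: dict[str, dict[str, tuple[float, float]]] = {
    "CPR": {
        "assembly_length": (630_000, 120_000),
        "estimated_genome_size": (1_020_000, 200_000),
        "gc": (42.04, 5.0),
        "coding_density": (89.47, 2.5),
        "n_genes": (1100, 200),
        "completeness": (62.0, 10.0),
    },
    "free_living": {
        "assembly_length": (3_500_000, 700_000),
        "estimated_genome_size": (3_700_000, 700_000),
        "gc": (50.0, 8.0),
        "coding_density": (88.0, 2.0),
        "n_genes": (3400, 600),
        "completeness": (95.0, 3.0),
    },
    "symbiont": {
        "assembly_length": (1_300_000, 400_000),
        "estimated_genome_size": (1_400_000, 400_000),
        "gc": (35.0, 6.0),
        "coding_density": (85.0, 3.0),
        "n_genes": (1300, 350),
        "completeness": (93.0, 4.0),
    },
}


def make_trait_table(seed: int,
                     n_per_group: int,
                     group_params: Mapping[str, Mapping[str, tuple[float, float]]]
                     = DEFAULT_GROUP_PARAMS,
                     ) -> tuple[pd.DataFrame, TruthRecord]:
    """Sample per-genome trait rows for each lifestyle category from normal
    distributions located at the category medians."""
    if n_per_group < 1:
        raise PipelineError("n_per_group must be >= 1")
    rng = np.random.default_rng(seed)
    rows = []
    truth = TruthRecord()
    for cat, params in group_params.items():
        truth.group_medians[cat] = {t: loc for t, (loc, _) in params.items()}
        for i in range(n_per_group):
            row = {"genome_id": f"{cat}_{i:04d}", "category": cat}
            for trait, (loc, scale) in params.items():
                v = float(rng.normal(loc, scale)) if scale > 0 else float(loc)
                if trait == "coding_density":
                    v = min(max(v, 1e-6), 100.0)
                elif trait == "gc":
                    v = min(max(v, 0.0), 100.0)
                elif trait in ("assembly_length", "estimated_genome_size",
                               "n_genes"):
                    v = max(round(v), 1)
                row[trait] = v
            rows.append(row)
    return pd.DataFrame(rows), truth
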