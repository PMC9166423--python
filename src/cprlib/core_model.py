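"""Domain types, configuration, and on-disk formats for the CPR MAG pipeline.

The pipeline's central unit is the :class:`Bin`: a set of assembled contigs
with predicted genes and their annotations.  Everything downstream (taxonomy
vote decontamination, single-copy-gene quality estimation, dereplication,
read recruitment, rhodopsin screening, trait statistics) consumes either a
``Bin`` or one of the flat tables defined here.

Conventions
-----------
* Gene and interval coordinates are 1-based inclusive (GFF convention) in
  every on-disk table and in-memory type; BED input is converted once at the
  boundary by the reader.
* Taxonomy class labels are opaque strings; no taxonomy database is resolved.
* All randomness flows from ``PipelineConfig.rng_seed``; stages derive
  sub-seeds from it so each stage is independently reproducible.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


# ---------------------------------------------------------------------------
# Errors
# ---------------------------------------------------------------------------

class PipelineError(Exception):
    """Base class for all cprlib errors."""


class ParseError(PipelineError):
    """An on-disk file could not be parsed; message names record/line."""


class ValidationError(PipelineError):
    """An in-memory object violates a domain invariant."""


class ConfigError(PipelineError):
    """A configuration value is out of range or inconsistent."""


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

#: Bacterial single-copy marker genes used for completeness/contamination
#: estimation: 43 ribosomal proteins, polymerase subunits and universal
#: translation/replication factors expected exactly once per genome.
DEFAULT_SCG_MARKERS: tuple[str, ...] = (
    "Ribosomal_L1", "Ribosomal_L2", "Ribosomal_L3", "Ribosomal_L4",
    "Ribosomal_L5", "Ribosomal_L6", "Ribosomal_L9", "Ribosomal_L10",
    "Ribosomal_L11", "Ribosomal_L13", "Ribosomal_L14", "Ribosomal_L15",
    "Ribosomal_L16", "Ribosomal_L17", "Ribosomal_L18", "Ribosomal_L19",
    "Ribosomal_L20", "Ribosomal_L21", "Ribosomal_L22", "Ribosomal_L23",
    "Ribosomal_L24", "Ribosomal_L27", "Ribosomal_L29", "Ribosomal_L30",
    "Ribosomal_S2", "Ribosomal_S3", "Ribosomal_S4", "Ribosomal_S5",
    "Ribosomal_S6", "Ribosomal_S8", "Ribosomal_S9", "Ribosomal_S10",
    "Ribosomal_S11", "Ribosomal_S12", "Ribosomal_S13", "Ribosomal_S15",
    "Ribosomal_S16", "Ribosomal_S17", "Ribosomal_S19", "Ribosomal_S20",
    "RNA_pol_A", "RNA_pol_B", "IF-2",
)

N_SCG_MARKERS = 43


@dataclass
class PipelineConfig:
    """All tunable thresholds of the pipeline, defaulting to the study values.

    Boundary semantics are strict exactly as printed in the source study:
    a contig is removed when its dominant-class gene fraction is *below* 0.30,
    a contig is removed when its viral gene fraction *exceeds* 0.25, a bin
    passes quality control when completeness is *above* 40% and contamination
    *below* 5%, and genomes are dereplicated at ANI strictly *above* 99%.
    """

    min_contig_len: int = 3000
    dominant_class_min_frac: float = 0.30
    viral_max_frac: float = 0.25
    scg_marker_ids: tuple[str, ...] = DEFAULT_SCG_MARKERS
    completeness_min: float = 40.0          # percent, strict >
    contamination_max: float = 5.0          # percent, strict <
    strain_het_identity_min: float = 90.0   # percent aa identity for SH calls
    ani_threshold: float = 99.0             # percent, strict >
    reads_subsample: int = 20_000_000
    rhodopsin_min_len: int = 150            # residues, strict >
    rhodopsin_max_p: float = 1e-2           # strict <
    required_helices: int = 7
    hit_evalue_max: float = 1e-3
    hit_min_similarity: float = 10.0        # percent identity
    hit_min_coverage: float = 10.0          # percent query coverage
    hit_min_bitscore: float = 50.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("dominant_class_min_frac", "viral_max_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name}={v} must lie in [0, 1]")
        for name in ("completeness_min", "contamination_max", "ani_threshold",
                     "hit_min_similarity", "hit_min_coverage",
                     "strain_het_identity_min"):
            v = getattr(self, name)
            if not 0.0 <= v <= 100.0:
                raise ConfigError(f"{name}={v} must lie in [0, 100]")
        markers = tuple(self.scg_marker_ids)
        if len(markers) != N_SCG_MARKERS or len(set(markers)) != N_SCG_MARKERS:
            raise ConfigError(
                f"scg_marker_ids must contain exactly {N_SCG_MARKERS} distinct "
                f"entries, got {len(markers)} ({len(set(markers))} distinct)")
        self.scg_marker_ids = markers

    def sub_seed(self, stage: str) -> int:
        """Deterministic per-stage seed derived from ``rng_seed``.

        Keeps stages independently reproducible: re-running one stage does
        not perturb the random stream of another.
        """
        h = 2166136261
        for ch in stage:
            h = ((h ^ ord(ch)) * 16777619) & 0xFFFFFFFF
        return (self.rng_seed * 1_000_003 + h) % (2**31 - 1)

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        """Read a flat ``key = value`` text config; unknown keys are errors."""
        fields = {f.name: f for f in dataclasses.fields(cls)}
        kwargs: dict = {}
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ParseError(f"{path}:{lineno}: expected 'key = value'")
            key, _, value = line.partition("=")
            key, value = key.strip(), value.strip()
            if key not in fields:
                raise ConfigError(f"{path}:{lineno}: unknown config key {key!r}")
            if key == "scg_marker_ids":
                kwargs[key] = tuple(v.strip() for v in value.split(","))
            elif fields[key].type in ("int", int):
                kwargs[key] = int(value)
            else:
                kwargs[key] = float(value)
        return cls(**kwargs)

    def to_file(self, path: str | Path) -> Path:
        path = Path(path)
        lines = []
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if f.name == "scg_marker_ids":
                v = ",".join(v)
            lines.append(f"{f.name} = {v}")
        path.write_text("\n".join(lines) + "\n")
        return path


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class Contig:
    id: str
    length: int
    sequence: str | None = None
    gene_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValidationError(f"contig {self.id}: length must be >= 1")
        if self.sequence is not None and len(self.sequence) != self.length:
            raise ValidationError(
                f"contig {self.id}: sequence length {len(self.sequence)} "
                f"!= declared length {self.length}")


@dataclass
class Gene:
    id: str
    contig_id: str
    start: int              # 1-based inclusive
    end: int                # 1-based inclusive
    strand: str = "+"
    protein_length: int | None = None
    best_hit_class: str | None = None
    viral: bool = False

    def __post_init__(self) -> None:
        if not 1 <= self.start <= self.end:
            raise ValidationError(
                f"gene {self.id}: invalid coordinates {self.start}..{self.end}")
        if self.strand not in ("+", "-"):
            raise ValidationError(f"gene {self.id}: strand must be + or -")


@dataclass
class Bin:
    """A set of contigs with their genes — one metagenome-assembled genome."""

    id: str
    contigs: dict[str, Contig] = field(default_factory=dict)
    genes: dict[str, Gene] = field(default_factory=dict)
    lake: str = ""
    metagenome: str = ""

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for gene in self.genes.values():
            contig = self.contigs.get(gene.contig_id)
            if contig is None:
                raise ValidationError(
                    f"gene {gene.id}: unknown contig {gene.contig_id!r}")
            if gene.end > contig.length:
                raise ValidationError(
                    f"gene {gene.id}: end {gene.end} exceeds contig "
                    f"{contig.id} length {contig.length}")
        for contig in self.contigs.values():
            for gid in contig.gene_ids:
                if gid not in self.genes:
                    raise ValidationError(
                        f"contig {contig.id}: lists unknown gene {gid!r}")

    def genes_on(self, contig_id: str) -> list[Gene]:
        return [self.genes[g] for g in self.contigs[contig_id].gene_ids]

    @property
    def assembly_length(self) -> int:
        return sum(c.length for c in self.contigs.values())


@dataclass(frozen=True)
class Hit:
    """One row of a tabular alignment-hit table (BLAST outfmt-6 style plus a
    subject taxonomy class column)."""

    query: str
    subject: str
    evalue: float
    similarity: float       # percent identity
    coverage: float         # percent query coverage
    bitscore: float
    subject_class: str


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

GENE_TABLE_COLUMNS = ("gene_id", "contig_id", "start", "end", "strand")


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an ordered id -> sequence mapping."""
    seqs: dict[str, str] = {}
    try:
        for rec in SeqIO.parse(str(path), "fasta"):
            if not rec.id:
                raise ParseError(f"{path}: FASTA record without an identifier")
            if rec.id in seqs:
                raise ParseError(f"{path}: duplicate FASTA record {rec.id!r}")
            seqs[rec.id] = str(rec.seq).upper()
    except ValueError as exc:  # Biopython malformed-record errors
        raise ParseError(f"{path}: {exc}") from exc
    return seqs


def write_fasta(seqs: Mapping[str, str], path: str | Path) -> Path:
    records = [SeqRecord(Seq(s), id=name, description="")
               for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")
    return Path(path)


def read_gene_table(path: str | Path) -> list[Gene]:
    """Read a GFF-like tab-separated gene coordinate table.

    Required columns: gene_id, contig_id, start, end, strand (1-based
    inclusive coordinates).  Optional columns: protein_length, viral (0/1).
    """
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise ParseError(f"{path}: empty gene table (header required)")
    header = lines[0].rstrip("\n").split("\t")
    missing = [c for c in GENE_TABLE_COLUMNS if c not in header]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    idx = {c: header.index(c) for c in header}
    genes: list[Gene] = []
    for lineno, line in enumerate(lines[1:], 2):
        if not line.strip():
            continue
        parts = line.split("\t")
        try:
            gene = Gene(
                id=parts[idx["gene_id"]],
                contig_id=parts[idx["contig_id"]],
                start=int(parts[idx["start"]]),
                end=int(parts[idx["end"]]),
                strand=parts[idx["strand"]],
                protein_length=(int(parts[idx["protein_length"]])
                                if "protein_length" in idx
                                and parts[idx["protein_length"]] else None),
                viral=(parts[idx["viral"]] in ("1", "true", "True")
                       if "viral" in idx else False),
            )
        except (ValueError, IndexError) as exc:
            raise ParseError(f"{path}:{lineno}: {exc}") from exc
        genes.append(gene)
    return genes


def write_gene_table(genes: Iterable[Gene], path: str | Path) -> Path:
    path = Path(path)
    cols = GENE_TABLE_COLUMNS + ("protein_length", "viral")
    rows = ["\t".join(cols)]
    for g in genes:
        rows.append("\t".join([
            g.id, g.contig_id, str(g.start), str(g.end), g.strand,
            "" if g.protein_length is None else str(g.protein_length),
            "1" if g.viral else "0",
        ]))
    path.write_text("\n".join(rows) + "\n")
    return path


def read_bin(contig_fasta: str | Path, gene_table: str | Path,
             bin_id: str | None = None) -> Bin:
    """Assemble a :class:`Bin` from a contig FASTA and a gene table.

    Genes placed on contigs absent from the FASTA, or whose coordinates fall
    outside the contig, raise :class:`ValidationError` naming the gene.
    """
    seqs = read_fasta(contig_fasta)
    contigs = {cid: Contig(id=cid, length=len(s), sequence=s)
               for cid, s in seqs.items()}
    genes = read_gene_table(gene_table)
    gene_map: dict[str, Gene] = {}
    for gene in genes:
        if gene.contig_id not in contigs:
            raise ValidationError(
                f"gene {gene.id}: unknown contig {gene.contig_id!r}")
        if gene.id in gene_map:
            raise ValidationError(f"duplicate gene id {gene.id!r}")
        gene_map[gene.id] = gene
        contigs[gene.contig_id].gene_ids.append(gene.id)
    return Bin(id=bin_id or Path(contig_fasta).stem,
               contigs=contigs, genes=gene_map)


def read_hit_table(path: str | Path) -> dict[str, list[Hit]]:
    """Read a tab-separated alignment-hit table grouped per query gene.

    Columns: query, subject, evalue, similarity, coverage, bitscore,
    subject_class.  Extra columns are ignored (the format is a documented
    superset of BLAST outfmt 6).  Original hit order per query is preserved.
    """
    hits: dict[str, list[Hit]] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 7:
            raise ParseError(f"{path}:{lineno}: expected >= 7 columns, "
                             f"got {len(parts)}")
        try:
            hit = Hit(query=parts[0], subject=parts[1],
                      evalue=float(parts[2]), similarity=float(parts[3]),
                      coverage=float(parts[4]), bitscore=float(parts[5]),
                      subject_class=parts[6])
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: non-numeric field: {exc}")
        if not math.isfinite(hit.bitscore):
            raise ParseError(f"{path}:{lineno}: non-finite bitscore")
        hits.setdefault(hit.query, []).append(hit)
    return hits


def write_hit_table(hits: Mapping[str, Sequence[Hit]], path: str | Path) -> Path:
    path = Path(path)
    rows = []
    for query in hits:
        for h in hits[query]:
            rows.append("\t".join([
                h.query, h.subject, repr(h.evalue), repr(h.similarity),
                repr(h.coverage), repr(h.bitscore), h.subject_class]))
    path.write_text("\n".join(rows) + ("\n" if rows else ""))
    return path


def read_bed(path: str | Path) -> dict[str, list[tuple[int, int]]]:
    """Read a BED file (0-based half-open) into 1-based inclusive intervals
    per contig — the single coordinate conversion boundary."""
    out: dict[str, list[tuple[int, int]]] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise ParseError(f"{path}:{lineno}: BED needs >= 3 columns")
        try:
            start0, end0 = int(parts[1]), int(parts[2])
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: {exc}") from exc
        if end0 <= start0:
            raise ParseError(f"{path}:{lineno}: empty/inverted interval")
        out.setdefault(parts[0], []).append((start0 + 1, end0))
    return out


# ---------------------------------------------------------------------------
# Generic flat-row TSV report IO
# ---------------------------------------------------------------------------

def write_report(objects: Sequence, path: str | Path) -> Path:
    """Write dataclass instances (or mappings) as a TSV with a header.

    Column order is the dataclass field order (or insertion order for
    mappings), so output is deterministic and round-trips through
    :func:`read_report`.
    """
    path = Path(path)
    if not objects:
        path.write_text("")
        return path
    first = objects[0]
    if dataclasses.is_dataclass(first):
        cols = [f.name for f in dataclasses.fields(first)]
        rows = [[getattr(o, c) for c in cols] for o in objects]
    elif isinstance(first, Mapping):
        cols = list(first.keys())
        rows = [[o[c] for c in cols] for o in objects]
    else:
        raise ValidationError(
            f"cannot serialize objects of type {type(first).__name__}")
    lines = ["\t".join(cols)]
    for row in rows:
        lines.append("\t".join(_fmt_cell(v) for v in row))
    path.write_text("\n".join(lines) + "\n")
    return path


def _fmt_cell(v) -> str:
    if v is None:
        return "NA"
    if isinstance(v, bool):
        return "1" if v else "0"
    if isinstance(v, float):
        return repr(v)
    return str(v)


def read_report(path: str | Path) -> list[dict[str, str]]:
    """Read a TSV written by :func:`write_report` back into row dicts.

    Values come back as strings ('NA' for missing); callers coerce types.
    """
    text = Path(path).read_text()
    if not text.strip():
        return []
    lines = text.splitlines()
    cols = lines[0].split("\t")
    out = []
    for lineno, line in enumerate(lines[1:], 2):
        parts = line.split("\t")
        if len(parts) != len(cols):
            raise ParseError(f"{path}:{lineno}: expected {len(cols)} columns")
        out.append(dict(zip(cols, parts)))
    return out
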