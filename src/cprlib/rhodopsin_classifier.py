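"""Rhodopsin vs. heliorhodopsin classification from sequence alone.

Microbial Type I rhodopsins and heliorhodopsins are both seven-transmembrane
-helix retinal-binding proteins, but they sit in the membrane with opposite
orientations: Type I ion pumps expose the N-terminus extracellularly, while
heliorhodopsins have a cytoplasmic N-terminus.  The retinal-binding lysine
in transmembrane helix 7 is preceded four residues upstream by an aspartate
in Type I rhodopsins (DxxxK) and by a serine in heliorhodopsins (SxxxK; the
observed motifs SLVAK, SLIAK, SFVAK all match).

The classifier works in three stages:

1. **Candidate filter** — profile-search hits are kept when longer than 150
   residues with P < 1e-2 (both strict).
2. **Topology** — transmembrane helices are predicted as maximal runs where
   a 19-residue Kyte-Doolittle hydropathy window averages >= 1.6 (runs
   separated by fewer than 5 residues are merged), and orientation follows
   the positive-inside rule: the alternating loop side carrying more K+R
   residues is cytoplasmic (ambiguous when the two sides differ by fewer
   than 2 basic residues).
3. **Call** — proteins without exactly 7 helices are rejected; with 7, the
   TM7 span (plus 3 residues of slack at each edge) is scanned for DxxxK
   (ion pump, expects N-out) then SxxxK (heliorhodopsin, expects N-in).  A
   motif contradicting the predicted orientation yields ``ambiguous``; no
   motif yields ``rhodopsin_like_unclassified``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core_model import PipelineConfig, PipelineError, ValidationError


#: Kyte-Doolittle hydropathy values.
KYTE_DOOLITTLE: dict[str, float] = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5, "Q": -3.5,
    "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5, "L": 3.8, "K": -3.9,
    "M": 1.9, "F": 2.8, "P": -1.6, "S": -0.8, "T": -0.7, "W": -0.9,
    "Y": -1.3, "V": 4.2,
}

HYDROPATHY_WINDOW = 19
HYDROPATHY_THRESHOLD = 1.6
HELIX_MERGE_GAP = 5
ORIENTATION_MARGIN = 2
MOTIF_EDGE_SLACK = 3

_DXXXK = re.compile(r"D.{3}K")
_SXXXK = re.compile(r"S.{3}K")


@dataclass
class ProteinTopology:
    helix_spans: list[tuple[int, int]]      # 0-based half-open residue spans
    orientation: str                        # N-in | N-out | ambiguous
    basic_side_a: int                       # K+R in loops 0, 2, 4, ...
    basic_side_b: int                       # K+R in loops 1, 3, 5, ...

    @property
    def n_helices(self) -> int:
        return len(self.helix_spans)


@dataclass
class RhodopsinCall:
    protein_id: str
    n_helices: int
    orientation: str
    tm7_motif: str                          # none | DxxxK | SxxxK
    call: str   # ion_pump | heliorhodopsin | rhodopsin_like_unclassified
                # | rejected | ambiguous
    rejection_reason: str = ""


# ---------------------------------------------------------------------------
# Candidate filtering
# ---------------------------------------------------------------------------

def filter_candidates(records: Mapping[str, tuple[int, float]],
                      config: PipelineConfig) -> list[str]:
    """Keep proteins longer than 150 residues with P < 1e-2 (both strict)."""
    kept = []
    for pid, (length, p) in records.items():
        if length < 0:
            raise ValidationError(f"{pid}: negative protein length")
        if length > config.rhodopsin_min_len and p < config.rhodopsin_max_p:
            kept.append(pid)
    return kept


def rejection_for(length: int, p: float, config: PipelineConfig) -> str:
    if length <= config.rhodopsin_min_len:
        return "too_short"
    if p >= config.rhodopsin_max_p:
        return "p_value"
    return ""


# ---------------------------------------------------------------------------
# Topology prediction
# ---------------------------------------------------------------------------

def predict_topology(sequence: str,
                     window: int = HYDROPATHY_WINDOW,
                     threshold: float = HYDROPATHY_THRESHOLD,
                     merge_gap: int = HELIX_MERGE_GAP,
                     margin: int = ORIENTATION_MARGIN) -> ProteinTopology:
    """Hydropathy-based helix prediction plus positive-inside orientation."""
    bad = [i for i, aa in enumerate(sequence) if aa not in KYTE_DOOLITTLE]
    if bad:
        raise ValidationError(
            f"non-standard residues at positions {[i + 1 for i in bad[:5]]}")
    n = len(sequence)
    if n < window:
        return ProteinTopology([], "ambiguous", 0, 0)
    kd = np.array([KYTE_DOOLITTLE[aa] for aa in sequence])
    means = np.convolve(kd, np.ones(window) / window, mode="valid")
    covered = np.zeros(n, dtype=bool)
    for i in np.flatnonzero(means >= threshold):
        covered[i:i + window] = True

    spans: list[tuple[int, int]] = []
    i = 0
    while i < n:
        if covered[i]:
            j = i
            while j < n and covered[j]:
                j += 1
            if spans and i - spans[-1][1] < merge_gap:
                spans[-1] = (spans[-1][0], j)
            else:
                spans.append((i, j))
            i = j
        else:
            i += 1

    # Loop side parity: the loop before helix 1 (index 0) and every second
    # loop after belong to side A; the rest to side B.
    side_a = side_b = 0
    bounds = [0] + [b for span in spans for b in span] + [n]
    loops = [(bounds[2 * k], bounds[2 * k + 1]) for k in range(len(spans) + 1)]
    for k, (s, e) in enumerate(loops):
        basic = sum(1 for aa in sequence[s:e] if aa in "KR")
        if k % 2 == 0:
            side_a += basic
        else:
            side_b += basic
    diff = side_a - side_b
    if abs(diff) < margin:
        orientation = "ambiguous"
    elif diff > 0:
        orientation = "N-in"    # N-terminal side is the basic (cytoplasmic) one
    else:
        orientation = "N-out"
    return ProteinTopology(spans, orientation, side_a, side_b)


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------

def classify(protein_id: str,
             sequence: str,
             topology: ProteinTopology,
             config: PipelineConfig,
             edge_slack: int = MOTIF_EDGE_SLACK) -> RhodopsinCall:
    """Final call from helix count, orientation and the TM7 motif."""
    if topology.n_helices != config.required_helices:
        return RhodopsinCall(protein_id, topology.n_helices,
                             topology.orientation, "none",
                             "rejected", "helix_count")
    s, e = topology.helix_spans[-1]
    region = sequence[max(0, s - edge_slack):min(len(sequence), e + edge_slack)]
    orientation = topology.orientation
    if _DXXXK.search(region):
        motif = "DxxxK"
        call = "ion_pump" if orientation in ("N-out", "ambiguous") else "ambiguous"
    elif _SXXXK.search(region):
        motif = "SxxxK"
        call = ("heliorhodopsin" if orientation in ("N-in", "ambiguous")
                else "ambiguous")
    else:
        motif = "none"
        call = "rhodopsin_like_unclassified"
    return RhodopsinCall(protein_id, topology.n_helices, orientation,
                         motif, call)


def classify_protein(protein_id: str,
                     sequence: str,
                     config: PipelineConfig,
                     length: int | None = None,
                     p_value: float = 0.0) -> RhodopsinCall:
    """Filter, topology and call in one step for a single protein."""
    length = len(sequence) if length is None else length
    reason = rejection_for(length, p_value, config)
    if reason:
        return RhodopsinCall(protein_id, 0, "ambiguous", "none",
                             "rejected", reason)
    return classify(protein_id, sequence, predict_topology(sequence), config)


# ---------------------------------------------------------------------------
# Per-class summary
# ---------------------------------------------------------------------------

def summarize_calls(calls: Sequence[RhodopsinCall],
                    protein_to_genome: Mapping[str, str],
                    genome_to_class: Mapping[str, str]) -> pd.DataFrame:
    """Tabulate ion pumps and heliorhodopsins per taxonomy class."""
    counts: dict[str, dict[str, int]] = {}
    for call in calls:
        if call.protein_id not in protein_to_genome:
            raise PipelineError(f"protein {call.protein_id} has no genome")
        genome = protein_to_genome[call.protein_id]
        if genome not in genome_to_class:
            raise PipelineError(f"genome {genome} has no taxonomy class")
        cls = genome_to_class[genome]
        row = counts.setdefault(cls, {"ion_pump": 0, "heliorhodopsin": 0})
        if call.call in row:
            row[call.call] += 1
    return pd.DataFrame(
        [{"class": c, "n_ion_pump": v["ion_pump"],
          "n_heliorhodopsin": v["heliorhodopsin"]}
         for c, v in sorted(counts.items())],
        columns=["class", "n_ion_pump", "n_heliorhodopsin"])
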