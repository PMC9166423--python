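"""ANI-based genome dereplication with scored representative selection.

Genomes are clustered by single-linkage over the graph whose edges connect
pairs with average nucleotide identity strictly above the threshold (99% by
default).  Within each cluster, one representative is chosen by the highest
composite score combining completeness, contamination, strain heterogeneity,
assembly contiguity (log10 N50) and centrality (mean ANI to the other
cluster members):

    score = completeness - 5*contamination
            + contamination * strain_heterogeneity / 100
            + 0.5*log10(N50) + 0*log10(size) + centrality

These are the default weights of the dRep scoring scheme.  Single-linkage is
the literal reading of "dereplicate at ANI > 99%"; no MASH pre-clustering
stage is reproduced.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .core_model import PipelineError, ValidationError


#: dRep default score weights: completeness, contamination, strain
#: heterogeneity interaction, log10 N50, log10 size, centrality.
DEFAULT_SCORE_WEIGHTS = (1.0, 5.0, 1.0, 0.5, 0.0, 1.0)


@dataclass
class GenomeStats:
    genome_id: str
    completeness: float
    contamination: float
    strain_heterogeneity: float
    n50: int
    size: int

    def __post_init__(self) -> None:
        if self.n50 > self.size:
            raise ValidationError(
                f"{self.genome_id}: N50 {self.n50} exceeds size {self.size}")
        for name in ("completeness", "contamination", "strain_heterogeneity"):
            v = getattr(self, name)
            if v < 0 or (name != "contamination" and v > 100):
                raise ValidationError(f"{self.genome_id}: invalid {name}={v}")


@dataclass
class Cluster:
    members: list[str]
    representative: str | None = None
    scores: dict[str, float] = field(default_factory=dict)
    centrality: dict[str, float] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Clustering
# ---------------------------------------------------------------------------

def read_ani_table(path) -> pd.DataFrame:
    """Read an ANI table as either a square matrix TSV (header row + index
    column) or a 3-column long form (query, reference, ani).  Pairs missing
    from a long-form table are treated as below any threshold (ANI 0)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[1] == 2 and not df.columns.equals(df.index):
        long = pd.read_csv(path, sep="\t", header=None if df.shape[0] else 0)
        long.columns = ["query", "reference", "ani"]
        genomes = sorted(set(long["query"]) | set(long["reference"]))
        mat = pd.DataFrame(0.0, index=genomes, columns=genomes)
        np.fill_diagonal(mat.values, 100.0)
        for _, row in long.iterrows():
            mat.loc[row["query"], row["reference"]] = float(row["ani"])
            mat.loc[row["reference"], row["query"]] = float(row["ani"])
        return mat
    return df


def cluster_by_ani(matrix: pd.DataFrame, threshold: float = 99.0,
                   symmetry_tol: float = 0.01) -> list[Cluster]:
    """Single-linkage connected components of the ANI > threshold graph.

    The partition covers all genomes; clusters are ordered by their first
    member's position in the input, members in input order.
    """
    if list(matrix.index) != list(matrix.columns):
        raise ValidationError("ANI matrix rows and columns must match")
    vals = matrix.to_numpy(dtype=float)
    if np.nanmax(np.abs(vals - vals.T)) > symmetry_tol:
        raise ValidationError(
            f"ANI matrix asymmetric beyond tolerance {symmetry_tol}")
    if np.nanmin(np.diag(vals)) < threshold:
        raise ValidationError("ANI matrix diagonal below threshold")
    adj = csr_matrix(np.nan_to_num(vals, nan=0.0) > threshold)
    n_comp, labels = connected_components(adj, directed=False)
    names = list(matrix.index)
    clusters: dict[int, list[str]] = {}
    for name, lab in zip(names, labels):
        clusters.setdefault(lab, []).append(name)
    ordered = sorted(clusters.values(), key=lambda ms: names.index(ms[0]))
    return [Cluster(members=ms) for ms in ordered]


# ---------------------------------------------------------------------------
# Scoring and representative selection
# ---------------------------------------------------------------------------

def score_genome(stats: GenomeStats, centrality: float,
                 weights: Sequence[float] = DEFAULT_SCORE_WEIGHTS) -> float:
    """Composite genome score (dRep default weighting)."""
    if stats.n50 <= 0:
        raise PipelineError(f"{stats.genome_id}: N50 must be > 0")
    w_comp, w_cont, w_sh, w_n50, w_size, w_cent = weights
    return (w_comp * stats.completeness
            - w_cont * stats.contamination
            + w_sh * stats.contamination * stats.strain_heterogeneity / 100.0
            + w_n50 * math.log10(stats.n50)
            + w_size * math.log10(stats.size)
            + w_cent * centrality)


def choose_representatives(clusters: Sequence[Cluster],
                           stats: Mapping[str, GenomeStats],
                           matrix: pd.DataFrame | None = None,
                           weights: Sequence[float] = DEFAULT_SCORE_WEIGHTS,
                           ) -> list[Cluster]:
    """Pick the highest-scoring member of each cluster as representative.

    Centrality is the mean ANI of a member to the other cluster members
    (100 for singletons, which represent themselves).  Exact score ties
    break to the lexicographically smaller genome id.
    """
    out: list[Cluster] = []
    for cluster in clusters:
        missing = [m for m in cluster.members if m not in stats]
        if missing:
            raise PipelineError(f"missing genome stats for {missing}")
        cent: dict[str, float] = {}
        for m in cluster.members:
            others = [o for o in cluster.members if o != m]
            if not others:
                cent[m] = 100.0
            elif matrix is None:
                raise PipelineError(
                    "an ANI matrix is required to score multi-member clusters")
            else:
                cent[m] = float(np.mean([matrix.loc[m, o] for o in others]))
        scores = {m: score_genome(stats[m], cent[m], weights)
                  for m in cluster.members}
        rep = min(scores, key=lambda m: (-scores[m], m))
        out.append(Cluster(members=list(cluster.members), representative=rep,
                           scores=scores, centrality=cent))
    return out


def dereplicate(matrix: pd.DataFrame,
                stats: Mapping[str, GenomeStats],
                threshold: float = 99.0,
                weights: Sequence[float] = DEFAULT_SCORE_WEIGHTS,
                ) -> list[Cluster]:
    """Cluster at ANI > threshold and select one representative per cluster."""
    return choose_representatives(
        cluster_by_ani(matrix, threshold), stats, matrix, weights)


def clusters_to_frame(clusters: Sequence[Cluster]) -> pd.DataFrame:
    """Flatten clusters to a (genome, cluster, representative, score,
    centrality) table for TSV output."""
    rows = []
    for k, c in enumerate(clusters):
        for m in c.members:
            rows.append({
                "genome": m,
                "cluster": k,
                "representative": c.representative or "",
                "score": c.scores.get(m, float("nan")),
                "centrality": c.centrality.get(m, float("nan")),
            })
    return pd.DataFrame(rows)
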