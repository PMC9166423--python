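# Methods

This note documents the models behind each `cprlib` stage, the tunable
parameters and their defaults, what the synthetic-data generators do and do
not emulate, and the numerical choices made where the design was open.

## Bin decontamination and quality gating

**Gene taxonomy.** Each gene's taxonomy class is the class of its best
surviving alignment hit. A hit survives when e-value ≤ 1e-3, percent
identity ≥ 10, query coverage ≥ 10 and bitscore ≥ 50 ("similarity" and
"coverage" are interpreted as percent identity and query-coverage percent);
"best" is the highest bitscore, with the first-listed hit winning exact
ties. These permissive floors suit divergent CPR proteins, where stricter
cutoffs would leave most genes unassigned.

**Contig vote.** The dominant class is the class with the most assigned
genes bin-wide (ties break lexicographically so results are reproducible),
computed once on the unfiltered bin — there is no iterative re-voting. A
contig is removed iff it has ≥ 1 assigned gene and its dominant-class share
among *assigned* genes is < 0.30 (strict). Contigs with zero assigned genes
are retained and flagged: CPR genes frequently lack database hits, and
counting unassigned genes in the denominator would purge precisely the
novel contigs of interest. This denominator choice is switchable in the
sense that callers can pre-filter the taxonomy mapping, and the flagged
list makes the affected contigs auditable.

**Viral filter.** A contig is removed iff virus-flagged genes exceed 25% of
its predicted genes (strict >). Gene-less contigs carry no evidence and are
kept.

**SCG quality.** Completeness = 100 × (markers present)/43; contamination =
100 × (surplus copies)/43; strain heterogeneity = the percentage of
multi-copy markers whose extra copies are all ≥ 90% amino-acid identical to
the first copy (0 when no marker is duplicated; duplicates without recorded
identities count as divergent). The 90% identity threshold follows the
common practice of treating near-identical duplicates as strain-level
redundancy rather than contamination; it is configurable
(`strain_het_identity_min`). The gate is strict: pass iff completeness > 40
and contamination < 5. The default marker list is a 43-gene bacterial
single-copy set (ribosomal proteins, RNA-polymerase subunits, IF-2); any
43-identifier list can be configured, and marker identifiers are otherwise
opaque. This simple-count estimator deliberately omits collocated-marker-set
weighting; with a fixed 43-marker universe the plain counts are exact and
auditable.

## Dereplication

Clustering is single-linkage over the graph with edges at ANI strictly
above the threshold (default 99%), computed as connected components — the
literal reading of "dereplicate at ANI > 99%". No MASH-style pre-clustering
is performed; on matrices where pre-clustering would split long
single-linkage chains, cluster counts can differ slightly from two-stage
tools. Matrices must be symmetric within 0.01; pairs missing from a
long-form table count as ANI 0 (below any threshold).

Representatives maximize the composite score
`1·completeness − 5·contamination + 1·(contamination·SH/100) +
0.5·log10(N50) + 0·log10(size) + 1·centrality`, where centrality is a
member's mean ANI to the other members (singletons, which represent
themselves, are assigned centrality 100 for completeness of the report).
The weights are the scoring defaults of the dRep dereplication tool and are
configurable as a 6-tuple. Ties break to the lexicographically smaller id.

## Recruitment and abundance

rRNA intervals are masked to `N` before mapping because conserved rRNA
recruits reads from unrelated taxa and would inflate abundance; the
effective genome length excludes masked positions (overlapping intervals
are merged first; BED input is converted to 1-based inclusive coordinates
at the parsing boundary only).

The built-in mapper is an ungapped full-read aligner seeded with
non-overlapping 15-mers: by pigeonhole it finds every alignment with fewer
than ⌊read/15⌋ mismatches, ample at the default 95% identity floor for
150-bp reads (≤ 7 mismatches). It exists so desk-scale analyses and tests
need no external aligner; for real metagenomes a hit table from any mapper
can be supplied instead. The identity floor mirrors typical strict
recruitment settings and is configurable.

Abundance is **coverage per Gbp** = (mapped bases / effective genome
length) ÷ (sampled bases / 10⁹). The definition makes the value invariant,
in expectation, under read subsampling and comparable across genomes and
metagenomes; both the hit count and mapped bases are reported so hit-based
normalizations can be recomputed. Subsampling (default 20 million reads)
uses reservoir sampling with original order preserved.

## Replication-skew index

Window coverages (default 5-kb windows, ≥ 20 required, trailing partial
window dropped) are sorted; the extreme 2% of windows on each side is
discarded; the index is the mean of the top decile over the mean of the
bottom decile, floored at 1.0, and reported as NA when mean coverage is
below 0.2× (the ratio of two small Poisson means is then mostly noise) or
the bottom decile is zero. This is an intentionally transparent reduction
of origin/terminus peak-to-trough estimation; it omits species-
heterogeneity refinement.

Two systematic effects matter at desk scale and are visible in the tests:
(i) with a linear exponential gradient the decile ratio estimates roughly
`ptr^0.9` (the deciles average the outer 10% position bands rather than the
exact endpoints), a −4% to −10% bias over ptr 1.5–3; (ii) on uniform
coverage the ratio of extreme-decile means is biased *above* 1 by sampling
noise, approximately `1 + 3.5/√(reads per window)`. The uniform-coverage
validation therefore simulates at 80× depth, where that bias falls below
the ±0.1 assertion band (reads/window ≈ 2,700, predicted bias ≈ 1.07);
gradient recovery is validated at 20× depth on a 150-kb genome (30
windows), where the combined bias and noise stay within ±15% of the planted
ratio in the mean over 20 seeds.

## Rhodopsin classification

Candidates must exceed 150 residues with P < 1e-2 (both strict; the
P-values come from an upstream profile search consumed as a hit table).
Topology is predicted from sequence: transmembrane helices are the unions
of 19-residue windows whose mean Kyte–Doolittle hydropathy is ≥ 1.6, with
runs separated by < 5 residues merged; orientation follows the
positive-inside rule on the alternating loop sides, with K+R differences
below 2 declared ambiguous. Window 19 matches a membrane-spanning helix,
1.6 is the classical strong-hydropathy cutoff, and the merge gap absorbs
single polar residues inside a helix. This replaces an external
consensus-topology predictor while keeping the downstream decision logic
(7 helices, orientation, TM7 motif) unchanged; parameters are arguments of
`predict_topology`.

With exactly 7 helices, the last helix span ± 3 residues of slack (for
boundary jitter) is scanned for `DxxxK`, then `SxxxK`. `DxxxK` with an
extracellular or ambiguous N-terminus → ion pump; `SxxxK` with a
cytoplasmic or ambiguous N-terminus → heliorhodopsin; a motif contradicting
the orientation → `ambiguous` (a category of this implementation — upstream
descriptions do not define the conflicting case); no motif →
`rhodopsin_like_unclassified`; ≠ 7 helices → rejected.

## Genome traits

Estimated genome size = assembly length × 100 / completeness; this is the
only definition consistent with reporting both an assembly length and a
larger "estimated" size for incomplete MAGs, and it is undefined (NA) at
completeness 0. Coding density uses the union of gene spans, so overlapping
genes are not double-counted. Group summaries are per-category median, min
and max, order-invariant; empty categories are omitted. KEGG-module
completeness is |KOs present ∩ required| / |required| per module, averaged
per genome over modules, then unweighted over genomes per group — the
two-step mean keeps small-genome members from being swamped. CAZy
tabulation reports per-genome totals, each family's share of all hits and
its prevalence across genomes. Whether group plots should use assembly or
estimated size is left to the caller: both columns are always emitted.

## Synthetic data: what it emulates, and what it does not

Generators plant exactly the feature the downstream stage measures:

- `make_bin` — clean contigs at 80% dominant-class genes, foreign contigs
  at 10%, viral contigs at 50% flagged genes; `round(frac·n)` contigs of
  each kind, disjointly. Truth lists the planted contigs.
- `make_scg_profile` — presence/duplication on the 43-marker grid; targets
  round to the nearest representable 100/43 step.
- `simulate_reads` — error-free, ungapped reads whose start density decays
  exponentially from origin (position 0) to terminus with the requested
  density ratio; strands are random; an optional substitution rate exists
  for robustness tests. Expected total bases = depth × genome length.
- `make_rhodopsin_protein` — helices of I/V/L/F (21 residues; 23 for the
  motif helix), loops of N/Q/E (18 residues) with three arginines on each
  cytoplasmic loop; S, D and K appear only in the planted motif. Loop
  length and composition guarantee a 19-window cannot bridge two helices,
  so the topology predictor recovers the construction exactly.
- `make_ani_matrix` — intra-cluster ANI drawn strictly above, inter-cluster
  strictly below, the threshold; overlapping ranges are rejected because
  the planted truth would be ambiguous.
- `make_trait_table` — normal draws per trait around category medians; the
  defaults emulate small, densely coded, moderately AT-rich CPR genomes
  against larger free-living genomes and intermediate symbionts.

None of this models sequence evolution, codon usage, chimeric contigs,
partial-gene boundaries or community composition, so passing closed-loop
tests demonstrates the *decision logic* is faithful to its rules, not that
the rules are robust to every artifact of real assemblies. All generators
are byte-deterministic under a fixed seed.

## Problem sizes and numerical conventions

Validation suites run at desk scale by design: 50 ten-contig bins for the
decontamination loop, 10⁴ random marker profiles against a recount oracle,
200-genome random ANI matrices against a union-find oracle plus 20 planted
matrices, 100–150-kb genomes at 3–80× depth for recruitment and replication
skew, and 200 proteins per class for the classifier. Boundary semantics are
strict everywhere exactly as stated above; all thresholds live in
`PipelineConfig` (a flat key=value text file) and every stage derives its
RNG stream from the single `rng_seed` so stages are independently
reproducible.

## Known limitations

- Single-linkage dereplication can chain clusters that two-stage
  (pre-cluster + threshold) tools would split.
- The built-in mapper is O(reads × candidate sites) and meant for desk
  scale; supply external hit tables for real metagenomes.
- The replication index inherits the decile-ratio biases quantified above;
  values between 1.0 and ~1.1 at modest depth are not evidence of
  replication.
- The hydropathy topology predictor has no evolutionary information; highly
  hydrophobic non-membrane stretches can count as helices on real proteins.
- Strain heterogeneity requires per-copy identities; when absent it is
  conservatively reported as 0 heterogeneous duplicates.
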