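"""Taxonomy-vote decontamination, viral filtering and SCG quality gating."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cprlib import (
    Bin,
    Contig,
    Gene,
    Hit,
    PipelineError,
    ValidationError,
    assign_gene_taxonomy,
    decontaminate,
    dominant_class,
    estimate_quality,
    scg_profile,
    viral_filter,
)
from cprlib import synthetic_data as sd
from cprlib.bin_qc import SCGProfile

from conftest import gene_taxonomy


def _hit(bitscore=100.0, evalue=1e-10, similarity=50.0, coverage=50.0,
         cls="ClassA"):
    return Hit("g", "s", evalue, similarity, coverage, bitscore, cls)


class TestAssignGeneTaxonomy:
    def test_best_bitscore_supplies_the_class(self, config):
        hits = {"g": [_hit(80, cls="ClassA"), _hit(60, cls="ClassB")]}
        assert assign_gene_taxonomy(hits, config)["g"] == "ClassA"

    @pytest.mark.parametrize("kwargs", [
        dict(bitscore=49.0),          # below the bitscore floor
        dict(evalue=1e-2),            # above the e-value ceiling
        dict(similarity=9.9),         # below the identity floor
        dict(coverage=9.9),           # below the coverage floor
    ])
    def test_each_criterion_discards_the_hit(self, config, kwargs):
        assert assign_gene_taxonomy({"g": [_hit(**kwargs)]}, config) == \
            {"g": None}

    def test_boundary_values_pass(self, config):
        hits = {"g": [_hit(bitscore=50.0, evalue=1e-3, similarity=10.0,
                           coverage=10.0)]}
        assert assign_gene_taxonomy(hits, config)["g"] == "ClassA"

    def test_empty_input_gives_no_assignments(self, config):
        assert assign_gene_taxonomy({}, config) == {}


def _manual_bin(class_per_gene, viral_flags=None):
    """A one-contig-per-row bin: class_per_gene[i] lists each gene's class
    (None = unassigned) on contig i."""
    contigs, genes = {}, {}
    viral_flags = viral_flags or [[False] * len(r) for r in class_per_gene]
    for ci, classes in enumerate(class_per_gene):
        cid = f"c{ci}"
        length = 100 * len(classes) + 100
        contig = Contig(id=cid, length=length)
        for gi, cls in enumerate(classes):
            gid = f"{cid}_g{gi}"
            genes[gid] = Gene(id=gid, contig_id=cid, start=gi * 100 + 1,
                              end=gi * 100 + 90,
                              best_hit_class=cls,
                              viral=viral_flags[ci][gi])
            contig.gene_ids.append(gid)
        contigs[cid] = contig
    bin_ = Bin(id="b", contigs=contigs, genes=genes)
    taxonomy = {g.id: g.best_hit_class for g in genes.values()}
    return bin_, taxonomy


class TestDominantClass:
    def test_majority_wins(self, config):
        bin_, tax = _manual_bin([["A"] * 6 + ["B"] * 4])
        assert dominant_class(bin_, tax) == "A"

    def test_tie_breaks_lexicographically(self):
        bin_, tax = _manual_bin([["Beta", "Alpha", "Beta", "Alpha"]])
        assert dominant_class(bin_, tax) == "Alpha"

    def test_all_unassigned_is_an_error(self):
        bin_, tax = _manual_bin([[None, None]])
        with pytest.raises(PipelineError):
            dominant_class(bin_, tax)


class TestDecontaminate:
    def test_contig_below_30_percent_removed(self, config):
        bin_, tax = _manual_bin([
            ["A"] * 10,
            ["A"] * 2 + ["B"] * 8,      # 20% dominant -> removed
        ])
        clean, removed, flagged = decontaminate(bin_, tax, config)
        assert removed == ["c1"]
        assert "c1" not in clean.contigs
        assert all(g.contig_id != "c1" for g in clean.genes.values())

    def test_exactly_30_percent_retained(self, config):
        bin_, tax = _manual_bin([
            ["A"] * 10,
            ["A"] * 3 + ["B"] * 7,      # exactly 30% -> strict < keeps it
        ])
        clean, removed, _ = decontaminate(bin_, tax, config)
        assert removed == []
        assert "c1" in clean.contigs

    def test_unassigned_contig_retained_and_flagged(self, config):
        bin_, tax = _manual_bin([["A"] * 10, [None] * 5])
        clean, removed, flagged = decontaminate(bin_, tax, config)
        assert removed == []
        assert flagged == ["c1"]
        assert "c1" in clean.contigs

    def test_idempotent(self, config, small_bin):
        bin_, _ = small_bin
        tax = gene_taxonomy(bin_)
        once, removed1, _ = decontaminate(bin_, tax, config)
        twice, removed2, _ = decontaminate(once, tax, config)
        assert removed2 == []
        assert set(twice.contigs) == set(once.contigs)

    def test_closed_loop_on_planted_bin(self, config, small_bin):
        bin_, truth = small_bin
        clean, removed, _ = decontaminate(bin_, gene_taxonomy(bin_), config)
        assert sorted(removed) == sorted(truth.foreign_contigs)


class TestViralFilter:
    def test_26_of_100_viral_removed(self, config):
        flags = [[i < 26 for i in range(100)]]
        bin_, _ = _manual_bin([["A"] * 100], flags)
        _, removed = viral_filter(bin_, config)
        assert removed == ["c0"]

    def test_exactly_25_percent_retained(self, config):
        flags = [[i < 25 for i in range(100)]]
        bin_, _ = _manual_bin([["A"] * 100], flags)
        clean, removed = viral_filter(bin_, config)
        assert removed == []

    def test_contig_without_genes_retained(self, config):
        bin_ = Bin(id="b", contigs={"c0": Contig(id="c0", length=5000)})
        clean, removed = viral_filter(bin_, config)
        assert removed == [] and "c0" in clean.contigs

    def test_closed_loop_on_planted_bin(self, config, small_bin):
        bin_, truth = small_bin
        _, removed = viral_filter(bin_, config)
        assert sorted(removed) == sorted(truth.viral_contigs)


class TestSCGProfileCounting:
    def test_one_gene_per_marker_counts_one(self, config):
        annotations = {f"g{i}": m for i, m in enumerate(config.scg_marker_ids)}
        profile = scg_profile(annotations, config)
        assert all(c == 1 for c in profile.counts.values())

    def test_duplicate_marker_counts_two(self, config):
        m = config.scg_marker_ids[0]
        profile = scg_profile({"g1": m, "g2": m}, config)
        assert profile.counts[m] == 2

    def test_non_marker_annotations_ignored(self, config):
        profile = scg_profile({"g1": "not_a_marker"}, config)
        assert all(c == 0 for c in profile.counts.values())


class TestEstimateQuality:
    def test_perfect_profile(self, config):
        profile = SCGProfile({m: 1 for m in config.scg_marker_ids})
        q = estimate_quality(profile, config)
        assert (q.completeness, q.contamination) == (100.0, 0.0)
        assert q.passed

    def test_22_markers_pass_the_gate(self, config):
        counts = {m: (1 if i < 22 else 0)
                  for i, m in enumerate(config.scg_marker_ids)}
        q = estimate_quality(SCGProfile(counts), config)
        assert q.completeness == pytest.approx(100 * 22 / 43)
        assert q.passed

    def test_three_duplicates_fail_on_contamination(self, config):
        counts = {m: (2 if i < 3 else 1)
                  for i, m in enumerate(config.scg_marker_ids)}
        q = estimate_quality(SCGProfile(counts), config)
        assert q.contamination == pytest.approx(100 * 3 / 43)
        assert not q.passed

    def test_strain_heterogeneity_counts_near_identical_duplicates(self, config):
        markers = config.scg_marker_ids
        counts = {m: (2 if i < 2 else 1) for i, m in enumerate(markers)}
        identities = {markers[0]: [95.0], markers[1]: [70.0]}
        q = estimate_quality(SCGProfile(counts, identities), config)
        assert q.strain_heterogeneity == pytest.approx(50.0)

    def test_wrong_marker_set_rejected(self, config):
        with pytest.raises(ValidationError):
            estimate_quality(SCGProfile({"x": 1}), config)

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    @settings(max_examples=200, deadline=None)
    def test_matches_brute_force_recount(self, seed):
        """Estimator equals an independent per-marker tally on random
        profiles, and the gate is exactly the strict >40 / <5 rule."""
        from cprlib import PipelineConfig
        config = PipelineConfig()
        rng = np.random.default_rng(seed)
        counts = {m: int(c) for m, c in
                  zip(config.scg_marker_ids, rng.integers(0, 4, 43))}
        q = estimate_quality(SCGProfile(counts), config)
        present = surplus = 0
        for c in counts.values():
            if c >= 1:
                present += 1
            surplus += c - 1 if c > 1 else 0
        assert q.completeness == pytest.approx(100 * present / 43)
        assert q.contamination == pytest.approx(100 * surplus / 43)
        assert q.passed == (q.completeness > 40 and q.contamination < 5)

    def test_monotone_in_markers_and_duplicates(self, config):
        markers = config.scg_marker_ids
        base = {m: 0 for m in markers}
        prev_completeness = 0.0
        for i, m in enumerate(markers):
            base[m] = 1
            q = estimate_quality(SCGProfile(dict(base)), config)
            assert q.completeness >= prev_completeness
            prev_completeness = q.completeness
        prev_contamination = 0.0
        for m in markers:
            base[m] = 2
            q = estimate_quality(SCGProfile(dict(base)), config)
            assert q.contamination >= prev_contamination
            prev_contamination = q.contamination

    def test_closed_loop_with_planted_profile(self, config):
        for seed, (comp, cont) in enumerate([(100, 0), (51.16, 0),
                                             (100, 4.65), (60, 2.3)]):
            counts, truth = sd.make_scg_profile(seed, comp, cont)
            q = estimate_quality(SCGProfile(counts), config)
            assert q.completeness == pytest.approx(truth.completeness)
            assert q.contamination == pytest.approx(truth.contamination)
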