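"""Simulator: determinism, truth-map correctness, panel construction."""

from __future__ import annotations

from collections import Counter

import numpy as np
import pytest

from snpbridge.genome_io import Parameters, complement, revcomp
from snpbridge.reconcile import FLIPPED, SAME, harmonize_genotype
from snpbridge.simulate import (
    EXPECT_DISCORDANT, EXPECT_FILTERED, EXPECT_MULTI, EXPECT_UNMAPPED,
    TRANSFERABLE_CONCORDANT, EditSpec, PanelSpec, SiteTruth, TruthMap,
    TruthSegment, derive_assembly, evaluate_recovery,
    read_truth_tsv, simulate_panels, simulate_reference, write_truth_tsv,
)
from snpbridge.reconcile import PairedSnp, SiteKey


# ---------------------------------------------------------------------------
# reference simulation
# ---------------------------------------------------------------------------

class TestReference:
    def test_seed_determinism(self):
        a1 = simulate_reference([2000, 1000], seed=3)
        a2 = simulate_reference([2000, 1000], seed=3)
        assert a1.contigs == a2.contigs
        a3 = simulate_reference([2000, 1000], seed=4)
        assert a3.contigs != a1.contigs

    def test_base_composition_near_uniform(self):
        asm = simulate_reference([100_000], seed=1)
        seq = asm.contigs["chr01"]
        for b in "ACGT":
            assert seq.count(b) / len(seq) == pytest.approx(0.25, abs=0.01)

    def test_named_lengths_and_errors(self):
        asm = simulate_reference({"x": 10}, seed=0)
        assert list(asm.contigs) == ["x"] and len(asm.contigs["x"]) == 10
        with pytest.raises(ValueError):
            simulate_reference({"x": 0}, seed=0)


# ---------------------------------------------------------------------------
# TruthSegment / TruthMap
# ---------------------------------------------------------------------------

class TestTruthMap:
    def test_reverse_segment_projection(self):
        seg = TruthSegment("cA", 10, 20, "cB", 100, 110, "-")
        assert seg.project(10) == 109
        assert seg.project(19) == 100

    def test_project_and_substitution_flag(self):
        tm = TruthMap([TruthSegment("cA", 0, 10, "cB", 5, 15, "+")],
                      {("cA", 3): "G"})
        (pr,) = tm.project("cA", 3)
        assert (pr.contig_b, pr.pos0_b, pr.strand) == ("cB", 8, "+")
        assert pr.mismatch
        assert not tm.project("cA", 3)[0].ambiguous
        assert tm.project("cA", 99) == []

    def test_inverse_round_trip(self):
        tm = TruthMap([TruthSegment("cA", 0, 10, "cB", 5, 15, "+"),
                       TruthSegment("cA", 20, 30, "cB", 40, 50, "-")],
                      {("cA", 3): "G", ("cA", 25): "T"})
        inv = tm.inverse()
        for pos in range(0, 10):
            (pr,) = tm.project("cA", pos)
            (back,) = inv.project(pr.contig_b, pr.pos0_b)
            assert (back.contig_b, back.pos0_b) == ("cA", pos)
        # substitutions re-keyed to B coordinates
        assert set(inv.substitutions) == {("cB", 8), ("cB", 44)}

    def test_clean_segment_rules(self):
        tm = TruthMap([TruthSegment("cA", 0, 100, "cB", 0, 100, "+"),
                       TruthSegment("cA", 200, 300, "cB", 200, 300, "+",
                                    ambiguous=True)],
                      {("cA", 50): "G"})
        assert tm.clean_segment("cA", 5, 30) is not None
        assert tm.clean_segment("cA", 40, 60) is None  # contains the sub
        assert tm.clean_segment("cA", 40, 60,
                                ignore_substitutions=True) is not None
        assert tm.clean_segment("cA", 210, 220) is None  # ambiguous
        assert tm.clean_segment("cA", 90, 110) is None  # not contained


# ---------------------------------------------------------------------------
# derive_assembly
# ---------------------------------------------------------------------------

class TestDerive:
    def test_no_edits_identity(self):
        a = simulate_reference([3000, 2000], seed=5)
        b, tm = derive_assembly(a, EditSpec(
            substitution_rate=0.0, n_insertions=0, n_deletions=0,
            n_inversions=0, n_duplications=0, n_translocations=0, n_gaps=0,
        ), seed=6)
        assert b.contigs == a.contigs
        segs = sorted(tm.segments, key=lambda s: s.contig_a)
        assert len(segs) == 2
        for seg, name in zip(segs, sorted(a.contigs)):
            assert (seg.contig_a, seg.a_start0, seg.a_end0) == \
                   (name, 0, len(a.contigs[name]))
            assert seg.strand == "+" and not seg.ambiguous
        assert not tm.substitutions

    def test_projection_oracle_base_identity(self):
        """At 1000 random A positions, the projected B base must equal the A
        base (complemented on '-' segments) unless flagged as a
        substitution."""
        a = simulate_reference([40_000], seed=8)
        edits = EditSpec(substitution_rate=2e-3, n_insertions=3, n_deletions=3,
                         n_inversions=1, inversion_len=(1000, 2000),
                         n_duplications=1, duplication_len=(1500, 2500),
                         n_translocations=0, n_gaps=1, gap_len=(100, 200),
                         end_margin=500)
        b, tm = derive_assembly(a, edits, seed=9)
        rng = np.random.default_rng(10)
        seq_a = a.contigs["chr01"]
        checked = 0
        for pos in rng.integers(0, len(seq_a), size=1000):
            pos = int(pos)
            for pr in tm.project("chr01", pos):
                base_b = b.contigs[pr.contig_b][pr.pos0_b]
                expected = seq_a[pos] if pr.strand == "+" else \
                    complement(seq_a[pos])
                if pr.mismatch:
                    assert base_b != expected
                else:
                    assert base_b == expected
                checked += 1
        assert checked > 500

    def test_inversion_region_reverse_strand(self):
        a = simulate_reference([20_000], seed=12)
        edits = EditSpec(substitution_rate=0.0, n_insertions=0, n_deletions=0,
                         n_inversions=1, inversion_len=(1000, 1500),
                         n_duplications=0, n_translocations=0, n_gaps=0,
                         end_margin=500)
        b, tm = derive_assembly(a, edits, seed=13)
        rev = [s for s in tm.segments if s.strand == "-"]
        assert len(rev) == 1
        (seg,) = rev
        a_part = a.contigs[seg.contig_a][seg.a_start0:seg.a_end0]
        b_part = b.contigs[seg.contig_b][seg.b_start0:seg.b_end0]
        assert b_part == revcomp(a_part)

    def test_duplication_ambiguous_one_to_many(self):
        a = simulate_reference([20_000], seed=14)
        edits = EditSpec(substitution_rate=0.0, n_insertions=0, n_deletions=0,
                         n_inversions=0, n_duplications=1,
                         duplication_len=(1500, 2000), n_translocations=0,
                         n_gaps=0, end_margin=500)
        b, tm = derive_assembly(a, edits, seed=15)
        amb = [s for s in tm.segments if s.ambiguous]
        assert len(amb) == 2  # the two copies of one source
        mid = (amb[0].a_start0 + amb[0].a_end0) // 2
        prs = tm.project("chr01", mid)
        assert sum(1 for p in prs if p.ambiguous) == 2

    def test_impossible_demands_error(self):
        a = simulate_reference([3000], seed=16)
        with pytest.raises(ValueError, match="exceed the genome length"):
            derive_assembly(a, EditSpec(n_inversions=5,
                                        inversion_len=(1000, 1000),
                                        end_margin=500), seed=17)


# ---------------------------------------------------------------------------
# panels and truth labels
# ---------------------------------------------------------------------------

class TestPanels:
    def make(self, seed=30, **panel_kw):
        a = simulate_reference([30_000, 30_000], seed=seed)
        edits = EditSpec(n_insertions=2, n_deletions=2, n_inversions=1,
                         inversion_len=(1000, 2000), n_duplications=1,
                         duplication_len=(1500, 2500), n_translocations=0,
                         n_gaps=1, gap_len=(100, 200), end_margin=500)
        b, tm = derive_assembly(a, edits, seed=seed + 1)
        panel = PanelSpec(n_samples=15, n_snps=60, seed=seed + 2, **panel_kw)
        params = Parameters(flank=200)
        ta, tb, truths = simulate_panels(a, b, tm, panel, params)
        return a, b, tm, ta, tb, truths

    def test_zero_error_panels_harmonize_identically(self):
        a, b, tm, ta, tb, truths = self.make(
            missing_rate=0.0, genotype_error_rate=0.0,
            discordant_fraction=0.0, lowqual_fraction=0.0)
        idx_a = ta.site_index()
        idx_b = tb.site_index()
        for t in truths:
            if t.label != TRANSFERABLE_CONCORDANT:
                continue
            sa = idx_a[(t.contig_a, t.pos1_a)]
            sb = idx_b[(t.contig_b, t.pos1_b)]
            rel = SAME if t.strand == "+" else FLIPPED
            for ga, gb in zip(sa.genotypes, sb.genotypes):
                assert harmonize_genotype(ga, sa.ref, sa.alt, SAME) == \
                    harmonize_genotype(gb, sb.ref, sb.alt, rel)

    def test_reverse_sites_alleles_complemented_ref_matches_genome(self):
        # a large inversion guarantees reverse-strand clean sites are drawn
        a = simulate_reference([30_000], seed=33)
        edits = EditSpec(n_insertions=0, n_deletions=0, n_inversions=1,
                         inversion_len=(15_000, 20_000), n_duplications=0,
                         n_translocations=0, n_gaps=0, end_margin=500)
        b, tm = derive_assembly(a, edits, seed=34)
        panel = PanelSpec(n_samples=15, n_snps=60, seed=35,
                          multi_fraction=0.0)
        ta, tb, truths = simulate_panels(a, b, tm, panel, Parameters(flank=200))
        idx_a = ta.site_index()
        idx_b = tb.site_index()
        seen_rev = 0
        for t in truths:
            if t.contig_b is None or (t.contig_b, t.pos1_b) not in idx_b:
                continue
            sa = idx_a[(t.contig_a, t.pos1_a)]
            sb = idx_b[(t.contig_b, t.pos1_b)]
            assert sb.ref == b.contigs[sb.contig][sb.pos1 - 1]
            if t.strand == "-":
                seen_rev += 1
                assert {sb.ref, sb.alt} == \
                    {complement(sa.ref), complement(sa.alt)}
        assert seen_rev > 0

    def test_expect_multi_sites_in_ambiguous_regions(self):
        a, b, tm, ta, tb, truths = self.make()
        multi = [t for t in truths if t.label == EXPECT_MULTI]
        assert multi
        for t in multi:
            prs = tm.project(t.contig_a, t.pos1_a - 1)
            assert any(p.ambiguous for p in prs)

    def test_expect_unmapped_sites_have_divergent_flanks(self):
        a, b, tm, ta, tb, truths = self.make()
        unmapped = [t for t in truths if t.label == EXPECT_UNMAPPED]
        assert unmapped
        for t in unmapped:
            # window around the site is disqualified as clean (a substitution
            # or structural break falls inside the flank span)
            f = 200
            c0 = t.pos1_a - 1
            assert tm.clean_segment(t.contig_a, c0 - f, c0 + f + 1) is None

    def test_label_inventory_and_determinism(self):
        _, _, _, ta1, tb1, tr1 = self.make()
        _, _, _, ta2, tb2, tr2 = self.make()
        assert tr1 == tr2
        assert [s.genotypes for s in ta1.sites] == \
               [s.genotypes for s in ta2.sites]
        labels = Counter(t.label for t in tr1)
        assert labels[TRANSFERABLE_CONCORDANT] > 0
        assert labels[EXPECT_DISCORDANT] > 0
        assert set(labels) <= {TRANSFERABLE_CONCORDANT, EXPECT_DISCORDANT,
                               EXPECT_MULTI, EXPECT_UNMAPPED, EXPECT_FILTERED}

    def test_truth_tsv_round_trip(self, tmp_path):
        *_, truths = self.make()
        p = tmp_path / "truth.tsv"
        write_truth_tsv(truths, p, header_lines=["demo"])
        back = read_truth_tsv(p)
        assert back == truths


# ---------------------------------------------------------------------------
# evaluate_recovery
# ---------------------------------------------------------------------------

class TestRecovery:
    def test_hand_example(self):
        truths = [
            SiteTruth("a1", "c1", 1, "c1", 1, "+", TRANSFERABLE_CONCORDANT),
            SiteTruth("a2", "c1", 2, "c1", 2, "+", TRANSFERABLE_CONCORDANT),
            SiteTruth("a3", "c1", 3, None, None, None, EXPECT_UNMAPPED),
            SiteTruth("a4", "c1", 4, "c1", 4, "+", EXPECT_DISCORDANT),
        ]
        kept = [PairedSnp("a1~b", SiteKey("c1", 1, "A", "G"),
                          SiteKey("c1", 1, "A", "G"), SAME),
                PairedSnp("a4~b", SiteKey("c1", 4, "A", "G"),
                          SiteKey("c1", 4, "A", "G"), SAME)]
        r = evaluate_recovery(kept, truths)
        assert r.precision == pytest.approx(0.5)
        assert r.recall == pytest.approx(0.5)
        assert r.confusion[EXPECT_DISCORDANT] == {"total": 1, "kept": 1}

    def test_empty_truths_error(self):
        with pytest.raises(ValueError):
            evaluate_recovery([], [])


# ---------------------------------------------------------------------------
# scenario-level end-to-end expectations
# ---------------------------------------------------------------------------

def test_default_scenario_shape(scenario):
    sc = scenario
    assert set(sc.genome_a.contigs) == {"chr01", "chr02"}
    assert all(len(s) == 500_000 for s in sc.genome_a.contigs.values())
    assert len(sc.table_a.samples) == 60
    assert len(sc.table_a.sites) == 2000
    assert len(sc.truths) == 2000


def test_pipeline_recovery_on_default_scenario(pipeline_result, scenario):
    rep = evaluate_recovery([r.pair for r in pipeline_result.kept],
                            scenario.truths)
    assert rep.precision > 0.98
    assert rep.recall > 0.98
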