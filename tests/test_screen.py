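"""Family cutoffs, the six-family 300-bp window rule, the gene screen, enrichment."""

import math

import numpy as np
import pytest

from crmscreen.geometry import RegionSet
from crmscreen.io import FamilyMap
from crmscreen.screen import (
    DEFAULT_FAMILY_P,
    REQUIRED_FAMILIES,
    call_crm_windows,
    enrichment_test,
    gene_screen,
    label_and_filter_hits,
)
from crmscreen.simulate import FAMILY_CONSENSUS, SimulationConfig, simulate_genome

from conftest import make_hit

FAMS = list(FAMILY_CONSENSUS)  # WRKY, G2like, MYBR_B, DOF, IDD, DPBF


def sextet(starts, p=1e-6):
    return [make_hit(f, s, p_value=p) for f, s in zip(FAMS, starts)]


class TestLabelAndFilter:
    def test_strict_family_cutoffs(self):
        fm = FamilyMap({"DOF_syn1": "DOF", "WRKY_syn1": "WRKY"})
        dof = make_hit("", 10, p_value=5e-4, motif_id="DOF_syn1")
        wrky = make_hit("", 40, p_value=5e-4, motif_id="WRKY_syn1")
        kept = label_and_filter_hits([dof, wrky], fm)
        assert [(h.motif_id, h.family) for h in kept] == [("WRKY_syn1", "WRKY")]

    def test_boundary_is_strict(self):
        fm = FamilyMap({"DOF_syn1": "DOF"})
        at_cutoff = make_hit("", 10, p_value=1e-4, motif_id="DOF_syn1")
        below = make_hit("", 10, p_value=0.99e-4, motif_id="DOF_syn1")
        assert label_and_filter_hits([at_cutoff], fm) == []
        assert len(label_and_filter_hits([below], fm)) == 1

    def test_unmapped_motif_dropped_with_warning(self, caplog):
        fm = FamilyMap()
        with caplog.at_level("WARNING", logger="crmscreen"):
            assert label_and_filter_hits([make_hit("", 10, motif_id="mystery")], fm) == []
        assert any("without a screened family" in r.message for r in caplog.records)

    def test_empty_input_empty_output(self):
        assert label_and_filter_hits([], FamilyMap()) == []


class TestCallCrmWindows:
    def test_five_families_no_call(self):
        hits = sextet([100, 120, 140, 160, 180, 200])[:5]
        assert call_crm_windows(hits) == []

    def test_span_299_called_span_301_not(self):
        # first hit starts at 100; last hit of 9 bp ends at start+8
        ok = sextet([100, 130, 160, 190, 220, 390])  # span 390+8-100+1 = 299
        too_wide = sextet([100, 130, 160, 190, 220, 392])  # span 301
        assert len(call_crm_windows(ok)) == 1
        assert call_crm_windows(too_wide) == []

    def test_call_records_minimal_window_and_support(self):
        hits = sextet([100, 120, 140, 160, 180, 200])
        (call,) = call_crm_windows(hits)
        assert call.window_start == 100 and call.window_end == 208
        assert call.span_length == 109
        assert set(call.supporting_hits) == REQUIRED_FAMILIES
        assert call.families_present >= REQUIRED_FAMILIES

    def test_no_bridging_across_region_gaps(self):
        hits = sextet([100, 120, 140, 160, 180, 260])
        one_interval = RegionSet("g", "crm_search", "chr1", "+", [(50, 400)])
        split = RegionSet("g", "crm_search", "chr1", "+", [(50, 200), (250, 400)])
        assert len(call_crm_windows(hits, regions=one_interval)) == 1
        assert call_crm_windows(hits, regions=split) == []

    def test_window_monotonicity(self):
        """Enlarging the window never removes a call."""
        hits = sextet([100, 150, 200, 250, 300, 340])
        for small, large in [(200, 300), (249, 260), (300, 1000)]:
            calls_small = call_crm_windows(hits, window_bp=small)
            calls_large = call_crm_windows(hits, window_bp=large)
            assert len(calls_large) >= len(calls_small)

    def test_overlapping_candidates_reduced_to_minimal_span(self):
        # a seventh (duplicate-family) hit creates overlapping candidates
        hits = sextet([100, 120, 140, 160, 180, 200]) + [make_hit("WRKY", 150)]
        calls = call_crm_windows(hits)
        assert len(calls) == 1
        assert calls[0].span_length <= 109

    def test_best_supporting_hit_has_lowest_p(self):
        hits = sextet([100, 120, 140, 160, 180, 200], p=1e-5)
        hits.append(make_hit("DOF", 165, p_value=1e-8))
        (call,) = call_crm_windows(hits)
        assert call.supporting_hits["DOF"].p_value == 1e-8


class TestGeneScreen:
    def test_planted_truth_recovered(self, sim_genome_small):
        sim = sim_genome_small
        res = gene_screen(sim.genes, sim.genome, sim.dhs, sim.library, sim.family_map)
        t = res.table.merge(sim.truth, on="gene_id")
        both = t[t.category == "both"]
        assert both.has_both.all()
        five = t[t.category == "five_family"]
        assert not five.has_crm.any()
        assert not t[t.category.isin(["ypatch_only", "neither"])].has_crm.any()

    def test_empty_dhs_means_no_crm(self, sim_genome_small):
        sim = sim_genome_small
        res = gene_screen(sim.genes, sim.genome, {}, sim.library, sim.family_map)
        assert not res.table.has_crm.any()

    def test_plants_outside_dhs_not_called(self):
        cfg = SimulationConfig(seed=13, n_genes=12, dhs_mode="exclude-plants")
        sim = simulate_genome(cfg)
        res = gene_screen(sim.genes, sim.genome, sim.dhs, sim.library, sim.family_map)
        assert not res.table.has_crm.any()

    def test_deterministic_tables(self, sim_genome_small):
        sim = sim_genome_small
        r1 = gene_screen(sim.genes, sim.genome, sim.dhs, sim.library, sim.family_map)
        r2 = gene_screen(sim.genes, sim.genome, sim.dhs, sim.library, sim.family_map)
        assert r1.table.to_csv() == r2.table.to_csv()

    def test_missing_chromosome_skipped(self, sim_genome_small, caplog):
        sim = sim_genome_small
        genome = dict(sim.genome)
        dropped = sim.genes[0].chrom
        del genome[dropped]
        with caplog.at_level("WARNING", logger="crmscreen"):
            res = gene_screen(sim.genes, genome, sim.dhs, sim.library, sim.family_map)
        assert len(res.table) == len(sim.genes) - 1


class TestEnrichment:
    def test_balanced_table_no_association(self):
        universe = set(range(40))
        flag = set(range(20))
        klass = set(range(10, 30))
        res = enrichment_test(flag, klass, universe)
        assert res.table == ((10, 10), (10, 10))
        assert res.odds_ratio == pytest.approx(1.0)
        assert res.p_value == pytest.approx(1.0)

    def test_strong_association_closed_form(self):
        # 2x2 table (9,1;1,9): OR = 81; two-sided Fisher p from the
        # hypergeometric sum P(X>=9) + P(X<=1), X ~ Hypergeom(20, 10, 10)
        universe = set(range(20))
        flag = set(range(10))
        klass = set(range(9)) | {10}
        res = enrichment_test(flag, klass, universe)
        assert res.table == ((9, 1), (1, 9))
        assert res.odds_ratio == pytest.approx(81.0)
        c = math.comb
        denom = c(20, 10)
        p_exact = 2 * (c(10, 9) * c(10, 1) + c(10, 10) * c(10, 0)) / denom
        assert res.p_value == pytest.approx(p_exact, rel=1e-9)

    def test_degenerate_table_flagged(self):
        universe = set(range(10))
        res = enrichment_test(universe, universe, universe)
        assert res.degenerate

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError):
            enrichment_test(set(), set(), set())
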