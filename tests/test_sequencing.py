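"""Topology generation, Y-ladders, branch detection and ranking."""

import numpy as np
import pytest

from glycoseq.glycan import Composition, parse_condensed
from glycoseq.masses import DEPROTONATED
from glycoseq.peaklist import PeakList
from glycoseq.sequencing import (DEFAULT_GRAMMAR, PSM_GRAMMAR,
                                 TopologyGrammar, detect_branch,
                                 generate_candidates, is_grammar_legal,
                                 match_and_rank, theoretical_Y_ions)
from glycoseq.simulate import GlycomeParams, simulate_oglycome
from conftest import FOUR_M_F1
from oracles import brute_force_ladder, brute_force_topologies


class TestGrammar:
    def test_serialization_roundtrip(self):
        g = TopologyGrammar(glcnac_acceptor_positions=(4,), max_children=2)
        assert TopologyGrammar.from_dict(g.to_dict()) == g

    def test_psm_prior_excludes_type1(self):
        type1 = parse_condensed("Gal(b1-3)GlcNAc")
        assert is_grammar_legal(type1, DEFAULT_GRAMMAR)
        assert not is_grammar_legal(type1, PSM_GRAMMAR)


class TestGenerateCandidates:
    def test_single_hexose(self):
        cands = generate_candidates(Composition(Hex=1), DEFAULT_GRAMMAR)
        assert [c.to_condensed() for c in cands] == ["Gal"]

    def test_fig4e_topology_among_candidates(self, fmf1_tree):
        cands = generate_candidates(Composition(dHex=1, Hex=2, HexNAc=3),
                                    PSM_GRAMMAR)
        assert any(c == fmf1_tree for c in cands)

    def test_unreachable_composition_gives_empty_list(self):
        assert generate_candidates(Composition(dHex=3), DEFAULT_GRAMMAR) == []

    def test_all_candidates_unique_and_legal(self):
        cands = generate_candidates(Composition(dHex=1, Hex=2, HexNAc=2),
                                    DEFAULT_GRAMMAR)
        strings = [c.to_condensed() for c in cands]
        assert len(strings) == len(set(strings))
        assert all(is_grammar_legal(c, DEFAULT_GRAMMAR) for c in cands)
        assert all(c.composition() == Composition(dHex=1, Hex=2, HexNAc=2)
                   for c in cands)

    @pytest.mark.parametrize("comp_str", [
        "Hex1", "Hex1HexNAc1", "dHex1Hex1HexNAc1", "Hex2HexNAc2",
        "dHex1Hex2HexNAc2", "dHex1Hex2HexNAc3",
    ])
    def test_equivalent_to_brute_force_enumeration(self, comp_str):
        comp = Composition.from_string(comp_str)
        got = {c.to_condensed()
               for c in generate_candidates(comp, DEFAULT_GRAMMAR)}
        expected = brute_force_topologies(comp, DEFAULT_GRAMMAR)
        assert got == expected


class TestYLadders:
    def test_fig4e_ladder_nominal_values(self, fmf1_tree):
        ladder = theoretical_Y_ions(fmf1_tree, "ADHP_OY", DEPROTONATED)
        assert {2033, 1887, 1830, 1725, 1522, 1157, 954} <= ladder.nominal_set()

    def test_single_residue_gives_precursor_and_y0(self):
        tree = parse_condensed("Gal")
        ladder = theoretical_Y_ions(tree, "ADHP_OY", DEPROTONATED)
        assert len(ladder.ions) == 2

    def test_linear_isomer_lacks_branch_signature(self):
        linear = parse_condensed(
            "Fuc(a1-3)GlcNAc(b1-3)Gal(b1-4)GlcNAc(b1-3)Gal(b1-4)GlcNAc")
        nominal = theoretical_Y_ions(linear, "ADHP_OY", DEPROTONATED).nominal_set()
        assert 1830 not in nominal  # no single-HexNAc first loss
        assert 1725 not in nominal  # no -dHexHex double loss

    def test_matches_brute_force_subset_enumeration(self):
        rng = np.random.default_rng(13)
        glycome = simulate_oglycome(GlycomeParams(n_structures=12, seed=13))
        for core in glycome:
            for arm in core.children:
                tree = arm.copy(linkage=None)
                if tree.n_residues() > 8:
                    continue
                ladder = theoretical_Y_ions(tree, "ADHP_OY", DEPROTONATED)
                got = {round(i.mz, 6) for i in ladder.ions}
                assert got == brute_force_ladder(tree, "ADHP_OY")

    def test_ladder_closure(self, fmf1_tree):
        """In the complete theoretical ladder every ion differs from some
        other ion by exactly one residue mass; gaps only arise in observed
        subsets, which is precisely the branch diagnostic."""
        from glycoseq.masses import RESIDUE_MASS
        ladder = theoretical_Y_ions(fmf1_tree, "ADHP_OY", DEPROTONATED)
        mzs = sorted(i.mz for i in ladder.ions)
        steps = [round(m, 2) for m in
                 (RESIDUE_MASS["dHex"], RESIDUE_MASS["Hex"],
                  RESIDUE_MASS["HexNAc"])]
        orphan = []
        for m in mzs:
            has_neighbor = any(
                any(abs(abs(m - other) - s) < 0.01 for s in steps)
                for other in mzs if other != m)
            if not has_neighbor:
                orphan.append(round(m))
        assert orphan == []


class TestDetectBranch:
    def test_fig4e_branch_between_1522_and_1157(self, fig4e_peaklist):
        evidence = detect_branch(fig4e_peaklist, tolerance=0.5)
        gaps = [(round(e.upper_mz), round(e.lower_mz)) for e in evidence
                if e.kind == "HexHexNAc-gap"]
        assert gaps == [(1522, 1157)]
        stubs = [e for e in evidence if e.kind == "terminal-HexNAc-stub"]
        assert len(stubs) == 1 and round(stubs[0].lower_mz) == 1830

    def test_linear_ladder_has_no_branch_evidence(self):
        linear = parse_condensed(
            "Fuc(a1-2)Gal(b1-4)GlcNAc(b1-3)Gal(b1-4)GlcNAc")
        ladder = theoretical_Y_ions(linear, "ADHP_OY", DEPROTONATED)
        peaks = PeakList.from_pairs([(i.mz, 10.0) for i in ladder.ions],
                                    level="MS2",
                                    precursor_mz=max(i.mz for i in ladder.ions))
        assert detect_branch(peaks, tolerance=0.2) == []

    def test_sensitivity_and_specificity_on_simulated_structures(self):
        """Complete ladders of branched arms show evidence; linear arms
        never do (no false positives at 0.2 Da tolerance)."""
        glycome = simulate_oglycome(GlycomeParams(n_structures=100, seed=7))
        arms = [arm.copy(linkage=None) for core in glycome
                for arm in core.children]
        branched = [a for a in arms
                    if any(len(n.children) > 1 for n in a.walk())][:50]
        linear = [a for a in arms if a.n_residues() >= 3
                  and all(len(n.children) <= 1 for n in a.walk())][:50]
        assert branched and linear
        def has_evidence(tree):
            ladder = theoretical_Y_ions(tree, "ADHP_OY", DEPROTONATED)
            peaks = PeakList.from_pairs(
                [(i.mz, 10.0) for i in ladder.ions], level="MS2",
                precursor_mz=max(i.mz for i in ladder.ions))
            return bool(detect_branch(peaks, tolerance=0.2))
        specificity = np.mean([not has_evidence(t) for t in linear])
        sensitivity = np.mean([has_evidence(t) for t in branched])
        assert specificity == 1.0
        assert sensitivity >= 0.5  # double losses need non-terminal branches


class TestMatchAndRank:
    def test_fig4e_top_candidate_properties(self, fig4e_peaklist):
        cands = generate_candidates(Composition(dHex=1, Hex=2, HexNAc=3),
                                    PSM_GRAMMAR)
        ranked = match_and_rank(fig4e_peaklist, cands, "ADHP_OY",
                                DEPROTONATED, tolerance=0.5)
        top, score = ranked[0]
        assert score.matched_peaks == len(fig4e_peaklist)
        assert score.unexplained_major_peaks == 0
        # branched, with a terminal HexNAc stub and a dHex-Hex-HexNAc arm
        assert any(len(n.children) > 1 for n in top.walk())
        assert any(n.mass_class == "HexNAc" and n.is_leaf() for n in top.walk())
        fuc = [n for n in top.walk() if n.symbol == "Fuc"]
        assert len(fuc) == 1

    def test_self_consistency_full_ladder(self):
        cands = generate_candidates(Composition(dHex=1, Hex=2, HexNAc=2),
                                    DEFAULT_GRAMMAR)
        target = cands[3]
        ladder = theoretical_Y_ions(target, "ADHP_OY", DEPROTONATED)
        peaks = PeakList.from_pairs([(i.mz, 10.0) for i in ladder.ions],
                                    level="MS2",
                                    precursor_mz=max(i.mz for i in ladder.ions))
        ranked = match_and_rank(peaks, cands, "ADHP_OY", DEPROTONATED, 0.2)
        top, score = ranked[0]
        assert score.unexplained_major_peaks == 0
        assert score.matched_peaks == len(peaks)
        # the true structure is within the tied-top group
        top_key = score.sort_key()
        tied = [c for c, s in ranked if s.sort_key() == top_key]
        assert any(c == target for c in tied)

    def test_ranking_invariant_under_intensity_rescaling(self, fig4e_peaklist):
        cands = generate_candidates(Composition(dHex=1, Hex=2, HexNAc=3),
                                    PSM_GRAMMAR)
        ranked1 = match_and_rank(fig4e_peaklist, cands, "ADHP_OY")
        scaled = PeakList(fig4e_peaklist.mz.copy(),
                          fig4e_peaklist.intensity * 37.0, level="MS2",
                          precursor_mz=fig4e_peaklist.precursor_mz)
        ranked2 = match_and_rank(scaled, cands, "ADHP_OY")
        assert [c.to_condensed() for c, _ in ranked1] == \
            [c.to_condensed() for c, _ in ranked2]

    def test_empty_candidate_list_rejected(self, fig4e_peaklist):
        with pytest.raises(ValueError):
            match_and_rank(fig4e_peaklist, [], "ADHP_OY")
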