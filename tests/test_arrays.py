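"""Binding summarization, hit calling, motif inference, temperature trend."""

import numpy as np
import pandas as pd
import pytest

from glycoseq.arrays import (call_hits, infer_discriminating_motif,
                             pattern_subsumes, summarize, temperature_trend)
from glycoseq.glycan import MotifPattern, contains_motif, parse_condensed
from glycoseq.probes import (F77_NEGATIVE, F77_POSITIVE, FOCUSED_ARRAY,
                             PROBE_STRUCTURES)
from glycoseq.simulate import (BindingModel, GlycomeParams, simulate_array,
                               simulate_oglycome)
from oracles import brute_force_contains

H6_MOTIF = "Fuc(a1-2)Gal(b1-4)GlcNAc!(b1-6)*"


def _table(rows):
    return pd.DataFrame(rows)


class TestSummarize:
    def test_duplicate_mean_and_half_difference(self):
        t = _table([{"probe_id": "p1", "rep1": 1000.0, "rep2": 1200.0}])
        s = summarize(t)
        assert s.loc[0, "mean"] == 1100.0
        assert s.loc[0, "half_difference"] == 100.0

    def test_all_zero(self):
        s = summarize(_table([{"probe_id": "p", "rep1": 0.0, "rep2": 0.0}]))
        assert s.loc[0, "mean"] == 0.0 and s.loc[0, "half_difference"] == 0.0

    def test_matches_rowwise_recomputation(self):
        rng = np.random.default_rng(5)
        rows = [{"probe_id": f"p{i}", "rep1": float(rng.uniform(0, 5e4)),
                 "rep2": float(rng.uniform(0, 5e4))} for i in range(16)]
        s = summarize(_table(rows))
        for i, row in enumerate(rows):
            a, b = row["rep1"], row["rep2"]
            assert s.loc[i, "mean"] == pytest.approx((a + b) / 2)
            assert s.loc[i, "half_difference"] == pytest.approx(abs(a - b) / 2)

    def test_nonduplicate_flagged(self):
        s = summarize(_table([{"probe_id": "p", "rep1": 1.0, "rep2": 2.0,
                               "rep3": 6.0}]))
        assert bool(s.loc[0, "dispersion_flagged"])
        assert s.loc[0, "half_difference"] == 2.5  # half the range

    def test_negative_intensity_rejected(self):
        with pytest.raises(ValueError):
            summarize(_table([{"probe_id": "p", "rep1": -1.0, "rep2": 0.0}]))


class TestCallHits:
    def test_two_planted_positives_in_large_screen(self):
        rng = np.random.default_rng(11)
        n = 492
        rows, crows = [], []
        for i in range(n):
            mu = 30000.0 if i in (225, 226) else 150.0
            rows.append({"probe_id": f"probe{i}",
                         "rep1": float(mu * rng.lognormal(0, 0.1)),
                         "rep2": float(mu * rng.lognormal(0, 0.1))})
            crows.append({"probe_id": f"probe{i}",
                          "rep1": float(150.0 * rng.lognormal(0, 0.1)),
                          "rep2": float(150.0 * rng.lognormal(0, 0.1))})
        hits = call_hits(summarize(_table(rows)), summarize(_table(crows)))
        called = set(hits.loc[hits.positive, "probe_id"])
        assert called == {"probe225", "probe226"}

    def test_all_zero_intensities_give_no_hits(self):
        t = summarize(_table([{"probe_id": "p", "rep1": 0.0, "rep2": 0.0}]))
        hits = call_hits(t)
        assert not hits["positive"].any()

    def test_scale_invariance(self):
        rng = np.random.default_rng(2)
        rows = [{"probe_id": f"p{i}", "rep1": float(rng.uniform(10, 1e4)),
                 "rep2": float(rng.uniform(10, 1e4))} for i in range(20)]
        t = _table(rows)
        h1 = call_hits(summarize(t))
        t2 = t.copy()
        t2[["rep1", "rep2"]] *= 123.0
        h2 = call_hits(summarize(t2))
        assert (h1["positive"] == h2["positive"]).all()

    def test_missing_control_rows_warn_and_skip(self):
        t = summarize(_table([{"probe_id": "a", "rep1": 100.0, "rep2": 100.0},
                              {"probe_id": "b", "rep1": 90.0, "rep2": 90.0}]))
        ctrl = summarize(_table([{"probe_id": "a", "rep1": 5.0, "rep2": 5.0}]))
        with pytest.warns(UserWarning):
            hits = call_hits(t, ctrl)
        assert hits["positive"].all()


class TestMotifInference:
    def test_focused_array_recovers_h_on_6_branch(self):
        pos = [PROBE_STRUCTURES[n] for n in F77_POSITIVE]
        neg = [PROBE_STRUCTURES[n] for n in F77_NEGATIVE]
        motifs = infer_discriminating_motif(pos, neg, max_size=6)
        assert [m.to_string() for m in motifs] == [H6_MOTIF]

    def test_identical_sets_give_empty_list(self):
        t = parse_condensed("Gal(b1-4)GlcNAc")
        assert infer_discriminating_motif([t], [t]) == []

    def test_empty_sets_rejected(self):
        with pytest.raises(ValueError):
            infer_discriminating_motif([], [parse_condensed("Gal")])

    def test_returned_patterns_verified_by_independent_matcher(self):
        pos = [PROBE_STRUCTURES[n] for n in F77_POSITIVE]
        neg = [PROBE_STRUCTURES[n] for n in F77_NEGATIVE]
        for motif in infer_discriminating_motif(pos, neg, max_size=6):
            assert all(brute_force_contains(t, motif) for t in pos)
            assert not any(brute_force_contains(t, motif) for t in neg)

    def test_minimality_by_exhaustive_mutation(self):
        """Dropping any leaf or opening any closed flag of the returned
        pattern breaks all-positives or no-negatives."""
        pos = [PROBE_STRUCTURES[n] for n in F77_POSITIVE]
        neg = [PROBE_STRUCTURES[n] for n in F77_NEGATIVE]
        (motif,) = infer_discriminating_motif(pos, neg, max_size=6)

        def qualifies(pat):
            return (all(contains_motif(t, pat)[0] for t in pos)
                    and not any(contains_motif(t, pat)[0] for t in neg))

        assert qualifies(motif)
        nodes = list(motif.root.walk())
        for i, node in enumerate(nodes):
            if node.closed:
                variant = motif.root.copy()
                list(variant.walk())[i].closed = False
                assert not qualifies(MotifPattern(variant))
        # drop each leaf in turn
        for i, node in enumerate(nodes):
            if node.children:
                continue
            variant = motif.root.copy()
            vnodes = list(variant.walk())
            target = vnodes[i]
            for parent in vnodes:
                if target in parent.children:
                    parent.children.remove(target)
                    break
            else:
                continue  # pattern root itself
            assert not qualifies(MotifPattern(variant))

    def test_planted_motifs_recovered_on_synthetic_sets(self):
        """For seeded probe sets split by a planted pattern, inference
        returns qualifying patterns, at least one of which generalizes
        the planted one."""
        rng = np.random.default_rng(41)
        glycome = simulate_oglycome(GlycomeParams(n_structures=400, seed=41))
        arms = [arm.copy(linkage=None) for core in glycome
                for arm in core.children if arm.n_residues() >= 2]
        n_recovered = 0
        n_sets = 0
        for trial in range(200):
            idx = rng.choice(len(arms), size=12, replace=False)
            structures = [arms[i] for i in idx]
            seed_struct = structures[int(rng.integers(0, len(structures)))]
            nodes = [n for n in seed_struct.walk() if n.linkage is not None]
            if not nodes:
                continue
            anchor = nodes[int(rng.integers(0, len(nodes)))]
            from glycoseq.glycan import PatternNode

            def conv(node):
                return PatternNode(node.symbol, node.anomer, node.linkage,
                                   False, [conv(c) for c in node.children])
            planted = MotifPattern(PatternNode("*", "?", None, False,
                                               [conv(anchor)]))
            pos = [t for t in structures if contains_motif(t, planted)[0]]
            neg = [t for t in structures if not contains_motif(t, planted)[0]]
            if not pos or not neg:
                continue
            if planted.n_nodes() > 7:
                continue
            n_sets += 1
            motifs = infer_discriminating_motif(pos, neg, max_size=6)
            assert motifs, "a qualifying pattern exists by construction"
            if any(pattern_subsumes(m, planted) for m in motifs):
                n_recovered += 1
        assert n_sets >= 50
        assert n_recovered == n_sets


class TestTemperatureTrend:
    def test_cold_agglutinin_model_positives_strictly_decreasing(self):
        motif = MotifPattern.from_string(H6_MOTIF)
        tables = {}
        for temp in (4, 20, 37):
            binding, _ = simulate_array(
                FOCUSED_ARRAY, BindingModel(motif, seed=3),
                temperatures=(temp,), replicates=100)
            tables[temp] = binding
        verdicts = temperature_trend(tables).set_index("probe_id")["verdict"]
        for name in F77_POSITIVE:
            assert verdicts[name] == "strictly-decreasing"

    def test_constant_intensities_flagged_flat(self):
        t = {temp: _table([{"probe_id": "p", "rep1": 10.0, "rep2": 10.0}])
             for temp in (4, 20, 37)}
        verdicts = temperature_trend(t)
        assert verdicts.loc[0, "verdict"] == "flat"

    def test_decreasing_means_by_definition(self):
        t = {4: _table([{"probe_id": "p", "rep1": 30.0, "rep2": 30.0}]),
             20: _table([{"probe_id": "p", "rep1": 20.0, "rep2": 20.0}]),
             37: _table([{"probe_id": "p", "rep1": 10.0, "rep2": 10.0}])}
        assert temperature_trend(t).loc[0, "verdict"] == "strictly-decreasing"

    def test_missing_temperature_level_rejected(self):
        with pytest.raises(ValueError):
            temperature_trend({20: _table([{"probe_id": "p", "rep1": 1.0,
                                            "rep2": 1.0}])})
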