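import numpy as np
import pandas as pd
import pytest

from hapscna import (
    ParentalKaryotype,
    apply_bfb_break,
    apply_missegregation,
    apply_wgd,
    assign_wgd_to_branches,
    build_tree,
    classify_chromosome,
    classify_event_relation,
    match_breakpoints,
    simulate_clone_tree,
    snv_similarity,
    time_scna_vs_wgd,
)
from hapscna.classify import ScnaEvent
from hapscna.genome import human_autosome_genome


def ev(sample, bps, change=-1, category=None, chrom="chr1", homolog="A"):
    if category is None:
        category = {1: "terminal_loss" if change < 0 else "terminal_gain"}.get(
            len(bps), "paracentric_loss" if change < 0 else "paracentric_gain"
        )
    return ScnaEvent(sample, chrom, homolog, category, tuple(bps), change)


class TestMatchBreakpoints:
    def test_identical_within_tolerance(self):
        m = match_breakpoints(ev("a", [60_000_000]), ev("b", [60_050_000]))
        assert m.relation == "identical" and m.distance == 50_000

    def test_complementary_opposite_direction(self):
        m = match_breakpoints(ev("a", [60_000_000], -1), ev("b", [60_050_000], +1))
        assert m.relation == "complementary"

    def test_distinct_beyond_tolerance(self):
        assert match_breakpoints(ev("a", [60_000_000]), ev("b", [60_200_000])).relation == "distinct"

    def test_different_homolog_distinct_by_definition(self):
        assert match_breakpoints(ev("a", [1_000_000]), ev("b", [1_000_000], homolog="B")).relation == "distinct"

    def test_symmetric(self):
        a, b = ev("a", [60_000_000]), ev("b", [60_050_000])
        assert match_breakpoints(a, b) == match_breakpoints(b, a)


class TestEventRelation:
    def test_all_matched_is_shared(self):
        a = ev("a", [30_000_000, 50_000_000])
        b = ev("b", [30_040_000, 50_010_000])
        assert classify_event_relation(a, b) == "shared"

    def test_subset_matched_is_branching(self):
        a = ev("a", [30_000_000, 50_000_000])
        b = ev("b", [30_040_000, 70_000_000])
        assert classify_event_relation(a, b) == "branching"

    def test_complementary_pair_is_branching(self):
        # reciprocal daughters of one dicentric break
        a = ev("a", [60_000_000], -1)
        b = ev("b", [60_030_000], +1, category="terminal_gain")
        assert classify_event_relation(a, b) == "branching"

    def test_nothing_matched_is_unrelated(self):
        assert classify_event_relation(ev("a", [10_000_000]), ev("b", [90_000_000])) == "unrelated"

    def test_swap_invariant(self):
        a = ev("a", [30_000_000, 50_000_000])
        b = ev("b", [30_040_000, 70_000_000])
        assert classify_event_relation(a, b) == classify_event_relation(b, a)


class TestBuildTree:
    def test_nothing_shared_gives_star(self):
        events = {"s1": [ev("s1", [10_000_000])], "s2": [ev("s2", [90_000_000])]}
        tree = build_tree(["s1", "s2"], events)
        assert set(tree.nodes[tree.root].children) == {"anc0"}
        anc = tree.nodes["anc0"]
        assert set(anc.children) == {"s1", "s2"}

    def test_shared_marker_defines_clade(self):
        shared = [ev(s, [40_000_000]) for s in ("s1", "s2", "s3")]
        events = {
            "s1": [shared[0], ev("s1", [10_000_000], chrom="chr2")],
            "s2": [shared[1]],
            "s3": [shared[2]],
            "s4": [ev("s4", [80_000_000], chrom="chr3")],
        }
        tree = build_tree(list(events), events)
        clades = tree.clades()
        assert frozenset({"s1", "s2", "s3"}) in clades

    def test_branch_length_counts_altered_chromosomes(self):
        shared1 = [ev(s, [40_000_000], chrom="chr1") for s in ("s1", "s2")]
        shared2 = [ev(s, [20_000_000], chrom="chr2") for s in ("s1", "s2")]
        shared3 = [ev(s, [25_000_000], chrom="chr2", homolog="B") for s in ("s1", "s2")]
        events = {
            "s1": [shared1[0], shared2[0], shared3[0]],
            "s2": [shared1[1], shared2[1], shared3[1]],
            "s3": [ev("s3", [70_000_000], chrom="chr3")],
        }
        tree = build_tree(list(events), events)
        clade_node = next(nd for nd in tree.nodes.values() if nd.samples == frozenset({"s1", "s2"}))
        assert clade_node.branch_length == 2  # chr1 + chr2, two markers on chr2 count once

    def test_erasure_conflict_logged_not_silent(self):
        # an ancestral breakpoint erased by whole-chromosome loss in s3 makes
        # the marker look private to {s1,s2}; a second marker contradicts it
        m1 = [ev(s, [40_000_000], chrom="chr1") for s in ("s1", "s2")]
        m2 = [ev(s, [30_000_000], chrom="chr2") for s in ("s2", "s3")]
        m3 = [ev(s, [50_000_000], chrom="chr3") for s in ("s1", "s3")]
        events = {
            "s1": [m1[0], m3[0]],
            "s2": [m1[1], m2[0]],
            "s3": [m2[1], m3[1]],
        }
        tree = build_tree(["s1", "s2", "s3"], events)
        assert len(tree.conflicts) >= 1

    def test_recovers_simulated_topology_with_dendropy_oracle(self):
        import dendropy

        genome = human_autosome_genome(chrom_length=120_000_000, seed=0)
        menu = {"bfb_terminal": 2.0, "bfb_paracentric": 1.0, "focal_del": 1.0, "focal_dup": 1.0}
        exact = 0
        for seed in range(8):
            tree = simulate_clone_tree(
                genome, n_leaves=6, seed=500 + seed, min_events_per_branch=3,
                events_per_branch=3.0, event_menu=menu, wgd_prob=0.0, unique_targets=True,
            )
            events = {}
            for leaf in tree.leaves:
                evs = []
                for c in genome.chromosomes:
                    evs.extend(classify_chromosome(tree.nodes[leaf].karyotype, c, genome, sample=leaf))
                events[leaf] = evs
            inferred = build_tree(tree.leaves, events)
            tns = dendropy.TaxonNamespace()
            t1 = dendropy.Tree.get(data=tree.newick(), schema="newick", taxon_namespace=tns)
            t2 = dendropy.Tree.get(data=inferred.newick(), schema="newick", taxon_namespace=tns)
            t1.retain_taxa_with_labels(tree.leaves)
            t2.retain_taxa_with_labels(tree.leaves)
            t1.encode_bipartitions()
            t2.encode_bipartitions()
            rf = dendropy.calculate.treecompare.symmetric_difference(t1, t2)
            exact += rf == 0
        assert exact >= 7


class TestWgdPlacement:
    def _tree(self):
        events = {
            s: [ev(s, [40_000_000 + i * 7_000_000], chrom="chr1") for i in range(1)]
            for s in ("s1", "s2", "s3", "s4")
        }
        shared12 = [ev(s, [20_000_000], chrom="chr2") for s in ("s1", "s2")]
        shared34 = [ev(s, [60_000_000], chrom="chr3") for s in ("s3", "s4")]
        events["s1"].append(shared12[0])
        events["s2"].append(shared12[1])
        events["s3"].append(shared34[0])
        events["s4"].append(shared34[1])
        # distinct private markers so leaves differ
        for i, s in enumerate(("s1", "s2", "s3", "s4")):
            events[s].append(ev(s, [5_000_000 + i * 10_000_000], chrom="chr4"))
        return build_tree(list(events), events)

    def test_all_wgd_places_at_root_branch(self):
        tree = self._tree()
        assign_wgd_to_branches(tree, {s: True for s in ("s1", "s2", "s3", "s4")})
        top = [n for n in tree.nodes.values() if n.parent == tree.root]
        assert any(nd.wgd for nd in top)

    def test_disjoint_wgd_clades_get_independent_events(self):
        tree = self._tree()
        assign_wgd_to_branches(tree, {"s1": True, "s2": True, "s3": True, "s4": True and False})
        wgd_nodes = [n for n, nd in tree.nodes.items() if nd.wgd]
        # {s1,s2} clade plus the singleton s3 -> two independent placements
        assert len(wgd_nodes) == 2

    def test_no_wgd_no_placement(self):
        tree = self._tree()
        assign_wgd_to_branches(tree, {s: False for s in ("s1", "s2", "s3", "s4")})
        assert not any(nd.wgd for nd in tree.nodes.values())


class TestTiming:
    def test_two_copy_difference_is_pre_wgd(self, genome, diploid):
        k = apply_wgd(apply_bfb_break(diploid, "chr1", "A", 100_000_000)[0])
        (e,) = classify_chromosome(k, "chr1", genome, baseline=(2, 2))
        assert time_scna_vs_wgd(e, k, True) == "pre-WGD"

    def test_single_copy_difference_is_post_wgd(self, genome, diploid):
        k = apply_bfb_break(apply_wgd(diploid), "chr1", "A", 100_000_000)[0]
        (e,) = classify_chromosome(k, "chr1", genome, baseline=(2, 2))
        assert time_scna_vs_wgd(e, k, True) == "post-WGD"

    def test_whole_chromosome_final_state_one_is_post(self, genome, diploid):
        k = apply_missegregation(apply_wgd(diploid), "chr2", "A", -1)
        (e,) = classify_chromosome(k, "chr2", genome, baseline=(2, 2))
        assert time_scna_vs_wgd(e, k, True) == "post-WGD"

    def test_whole_chromosome_odd_state_is_post(self, genome, diploid):
        k = apply_missegregation(apply_wgd(diploid), "chr2", "A", +1)
        (e,) = classify_chromosome(k, "chr2", genome, baseline=(2, 2))
        assert time_scna_vs_wgd(e, k, True) == "post-WGD"

    def test_whole_chromosome_even_state_is_pre(self, genome, diploid):
        k = apply_wgd(apply_missegregation(diploid, "chr2", "A", +1))
        (e,) = classify_chromosome(k, "chr2", genome, baseline=(2, 2))
        assert time_scna_vs_wgd(e, k, True) == "pre-WGD"

    def test_na_without_wgd_on_lineage(self, genome, diploid):
        k = apply_bfb_break(diploid, "chr1", "A", 100_000_000)[0]
        (e,) = classify_chromosome(k, "chr1", genome)
        assert time_scna_vs_wgd(e, k, False) == "NA"


class TestSnvSimilarity:
    def test_asymmetric_set_arithmetic(self):
        sup = pd.DataFrame({"A": [5, 4, 3, 0], "B": [0, 6, 3, 9]}, index=list("wxyz"))
        m = snv_similarity(sup)
        assert m.loc["A", "B"] == pytest.approx(2 / 3)
        assert m.loc["B", "A"] == pytest.approx(2 / 3)

    def test_identical_sets_give_one(self):
        sup = pd.DataFrame({"A": [5, 4], "B": [9, 3]})
        m = snv_similarity(sup)
        assert m.loc["A", "B"] == 1.0 and m.loc["B", "A"] == 1.0

    def test_min_support_threshold(self):
        sup = pd.DataFrame({"A": [2, 4], "B": [5, 4]})
        m = snv_similarity(sup, min_support=3)
        assert m.loc["A", "B"] == 1.0  # A only has the second variant

    def test_empty_sample_gets_zero(self):
        sup = pd.DataFrame({"A": [0, 0], "B": [5, 4]})
        m = snv_similarity(sup)
        assert m.loc["A", "B"] == 0.0
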