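import itertools

import numpy as np
import pytest

from syntelog_phylo.core_io import GeneTree
from syntelog_phylo.errors import UndefinedComparisonError, ValidationError
from syntelog_phylo.treecompare import (Bipartition, are_compatible,
                                        bin_topologies, bipartitions,
                                        classify_bins_by_reference,
                                        rf_distance, splits_compatible)

from conftest import random_binary_tree


def bp(side, taxa, support=None):
    return Bipartition(frozenset(side), frozenset(taxa), support)


class TestBipartitions:
    def test_four_taxon_tree_has_single_split(self):
        t = GeneTree.from_newick("((A,B),(C,D));")
        (split,) = bipartitions(t)
        assert split.side == frozenset({"C", "D"})

    def test_support_cutoff_contracts_weak_branches(self):
        t = GeneTree.from_newick("((A,B)60,(C,D)100,E);")
        all_sides = {b.side for b in bipartitions(t)}
        assert all_sides == {frozenset("CDE"), frozenset("CD")}
        strong = {b.side for b in bipartitions(t, min_support=100)}
        assert strong == {frozenset("CD")}

    def test_star_tree_has_no_splits(self):
        t = GeneTree.from_newick("(A,B,C,D,E);")
        assert bipartitions(t) == set()


class TestRFDistance:
    def test_identical_trees_distance_zero(self):
        t = GeneTree.from_newick("((A,B),(C,D),(E,F));")
        assert rf_distance(t, t) == 0.0

    def test_alternative_quartets_are_maximally_distant(self):
        t1 = GeneTree.from_newick("((A,B),(C,D));")
        t2 = GeneTree.from_newick("((A,C),(B,D));")
        assert rf_distance(t1, t2, "absolute") == 2.0
        assert rf_distance(t1, t2, "normalized") == 1.0

    def test_six_taxon_caterpillars(self):
        # splits {AB, ABC, ABCD} vs {AB, ABC, DE}: symmetric difference 2
        t1 = GeneTree.from_newick("((((A,B),C),D),E,F);")
        t2 = GeneTree.from_newick("(((A,B),C),(D,E),F);")
        assert rf_distance(t1, t2, "absolute") == 2.0

    def test_distinct_leaf_sets_pruned_to_shared(self):
        t1 = GeneTree.from_newick("((A,B),(C,D),X);")
        t2 = GeneTree.from_newick("((A,B),(C,D),Y);")
        assert rf_distance(t1, t2) == 0.0

    def test_too_few_shared_leaves_is_undefined(self):
        t1 = GeneTree.from_newick("((A,B),(C,X1),X2);")
        t2 = GeneTree.from_newick("((A,B),(C,Y1),Y2);")
        with pytest.raises(UndefinedComparisonError):
            rf_distance(t1, t2)

    def test_metric_axioms_against_brute_force(self, rng):
        labels = [f"s{i}" for i in range(8)]
        for _ in range(40):
            t1, t2, t3 = (random_binary_tree(labels, rng, f"t{k}")
                          for k in range(3))
            d12 = rf_distance(t1, t2)
            d21 = rf_distance(t2, t1)
            assert d12 == d21 == len(_naive_splits(t1) ^ _naive_splits(t2))
            assert rf_distance(t1, t3) <= d12 + rf_distance(t2, t3)
            assert rf_distance(t1, t1) == 0.0


def _naive_splits(tree):
    """Independent split computation: all leaf subsets below each internal
    node of the (rooted representation) tree, canonicalized by min-leaf."""
    leaves = tree.leaves
    ref = min(leaves)
    out = set()
    dt = tree.dendropy_tree
    for nd in dt.postorder_internal_node_iter():
        if nd is dt.seed_node:
            continue
        below = frozenset(lf.taxon.label for lf in nd.leaf_iter())
        side = below if ref not in below else leaves - below
        if 1 < len(side) < len(leaves) - 1:
            out.add(side)
    return out


class TestCompatibility:
    TAXA = frozenset("ABCDE")

    def test_identical_splits_compatible(self):
        s = [bp("AB", self.TAXA)]
        assert are_compatible(s, s)

    def test_crossing_splits_incompatible(self):
        assert not are_compatible([bp("AB", self.TAXA)], [bp("AC", self.TAXA)])
        assert not splits_compatible(frozenset("AB"), frozenset("AC"), self.TAXA)

    def test_nested_and_disjoint_splits_compatible(self):
        assert are_compatible([bp("AB", self.TAXA)], [bp("DE", self.TAXA)])

    def test_mismatched_taxon_sets_rejected(self):
        with pytest.raises(ValidationError, match="prune"):
            are_compatible([bp("AB", "ABCDE")], [bp("AB", "ABCDEF")])

    def test_compatible_iff_joint_tree_exists_on_five_taxa(self):
        # exhaustive cross-check: two splits are compatible exactly when some
        # unrooted 5-taxon tree displays both
        from conftest import enumerate_unrooted_trees
        labels = list("ABCDE")
        split_sets = [s for _, s in enumerate_unrooted_trees(labels)]
        # canonical nontrivial sides never contain the smallest taxon 'A'
        sides = [frozenset(c) for k in (2, 3)
                 for c in itertools.combinations("BCDE", k)]
        for s1 in sides:
            for s2 in sides:
                joint = any({s1, s2} <= s for s in split_sets)
                assert splits_compatible(s1, s2, frozenset(labels)) == joint


class TestBinning:
    def test_identical_fully_supported_trees_share_one_bin(self):
        trees = [GeneTree.from_newick("((A,B)100,(C,D)100,E);", f"t{i}")
                 for i in range(2)]
        (b,) = bin_topologies(trees, support_cutoff=100)
        assert b.size == 2

    def test_incompatible_supported_topologies_split_bins(self):
        t1 = GeneTree.from_newick("((A,B)100,(C,D)100,E);", "t1")
        t2 = GeneTree.from_newick("((A,C)100,(B,D)100,E);", "t2")
        bins = bin_topologies([t1, t2], support_cutoff=100)
        assert len(bins) == 2

    def test_unconstrained_tree_joins_first_bin(self):
        t1 = GeneTree.from_newick("((A,B)100,(C,D)100,E);", "t1")
        t2 = GeneTree.from_newick("((A,C)50,(B,D)60,E);", "t2")
        bins = bin_topologies([t1, t2], support_cutoff=100)
        assert len(bins) == 1 and bins[0].size == 2

    def test_bins_partition_the_input(self, rng):
        labels = list("ABCDEF")
        trees = []
        for i in range(20):
            t = random_binary_tree(labels, rng, f"g{i:02d}")
            # give every branch full support
            for nd in t.dendropy_tree.preorder_internal_node_iter():
                if nd is not t.dendropy_tree.seed_node:
                    nd.label = "100"
            trees.append(t)
        bins = bin_topologies(trees, support_cutoff=100)
        all_members = [m for b in bins for m in b.members]
        assert sorted(all_members) == sorted(t.tree_id for t in trees)

    def test_k_incompatible_topologies_make_k_bins(self):
        newicks = ["((A,B)100,(C,D)100,E);",
                   "((A,C)100,(B,D)100,E);",
                   "((A,D)100,(B,C)100,E);"]
        trees = [GeneTree.from_newick(n, f"t{i}") for i, n in enumerate(newicks)]
        assert len(bin_topologies(trees, support_cutoff=100)) == 3


class TestClassifyBins:
    def test_exact_reference_match_and_unresolved(self):
        t1 = GeneTree.from_newick("((A,B)100,(C,D)100,E);", "t1")
        t2 = GeneTree.from_newick("((A,C)40,(B,D)40,E);", "t2")
        bins = bin_topologies([t1], support_cutoff=100) + \
            bin_topologies([t2], support_cutoff=100)
        bins[1].bin_id = "bin_002"
        refs = {"primary": {frozenset("CD")}}
        labels = classify_bins_by_reference(bins, refs)
        assert labels["bin_001"] == "primary"
        assert labels["bin_002"] == "unresolved"

    def test_overlapping_references_rejected(self):
        t1 = GeneTree.from_newick("((A,B)100,(C,D)100,E);", "t1")
        bins = bin_topologies([t1], support_cutoff=100)
        refs = {"x": {frozenset("CD")}, "y": {frozenset("CD")}}
        with pytest.raises(ValidationError, match="mutually exclusive"):
            classify_bins_by_reference(bins, refs)

    def test_mixture_recovers_source_proportions(self, rng):
        # genes drawn 60/40 from two fully supported topologies
        n1, n2 = 60, 40
        trees = []
        for i in range(n1):
            trees.append(GeneTree.from_newick(
                "((A,B)100,(C,D)100,E);", f"m{i:03d}"))
        for i in range(n2):
            trees.append(GeneTree.from_newick(
                "((A,C)100,(B,D)100,E);", f"z{i:03d}"))
        bins = bin_topologies(trees, support_cutoff=100)
        refs = {"topo1": {frozenset("CD")}, "topo2": {frozenset(["B", "D"])}}
        labels = classify_bins_by_reference(bins, refs)
        counts = {}
        for b in bins:
            counts[labels[b.bin_id]] = counts.get(labels[b.bin_id], 0) + b.size
        assert counts == {"topo1": 60, "topo2": 40}
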