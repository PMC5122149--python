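"""Tree-engine tests: NJ against closed forms and generating-tree oracles,
Robinson-Foulds against independent bipartition enumeration, bootstrap
behavior, outgroup rooting, and long-branch flagging."""

import itertools
import math

import dendropy
import numpy as np
import pytest

from chsphylo.io import Alignment, parse_newick
from chsphylo.oracles import patristic_matrix, random_unrooted_tree
from chsphylo.phylo import (DistanceMatrix, OutgroupError,
                            UndefinedDistanceError, bipartitions,
                            bootstrap_support, flag_long_branches, nj_tree,
                            pairwise_distance, rf_distance, root_by_outgroup)


class TestPairwiseDistance:
    def test_identical_rows_distance_zero(self):
        aln = Alignment(["a", "b", "c"], ["ACDEF", "ACDEF", "ACDEF"])
        dm = pairwise_distance(aln, "p")
        assert np.allclose(dm.matrix, 0.0)

    def test_hand_counted_p_and_poisson(self):
        aln = Alignment(["a", "b", "c"],
                        ["ACDEFGHIKL", "ACDEFYYYYY", "ACDEFGHIKL"])
        p = pairwise_distance(aln, "p").matrix[0, 1]
        assert p == pytest.approx(0.5)
        poisson = pairwise_distance(aln, "poisson").matrix[0, 1]
        assert poisson == pytest.approx(-math.log(0.5))

    def test_gap_only_overlap_names_the_pair(self):
        aln = Alignment(["a", "b", "c"], ["AC--", "--DE", "ACDE"])
        with pytest.raises(UndefinedDistanceError) as err:
            pairwise_distance(aln, "p")
        assert err.value.pair == ("a", "b")

    def test_saturated_pair_rejected_under_poisson(self):
        aln = Alignment(["a", "b", "c"], ["AAAA", "CCCC", "AAAC"])
        with pytest.raises(UndefinedDistanceError):
            pairwise_distance(aln, "poisson")


class TestNeighborJoining:
    def test_three_taxon_closed_form(self):
        D = np.array([[0.0, 0.3, 0.5],
                      [0.3, 0.0, 0.6],
                      [0.5, 0.6, 0.0]])
        t = nj_tree(DistanceMatrix(["a", "b", "c"], D))
        bl = {lf.taxon.label: lf.edge.length for lf in t.leaf_node_iter()}
        assert bl["a"] == pytest.approx((0.3 + 0.5 - 0.6) / 2)
        assert bl["b"] == pytest.approx((0.3 + 0.6 - 0.5) / 2)
        assert bl["c"] == pytest.approx((0.5 + 0.6 - 0.3) / 2)

    def test_five_taxon_additive_recovery_with_lengths(self, rng):
        labels = [f"L{i}" for i in range(5)]
        gen = random_unrooted_tree(labels, rng)
        D = patristic_matrix(gen, labels)
        t = nj_tree(DistanceMatrix(labels, D))
        assert rf_distance(t, gen) == 0
        assert np.allclose(patristic_matrix(t, labels), D, atol=1e-9)

    def test_additive_matrices_recover_topology(self, rng):
        # property over 100 random trees, 4-12 taxa
        for _ in range(100):
            n = int(rng.integers(4, 13))
            labels = [f"L{i:02d}" for i in range(n)]
            gen = random_unrooted_tree(labels, rng)
            D = patristic_matrix(gen, labels)
            assert rf_distance(nj_tree(DistanceMatrix(labels, D)), gen) == 0

    def test_asymmetric_matrix_rejected(self):
        D = np.array([[0.0, 0.3, 0.5],
                      [0.2, 0.0, 0.6],
                      [0.5, 0.6, 0.0]])
        with pytest.raises(ValueError):
            nj_tree(DistanceMatrix(["a", "b", "c"], D))

    def test_deterministic_tie_breaking(self):
        # fully symmetric distances: every Q entry ties; lexicographically
        # smallest pair must merge first, making output reproducible
        labels = list("dcba")
        D = np.full((4, 4), 1.0)
        np.fill_diagonal(D, 0.0)
        t1 = nj_tree(DistanceMatrix(labels, D.copy()))
        t2 = nj_tree(DistanceMatrix(labels, D.copy()))
        assert (t1.as_string(schema="newick")
                == t2.as_string(schema="newick"))
        cherry = min((sorted(lf.taxon.label for lf in nd.leaf_iter())
                      for nd in t1.preorder_node_iter()
                      if not nd.is_leaf() and nd.parent_node is not None),
                     key=len)
        assert cherry == ["a", "b"]


class TestRfDistance:
    def test_identical_trees_zero(self):
        t1 = parse_newick("((a,b),(c,d));")
        t2 = parse_newick("((a,b),(c,d));")
        assert rf_distance(t1, t2) == 0

    def test_alternative_quartet_resolutions(self):
        t1 = parse_newick("((a,b),(c,d));")
        t2 = parse_newick("((a,c),(b,d));")
        assert rf_distance(t1, t2) == 2

    def test_label_mismatch_rejected(self):
        with pytest.raises(ValueError):
            rf_distance(parse_newick("((a,b),(c,d));"),
                        parse_newick("((a,b),(c,e));"))

    def test_random_pairs_match_bruteforce_enumeration(self, rng):
        labels = [f"L{i}" for i in range(8)]

        def oracle_bips(tree):
            # independent enumeration: for every internal edge, collect the
            # leaf set on each side via explicit set arithmetic
            all_leaves = frozenset(lf.taxon.label
                                   for lf in tree.leaf_node_iter())
            out = set()
            for nd in tree.preorder_node_iter():
                if nd.parent_node is None or nd.is_leaf():
                    continue
                below = frozenset(lf.taxon.label for lf in nd.leaf_iter())
                if 2 <= len(below) <= len(all_leaves) - 2:
                    out.add(frozenset({below, all_leaves - below}))
            return out

        for _ in range(25):
            t1 = random_unrooted_tree(labels, rng)
            t2 = random_unrooted_tree(labels, rng)
            assert rf_distance(t1, t2) == len(
                oracle_bips(t1) ^ oracle_bips(t2))

    def test_metric_axioms_on_random_triples(self, rng):
        labels = [f"L{i}" for i in range(7)]
        for _ in range(10):
            a, b, c = (random_unrooted_tree(labels, rng) for _ in range(3))
            assert rf_distance(a, a) == 0
            assert rf_distance(a, b) == rf_distance(b, a)
            assert (rf_distance(a, c)
                    <= rf_distance(a, b) + rf_distance(b, c))


class TestBootstrap:
    def test_deep_split_saturates_support(self, class_dataset):
        tree = bootstrap_support(class_dataset.alignment, n_reps=50,
                                 correction="p", seed=4)
        truth = {}
        for g in class_dataset.genes:
            if g.true_class:
                truth.setdefault(g.true_class, set()).add(g.gene_id)
        supports = tree.bipartition_supports
        leaves = frozenset(lf.taxon.label for lf in tree.leaf_node_iter())
        for members in truth.values():
            bp = frozenset({frozenset(members), leaves - frozenset(members)})
            assert supports.get(bp, 0) >= 95

    def test_single_replicate_support_extremes(self, std_dataset):
        tree = bootstrap_support(std_dataset.alignment, n_reps=1,
                                 correction="p", seed=7)
        assert set(tree.bipartition_supports.values()) <= {0, 100}

    def test_fixed_seed_reproducible(self, std_dataset):
        t1 = bootstrap_support(std_dataset.alignment, 20, "p", seed=9)
        t2 = bootstrap_support(std_dataset.alignment, 20, "p", seed=9)
        assert t1.bipartition_supports == t2.bipartition_supports

    def test_supports_bounded_and_stable(self, std_dataset):
        runs = [bootstrap_support(std_dataset.alignment, 200, "p", seed=s)
                for s in (1, 2)]
        for t in runs:
            assert all(0 <= v <= 100 for v in t.bipartition_supports.values())
        common = (set(runs[0].bipartition_supports)
                  & set(runs[1].bipartition_supports))
        for bp in common:
            assert abs(runs[0].bipartition_supports[bp]
                       - runs[1].bipartition_supports[bp]) < 5


class TestOutgroupRooting:
    def test_rooting_on_quartet(self):
        t = parse_newick("((a:1,b:1):1,(c:1,d:1):1);", rooted=False)
        rooted = root_by_outgroup(t, {"c", "d"})
        assert rooted.is_rooted
        kids = [sorted(lf.taxon.label for lf in ch.leaf_iter())
                for ch in rooted.seed_node.child_nodes()]
        assert sorted(kids) == [["a", "b"], ["c", "d"]]

    def test_non_monophyletic_outgroup_names_intruders(self):
        t = parse_newick("((a:1,b:1):1,(c:1,d:1):1);", rooted=False)
        with pytest.raises(OutgroupError) as err:
            root_by_outgroup(t, {"a", "c"})
        assert set(err.value.intruders) & {"b", "d"}

    def test_simulated_root_recovers_true_split(self, std_dataset):
        ds = std_dataset
        tree = bootstrap_support(ds.alignment, 20, "p", seed=3)
        rooted = root_by_outgroup(tree, ds.outgroup_ids)
        kids = [frozenset(lf.taxon.label for lf in ch.leaf_iter())
                for ch in rooted.seed_node.child_nodes()]
        assert frozenset(ds.outgroup_ids) in kids

    def test_supports_preserved_across_rooting(self, std_dataset):
        tree = bootstrap_support(std_dataset.alignment, 20, "p", seed=3)
        before = dict(tree.bipartition_supports)
        rooted = root_by_outgroup(tree, std_dataset.outgroup_ids)
        assert rooted.bipartition_supports == before
        assert set(bipartitions(rooted)) <= set(before) | set()


class TestLongBranches:
    def test_star_like_tree_flags_nothing(self):
        t = parse_newick("(a:1,b:1,c:1,d:1);", rooted=False)
        assert flag_long_branches(t) == []

    def test_single_outlier_flagged(self):
        t = parse_newick("((a:1,b:1):0.5,(c:1,d:10):0.5);", rooted=False)
        assert flag_long_branches(t, k=4) == ["d"]

    def test_fast_evolving_duplicate_flagged(self, rng):
        # one leaf's terminal branch inflated 8x, as for a fast paralog
        labels = [f"L{i}" for i in range(8)]
        t = random_unrooted_tree(labels, rng, blmin=0.2, blmax=0.4)
        victim = next(lf for lf in t.leaf_node_iter()
                      if lf.taxon.label == "L3")
        victim.edge.length *= 8 * 4
        assert flag_long_branches(t, k=4) == ["L3"]
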