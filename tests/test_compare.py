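"""Robinson-Foulds scoring, consensus marks, deep nodes, benchmark runner."""

import itertools

import numpy as np
import pytest
from conftest import random_binary_tree

from phyrn.compare import (benchmark_run, consensus_marks, deep_node_recap,
                           deep_nodes, max_rf, rf_distance)
from phyrn.simulate import generate_tree
from phyrn.tree import Node, PhyloTree


def caterpillar(order):
    """Caterpillar tree joining leaves in the given label order."""
    clade = Node(order[0], 1.0)
    for lab in order[1:]:
        parent = Node(length=1.0)
        parent.add_child(clade)
        parent.add_child(Node(lab, 1.0))
        clade = parent
    return PhyloTree(clade)


def all_six_leaf_topologies():
    """All 105 unrooted binary topologies on 6 leaves by edge insertion."""
    labels = [f"l{i}" for i in range(6)]

    def insert_everywhere(edges, next_leaf):
        # edges: list of frozenset pairs over node ids; nodes are ints/labels
        out = []
        for k in range(len(edges)):
            a, b = edges[k]
            new_internal = ("int", next_leaf, k)
            new_edges = edges[:k] + edges[k + 1:]
            new_edges += [(a, new_internal), (new_internal, b),
                          (new_internal, labels[next_leaf])]
            out.append(new_edges)
        return out

    start = [("c", labels[0]), ("c", labels[1]), ("c", labels[2])]
    pool = [start]
    for leaf in range(3, 6):
        pool = [e for edges in pool for e in insert_everywhere(edges, leaf)]
    return pool, labels


def splits_by_graph_cut(edges, labels):
    """Non-trivial splits via BFS on the edge graph with one edge removed
    (independent of PhyloTree's recursive clade collection)."""
    adjacency = {}
    for a, b in edges:
        adjacency.setdefault(a, set()).add(b)
        adjacency.setdefault(b, set()).add(a)
    label_set = set(labels)
    splits = set()
    for cut in edges:
        a, b = cut
        seen = {a}
        stack = [a]
        while stack:
            node = stack.pop()
            for nxt in adjacency[node]:
                if nxt not in seen and {node, nxt} != {a, b}:
                    seen.add(nxt)
                    stack.append(nxt)
        side = frozenset(x for x in seen if x in label_set)
        if 2 <= len(side) <= len(labels) - 2:
            splits.add(frozenset({side, frozenset(label_set - side)}))
    return splits


def edges_to_phylotree(edges, labels):
    adjacency = {}
    for a, b in edges:
        adjacency.setdefault(a, []).append(b)
        adjacency.setdefault(b, []).append(a)

    def build(node, parent):
        out = Node(node if node in labels else None, 1.0)
        for nxt in adjacency[node]:
            if nxt != parent:
                out.add_child(build(nxt, node))
        return out

    root = build("c", None)
    return PhyloTree(root, rooted=False)


class TestRfDistance:
    def test_tree_vs_itself_is_zero(self):
        rng = np.random.default_rng(0)
        for n in (5, 20, 60):
            tree = random_binary_tree(n, rng)
            assert rf_distance(tree, tree.copy()) == 0

    def test_five_leaf_disjoint_pair(self):
        # each tree has n-3 = 2 non-trivial splits and none are shared
        t1 = PhyloTree.from_newick("((A:1,B:1):1,(C:1,D:1):1,E:1);")
        t2 = PhyloTree.from_newick("((A:1,C:1):1,(B:1,D:1):1,E:1);")
        assert rf_distance(t1, t2) == 4

    def test_leaf_set_mismatch_rejected(self):
        t1 = PhyloTree.from_newick("((A:1,B:1):1,(C:1,D:1):1);")
        t2 = PhyloTree.from_newick("((A:1,B:1):1,(C:1,E:1):1);")
        with pytest.raises(ValueError):
            rf_distance(t1, t2)

    def test_exhaustive_six_leaf_agreement_with_graph_cut_oracle(self):
        pool, labels = all_six_leaf_topologies()
        assert len(pool) == 105
        trees = [edges_to_phylotree(e, labels) for e in pool]
        split_sets = [splits_by_graph_cut(e, labels) for e in pool]
        for (ti, si), (tj, sj) in itertools.combinations(
                zip(trees, split_sets), 2):
            assert rf_distance(ti, tj) == len(si ^ sj)
        # identical topologies give zero through both routes
        for tree, splits in zip(trees[:10], split_sets[:10]):
            assert rf_distance(tree, tree.copy()) == 0 == len(splits ^ splits)

    def test_agrees_with_dendropy_on_random_pairs(self):
        import dendropy

        rng = np.random.default_rng(7)
        ns = dendropy.TaxonNamespace()
        for _ in range(20):
            a = random_binary_tree(12, rng)
            b = random_binary_tree(12, rng)
            da = dendropy.Tree.get(data=a.to_newick(), schema="newick",
                                   taxon_namespace=ns)
            db = dendropy.Tree.get(data=b.to_newick(), schema="newick",
                                   taxon_namespace=ns)
            expected = dendropy.calculate.treecompare.symmetric_difference(
                da, db)
            assert rf_distance(a, b) == expected

    def test_metric_properties_on_random_triples(self):
        rng = np.random.default_rng(5)
        for _ in range(15):
            a, b, c = (random_binary_tree(8, rng) for _ in range(3))
            assert rf_distance(a, b) == rf_distance(b, a)
            assert rf_distance(a, c) <= rf_distance(a, b) + rf_distance(b, c)

    @pytest.mark.parametrize("n", [10, 100])
    def test_disjoint_caterpillars_achieve_the_maximum(self, n):
        labels = [f"t{i}" for i in range(n)]
        interleaved = labels[::2] + labels[1::2]
        t1, t2 = caterpillar(labels), caterpillar(interleaved)
        assert rf_distance(t1, t2) == max_rf(n)


class TestMaxRf:
    @pytest.mark.parametrize("n,expected", [(4, 2), (100, 194), (1000, 1994)])
    def test_formula(self, n, expected):
        assert max_rf(n) == expected

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            max_rf(3)

    def test_upper_bounds_random_pairs(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            a, b = random_binary_tree(15, rng), random_binary_tree(15, rng)
            assert rf_distance(a, b) <= max_rf(15)


class TestConsensusMarks:
    def test_identical_trees_all_100(self):
        tree = generate_tree(16, "balanced", 0)
        marks = consensus_marks(tree, tree.copy())
        values = [n.support for n in marks.internal_nodes()
                  if n.support is not None]
        assert values and set(values) == {100.0}

    def test_fifty_marks_count_is_half_rf(self):
        t1 = PhyloTree.from_newick("((A:1,B:1):1,(C:1,D:1):1,E:1);")
        t2 = PhyloTree.from_newick("((A:1,C:1):1,(B:1,D:1):1,E:1);")
        marks = consensus_marks(t1, t2)
        values = [n.support for n in marks.internal_nodes()
                  if n.support is not None]
        assert sorted(values) == [50.0, 50.0]
        assert sum(v == 50.0 for v in values) == rf_distance(t1, t2) // 2

    def test_single_nni_gives_one_50_and_half_rf(self):
        rest = "(x0:1,(x1:1,(x2:1,(x3:1,(x4:1,x5:1):1):1):1):1)"
        t1 = PhyloTree.from_newick(f"(((A:1,B:1):1,(C:1,D:1):1):1,{rest});")
        t2 = PhyloTree.from_newick(f"(((A:1,(C:1,D:1):1):1,B:1):1,{rest});")
        # NNI swapped B with the (C,D) clade: one bipartition changed per tree
        assert rf_distance(t1, t2) == 2
        marks = consensus_marks(t1, t2)
        fifties = [n for n in marks.internal_nodes() if n.support == 50.0]
        assert len(fifties) == rf_distance(t1, t2) // 2


class TestDeepNodes:
    def test_balanced_eight_has_three_deep_nodes(self):
        tree = generate_tree(8, "balanced", 0)
        clades = deep_nodes(tree)
        sizes = sorted(len(c) for c in clades)
        assert sizes == [4, 4, 8]  # the root's children and the root

    def test_identical_balanced_sixteen_full_recap(self):
        tree = generate_tree(16, "balanced", 0)
        assert deep_node_recap(tree, tree.copy()) == 100.0

    def test_cross_root_cherry_swap_lowers_recap(self):
        tree = generate_tree(16, "balanced", 0)
        other = tree.copy()
        # swap one cherry from each side of the root
        left, right = other.root.children

        def first_cherry(node):
            for cand in PhyloTree(node).internal_nodes():
                if all(c.is_leaf for c in cand.children):
                    return cand
            raise AssertionError

        ca, cb = first_cherry(left), first_cherry(right)
        pa, pb = ca.parent, cb.parent
        ia, ib = pa.children.index(ca), pb.children.index(cb)
        pa.children[ia], pb.children[ib] = cb, ca
        ca.parent, cb.parent = pb, pa
        recap = deep_node_recap(tree, other)
        assert recap < 100.0
        # audit: recomputed directly from clade membership in the estimate
        est_splits = other.bipartitions()
        labels = set(tree.leaf_labels())
        ref = min(labels)
        hits = total = 0
        for clade in deep_nodes(tree):
            total += 1
            if len(clade) >= len(labels) - 1:
                hits += 1
                continue
            side = clade if ref not in clade else labels - clade
            hits += frozenset(side) in est_splits
        assert recap == pytest.approx(100.0 * hits / total)

    def test_star_tree_without_deep_nodes_rejected(self):
        root = Node()
        for lab in "ABCD":
            root.add_child(Node(lab, 1.0))
        star = PhyloTree(root, rooted=False)
        with pytest.raises(ValueError):
            deep_node_recap(star, star.copy())


class TestBenchmarkRun:
    def test_low_divergence_recovers_truth(self):
        result = benchmark_run(
            [30.0], replicates=2,
            methods=["phyrn_nj", "true_alignment_pdistance_nj",
                     "pairwise_pdistance_nj"],
            n_taxa=8, mean_seq_len=300, topology_mode="balanced", seed=1,
        )
        assert (result.table["rf"] == 0).all()

    def test_deterministic_under_fixed_seed(self):
        kwargs = dict(
            divergence_levels=[150.0], replicates=2,
            methods=["true_alignment_pdistance_nj"],
            n_taxa=8, mean_seq_len=120, seed=3,
        )
        a, b = benchmark_run(**kwargs), benchmark_run(**kwargs)
        assert a.table.equals(b.table)
        assert a.summary.equals(b.summary)

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            benchmark_run([], 1, ["phyrn_nj"])
        with pytest.raises(ValueError, match="unknown"):
            benchmark_run([100.0], 1, ["raxml"])
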