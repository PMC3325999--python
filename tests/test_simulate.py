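"""Tree generation, sequence evolution, and divergence statistics."""

import numpy as np
import pytest
import scipy.linalg

from phyrn import dayhoff
from phyrn.simulate import (DivergenceStats, SimConfig, alignment_identity_matrix,
                            evolve_family, family_stats, generate_tree,
                            scale_tree, simulate_family)
from phyrn.tree import Node, PhyloTree


class TestGenerateTree:
    def test_rejects_tiny_trees(self):
        with pytest.raises(ValueError):
            generate_tree(3, "yule", 0)

    @pytest.mark.parametrize("mode", ["yule", "balanced", "pectinate"])
    @pytest.mark.parametrize("n", [4, 7, 25])
    def test_valid_ultrametric_unit_depth(self, mode, n):
        tree = generate_tree(n, mode, seed=3)
        tree.validate()
        assert tree.n_leaves() == n
        assert tree.is_ultrametric()
        depths = tree.leaf_depths()
        assert max(depths.values()) == pytest.approx(1.0)

    def test_balanced_four_taxa_is_symmetric(self):
        tree = generate_tree(4, "balanced", 0)
        # ((A,B),(C,D)): the only non-trivial split pairs two cherries
        splits = tree.bipartitions()
        assert len(splits) == 1
        assert len(next(iter(splits))) == 2

    def test_pectinate_has_single_cherry(self):
        tree = generate_tree(8, "pectinate", 0)
        cherries = [
            n for n in tree.internal_nodes()
            if all(c.is_leaf for c in n.children)
        ]
        assert len(cherries) == 1

    def test_same_seed_same_tree(self):
        a = generate_tree(100, "yule", seed=1)
        b = generate_tree(100, "yule", seed=1)
        assert a.to_newick() == b.to_newick()

    def test_different_seed_different_yule_tree(self):
        a = generate_tree(50, "yule", seed=1)
        b = generate_tree(50, "yule", seed=2)
        assert a.to_newick() != b.to_newick()


class TestScaleTree:
    def test_balanced_tree_hits_target_exactly(self):
        tree = scale_tree(generate_tree(4, "balanced", 0), 700.0)
        assert tree.mean_pairwise_distance() == pytest.approx(700.0, rel=1e-9)

    def test_identity_when_target_is_current_mean(self):
        tree = generate_tree(10, "yule", 5)
        target = tree.mean_pairwise_distance()
        rescaled = scale_tree(tree, target)
        for a, b in zip(tree.preorder(), rescaled.preorder()):
            assert a.length == pytest.approx(b.length, rel=1e-12)

    def test_yule_100_recomputed_over_all_pairs(self, small_family):
        tree = scale_tree(generate_tree(100, "yule", 1), 550.0)
        from conftest import tree_path_distances

        _, d = tree_path_distances(tree)
        iu = np.triu_indices(100, 1)
        assert d[iu].mean() == pytest.approx(550.0, abs=1e-6)

    def test_zero_length_tree_cannot_scale(self):
        root = Node()
        for lab in "ABCD":
            root_child = Node(lab, 0.0)
            root.add_child(root_child)
        with pytest.raises(ValueError, match="zero"):
            scale_tree(PhyloTree(root, rooted=False), 100.0)


class TestEvolveFamily:
    CFG = dict(n_taxa=4, mean_pairwise_pam=100.0, mean_seq_len=80)

    def test_zero_branch_lengths_give_identical_leaves(self):
        tree = generate_tree(6, "balanced", 0).scaled(0.0)
        fam = evolve_family(tree, SimConfig(n_taxa=6, mean_pairwise_pam=1.0,
                                            mean_seq_len=60, seed=1))
        seqs = set(fam.leaf_sequences.values())
        assert len(seqs) == 1
        stats = family_stats(fam)
        assert stats.mean_pairwise_identity == 1.0

    def test_no_indels_means_no_gaps(self):
        fam = simulate_family(SimConfig(
            n_taxa=8, mean_pairwise_pam=300, mean_seq_len=100,
            indel_to_substitution_ratio=0.0, seed=2))
        assert all("-" not in row for row in fam.true_alignment.values())
        stats = family_stats(fam)
        assert stats.indel_events_per_position == 0
        assert stats.avg_gap_length == 0
        assert stats.isr == 0

    def test_ungapping_rows_recovers_sequences(self):
        for seed in range(3):
            fam = simulate_family(SimConfig(
                n_taxa=12, mean_pairwise_pam=400, mean_seq_len=90,
                indel_to_substitution_ratio=0.1, seed=seed))
            for label, row in fam.true_alignment.items():
                assert row.replace("-", "") == fam.leaf_sequences[label]
            lengths = {len(r) for r in fam.true_alignment.values()}
            assert len(lengths) == 1

    def test_same_seed_byte_identical_family(self):
        cfg = SimConfig(n_taxa=10, mean_pairwise_pam=250, mean_seq_len=100,
                        indel_to_substitution_ratio=0.05, seed=9)
        a, b = simulate_family(cfg), simulate_family(cfg)
        assert a.leaf_sequences == b.leaf_sequences
        assert a.true_alignment == b.true_alignment
        assert a.event_log == b.event_log
        assert a.true_tree.to_newick() == b.true_tree.to_newick()

    def test_two_taxon_identity_matches_matrix_power_oracle(self):
        """Sampled site identity agrees with sum_i f_i [P1^d]_ii, with P1^d
        computed by repeated matrix multiplication of expm(Q) (a route
        independent of the evolver's spectral powers)."""
        d = 160
        pam1 = scipy.linalg.expm(dayhoff._rate_matrix())
        expected = float(
            (dayhoff.EQUILIBRIUM_FREQS
             * np.diag(np.linalg.matrix_power(pam1, d))).sum())
        cfg = SimConfig(n_taxa=4, mean_pairwise_pam=float(d), mean_seq_len=450)
        idents = []
        n_sites = 0
        for seed in range(10):
            root = Node()
            a = Node("A", d / 2)
            b = Node("B", d / 2)
            root.add_child(a)
            root.add_child(b)
            fam = evolve_family(
                PhyloTree(root),
                SimConfig(n_taxa=4, mean_pairwise_pam=float(d),
                          mean_seq_len=450, seed=seed))
            sa, sb = fam.leaf_sequences["A"], fam.leaf_sequences["B"]
            idents.append(sum(x == y for x, y in zip(sa, sb)))
            n_sites += len(sa)
        phat = sum(idents) / n_sites
        se = np.sqrt(expected * (1 - expected) / n_sites)
        assert abs(phat - expected) < 3 * se


class TestFamilyStats:
    def test_pairwise_identity_excludes_gap_columns(self):
        ident = alignment_identity_matrix({"a": "ACDE-", "b": "ACD-F"})
        assert ident[0, 1] == 1.0  # 3 identical over the 3 residue-residue cols

    def test_identity_counts_mismatches(self):
        ident = alignment_identity_matrix({"a": "ACDEF", "b": "ACDGG"})
        assert ident[0, 1] == pytest.approx(3 / 5)

    def test_empty_alignment_rejected(self, small_family):
        import dataclasses

        broken = dataclasses.replace(small_family, true_alignment={},
                                     leaf_sequences={})
        with pytest.raises(ValueError):
            family_stats(broken)

    def test_identity_monotone_in_divergence(self):
        """Fig-2-style trend: mean identity falls as PAM distance grows."""
        means = []
        for pam in [100, 250, 400, 550, 700]:
            vals = [
                family_stats(simulate_family(SimConfig(
                    n_taxa=12, mean_pairwise_pam=pam, mean_seq_len=150,
                    indel_to_substitution_ratio=0.03, seed=100 + rep,
                ))).mean_pairwise_identity
                for rep in range(10)
            ]
            means.append(np.mean(vals))
        assert all(a > b for a, b in zip(means, means[1:]))

    def test_stats_fields_finite_and_positive(self, small_family):
        stats = family_stats(small_family)
        for value in vars(stats).values():
            assert np.isfinite(value) and value >= 0
        assert stats.mean_pairwise_identity <= 1


class TestSimConfigValidation:
    @pytest.mark.parametrize("kwargs", [
        dict(n_taxa=3, mean_pairwise_pam=100),
        dict(n_taxa=10, mean_pairwise_pam=0),
        dict(n_taxa=10, mean_pairwise_pam=100, indel_length_exponent=0.5),
        dict(n_taxa=10, mean_pairwise_pam=100, topology_mode="star"),
        dict(n_taxa=10, mean_pairwise_pam=100, indel_to_substitution_ratio=-1),
    ])
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SimConfig(**kwargs)
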