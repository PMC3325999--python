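import numpy as np
import pytest

from phyrn.profiles import build_library
from phyrn.simulate import SimConfig, simulate_family
from phyrn.tree import Node, PhyloTree


@pytest.fixture(scope="session")
def small_family():
    """10-taxon family at moderate divergence with indels."""
    return simulate_family(SimConfig(
        n_taxa=10, mean_pairwise_pam=150, mean_seq_len=120,
        indel_to_substitution_ratio=0.03, seed=42,
    ))


@pytest.fixture(scope="session")
def small_library(small_family):
    return build_library(small_family.leaf_sequences, seed=7)


def random_binary_tree(n, rng, min_internal=0.1, max_len=1.0):
    """Random rooted binary topology with random positive branch lengths."""
    labels = [f"x{i}" for i in range(n)]
    nodes = [Node(lab, rng.uniform(min_internal, max_len)) for lab in labels]
    while len(nodes) > 2:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = Node(length=rng.uniform(min_internal, max_len))
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        nodes = [x for k, x in enumerate(nodes) if k not in (i, j)] + [parent]
    root = Node()
    root.add_child(nodes[0])
    root.add_child(nodes[1])
    return PhyloTree(root)


def tree_path_distances(tree):
    """Leaf-to-leaf path length matrix computed by explicit path walking
    (independent of PhyloTree.mean_pairwise_distance's edge trick)."""
    leaves = tree.leaves()
    labels = [l.label for l in leaves]

    def path_to_root(node):
        out = {}
        acc = 0.0
        while node is not None:
            out[id(node)] = acc
            acc += node.length
            node = node.parent
        return out

    paths = [path_to_root(l) for l in leaves]
    n = len(leaves)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            shared = set(paths[i]) & set(paths[j])
            d[i, j] = d[j, i] = min(paths[i][k] + paths[j][k] for k in shared)
    return labels, d
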