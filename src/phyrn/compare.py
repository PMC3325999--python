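"""Scoring inferred trees against the true tree.

Robinson-Foulds symmetric distance counts the non-trivial bipartitions
present in exactly one of the two (unrooted) trees; its maximum for fully
resolved n-leaf trees is 2(n - 3).  Consensus marks annotate each internal
branch of the true tree with 100 (bipartition recovered by the estimate)
or 50 (missed), mirroring a strict two-tree consensus display.  Deep-node
recapitulation restricts that audit to internal nodes at least two edges
above every descendant leaf — the ancestors of the last two tiers of leaf
nodes, where phylogenetic signal is weakest.

The benchmark runner simulates families across a divergence grid and
scores PHYRN against alignment-based distance baselines computed in-repo.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulate import (SimConfig, alignment_identity_matrix, family_stats,
                       simulate_family)
from .tree import PhyloTree

__all__ = [
    "rf_distance",
    "max_rf",
    "consensus_marks",
    "deep_node_recap",
    "benchmark_run",
    "BenchmarkResult",
    "BENCHMARK_METHODS",
]


def _check_leafsets(t1: PhyloTree, t2: PhyloTree) -> None:
    if set(t1.leaf_labels()) != set(t2.leaf_labels()):
        raise ValueError("trees must share the same leaf label set")


def rf_distance(t1: PhyloTree, t2: PhyloTree) -> int:
    """Robinson-Foulds symmetric distance over non-trivial bipartitions."""
    _check_leafsets(t1, t2)
    return len(t1.bipartitions() ^ t2.bipartitions())


def max_rf(n_leaves: int) -> int:
    """Maximum RF distance between fully resolved n-leaf trees: 2(n - 3)."""
    if n_leaves < 4:
        raise ValueError("n_leaves must be >= 4")
    return 2 * (n_leaves - 3)


def consensus_marks(true_tree: PhyloTree, est_tree: PhyloTree) -> PhyloTree:
    """Copy of the true tree with internal branches marked 100 or 50.

    100 means the estimate contains the branch's bipartition, 50 means it
    does not; for fully resolved trees the number of 50-marks is RF / 2.
    """
    _check_leafsets(true_tree, est_tree)
    est_splits = est_tree.bipartitions()
    out = true_tree.copy()
    labels = set(out.leaf_labels())
    ref = min(labels)
    n = len(labels)

    def walk(node):
        if node.is_leaf:
            return frozenset([node.label])
        below = frozenset().union(*(walk(c) for c in node.children))
        if node is not out.root:
            side = below if ref not in below else labels - below
            if 2 <= len(side) <= n - 2:
                node.support = 100.0 if frozenset(side) in est_splits else 50.0
        return below

    walk(out.root)
    return out


def deep_nodes(true_tree: PhyloTree, min_leaf_depth: int = 2) -> list[frozenset]:
    """Clades of internal nodes whose closest descendant leaf is at least
    ``min_leaf_depth`` edges away (the root's total clade included)."""
    sets: list[frozenset] = []

    def walk(node) -> tuple[frozenset, int]:
        if node.is_leaf:
            return frozenset([node.label]), 0
        parts = [walk(c) for c in node.children]
        below = frozenset().union(*(p[0] for p in parts))
        depth = min(p[1] for p in parts) + 1
        if depth >= min_leaf_depth:
            sets.append(below)
        return below, depth

    walk(true_tree.root)
    return sets


def deep_node_recap(true_tree: PhyloTree, est_tree: PhyloTree,
                    min_leaf_depth: int = 2) -> float:
    """Percentage of the true tree's deep nodes whose bipartition the
    estimated tree contains."""
    _check_leafsets(true_tree, est_tree)
    clades = deep_nodes(true_tree, min_leaf_depth)
    if not clades:
        raise ValueError("true tree has no deep nodes")
    labels = set(true_tree.leaf_labels())
    ref = min(labels)
    n = len(labels)
    est_splits = est_tree.bipartitions()
    hit = 0
    for clade in clades:
        if len(clade) >= n - 1:  # root or near-root split: trivially present
            hit += 1
            continue
        side = clade if ref not in clade else labels - clade
        if len(side) < 2:
            hit += 1
        elif frozenset(side) in est_splits:
            hit += 1
    return 100.0 * hit / len(clades)


# ----------------------------------------------------------------------
# benchmark runner
# ----------------------------------------------------------------------
@dataclass
class BenchmarkResult:
    """Per-replicate RF table plus mean +/- SD aggregate per condition."""

    table: pd.DataFrame      # columns: pam, replicate, method, rf, identity
    summary: pd.DataFrame    # columns: pam, method, mean_rf, sd_rf, n


def _dm_from_square(values: np.ndarray, ids: list[str]):
    from .distance import DistanceMatrix

    return DistanceMatrix(values, ids)


def _phyrn_nj(family, params: dict) -> PhyloTree:
    from .align import populate_matrix
    from .distance import euclidean_distances, nj_tree
    from .profiles import build_library

    queries = family.leaf_sequences
    lib = build_library(
        queries,
        max_iter=params.get("max_iter", 6),
        evalue_cut=params.get("evalue_cut", 1e-6),
        seed=params.get("seed", 0),
    )
    psm = populate_matrix(queries, lib)
    return nj_tree(euclidean_distances(psm))


def _true_alignment_pdistance_nj(family, params: dict) -> PhyloTree:
    from .distance import nj_tree

    ident = alignment_identity_matrix(family.true_alignment)
    ids = sorted(family.true_alignment)
    return nj_tree(_dm_from_square(1.0 - ident, ids))


def _pairwise_pdistance_nj(family, params: dict) -> PhyloTree:
    """p-distance from global pairwise alignments (no MSA, no profiles)."""
    from Bio import Align
    from Bio.Align import substitution_matrices

    from .distance import nj_tree

    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    aligner.mode = "global"

    ids = sorted(family.leaf_sequences)
    seqs = [family.leaf_sequences[i] for i in ids]
    n = len(ids)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            aln = aligner.align(seqs[i], seqs[j])[0]
            a, b = str(aln[0]), str(aln[1])
            pairs = ident = 0
            for x, y in zip(a, b):
                if x != "-" and y != "-":
                    pairs += 1
                    if x == y:
                        ident += 1
            d[i, j] = d[j, i] = 1.0 - (ident / pairs if pairs else 0.0)
    return nj_tree(_dm_from_square(d, ids))


BENCHMARK_METHODS = {
    "phyrn_nj": _phyrn_nj,
    "true_alignment_pdistance_nj": _true_alignment_pdistance_nj,
    "pairwise_pdistance_nj": _pairwise_pdistance_nj,
}


def benchmark_run(
    divergence_levels: list[float],
    replicates: int,
    methods: list[str],
    n_taxa: int = 100,
    mean_seq_len: int = 450,
    indel_to_substitution_ratio: float = 0.03,
    topology_mode: str = "yule",
    seed: int = 0,
    method_params: dict | None = None,
) -> BenchmarkResult:
    """Simulate a divergence grid and score each method's RF to the truth.

    Fully seeded: replicate r at level index l uses a substream derived
    from (seed, l, r), so the same grid and seed reproduce the same table.
    """
    if not divergence_levels or replicates < 1 or not methods:
        raise ValueError("grid must be nonempty")
    unknown = set(methods) - set(BENCHMARK_METHODS)
    if unknown:
        raise ValueError(f"unknown methods: {sorted(unknown)}")
    method_params = method_params or {}

    records = []
    for l_idx, pam in enumerate(divergence_levels):
        for rep in range(replicates):
            sub = int(np.random.SeedSequence(
                [seed, l_idx, rep]).generate_state(1)[0] % (2 ** 31))
            family = simulate_family(SimConfig(
                n_taxa=n_taxa,
                mean_pairwise_pam=pam,
                mean_seq_len=mean_seq_len,
                indel_to_substitution_ratio=indel_to_substitution_ratio,
                topology_mode=topology_mode,
                seed=sub,
            ))
            identity = family_stats(family).mean_pairwise_identity
            for name in methods:
                params = dict(method_params.get(name, {}))
                params.setdefault("seed", sub)
                est = BENCHMARK_METHODS[name](family, params)
                records.append({
                    "pam": pam,
                    "replicate": rep,
                    "method": name,
                    "rf": rf_distance(family.true_tree, est),
                    "identity": identity,
                })
    table = pd.DataFrame.from_records(records)
    summary = (
        table.groupby(["pam", "method"], as_index=False)
        .agg(mean_rf=("rf", "mean"), sd_rf=("rf", "std"), n=("rf", "size"))
    )
    summary["sd_rf"] = summary["sd_rf"].fillna(0.0)
    return BenchmarkResult(table=table, summary=summary)
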