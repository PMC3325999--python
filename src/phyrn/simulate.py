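"""Synthetic protein-family evolution with a known true history.

A single root sequence is evolved down an ultrametric clock tree under the
Dayhoff PAM model.  Substitutions on a branch of length *d* PAM are drawn
from the PAM-1 matrix raised to the ``round(d)``-th power; indel events are
a Poisson process whose expectation is a configurable multiple of the
expected substitution count on that branch, with Zipf-distributed lengths.
Because every insertion and deletion is tracked through a global column
list, the simulator emits the exact multiple alignment of the leaves — the
"true alignment" — alongside the leaf sequences and the true tree, which is
what makes simulated families usable as a benchmark with a known answer.

With ``indel_to_substitution_ratio = 0`` the generator degenerates to a
substitution-only process (no gaps in the true alignment).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from . import dayhoff
from .tree import Node, PhyloTree

__all__ = [
    "SimConfig",
    "SimulatedFamily",
    "DivergenceStats",
    "generate_tree",
    "scale_tree",
    "evolve_family",
    "family_stats",
    "simulate_family",
]

TOPOLOGY_MODES = ("yule", "balanced", "pectinate")


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one simulated family.

    mean_pairwise_pam is the divergence dial: the tree is scaled so that
    the mean over all unordered leaf pairs of the leaf-to-leaf path length
    equals this many PAM units.
    """

    n_taxa: int
    mean_pairwise_pam: float
    mean_seq_len: int = 450
    indel_to_substitution_ratio: float = 0.0
    indel_length_exponent: float = 1.7
    max_indel_length: int = 40
    topology_mode: str = "yule"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_taxa < 4:
            raise ValueError("n_taxa must be >= 4")
        if self.mean_pairwise_pam <= 0:
            raise ValueError("mean_pairwise_pam must be > 0")
        if self.mean_seq_len < 1:
            raise ValueError("mean_seq_len must be >= 1")
        if self.indel_to_substitution_ratio < 0:
            raise ValueError("indel_to_substitution_ratio must be >= 0")
        if self.indel_length_exponent <= 1:
            raise ValueError("indel_length_exponent must be > 1")
        if self.max_indel_length < 1:
            raise ValueError("max_indel_length must be >= 1")
        if self.topology_mode not in TOPOLOGY_MODES:
            raise ValueError(f"topology_mode must be one of {TOPOLOGY_MODES}")


@dataclass
class SimulatedFamily:
    """One simulation replicate: sequences, true alignment, true tree."""

    true_tree: PhyloTree
    leaf_sequences: dict[str, str]
    true_alignment: dict[str, str]
    #: (branch id, "insertion"|"deletion", position, length) per indel event
    event_log: list[tuple[str, str, int, int]]
    #: number of sites whose residue changed along some branch
    n_substitutions: int = 0
    config: SimConfig | None = None

    def validate(self) -> None:
        rows = list(self.true_alignment.values())
        if not rows:
            raise ValueError("empty alignment")
        if len({len(r) for r in rows}) != 1:
            raise ValueError("alignment rows must have equal length")
        for label, row in self.true_alignment.items():
            if row.replace("-", "") != self.leaf_sequences[label]:
                raise ValueError(f"row for {label} does not match its sequence")
        if set(self.leaf_sequences) != set(self.true_tree.leaf_labels()):
            raise ValueError("leaf label sets of tree and sequences differ")


@dataclass(frozen=True)
class DivergenceStats:
    mean_pairwise_identity: float
    indel_events_per_position: float
    gap_chars_per_position: float
    avg_gap_length: float
    isr: float


# ----------------------------------------------------------------------
# tree generation
# ----------------------------------------------------------------------
def _leaf_labels(n: int) -> list[str]:
    width = len(str(n))
    return [f"t{i + 1:0{width}d}" for i in range(n)]


def _heights_to_lengths(tree: PhyloTree, heights: dict[int, float]) -> None:
    for node in tree.preorder():
        if node.parent is None:
            node.length = 0.0
        else:
            node.length = heights[id(node.parent)] - heights.get(id(node), 0.0)


def generate_tree(n_taxa: int, topology_mode: str = "yule", seed: int = 0) -> PhyloTree:
    """Random ultrametric rooted binary tree with unit root-to-leaf depth.

    ``yule`` draws a pure-birth tree (random lineage splits, exponential
    waiting times); ``balanced`` is a near-perfect binary tree; ``pectinate``
    is a caterpillar with equally spaced join heights.  Branch lengths are
    later rescaled to a target divergence by :func:`scale_tree`.
    """
    if n_taxa < 4:
        raise ValueError("n_taxa must be >= 4")
    if topology_mode not in TOPOLOGY_MODES:
        raise ValueError(f"topology_mode must be one of {TOPOLOGY_MODES}")
    labels = _leaf_labels(n_taxa)
    rng = np.random.default_rng(seed)
    heights: dict[int, float] = {}

    if topology_mode == "balanced":
        def build(lo: int, hi: int) -> tuple[Node, int]:
            if hi - lo == 1:
                return Node(labels[lo]), 0
            mid = (lo + hi + 1) // 2
            left, dl = build(lo, mid)
            right, dr = build(mid, hi)
            node = Node()
            node.add_child(left)
            node.add_child(right)
            return node, max(dl, dr) + 1
        root, depth = build(0, n_taxa)

        def set_heights(node: Node) -> int:
            if node.is_leaf:
                return 0
            d = max(set_heights(c) for c in node.children) + 1
            heights[id(node)] = d / depth
            return d
        set_heights(root)
        heights[id(root)] = 1.0
        tree = PhyloTree(root)

    elif topology_mode == "pectinate":
        clade = Node(labels[0])
        for k in range(1, n_taxa):
            parent = Node()
            parent.add_child(clade)
            parent.add_child(Node(labels[k]))
            heights[id(parent)] = k / (n_taxa - 1)
            clade = parent
        tree = PhyloTree(clade)

    else:  # yule
        root = Node()
        first, second = Node(), Node()
        root.add_child(first)
        root.add_child(second)
        node_height = {id(root): 0.0}
        active = [first, second]
        t = 0.0
        for k in range(2, n_taxa):
            t += rng.exponential(1.0 / k)
            idx = int(rng.integers(len(active)))
            node = active.pop(idx)
            node_height[id(node)] = t
            left, right = Node(), Node()
            node.add_child(left)
            node.add_child(right)
            active.extend([left, right])
        present = t + rng.exponential(1.0 / n_taxa)
        order = rng.permutation(n_taxa)
        for leaf, lab_idx in zip(active, order):
            leaf.label = labels[int(lab_idx)]
        # convert split times (from root) into heights above the leaves
        for nid, when in node_height.items():
            heights[nid] = (present - when) / present
        tree = PhyloTree(root)

    _heights_to_lengths(tree, heights)
    tree.validate()
    return tree


def scale_tree(tree: PhyloTree, mean_pairwise_pam: float) -> PhyloTree:
    """Rescale all branch lengths by one factor so that the mean pairwise
    leaf-to-leaf path length equals ``mean_pairwise_pam`` PAM units."""
    if mean_pairwise_pam <= 0:
        raise ValueError("mean_pairwise_pam must be > 0")
    current = tree.mean_pairwise_distance()
    if current <= 0:
        raise ValueError("cannot scale a tree whose branch lengths are all zero")
    return tree.scaled(mean_pairwise_pam / current)


# ----------------------------------------------------------------------
# sequence evolution
# ----------------------------------------------------------------------
def _sample_categorical(rng: np.random.Generator, cum_rows: np.ndarray,
                        states: np.ndarray) -> np.ndarray:
    u = rng.random(states.shape[0])
    return (u[:, None] > cum_rows[states]).sum(axis=1)


def _zipf_cdf(exponent: float, kmax: int) -> np.ndarray:
    weights = np.arange(1, kmax + 1, dtype=float) ** (-exponent)
    return np.cumsum(weights) / weights.sum()


def evolve_family(tree: PhyloTree, config: SimConfig) -> SimulatedFamily:
    """Evolve a root sequence down ``tree`` (branch lengths in PAM units)."""
    tree.validate()
    rng = np.random.default_rng(config.seed)
    pi = dayhoff.EQUILIBRIUM_FREQS
    cum_pi = np.cumsum(pi)
    zipf_cdf = _zipf_cdf(config.indel_length_exponent, config.max_indel_length)
    isr = config.indel_to_substitution_ratio

    length = config.mean_seq_len
    root_res = (rng.random(length)[:, None] > cum_pi[None, :]).sum(axis=1)

    # global alignment-column order as a linked list; -1 is the head sentinel
    nxt: dict[int, int] = {-1: 0}
    for c in range(length):
        nxt[c] = c + 1
    nxt[length - 1] = -2  # tail sentinel
    next_col = itertools.count(length)

    event_log: list[tuple[str, str, int, int]] = []
    n_subs = 0
    leaf_state: dict[str, tuple[list[int], list[int]]] = {}

    counter = itertools.count()

    def branch_id(node: Node) -> str:
        return node.label if node.is_leaf else f"node{next(counter)}"

    def descend(node: Node, cols: list[int], res: list[int]) -> None:
        nonlocal n_subs
        bid = branch_id(node)
        if node.parent is not None:
            d = int(round(node.length))
            arr = np.asarray(res, dtype=np.intp)
            if d > 0 and len(arr):
                prob = dayhoff.transition_matrix(d)
                cum = np.cumsum(prob, axis=1)
                new = _sample_categorical(rng, cum, arr)
                n_subs += int((new != arr).sum())
                res = new.tolist()
            if isr > 0:
                expected_subs = (node.length / 100.0) * len(res)
                n_events = int(rng.poisson(isr * expected_subs))
                for _ in range(n_events):
                    size = 1 + int((rng.random() > zipf_cdf).sum())
                    if rng.random() < 0.5 and len(res) > 0:  # deletion
                        start = int(rng.integers(len(res)))
                        size = min(size, len(res) - start)
                        del cols[start:start + size]
                        del res[start:start + size]
                        event_log.append((bid, "deletion", start, size))
                    else:  # insertion
                        pos = int(rng.integers(len(res) + 1))
                        anchor = cols[pos - 1] if pos > 0 else -1
                        fresh = [next(next_col) for _ in range(size)]
                        tail = nxt[anchor]
                        for c in fresh:
                            nxt[anchor] = c
                            anchor = c
                        nxt[anchor] = tail
                        new_res = ((rng.random(size)[:, None] > cum_pi[None, :])
                                   .sum(axis=1)).tolist()
                        cols[pos:pos] = fresh
                        res[pos:pos] = new_res
                        event_log.append((bid, "insertion", pos, size))
        if node.is_leaf:
            leaf_state[node.label] = (cols, res)
        else:
            for child in node.children:
                descend(child, list(cols), list(res))

    descend(tree.root, list(range(length)), root_res.tolist())

    # assemble the true alignment: only columns surviving in >= 1 leaf
    used = set()
    for cols, _ in leaf_state.values():
        used.update(cols)
    order: dict[int, int] = {}
    c = nxt[-1]
    while c != -2:
        if c in used:
            order[c] = len(order)
        c = nxt[c]

    aln_len = len(order)
    alphabet = dayhoff.ALPHABET
    sequences: dict[str, str] = {}
    alignment: dict[str, str] = {}
    for label, (cols, res) in leaf_state.items():
        row = ["-"] * aln_len
        for col, r in zip(cols, res):
            row[order[col]] = alphabet[r]
        alignment[label] = "".join(row)
        sequences[label] = "".join(alphabet[r] for r in res)

    family = SimulatedFamily(
        true_tree=tree.copy(),
        leaf_sequences=sequences,
        true_alignment=alignment,
        event_log=event_log,
        n_substitutions=n_subs,
        config=config,
    )
    family.validate()
    return family


# ----------------------------------------------------------------------
# divergence statistics
# ----------------------------------------------------------------------
def alignment_identity_matrix(alignment: dict[str, str]) -> np.ndarray:
    """Pairwise fraction of identical residues over residue-residue columns.

    Columns where either row carries a gap are excluded from both the
    numerator and the denominator; pairs with no shared residue columns get
    identity 0.
    """
    labels = sorted(alignment)
    rows = np.array([np.frombuffer(alignment[l].encode(), dtype=np.uint8)
                     for l in labels])
    gap = ord("-")
    n = len(labels)
    out = np.ones((n, n))
    for i in range(n):
        ri = rows[i]
        resi = ri != gap
        for j in range(i + 1, n):
            both = resi & (rows[j] != gap)
            denom = int(both.sum())
            ident = float((ri[both] == rows[j][both]).sum() / denom) if denom else 0.0
            out[i, j] = out[j, i] = ident
    return out


def family_stats(family: SimulatedFamily) -> DivergenceStats:
    family.validate()
    ident = alignment_identity_matrix(family.true_alignment)
    n = ident.shape[0]
    iu = np.triu_indices(n, 1)
    mean_ident = float(ident[iu].mean())

    total_residues = sum(len(s) for s in family.leaf_sequences.values())
    total_gap_chars = sum(r.count("-") for r in family.true_alignment.values())
    n_events = len(family.event_log)
    lengths = [e[3] for e in family.event_log]

    return DivergenceStats(
        mean_pairwise_identity=mean_ident,
        indel_events_per_position=n_events / total_residues,
        gap_chars_per_position=total_gap_chars / total_residues,
        avg_gap_length=float(np.mean(lengths)) if lengths else 0.0,
        isr=(n_events / family.n_substitutions) if family.n_substitutions else 0.0,
    )


def simulate_family(config: SimConfig) -> SimulatedFamily:
    """Generate a tree, scale it to the target divergence, and evolve it."""
    tree = generate_tree(config.n_taxa, config.topology_mode, config.seed)
    tree = scale_tree(tree, config.mean_pairwise_pam)
    return evolve_family(tree, config)
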