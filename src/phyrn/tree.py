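"""Phylogenetic tree container with branch lengths in PAM units.

A deliberately small rooted-node structure: the simulator walks it edge by
edge, the distance methods build it join by join, and the comparison module
reduces it to bipartitions.  Newick parsing is delegated to dendropy;
serialization is direct.
"""

from __future__ import annotations

from typing import Iterator

import dendropy

__all__ = ["Node", "PhyloTree"]


class Node:
    """Tree node; ``length`` is the PAM length of the edge to the parent."""

    __slots__ = ("label", "length", "parent", "children", "support")

    def __init__(self, label: str | None = None, length: float = 0.0):
        self.label = label
        self.length = float(length)
        self.parent: Node | None = None
        self.children: list[Node] = []
        self.support: float | None = None

    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        kind = "leaf" if self.is_leaf else f"internal({len(self.children)})"
        return f"<Node {self.label or ''} {kind} len={self.length:g}>"


class PhyloTree:
    """Rooted (or conventionally rooted unrooted) binary tree.

    ``rooted=False`` marks trees whose root is a placement artifact (e.g.
    the final three-way join of neighbor joining); such trees are compared
    only through their bipartitions.
    """

    def __init__(self, root: Node, rooted: bool = True):
        self.root = root
        self.rooted = rooted

    # ------------------------------------------------------------------
    # traversal
    # ------------------------------------------------------------------
    def preorder(self) -> Iterator[Node]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def postorder(self) -> Iterator[Node]:
        out: list[Node] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return iter(reversed(out))

    def leaves(self) -> list[Node]:
        return [n for n in self.preorder() if n.is_leaf]

    def leaf_labels(self) -> list[str]:
        return [n.label for n in self.leaves()]

    def n_leaves(self) -> int:
        return sum(1 for _ in self.leaves())

    def internal_nodes(self) -> list[Node]:
        return [n for n in self.preorder() if not n.is_leaf]

    # ------------------------------------------------------------------
    # validation / geometry
    # ------------------------------------------------------------------
    def validate(self) -> None:
        labels = self.leaf_labels()
        if len(labels) != len(set(labels)):
            raise ValueError("leaf labels must be unique")
        if any(not lab for lab in labels):
            raise ValueError("leaf labels must be nonempty")
        for node in self.preorder():
            if node.length < 0:
                raise ValueError("branch lengths must be non-negative")
            if node.children and len(node.children) != 2:
                if node is self.root and not self.rooted and len(node.children) == 3:
                    continue
                raise ValueError("internal nodes must be binary")

    def leaf_depths(self) -> dict[str, float]:
        depths: dict[str, float] = {}
        stack = [(self.root, 0.0)]
        while stack:
            node, acc = stack.pop()
            if node is not self.root:
                acc += node.length
            if node.is_leaf:
                depths[node.label] = acc
            stack.extend((c, acc) for c in node.children)
        return depths

    def is_ultrametric(self, rel_tol: float = 1e-9) -> bool:
        depths = list(self.leaf_depths().values())
        span = max(depths) - min(depths)
        scale = max(max(depths), 1e-300)
        return span <= rel_tol * scale

    def total_length(self) -> float:
        return sum(n.length for n in self.preorder() if n is not self.root)

    def mean_pairwise_distance(self) -> float:
        """Mean leaf-to-leaf path length over all unordered leaf pairs.

        Computed edge-wise: an edge splitting the leaves a|b lies on a*b of
        the n(n-1)/2 paths.
        """
        n = self.n_leaves()
        if n < 2:
            raise ValueError("need at least two leaves")
        total = 0.0
        below: dict[int, int] = {}
        for node in self.postorder():
            k = 1 if node.is_leaf else sum(below.pop(id(c))
                                           for c in node.children)
            below[id(node)] = k
            if node is not self.root:
                total += node.length * k * (n - k)
        return total / (n * (n - 1) / 2)

    def scaled(self, factor: float) -> "PhyloTree":
        clone = self.copy()
        for node in clone.preorder():
            node.length *= factor
        return clone

    def copy(self) -> "PhyloTree":
        clones: dict[int, Node] = {}
        for node in self.preorder():
            new = Node(node.label, node.length)
            new.support = node.support
            clones[id(node)] = new
            if node.parent is not None:
                clones[id(node.parent)].add_child(new)
        return PhyloTree(clones[id(self.root)], rooted=self.rooted)

    # ------------------------------------------------------------------
    # bipartitions
    # ------------------------------------------------------------------
    def bipartitions(self, include_trivial: bool = False) -> set[frozenset[str]]:
        """Non-trivial bipartitions of the (unrooted) tree.

        Each split is canonicalized as the side that does not contain the
        lexicographically smallest leaf label, so identical splits from
        differently rooted trees compare equal.
        """
        labels = set(self.leaf_labels())
        ref = min(labels)
        n = len(labels)
        splits: set[frozenset[str]] = set()
        below: dict[int, frozenset[str]] = {}
        for node in self.postorder():
            if node.is_leaf:
                b: frozenset[str] = frozenset([node.label])
            else:
                b = frozenset().union(*(below.pop(id(c))
                                        for c in node.children))
            below[id(node)] = b
            if node is not self.root:
                side = b if ref not in b else labels - b
                if include_trivial or 2 <= len(side) <= n - 2:
                    splits.add(frozenset(side))
        return splits

    def clade_leafsets(self) -> dict[int, frozenset[str]]:
        """Map ``id(node) -> descendant leaf set`` for every internal node."""
        out: dict[int, frozenset[str]] = {}
        below: dict[int, frozenset[str]] = {}
        for node in self.postorder():
            if node.is_leaf:
                b: frozenset[str] = frozenset([node.label])
            else:
                b = frozenset().union(*(below.pop(id(c))
                                        for c in node.children))
                out[id(node)] = b
            below[id(node)] = b
        return out

    # ------------------------------------------------------------------
    # newick
    # ------------------------------------------------------------------
    def to_newick(self, include_support: bool = False) -> str:
        parts: dict[int, str] = {}
        for node in self.postorder():
            if node.is_leaf:
                body = node.label
            else:
                inner = ",".join(parts.pop(id(c)) for c in node.children)
                sup = ""
                if include_support and node.support is not None:
                    sup = format(node.support, "g")
                elif node.label:
                    sup = node.label
                body = f"({inner}){sup}"
            if node is not self.root:
                body += f":{node.length:.10g}"
            parts[id(node)] = body
        return parts[id(self.root)] + ";"

    @classmethod
    def from_newick(cls, text: str, rooted: bool | None = None) -> "PhyloTree":
        try:
            dtree = dendropy.Tree.get(
                data=text, schema="newick", suppress_internal_node_taxa=True
            )
        except Exception as exc:
            raise ValueError(f"newick parse error: {exc}") from exc

        def convert(dnode) -> Node:
            label = None
            if dnode.taxon is not None:
                label = dnode.taxon.label
            elif dnode.label:
                label = dnode.label
            node = Node(label=label, length=dnode.edge.length or 0.0)
            if not dnode.is_leaf() and dnode.label:
                try:
                    node.support = float(dnode.label)
                except ValueError:
                    pass
            for child in dnode.child_nodes():
                node.add_child(convert(child))
            return node

        root = convert(dtree.seed_node)
        if rooted is None:
            rooted = len(root.children) != 3
        tree = cls(root, rooted=rooted)
        tree.validate()
        return tree

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"<PhyloTree n_leaves={self.n_leaves()} rooted={self.rooted}>"
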