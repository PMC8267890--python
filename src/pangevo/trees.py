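"""Lightweight rooted-tree container shared by all phylogenetic routines.

The algorithms in this package (Fitch/Sankoff parsimony, NNI search,
bipartition bookkeeping) need cheap structural surgery on trees, so nodes are
plain mutable objects with parent/child links.  Newick text is parsed with
dendropy and converted; writing is a direct recursive emit.
"""

from __future__ import annotations

import itertools
from typing import Callable, Iterator, Sequence

import dendropy
import numpy as np

__all__ = ["Node", "Tree", "random_tree", "all_unrooted_topologies"]


class Node:
    __slots__ = ("label", "length", "support", "children", "parent")

    def __init__(self, label: str | None = None, length: float | None = None):
        self.label = label
        self.length = length
        self.support: float | None = None
        self.children: list[Node] = []
        self.parent: Node | None = None

    def is_leaf(self) -> bool:
        return not self.children

    def add_child(self, node: "Node") -> "Node":
        node.parent = self
        self.children.append(node)
        return node

    def detach(self) -> "Node":
        if self.parent is not None:
            self.parent.children.remove(self)
            self.parent = None
        return self

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Node({self.label!r})"


class Tree:
    """A rooted tree; an unrooted tree is represented with a multifurcating root."""

    def __init__(self, root: Node):
        self.root = root

    # ------------------------------------------------------------------ I/O
    @classmethod
    def from_newick(cls, text: str) -> "Tree":
        dtree = dendropy.Tree.get(data=text, schema="newick",
                                  preserve_underscores=True,
                                  suppress_internal_node_taxa=True)

        def convert(dnode) -> Node:
            if dnode.is_leaf():
                label = dnode.taxon.label if dnode.taxon is not None else dnode.label
            else:
                label = dnode.label
            node = Node(label=label, length=dnode.edge.length)
            if label is not None and not dnode.is_leaf():
                try:
                    node.support = float(label)
                except ValueError:
                    pass
            for child in dnode.child_nodes():
                node.add_child(convert(child))
            return node

        return cls(convert(dtree.seed_node))

    def to_newick(self, lengths: bool = True, supports: bool = False) -> str:
        def emit(node: Node) -> str:
            if node.is_leaf():
                s = node.label or ""
            else:
                inner = ",".join(emit(c) for c in node.children)
                if supports and node.support is not None:
                    lab = f"{node.support:g}"
                else:
                    lab = node.label or ""
                s = f"({inner}){lab}"
            if lengths and node.length is not None:
                s += f":{node.length:g}"
            return s

        return emit(self.root) + ";"

    # ------------------------------------------------------------- traversal
    def postorder(self) -> Iterator[Node]:
        stack, out = [self.root], []
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return iter(reversed(out))

    def preorder(self) -> Iterator[Node]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def leaves(self) -> list[Node]:
        return [n for n in self.postorder() if n.is_leaf()]

    def leaf_labels(self) -> list[str]:
        return [n.label for n in self.leaves()]

    def internal_nodes(self) -> list[Node]:
        return [n for n in self.postorder() if not n.is_leaf()]

    def n_leaves(self) -> int:
        return len(self.leaves())

    def find(self, label: str) -> Node | None:
        for n in self.postorder():
            if n.label == label:
                return n
        return None

    def is_binary(self) -> bool:
        return all(len(n.children) == 2 for n in self.internal_nodes())

    def copy(self) -> "Tree":
        def dup(node: Node) -> Node:
            new = Node(node.label, node.length)
            new.support = node.support
            for c in node.children:
                new.add_child(dup(c))
            return new

        return Tree(dup(self.root))

    def label_internal(self, prefix: str = "N") -> None:
        """Assign deterministic labels to unlabeled internal nodes (preorder)."""
        i = 0
        for node in self.preorder():
            if not node.is_leaf() and node.label is None:
                node.label = f"{prefix}{i}"
                i += 1

    # ---------------------------------------------------------- bipartitions
    def bipartitions(self, include_trivial: bool = False) -> dict[frozenset, float]:
        """Unrooted bipartitions mapped to branch length.

        A split is canonicalised as the leaf-set side NOT containing the
        lexicographically smallest leaf.  Lengths of the two edges of a rooted
        tree that induce the same split (the two root edges) are summed.
        """
        all_leaves = frozenset(self.leaf_labels())
        ref = min(all_leaves)
        splits: dict[frozenset, float] = {}
        below: dict[int, frozenset] = {}
        for node in self.postorder():
            if node.is_leaf():
                below[id(node)] = frozenset([node.label])
            else:
                below[id(node)] = frozenset().union(*(below[id(c)] for c in node.children))
            if node is self.root:
                continue
            side = below[id(node)]
            if ref in side:
                side = all_leaves - side
            if not side or side == all_leaves:
                continue
            trivial = len(side) < 2 or len(all_leaves - side) < 2
            if trivial and not include_trivial:
                continue
            length = node.length or 0.0
            splits[side] = splits.get(side, 0.0) + length
        if include_trivial:
            # ensure every leaf edge appears even when length is None
            for leaf in self.leaves():
                side = all_leaves - frozenset([leaf.label]) if leaf.label == ref \
                    else frozenset([leaf.label])
                splits.setdefault(side, leaf.length or 0.0)
        return splits


# ----------------------------------------------------------- tree generators
def random_tree(labels: Sequence[str], rng: np.random.Generator,
                branch_length: float | Callable[[np.random.Generator], float] = 0.1,
                ) -> Tree:
    """Random binary rooted topology by sequential random attachment.

    ``branch_length`` is either a constant or a callable drawing one length.
    """
    if len(labels) < 2:
        raise ValueError("need at least two leaf labels")

    def bl() -> float:
        return branch_length(rng) if callable(branch_length) else float(branch_length)

    labels = list(labels)
    root = Node()
    a, b = Node(labels[0], bl()), Node(labels[1], bl())
    root.add_child(a)
    root.add_child(b)
    tree = Tree(root)
    edges = [a, b]
    for lab in labels[2:]:
        target = edges[rng.integers(len(edges))]
        parent = target.parent
        mid = Node(length=bl())
        idx = parent.children.index(target)
        parent.children[idx] = mid
        mid.parent = parent
        target.parent = mid
        mid.children = [target]
        leaf = Node(lab, bl())
        mid.add_child(leaf)
        edges.append(mid)
        edges.append(leaf)
    tree.label_internal()
    return tree


def all_unrooted_topologies(labels: Sequence[str]) -> list[Tree]:
    """Enumerate all unrooted binary topologies (15 for 5 taxa).

    Returned as rooted trees with a trifurcating root; intended for
    exhaustive-search oracles on <=6 taxa.
    """
    labels = list(labels)
    if len(labels) < 3:
        raise ValueError("need >=3 taxa")

    def base() -> Tree:
        root = Node()
        for lab in labels[:3]:
            root.add_child(Node(lab))
        return Tree(root)

    trees = [base()]
    for lab in labels[3:]:
        new_trees = []
        for tree in trees:
            edges = [n for n in tree.postorder() if n is not tree.root]
            for i in range(len(edges)):
                t2 = tree.copy()
                e2 = [n for n in t2.postorder() if n is not t2.root][i]
                parent = e2.parent
                mid = Node()
                idx = parent.children.index(e2)
                parent.children[idx] = mid
                mid.parent = parent
                e2.parent = mid
                mid.children = [e2]
                mid.add_child(Node(lab))
                new_trees.append(t2)
        trees = new_trees
    return trees
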