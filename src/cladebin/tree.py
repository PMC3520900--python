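"""Rooted phylogenetic tree structure used throughout the package.

The tree is a plain rooted tree of :class:`TreeNode` objects.  After
parsing (see :mod:`cladebin.formats_io`) every internal node has exactly
two children, which is what the parsimony and likelihood dynamic
programs assume.  An *edge* is identified by its child node; a rooted
binary tree on ``n`` leaves therefore has ``2n - 2`` edges (the root has
no parent edge).
"""

from __future__ import annotations

from typing import Callable, Iterator, Optional


class TreeNode:
    __slots__ = ("label", "length", "children", "parent")

    def __init__(self, label: Optional[str] = None, length: Optional[float] = None):
        self.label = label
        self.length = length
        self.children: list[TreeNode] = []
        self.parent: Optional[TreeNode] = None

    def add_child(self, node: "TreeNode") -> "TreeNode":
        node.parent = self
        self.children.append(node)
        return node

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        kind = "leaf" if self.is_leaf else f"internal[{len(self.children)}]"
        return f"<TreeNode {self.label or ''} {kind}>"


class Phylogeny:
    """A rooted tree with labelled leaves and per-edge branch lengths."""

    def __init__(self, root: TreeNode):
        self.root = root

    # -- traversal ----------------------------------------------------

    def preorder(self) -> Iterator[TreeNode]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            # reversed so children come out in their stored order
            stack.extend(reversed(node.children))

    def postorder(self) -> Iterator[TreeNode]:
        out: list[TreeNode] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return iter(reversed(out))

    @property
    def leaves(self) -> list[TreeNode]:
        return [n for n in self.preorder() if n.is_leaf]

    @property
    def leaf_labels(self) -> list[str]:
        return [n.label for n in self.leaves]

    @property
    def n_leaves(self) -> int:
        return sum(1 for n in self.preorder() if n.is_leaf)

    def edges(self) -> list[TreeNode]:
        """All edges in a stable preorder, each named by its child node."""
        return [n for n in self.preorder() if n.parent is not None]

    # -- copying ------------------------------------------------------

    def copy(self) -> tuple["Phylogeny", dict[TreeNode, TreeNode]]:
        """Deep copy; returns the copy and an old-node -> new-node map."""
        mapping: dict[TreeNode, TreeNode] = {}

        def clone(node: TreeNode) -> TreeNode:
            new = TreeNode(node.label, node.length)
            mapping[node] = new
            for child in node.children:
                new.add_child(clone(child))
            return new

        return Phylogeny(clone(self.root)), mapping

    # -- serialisation ------------------------------------------------

    def to_newick(self, lengths: bool = True) -> str:
        def fmt(node: TreeNode) -> str:
            if node.is_leaf:
                core = node.label or ""
            else:
                core = "(" + ",".join(fmt(c) for c in node.children) + ")"
                if node.label:
                    core += node.label
            if lengths and node.length is not None and node.parent is not None:
                core += ":" + format(node.length, ".10g")
            return core

        return fmt(self.root) + ";"

    # -- structural queries -------------------------------------------

    def leafsets(self) -> dict[TreeNode, frozenset[str]]:
        """Descendant leaf-label set for every node, bottom-up."""
        sets: dict[TreeNode, frozenset[str]] = {}
        for node in self.postorder():
            if node.is_leaf:
                sets[node] = frozenset((node.label,))
            else:
                acc: set[str] = set()
                for c in node.children:
                    acc |= sets[c]
                sets[node] = frozenset(acc)
        return sets

    def splits(self) -> set[frozenset[str]]:
        """Set of non-trivial leaf bipartition halves below each edge."""
        sets = self.leafsets()
        return {sets[e] for e in self.edges()}

    def map_lengths(self, fn: Callable[[float], float]) -> None:
        for node in self.preorder():
            if node.parent is not None and node.length is not None:
                node.length = fn(node.length)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"<Phylogeny n_leaves={self.n_leaves}>"
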