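"""Tree algorithms shared by weighting and binning.

Provides edge annotation against a clade solution (which edges lie
inside which named group), pendant attachment and removal of query
taxa, and a random-tree generator for the likelihood-weighting null.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np

from .formats_io import CladeSolution
from .tree import Phylogeny, TreeNode

logger = logging.getLogger("cladebin")


class NotMonophyleticError(ValueError):
    """A clade-solution group is not monophyletic on the tree."""


@dataclass(frozen=True)
class EdgeRef:
    """An edge of a :class:`Phylogeny`, named by its child node.

    ``group`` is the clade-solution group whose leaf set contains every
    leaf below the edge, or ``None`` when the edge spans more than one
    group (or sits above all group crowns): attaching a query there is
    an OUTSIDE placement.
    """

    child: TreeNode
    index: int
    group: Optional[str]


def annotate_edges(tree: Phylogeny, solution: CladeSolution) -> list[EdgeRef]:
    """Label every edge of ``tree`` with its containing solution group.

    Every group must be monophyletic on the tree — the premise of
    evaluating a candidate classification — otherwise
    :class:`NotMonophyleticError` names the offending group.  Taxa on
    the tree that the solution does not assign (e.g. outgroups) belong
    to no group; edges over them are OUTSIDE.
    """
    leaf_labels = set(tree.leaf_labels)
    extra = sorted(set(solution.assignment) - leaf_labels)
    if extra:
        raise NotMonophyleticError(
            f"solution {solution.name!r} assigns taxa not on the tree: {extra}"
        )
    sets = tree.leafsets()
    for g in solution.groups:
        members = frozenset(solution.members(g))
        if len(members) > 1 and members not in sets.values():
            raise NotMonophyleticError(
                f"group {g!r} not monophyletic on the tree"
            )
    group_of = solution.assignment
    refs: list[EdgeRef] = []
    for index, child in enumerate(tree.edges()):
        below = sets[child]
        groups_below = {group_of.get(lab) for lab in below}
        if len(groups_below) == 1 and None not in groups_below:
            group = next(iter(groups_below))
        else:
            group = None
        refs.append(EdgeRef(child=child, index=index, group=group))
    return refs


def random_tree(
    leaf_labels: Sequence[str],
    length_pool: Sequence[float],
    seed: Union[int, np.random.Generator],
) -> Phylogeny:
    """A uniform random rooted binary labelled topology.

    Built by random sequential attachment: the k-th leaf is attached
    to one of the ``2k-3`` positions (any existing edge, or above the
    root), which draws uniformly from the ``(2n-3)!!`` rooted binary
    topologies.  Branch lengths are a seeded random permutation of
    ``length_pool``, which must have exactly ``2n-2`` entries —
    typically the reference tree's own lengths, so the null preserves
    the observed length distribution while destroying structure.
    """
    labels = sorted(set(leaf_labels))
    n = len(labels)
    if n != len(list(leaf_labels)):
        raise ValueError("duplicate leaf labels")
    if n < 3:
        raise ValueError(f"random_tree needs >=3 leaves, got {n}")
    pool = np.asarray(length_pool, dtype=float)
    if pool.size != 2 * n - 2:
        raise ValueError(
            f"length_pool has {pool.size} entries, need 2n-2 = {2 * n - 2}"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    root = TreeNode()
    root.add_child(TreeNode(labels[0]))
    root.add_child(TreeNode(labels[1]))
    tree = Phylogeny(root)
    edges: list[TreeNode] = list(root.children)
    for label in labels[2:]:
        pos = int(rng.integers(len(edges) + 1))
        leaf = TreeNode(label)
        if pos == len(edges):  # attach above the current root
            new_root = TreeNode()
            old_root = tree.root
            new_root.add_child(old_root)
            new_root.add_child(leaf)
            tree.root = new_root
            edges.append(old_root)
            edges.append(leaf)
        else:
            target = edges[pos]
            parent = target.parent
            mid = TreeNode()
            idx = parent.children.index(target)
            parent.children[idx] = mid
            mid.parent = parent
            mid.add_child(target)
            mid.add_child(leaf)
            edges.append(mid)
            edges.append(leaf)

    perm = rng.permutation(pool.size)
    for e, node in enumerate(tree.edges()):
        node.length = float(pool[perm[e]])
    return tree


def attach_query(
    tree: Phylogeny, edge: Union[EdgeRef, TreeNode], label: str
) -> Phylogeny:
    """Return a copy of ``tree`` with a pendant leaf on ``edge``.

    The new internal node keeps the split edge's original length and
    the two newly created edges (pendant leaf, lower half of the split)
    get length 0, so detaching the leaf restores the original tree
    exactly.  Lengths are irrelevant to parsimony placement.
    """
    child = edge.child if isinstance(edge, EdgeRef) else edge
    if label in tree.leaf_labels:
        raise ValueError(f"taxon {label!r} is already a leaf")
    new_tree, mapping = tree.copy()
    target = mapping[child]
    parent = target.parent
    if parent is None:
        raise ValueError("cannot attach on the root node itself")
    mid = TreeNode(length=target.length)
    idx = parent.children.index(target)
    parent.children[idx] = mid
    mid.parent = parent
    target.length = 0.0
    mid.add_child(target)
    mid.add_child(TreeNode(label, length=0.0))
    return new_tree


def detach_leaf(tree: Phylogeny, label: str) -> Phylogeny:
    """Return a copy of ``tree`` without leaf ``label`` (inverse of attach)."""
    new_tree, _ = tree.copy()
    match = [n for n in new_tree.preorder() if n.is_leaf and n.label == label]
    if not match:
        raise ValueError(f"no leaf labelled {label!r}")
    leaf = match[0]
    parent = leaf.parent
    if parent is None:
        raise ValueError("cannot detach the root")
    parent.children.remove(leaf)
    _suppress(new_tree, parent)
    return new_tree


def _suppress(tree: Phylogeny, node: TreeNode) -> None:
    if len(node.children) != 1:
        return
    child = node.children[0]
    if node.parent is None:
        child.parent = None
        child.length = None
        tree.root = child
        return
    if node.length is not None and child.length is not None:
        child.length = child.length + node.length
    idx = node.parent.children.index(node)
    node.parent.children[idx] = child
    child.parent = node.parent
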