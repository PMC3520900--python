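"""Scoring one discrete character on one tree.

Two engines:

* minimum parsimony steps — Fitch set DP for unordered (incl. binary)
  characters, Sankoff DP with linear ``|i - j|`` costs for ordered
  multistate characters;
* Mk-model log-likelihood by Felsenstein pruning, with the k-state
  Jukes–Cantor-type closed-form transition probabilities, equal
  exchange rates, uniform stationary frequencies and the root at
  stationarity.

Missing leaves use the all-states-possible convention in both engines
(zero cost / all-ones conditionals), so the taxon set stays identical
across characters.  Exhaustive enumeration counterparts are provided
for validation at small size.
"""

from __future__ import annotations

import itertools
import math
from typing import Mapping, Optional

import numpy as np

from .formats_io import MISSING
from .tree import Phylogeny, TreeNode

_INF = float("inf")


def _leaf_state(states: Mapping[str, int], node: TreeNode) -> Optional[int]:
    s = states.get(node.label, MISSING)
    return None if s == MISSING or s is None else int(s)


def _check_observed(tree: Phylogeny, states: Mapping[str, int]) -> list[int]:
    obs = [
        s for n in tree.leaves
        if (s := _leaf_state(states, n)) is not None
    ]
    if not obs:
        raise ValueError("character has no non-missing state on the tree")
    return obs


# ---------------------------------------------------------------------------
# Parsimony
# ---------------------------------------------------------------------------


def fitch_steps(tree: Phylogeny, states: Mapping[str, int]) -> int:
    """Minimum unordered (0/1 cost) parsimony steps, Fitch set DP."""
    obs = _check_observed(tree, states)
    full = frozenset(range(max(obs) + 1)) | frozenset(obs)
    steps = 0
    sets: dict[TreeNode, frozenset[int]] = {}
    for node in tree.postorder():
        if node.is_leaf:
            s = _leaf_state(states, node)
            sets[node] = full if s is None else frozenset((s,))
        else:
            acc = sets[node.children[0]]
            for child in node.children[1:]:
                inter = acc & sets[child]
                if inter:
                    acc = inter
                else:
                    acc = acc | sets[child]
                    steps += 1
            sets[node] = acc
    return steps


def sankoff_steps(
    tree: Phylogeny, states: Mapping[str, int], cost: np.ndarray
) -> float:
    """Minimum parsimony cost under an arbitrary k x k cost matrix."""
    _check_observed(tree, states)
    k = cost.shape[0]
    table: dict[TreeNode, np.ndarray] = {}
    for node in tree.postorder():
        if node.is_leaf:
            s = _leaf_state(states, node)
            vec = np.zeros(k) if s is None else np.full(k, _INF)
            if s is not None:
                if s >= k:
                    raise ValueError(f"state {s} outside alphabet of size {k}")
                vec[s] = 0.0
            table[node] = vec
        else:
            vec = np.zeros(k)
            for child in node.children:
                vec = vec + np.min(cost + table[child][None, :], axis=1)
            table[node] = vec
    return float(table[tree.root].min())


def linear_cost(k: int) -> np.ndarray:
    """Wagner-style ordered cost matrix ``|i - j|``."""
    idx = np.arange(k)
    return np.abs(idx[:, None] - idx[None, :]).astype(float)


def unit_cost(k: int) -> np.ndarray:
    return 1.0 - np.eye(k)


def parsimony_steps(
    tree: Phylogeny,
    states: Mapping[str, int],
    k: Optional[int] = None,
    ordered: bool = False,
) -> int:
    """Minimum number of (weighted) state changes of one character.

    Unordered characters use Fitch; ordered characters use Sankoff with
    linear costs, so a 0 -> 2 change counts two steps.
    """
    obs = _check_observed(tree, states)
    if k is None:
        k = max(obs) + 1
    if not ordered:
        return fitch_steps(tree, states)
    return int(round(sankoff_steps(tree, states, linear_cost(k))))


def enumerate_steps(
    tree: Phylogeny, states: Mapping[str, int], k: int, ordered: bool = False
) -> int:
    """Exhaustive-minimisation reference for :func:`parsimony_steps`.

    Tries every assignment of internal-node states; exponential in the
    internal node count, usable only on small trees.
    """
    _check_observed(tree, states)
    cost = linear_cost(k) if ordered else unit_cost(k)
    internals = [n for n in tree.postorder() if not n.is_leaf]
    best = _INF
    for combo in itertools.product(range(k), repeat=len(internals)):
        assign = dict(zip(internals, combo))
        total = 0.0
        for node in tree.preorder():
            if node.parent is None:
                continue
            s = assign[node] if node in assign else _leaf_state(states, node)
            if s is None:
                # missing leaf: cheapest state given the parent
                total += cost[assign[node.parent]].min()
                continue
            total += cost[assign[node.parent], s]
        best = min(best, total)
    return int(round(best))


# ---------------------------------------------------------------------------
# Mk likelihood
# ---------------------------------------------------------------------------


def _mk_transition(k: int, t: float) -> np.ndarray:
    """Closed-form Mk transition matrix over branch length ``t``."""
    e = math.exp(-k * t / (k - 1))
    p_same = 1.0 / k + (k - 1.0) / k * e
    p_diff = 1.0 / k - 1.0 / k * e
    P = np.full((k, k), p_diff)
    np.fill_diagonal(P, p_same)
    return P


def mk_loglik(tree: Phylogeny, states: Mapping[str, int], k: int) -> float:
    """Natural-log likelihood of one character under the Mk model."""
    if k < 2:
        raise ValueError(f"Mk model needs k >= 2, got {k}")
    obs = _check_observed(tree, states)
    if max(obs) >= k:
        raise ValueError(f"observed state {max(obs)} outside alphabet size {k}")
    logscale = 0.0
    partial: dict[TreeNode, np.ndarray] = {}
    for node in tree.postorder():
        if node.is_leaf:
            s = _leaf_state(states, node)
            vec = np.ones(k) if s is None else np.zeros(k)
            if s is not None:
                vec[s] = 1.0
        else:
            vec = np.ones(k)
            for child in node.children:
                t = child.length if child.length is not None else 1.0
                if t < 0:
                    raise ValueError(f"negative branch length {t}")
                vec = vec * (_mk_transition(k, t) @ partial[child])
            m = vec.max()
            if m <= 0:
                return -_INF
            vec = vec / m
            logscale += math.log(m)
        partial[node] = vec
    like = float(partial[tree.root].mean())  # uniform root frequencies 1/k
    return math.log(like) + logscale


def mk_loglik_bruteforce(
    tree: Phylogeny, states: Mapping[str, int], k: int
) -> float:
    """Direct summation over all internal-state combinations.

    Reference implementation for :func:`mk_loglik`; exponential in the
    internal node count.
    """
    if k < 2:
        raise ValueError(f"Mk model needs k >= 2, got {k}")
    _check_observed(tree, states)
    internals = [n for n in tree.postorder() if not n.is_leaf]
    leaves = tree.leaves
    total = 0.0
    for combo in itertools.product(range(k), repeat=len(internals)):
        assign = dict(zip(internals, combo))
        # leaves may be missing: sum over their states too
        leaf_choices = []
        for leaf in leaves:
            s = _leaf_state(states, leaf)
            leaf_choices.append(range(k) if s is None else (s,))
        for leaf_combo in itertools.product(*leaf_choices):
            full = dict(assign)
            full.update(zip(leaves, leaf_combo))
            prob = 1.0 / k  # uniform root prior
            for node in tree.preorder():
                if node.parent is None:
                    continue
                t = node.length if node.length is not None else 1.0
                P = _mk_transition(k, t)
                prob *= P[full[node.parent], full[node]]
            total += prob
    return math.log(total)
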