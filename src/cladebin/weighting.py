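"""Character weights from tree fit, under the ML and MP schemes.

ML weighting compares each character's Mk log-likelihood on the
molecular reference tree against a shared set of randomized trees
(uniform topologies carrying a permutation of the reference branch
lengths): the weight is the fraction of random trees on which the
character scores *strictly worse*.  A character tracing a clean clade
loses on essentially every randomization and is weighted 1; a
character whose fit is indistinguishable from noise hovers near the
coin-flip expectation.

MP weighting needs only the reference tree: the character's parsimony
steps ``s`` are rescaled between the minimum possible steps ``m`` and
the maximum possible steps ``g`` as ``(g - s) / (g - m)`` — the
retention index — so a perfect synapomorphy gets weight 1 and a
maximally homoplastic character weight 0.  Invariant characters
(``g = m``) are defined to have weight 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from . import char_scores
from .formats_io import MISSING, ORDERED, MorphMatrix
from .tree import Phylogeny
from .tree_core import random_tree

logger = logging.getLogger("cladebin")

#: log-likelihood differences smaller than this count as ties
#: (ties are "not worse"), so characters whose likelihood is
#: mathematically tree-independent get weight 0 regardless of
#: floating-point evaluation order.
LOGLIK_TIE_TOL = 1e-9


@dataclass
class CharacterWeights:
    """Per-character weights in [0, 1] under one scheme."""

    scheme: str  # "ML" or "MP"
    characters: list[str]
    weights: np.ndarray
    diagnostics: pd.DataFrame

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if np.any((self.weights < 0) | (self.weights > 1)):
            raise ValueError("weights must lie in [0, 1]")

    def as_series(self) -> pd.Series:
        return pd.Series(self.weights, index=self.characters, name=self.scheme)


def _restrict(ref: Phylogeny, matrix: MorphMatrix) -> MorphMatrix:
    keep = [t for t in matrix.taxa if t in set(ref.leaf_labels)]
    if not keep:
        raise ValueError("no overlap between matrix taxa and tree leaves")
    return matrix.subset(keep)


def ml_weights(
    ref: Phylogeny,
    matrix: MorphMatrix,
    n_random: int = 100,
    seed: int = 0,
    rng: Optional[np.random.Generator] = None,
) -> CharacterWeights:
    """Likelihood-based weights against a shared randomized-tree null.

    ``w_c = #{random trees r : lnL(r, c) < lnL(ref, c)} / n_random``
    with strict inequality; one random-tree set (seeded) is shared by
    all characters.
    """
    if n_random < 1:
        raise ValueError("n_random must be >= 1")
    sub = _restrict(ref, matrix)
    rng = rng if rng is not None else np.random.default_rng(seed)
    pool = [e.length for e in ref.edges()]
    trees = [random_tree(ref.leaf_labels, pool, rng) for _ in range(n_random)]

    # state-space sizes from the full matrix (queries included), so the
    # same alphabet is used here and during placement
    ks = matrix.ks
    weights = np.zeros(sub.n_chars)
    ref_ll = np.zeros(sub.n_chars)
    worse = np.zeros(sub.n_chars, dtype=int)
    for c in range(sub.n_chars):
        states = sub.column(c)
        if not states:
            raise ValueError(
                f"character {sub.characters[c]!r} all-missing on reference taxa"
            )
        ref_ll[c] = char_scores.mk_loglik(ref, states, ks[c])
        for t in trees:
            if char_scores.mk_loglik(t, states, ks[c]) < ref_ll[c] - LOGLIK_TIE_TOL:
                worse[c] += 1
        weights[c] = worse[c] / n_random
    diagnostics = pd.DataFrame(
        {
            "character": sub.characters,
            "ref_loglik": ref_ll,
            "n_worse": worse,
            "n_random": n_random,
        }
    )
    return CharacterWeights("ML", list(sub.characters), weights, diagnostics)


def _min_steps(col: np.ndarray, ordered: bool) -> int:
    obs = col[col != MISSING]
    if ordered:
        return int(obs.max() - obs.min())
    return len(np.unique(obs)) - 1


def _max_steps(col: np.ndarray, ordered: bool) -> int:
    """Maximum parsimony steps of the character on any tree.

    Unordered: steps on the worst tree equal ``n_obs`` minus the
    largest state frequency.  Ordered: the completely unresolved tree
    is worst; its length is ``min_m sum_i |x_i - m|``, attained at a
    (weighted) median state ``m``.
    """
    obs = col[col != MISSING]
    if ordered:
        return int(
            min(np.abs(obs - m).sum() for m in range(int(obs.min()), int(obs.max()) + 1))
        )
    _, counts = np.unique(obs, return_counts=True)
    return int(len(obs) - counts.max())


def mp_weights(ref: Phylogeny, matrix: MorphMatrix) -> CharacterWeights:
    """Parsimony-based weights from the reference tree alone.

    ``w_c = (g_c - s_c) / (g_c - m_c)`` (retention index), with
    ``w_c = 1`` for invariant characters where ``g_c = m_c``.
    """
    sub = _restrict(ref, matrix)
    ks = matrix.ks
    n = sub.n_chars
    steps = np.zeros(n, dtype=int)
    mins = np.zeros(n, dtype=int)
    maxs = np.zeros(n, dtype=int)
    weights = np.zeros(n)
    for c in range(n):
        states = sub.column(c)
        if not states:
            raise ValueError(
                f"character {sub.characters[c]!r} all-missing on reference taxa"
            )
        ordered = sub.kinds[c] == ORDERED
        col = sub.states[:, c]
        steps[c] = char_scores.parsimony_steps(ref, states, ks[c], ordered=ordered)
        mins[c] = _min_steps(col, ordered)
        maxs[c] = _max_steps(col, ordered)
        if maxs[c] == mins[c]:
            weights[c] = 1.0
        else:
            weights[c] = (maxs[c] - steps[c]) / (maxs[c] - mins[c])
        weights[c] = min(1.0, max(0.0, weights[c]))
    diagnostics = pd.DataFrame(
        {
            "character": sub.characters,
            "steps": steps,
            "min_steps": mins,
            "max_steps": maxs,
        }
    )
    return CharacterWeights("MP", list(sub.characters), weights, diagnostics)


def compute_weights(
    ref: Phylogeny,
    matrix: MorphMatrix,
    scheme: str,
    n_random: int = 100,
    seed: int = 0,
) -> CharacterWeights:
    scheme = scheme.upper()
    if scheme == "ML":
        return ml_weights(ref, matrix, n_random=n_random, seed=seed)
    if scheme == "MP":
        return mp_weights(ref, matrix)
    raise ValueError(f"unknown weighting scheme {scheme!r}")
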