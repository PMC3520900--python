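"""Per-character Kruskal-Wallis discrimination across clade solutions.

For every morphological character and every candidate clade solution,
a Kruskal-Wallis rank ANOVA asks whether the character discriminates
between the solution's groups.  The per-solution summary counts
characters that are significant (p < 0.05) and marginally significant
(0.05 <= p < 0.10); a classification whose groups are morphologically
real should show more discriminating characters than a coarser merge
of the same taxa.

The tie-corrected H statistic and its chi-square approximation come
from scipy; an exact permutation p-value is available for very small
samples.  Since the test is rank-based, ordered multistate characters
are analysed on their numeric codes and binary characters as 0/1.  No
multiple-testing correction is applied to the headline counts (they
count raw p thresholds); Benjamini-Hochberg adjusted p-values are
emitted alongside for transparency.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats

from .formats_io import MISSING, CladeSolution, MorphMatrix

logger = logging.getLogger("cladebin")

SIGNIFICANT = 0.05
MARGINAL = 0.10


def _group_samples(
    values: Sequence[float], groups: Sequence[str]
) -> list[np.ndarray]:
    values = np.asarray(values, dtype=float)
    groups = list(groups)
    if len(values) != len(groups):
        raise ValueError("values and groups differ in length")
    keep = ~np.isnan(values)
    values, groups = values[keep], [g for g, k in zip(groups, keep) if k]
    names: list[str] = []
    for g in groups:
        if g not in names:
            names.append(g)
    samples = [
        values[np.array([gg == g for gg in groups])] for g in names
    ]
    samples = [s for s in samples if s.size > 0]
    if len(samples) < 2:
        raise ValueError(
            "fewer than 2 groups with observations after dropping missing"
        )
    return samples


def kruskal_wallis(
    values: Sequence[float], groups: Sequence[str]
) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H and its chi-square p-value.

    Missing values (NaN) are dropped together with their labels.  When
    every observation is identical the statistic is defined as H = 0,
    p = 1.
    """
    samples = _group_samples(values, groups)
    pooled = np.concatenate(samples)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    H, p = scipy.stats.kruskal(*samples)
    return float(H), float(p)


MAX_EXACT_N = 12


def kruskal_wallis_exact(
    values: Sequence[float], groups: Sequence[str]
) -> tuple[float, float]:
    """Exact permutation p-value for the Kruskal-Wallis statistic.

    Enumerates every distinct reassignment of observations to groups of
    the same sizes; feasible only for n <= 12.
    """
    samples = _group_samples(values, groups)
    pooled = np.concatenate(samples)
    n = pooled.size
    if n > MAX_EXACT_N:
        raise ValueError(f"exact test limited to n <= {MAX_EXACT_N}, got {n}")
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    sizes = [s.size for s in samples]
    H_obs = _h_statistic(samples)

    hits = 0
    total = 0
    indices = tuple(range(n))

    def recurse(remaining: tuple[int, ...], g: int, chosen: list[np.ndarray]):
        nonlocal hits, total
        if g == len(sizes) - 1:
            final = chosen + [pooled[list(remaining)]]
            total += 1
            if _h_statistic(final) >= H_obs - 1e-12:
                hits += 1
            return
        for combo in itertools.combinations(remaining, sizes[g]):
            rest = tuple(i for i in remaining if i not in combo)
            recurse(rest, g + 1, chosen + [pooled[list(combo)]])

    recurse(indices, 0, [])
    return float(H_obs), hits / total


def _h_statistic(samples: list[np.ndarray]) -> float:
    """Tie-corrected H over explicit midranks (independent of scipy path)."""
    pooled = np.concatenate(samples)
    ranks = scipy.stats.rankdata(pooled)
    n = pooled.size
    start = 0
    H = 0.0
    for s in samples:
        r = ranks[start:start + s.size]
        H += r.sum() ** 2 / s.size
        start += s.size
    H = 12.0 / (n * (n + 1)) * H - 3 * (n + 1)
    _, counts = np.unique(pooled, return_counts=True)
    tie = 1.0 - float(((counts**3 - counts).sum()) / (n**3 - n))
    if tie == 0:
        return 0.0
    return H / tie


@dataclass
class KWSummary:
    """Kruskal-Wallis results across characters and solutions."""

    pvalues: pd.DataFrame   # character x solution
    h: pd.DataFrame         # character x solution
    counts: pd.DataFrame    # solution x (significant, marginal, total)
    bh: pd.DataFrame        # Benjamini-Hochberg adjusted p, character x solution

    def table5(self) -> pd.DataFrame:
        """Report grid: p-values shown only when below 0.1, else blank."""
        def fmt(p: float) -> str:
            return f"{p:.4f}" if p < MARGINAL else ""

        out = self.pvalues.map(fmt)
        out.insert(0, "character", self.pvalues.index)
        return out.reset_index(drop=True)


def discrimination_table(
    matrix: MorphMatrix,
    solutions: Sequence[CladeSolution] | Mapping[str, Mapping[str, str]],
) -> KWSummary:
    """Kruskal-Wallis tests of every character against every solution.

    ``solutions`` may be :class:`CladeSolution` objects (their
    assignments must cover the matrix taxa used) or a mapping from a
    solution name to a taxon -> group mapping, which allows grouping
    variables produced by binning (query taxa included).  Matrix taxa
    absent from an assignment are dropped for that solution.
    """
    if isinstance(solutions, Mapping):
        named: list[tuple[str, Mapping[str, str]]] = list(solutions.items())
    else:
        named = [(s.name, s.assignment) for s in solutions]
    if not named:
        raise ValueError("need at least one solution")

    X = matrix.states.astype(float)
    X[matrix.states == MISSING] = np.nan
    pvals = {}
    hstats = {}
    rows = []
    for name, assignment in named:
        keep = [i for i, t in enumerate(matrix.taxa) if t in assignment]
        labels = [assignment[matrix.taxa[i]] for i in keep]
        col_p = np.ones(matrix.n_chars)
        col_h = np.zeros(matrix.n_chars)
        for c in range(matrix.n_chars):
            vals = X[keep, c]
            try:
                col_h[c], col_p[c] = kruskal_wallis(vals, labels)
            except ValueError:
                # e.g. all observed values in a single group: uninformative
                col_h[c], col_p[c] = 0.0, 1.0
        pvals[name] = col_p
        hstats[name] = col_h
        n_sig = int(np.sum(col_p < SIGNIFICANT))
        n_marg = int(np.sum((col_p >= SIGNIFICANT) & (col_p < MARGINAL)))
        rows.append(
            {
                "solution": name,
                "significant": n_sig,
                "marginal": n_marg,
                "total": n_sig + n_marg,
            }
        )
    index = pd.Index(matrix.characters, name="character")
    pdf = pd.DataFrame(pvals, index=index)
    hdf = pd.DataFrame(hstats, index=index)
    bh = pd.DataFrame(
        {
            name: scipy.stats.false_discovery_control(pdf[name].to_numpy())
            for name in pdf.columns
        },
        index=index,
    )
    counts = pd.DataFrame(rows)
    return KWSummary(pvalues=pdf, h=hdf, counts=counts, bh=bh)
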