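"""Synthetic study scenarios for the binning/MRPP framework.

No morphological matrix is distributed with typical studies of this
kind, so validation relies on generated scenarios that reproduce the
statistical structure the framework assumes: a molecular reference
tree whose leaves fall into named monophyletic clades, a larger set of
query taxa known only from morphology, and a matrix of binary/ordered
characters in which a tunable fraction is clade-diagnostic while the
rest evolves neutrally on the tree.

The default scenario mirrors the motivating study design: 21 sequenced
reference species, 65 morphology-only query species, 24 characters,
and nested 2-, 4- and 5-clade candidate solutions with group sizes
proportional to the published 4/5-clade placements (16/24/5/20 of 65,
with clade I split 8/8 at the 5-clade level).

Clade-diagnostic characters are generated state-per-group (not
evolved), so ground-truth synapomorphies are known exactly; each
taxon's state is then flipped to a random different state with
probability ``noise_rate``.  Diagnostic states are assigned at the
4-clade level (I, IIa, IIb, IIc): the subdivision of clade I into
Ia/Ib is phylogenetically real but carries no diagnostic morphology,
mirroring the study system where the finest split lacked clear
phenotypic support.  Each query taxon is modelled as a sister lineage
of a randomly chosen reference member of its group: diagnostic
characters take the group's diagnostic state (with noise), neutral
characters evolve onward from the donor's state along the query's own
pendant branch.  Cells are masked missing with probability
``missing_rate``.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import asdict, dataclass
from typing import Optional

import numpy as np

from .char_scores import _mk_transition
from .formats_io import (
    BINARY,
    MISSING,
    ORDERED,
    CladeSolution,
    MorphMatrix,
    write_newick,
)
from .tree import Phylogeny, TreeNode

#: finest-level groups; clade I = Ia + Ib, clade II = IIa + IIb + IIc
FINE_GROUPS = ("Ia", "Ib", "IIa", "IIb", "IIc")

#: query-pool fractions per fine group (4-clade 16/24/5/20 of 65,
#: clade I split evenly at the 5-clade level)
GROUP_FRACTIONS = {
    "Ia": 8 / 65,
    "Ib": 8 / 65,
    "IIa": 24 / 65,
    "IIb": 5 / 65,
    "IIc": 20 / 65,
}

_SOLUTION_LEVELS = {
    "2-clade": {"Ia": "I", "Ib": "I", "IIa": "II", "IIb": "II", "IIc": "II"},
    "4-clade": {"Ia": "I", "Ib": "I", "IIa": "IIa", "IIb": "IIb", "IIc": "IIc"},
    "5-clade": {g: g for g in FINE_GROUPS},
}


@dataclass
class ScenarioParams:
    n_ref: int = 21
    n_query: int = 65
    n_chars: int = 24
    clade_signal: float = 0.8
    noise_rate: float = 0.1
    missing_rate: float = 0.0
    prop_binary: float = 0.75
    branch_scale: float = 0.2
    mk_rate: float = 5.0

    def validate(self) -> None:
        n_groups = len(FINE_GROUPS)
        if self.n_ref < 2 * n_groups:
            raise ValueError(
                f"n_ref must be >= {2 * n_groups} (2 per group), got {self.n_ref}"
            )
        if self.n_query < 1:
            raise ValueError("n_query must be >= 1")
        if self.n_chars < 1:
            raise ValueError("n_chars must be >= 1")
        for name in ("clade_signal", "noise_rate", "missing_rate", "prop_binary"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.mk_rate <= 0:
            raise ValueError("mk_rate must be positive")
        if self.branch_scale <= 0:
            raise ValueError("branch_scale must be positive")


@dataclass
class Scenario:
    ref_tree: Phylogeny
    solutions: dict[str, CladeSolution]
    matrix: MorphMatrix              # reference + query rows, shared coding
    ref_taxa: list[str]
    query_taxa: list[str]
    true_query_groups: dict[str, dict[str, str]]  # solution -> query -> group
    diagnostic: list[bool]           # per character: clade-diagnostic?
    params: ScenarioParams
    seed: int = 0

    @property
    def ref_matrix(self) -> MorphMatrix:
        return self.matrix.subset(self.ref_taxa)

    @property
    def query_matrix(self) -> MorphMatrix:
        return self.matrix.subset(self.query_taxa)

    def true_groups_fine(self) -> dict[str, str]:
        return dict(self.true_query_groups["5-clade"])

    def write(self, outdir: str) -> None:
        os.makedirs(outdir, exist_ok=True)
        with open(os.path.join(outdir, "ref_tree.nwk"), "w") as fh:
            fh.write(write_newick(self.ref_tree) + "\n")
        self.matrix.to_csv(os.path.join(outdir, "matrix.csv"))
        for name, sol in self.solutions.items():
            sol.to_csv(os.path.join(outdir, f"solution_{name}.csv"))
        for name, mapping in self.true_query_groups.items():
            path = os.path.join(outdir, f"true_query_groups_{name}.csv")
            with open(path, "w", newline="") as fh:
                fh.write("taxon,group\n")
                for taxon, group in mapping.items():
                    fh.write(f"{taxon},{group}\n")
        meta = asdict(self.params)
        meta["seed"] = self.seed
        meta["queries"] = self.query_taxa
        with open(os.path.join(outdir, "params.json"), "w") as fh:
            json.dump(meta, fh, indent=2, sort_keys=True)
            fh.write("\n")


# ---------------------------------------------------------------------------
# Tree simulation
# ---------------------------------------------------------------------------


def _yule_subtree(
    labels: list[str], rng: np.random.Generator, scale: float
) -> TreeNode:
    """Pure-birth subtree over ``labels``, exp(scale) branch lengths."""
    if len(labels) == 1:
        node = TreeNode(labels[0], length=float(rng.exponential(scale)))
        return node
    root = TreeNode()
    pendants = [root]
    while len(pendants) < len(labels):
        idx = int(rng.integers(len(pendants)))
        node = pendants.pop(idx)
        a, b = TreeNode(), TreeNode()
        node.add_child(a)
        node.add_child(b)
        pendants.extend([a, b])
    for leaf, label in zip(pendants, labels):
        leaf.label = label
    stack = [root]
    while stack:
        node = stack.pop()
        for child in node.children:
            child.length = float(rng.exponential(scale))
            stack.append(child)
    return root


def _build_tree(
    group_members: dict[str, list[str]],
    rng: np.random.Generator,
    scale: float,
) -> Phylogeny:
    """Backbone ((Ia,Ib),(IIa,(IIb,IIc))) with Yule subtrees per group."""
    sub = {g: _yule_subtree(group_members[g], rng, scale) for g in FINE_GROUPS}
    for g in FINE_GROUPS:
        sub[g].length = float(rng.exponential(scale))
    clade_i = TreeNode(length=float(rng.exponential(scale)))
    clade_i.add_child(sub["Ia"])
    clade_i.add_child(sub["Ib"])
    clade_iibc = TreeNode(length=float(rng.exponential(scale)))
    clade_iibc.add_child(sub["IIb"])
    clade_iibc.add_child(sub["IIc"])
    clade_ii = TreeNode(length=float(rng.exponential(scale)))
    clade_ii.add_child(sub["IIa"])
    clade_ii.add_child(clade_iibc)
    root = TreeNode()
    root.add_child(clade_i)
    root.add_child(clade_ii)
    return Phylogeny(root)


def simulate_mk_character(
    tree: Phylogeny, k: int, rate: float, rng: np.random.Generator
) -> dict[str, int]:
    """Evolve one k-state character on the tree under Mk at ``rate``."""
    states: dict[TreeNode, int] = {}
    out: dict[str, int] = {}
    for node in tree.preorder():
        if node.parent is None:
            states[node] = int(rng.integers(k))
        else:
            t = (node.length if node.length is not None else 1.0) * rate
            row = _mk_transition(k, t)[states[node.parent]]
            states[node] = int(rng.choice(k, p=row / row.sum()))
        if node.is_leaf:
            out[node.label] = states[node]
    return out


# ---------------------------------------------------------------------------
# Scenario assembly
# ---------------------------------------------------------------------------


def _allocate(total: int, minimum: int) -> dict[str, int]:
    """Largest-remainder allocation of ``total`` over the fine groups."""
    names = list(FINE_GROUPS)
    raw = {g: total * GROUP_FRACTIONS[g] for g in names}
    sizes = {g: math.floor(raw[g]) for g in names}
    leftover = total - sum(sizes.values())
    by_rem = sorted(names, key=lambda g: (-(raw[g] - sizes[g]), names.index(g)))
    for g in by_rem[:leftover]:
        sizes[g] += 1
    while any(sizes[g] < minimum for g in names):
        small = min(names, key=lambda g: (sizes[g], names.index(g)))
        big = max(names, key=lambda g: (sizes[g], -names.index(g)))
        sizes[small] += 1
        sizes[big] -= 1
    return sizes


def _flip(state: int, k: int, rng: np.random.Generator, rate: float) -> int:
    if k > 1 and rng.random() < rate:
        alt = int(rng.integers(k - 1))
        return alt if alt < state else alt + 1
    return state


def _modal(states: list[int]) -> int:
    vals, counts = np.unique(np.array(states), return_counts=True)
    return int(vals[np.argmax(counts)])  # ties: smallest state


def simulate_scenario(
    params: Optional[ScenarioParams] = None, seed: int = 0
) -> Scenario:
    """Generate a full scenario as a pure function of (params, seed).

    Randomness is split into per-purpose substreams (tree, each
    character, noise, missingness), so that varying ``clade_signal``
    with the seed held fixed converts characters between neutral and
    diagnostic while leaving every other character byte-identical —
    scenarios along a signal grid are coupled (common random numbers),
    which makes signal-response comparisons paired rather than
    independent.
    """
    params = params or ScenarioParams()
    params.validate()
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0]))

    ref_sizes = _allocate(params.n_ref, minimum=2)
    query_sizes = _allocate(params.n_query, minimum=1)

    ref_members: dict[str, list[str]] = {}
    query_members: dict[str, list[str]] = {}
    r = q = 0
    for g in FINE_GROUPS:
        ref_members[g] = [f"R{r + i + 1:02d}" for i in range(ref_sizes[g])]
        r += ref_sizes[g]
        query_members[g] = [f"Q{q + i + 1:02d}" for i in range(query_sizes[g])]
        q += query_sizes[g]
    ref_taxa = [t for g in FINE_GROUPS for t in ref_members[g]]
    query_taxa = [t for g in FINE_GROUPS for t in query_members[g]]
    fine_of = {t: g for g in FINE_GROUPS for t in ref_members[g] + query_members[g]}

    tree = _build_tree(ref_members, rng, params.branch_scale)

    # each query is a distinct species: a sister lineage of a randomly
    # drawn reference member of its group, with its own pendant branch
    query_donor = {}
    query_pendant = {}
    for t in query_taxa:
        members = ref_members[fine_of[t]]
        query_donor[t] = members[int(rng.integers(len(members)))]
        query_pendant[t] = float(rng.exponential(params.branch_scale))

    n_all = len(ref_taxa) + len(query_taxa)
    taxa = ref_taxa + query_taxa
    states = np.full((n_all, params.n_chars), MISSING, dtype=np.int16)
    kinds: list[str] = []
    diagnostic: list[bool] = []
    for c in range(params.n_chars):
        # every draw for character c comes from substreams keyed by
        # (seed, c), so characters are independent of one another and
        # stable across clade_signal values
        rng_c = np.random.default_rng(np.random.SeedSequence([seed, 1, c]))
        if rng_c.random() < params.prop_binary:
            k = 2
        else:
            k = int(rng_c.integers(3, 5))
        kinds.append(BINARY if k == 2 else ORDERED)
        is_diag = rng_c.random() < params.clade_signal
        diagnostic.append(is_diag)
        if is_diag:
            # a diagnostic character is a clean synapomorphy of one clade
            # at the 4-clade level: the marked group carries the derived
            # state k-1, everything else the ancestral state 0.  Ia and Ib
            # always share diagnostic states (the finest split carries no
            # morphology).
            rng_diag = np.random.default_rng(
                np.random.SeedSequence([seed, 2, c])
            )
            diag_level = _SOLUTION_LEVELS["4-clade"]
            diag_groups = sorted(set(diag_level.values()))
            target = diag_groups[int(rng_diag.integers(len(diag_groups)))]
            profile = {
                t: (k - 1 if diag_level[fine_of[t]] == target else 0)
                for t in taxa
            }
        else:
            # neutral character: evolve on the tree, then extend to each
            # query by evolving further along its own pendant branch from
            # its donor — phylogenetic signal, but no fixed group marker
            rng_mk = np.random.default_rng(np.random.SeedSequence([seed, 3, c]))
            leaf_states = simulate_mk_character(tree, k, params.mk_rate, rng_mk)
            profile = {t: leaf_states[t] for t in ref_taxa}
            for t in query_taxa:
                t_len = query_pendant[t] * params.mk_rate
                row = _mk_transition(k, t_len)[leaf_states[query_donor[t]]]
                profile[t] = int(rng_mk.choice(k, p=row / row.sum()))
        rng_noise = np.random.default_rng(np.random.SeedSequence([seed, 4, c]))
        for i, t in enumerate(taxa):
            states[i, c] = _flip(profile[t], k, rng_noise, params.noise_rate)

    if params.missing_rate > 0:
        rng_missing = np.random.default_rng(np.random.SeedSequence([seed, 5]))
        mask = rng_missing.random(states.shape) < params.missing_rate
        states = np.where(mask, np.int16(MISSING), states)
        n_ref = len(ref_taxa)
        for c in range(params.n_chars):  # keep every character observable
            if np.all(states[:n_ref, c] == MISSING):
                states[0, c] = 0
        for i in range(n_all):          # keep every taxon observable
            if np.all(states[i] == MISSING):
                states[i, 0] = 0

    # compact each column to consecutive codes 0..k-1 (order-preserving),
    # matching what reading the matrix back from CSV would produce
    for c in range(params.n_chars):
        col = states[:, c]
        observed = sorted({int(s) for s in col[col != MISSING]})
        remap = {orig: code for code, orig in enumerate(observed)}
        for i in range(n_all):
            if col[i] != MISSING:
                col[i] = remap[int(col[i])]

    matrix = MorphMatrix(
        taxa=taxa,
        characters=[f"char_{c + 1:02d}" for c in range(params.n_chars)],
        states=states,
        kinds=kinds,
    )

    solutions = {}
    true_query_groups = {}
    for name, level in _SOLUTION_LEVELS.items():
        assignment = {t: level[fine_of[t]] for t in ref_taxa}
        solutions[name] = CladeSolution(name=name, assignment=assignment)
        true_query_groups[name] = {t: level[fine_of[t]] for t in query_taxa}

    return Scenario(
        ref_tree=tree,
        solutions=solutions,
        matrix=matrix,
        ref_taxa=ref_taxa,
        query_taxa=query_taxa,
        true_query_groups=true_query_groups,
        diagnostic=diagnostic,
        params=params,
        seed=seed,
    )


def default_study_scenario(
    seed: int = 0,
    clade_signal: float = 0.8,
    noise_rate: float = 0.1,
    missing_rate: float = 0.0,
) -> Scenario:
    """The 21-reference / 65-query / 24-character default scenario."""
    params = ScenarioParams(
        n_ref=21,
        n_query=65,
        n_chars=24,
        clade_signal=clade_signal,
        noise_rate=noise_rate,
        missing_rate=missing_rate,
    )
    return simulate_scenario(params, seed=seed)
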