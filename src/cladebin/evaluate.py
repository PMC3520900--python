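"""End-to-end comparison of candidate clade classifications.

Pipeline: weight characters (ML and MP) on the reference tree, bin
every query taxon into each candidate solution, then ask — per
solution and weighting scheme — whether the resulting groups are
morphologically coherent: MRPP on Euclidean and correlation distances,
and per-character Kruskal-Wallis discrimination counts.  Group
membership of query taxa comes from their *binned* assignment (that is
the framework's own pipeline: binning assigns, MRPP evaluates the
assignment); passing ``use_true_groups`` substitutes known groups for
recovery experiments on synthetic data.

The ranked verdict orders solution x scheme combinations by lowest
MRPP p (minimum over the distance metrics), breaking ties by more
significantly discriminating characters and then fewer conflicting
placements.  The verdict is advisory: the full per-stage tables are
always emitted alongside.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from . import __version__
from .binning import OUTSIDE, BinningReport, _stable_hash, bin_all
from .discrimination import discrimination_table
from .formats_io import (
    CladeSolution,
    MorphMatrix,
    read_clade_solution,
    read_morph_matrix,
    read_newick,
    write_tsv,
)
from .mrpp import mrpp_test, pairwise_distances
from .tree import Phylogeny

logger = logging.getLogger("cladebin")


@dataclass
class EvaluationConfig:
    tree: Union[str, Phylogeny]
    matrix: Union[str, MorphMatrix]
    solutions: Sequence[Union[str, CladeSolution]]
    queries: Optional[Sequence[str]] = None  # default: matrix taxa not on tree
    n_random: int = 100
    n_boot: int = 100
    n_perm: int = 999
    seed: int = 0
    metrics: Sequence[str] = ("euclidean", "correlation")
    pool: str = "ref+query"  # taxa entering MRPP/KW: ref, query, or both
    use_true_groups: Optional[Mapping[str, Mapping[str, str]]] = None

    @classmethod
    def from_json(cls, path: str) -> "EvaluationConfig":
        with open(path) as fh:
            raw = json.load(fh)
        base = os.path.dirname(os.path.abspath(path))

        def resolve(p):
            return p if os.path.isabs(p) else os.path.join(base, p)

        raw["tree"] = resolve(raw["tree"])
        raw["matrix"] = resolve(raw["matrix"])
        raw["solutions"] = [resolve(p) for p in raw["solutions"]]
        if isinstance(raw.get("use_true_groups"), str):
            with open(resolve(raw["use_true_groups"])) as fh:
                raw["use_true_groups"] = json.load(fh)
        known = {f.name for f in cls.__dataclass_fields__.values()}  # type: ignore[attr-defined]
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


@dataclass
class EvaluationReport:
    mrpp: pd.DataFrame        # solution x scheme x metric: delta, E[delta], A, p
    kw_counts: pd.DataFrame   # solution x scheme: significant, marginal, total
    kw_pvalues: pd.DataFrame  # character x (solution|scheme)
    binning: BinningReport
    ranking: pd.DataFrame
    verdict: str
    manifest: dict = field(default_factory=dict)

    def write(self, outdir: str) -> None:
        os.makedirs(outdir, exist_ok=True)
        write_tsv(_table2(self.binning.counts), os.path.join(outdir, "binning_counts.tsv"))
        write_tsv(self.binning.assignments, os.path.join(outdir, "placements.tsv"))
        write_tsv(_table3(self.mrpp), os.path.join(outdir, "mrpp_pvalues.tsv"))
        write_tsv(self.mrpp, os.path.join(outdir, "mrpp_full.tsv"))
        write_tsv(self.kw_counts, os.path.join(outdir, "kw_summary.tsv"))
        write_tsv(_table5(self.kw_pvalues), os.path.join(outdir, "kw_pvalues.tsv"))
        write_tsv(self.ranking, os.path.join(outdir, "ranking.tsv"))
        with open(os.path.join(outdir, "manifest.json"), "w") as fh:
            json.dump(self.manifest, fh, indent=2, sort_keys=True)
            fh.write("\n")


def _digest(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        h.update(fh.read())
    return h.hexdigest()


def _load(config: EvaluationConfig):
    manifest: dict = {"version": __version__, "seed": config.seed,
                      "n_random": config.n_random, "n_boot": config.n_boot,
                      "n_perm": config.n_perm, "pool": config.pool,
                      "metrics": list(config.metrics)}
    if isinstance(config.tree, str):
        manifest["tree"] = {"path": config.tree, "sha256": _digest(config.tree)}
        with open(config.tree) as fh:
            tree = read_newick(fh.read())
    else:
        tree = config.tree
    if isinstance(config.matrix, str):
        manifest["matrix"] = {"path": config.matrix, "sha256": _digest(config.matrix)}
        matrix = read_morph_matrix(config.matrix)
    else:
        matrix = config.matrix
    solutions = []
    for sol in config.solutions:
        if isinstance(sol, str):
            name = os.path.splitext(os.path.basename(sol))[0]
            if name.startswith("solution_"):
                name = name[len("solution_"):]
            manifest.setdefault("solutions", []).append(
                {"path": sol, "sha256": _digest(sol)}
            )
            solutions.append(read_clade_solution(sol, name=name, reference=tree))
        else:
            solutions.append(sol)
    if len(solutions) < 2:
        raise ValueError("evaluation needs >= 2 candidate solutions")
    return tree, matrix, solutions, manifest


def evaluate(config: EvaluationConfig) -> EvaluationReport:
    """Run the full decision procedure over all candidate solutions."""
    tree, matrix, solutions, manifest = _load(config)
    leaf_set = set(tree.leaf_labels)
    queries = (
        list(config.queries)
        if config.queries is not None
        else [t for t in matrix.taxa if t not in leaf_set]
    )
    logger.info("evaluating %d solutions, %d queries", len(solutions), len(queries))

    binning = bin_all(
        tree, solutions, matrix, queries,
        n_random=config.n_random, n_boot=config.n_boot, seed=config.seed,
    )

    assigned = {
        (row.solution, row.scheme): {}
        for row in binning.assignments.itertuples()
    }
    for row in binning.assignments.itertuples():
        assigned[(row.solution, row.scheme)][row.query] = row.group

    dist_cache = {m: pairwise_distances(matrix, m) for m in config.metrics}

    mrpp_rows = []
    groupings: dict[str, dict[str, str]] = {}
    for solution in solutions:
        for scheme in ("ML", "MP"):
            grouping: dict[str, str] = {}
            if config.pool in ("ref", "ref+query"):
                grouping.update(solution.assignment)
            if config.pool in ("query", "ref+query"):
                if config.use_true_groups is not None:
                    qmap = config.use_true_groups[solution.name]
                    grouping.update({q: qmap[q] for q in queries})
                else:
                    qmap = assigned[(solution.name, scheme)]
                    for q in queries:
                        if qmap[q] != OUTSIDE:
                            grouping[q] = qmap[q]
            key = f"{scheme}-{solution.name}"
            groupings[key] = grouping
            for metric in config.metrics:
                sub = dist_cache[metric].subset(list(grouping))
                try:
                    res = mrpp_test(
                        sub, grouping, n_perm=config.n_perm,
                        seed=np.random.default_rng(np.random.SeedSequence(
                            [config.seed, _stable_hash(key), _stable_hash(metric)]
                        )),
                    )
                except ValueError as exc:
                    logger.warning("MRPP skipped for %s/%s: %s", key, metric, exc)
                    mrpp_rows.append(
                        {
                            "solution": solution.name,
                            "scheme": scheme,
                            "metric": metric,
                            "delta": float("nan"),
                            "expected_delta": float("nan"),
                            "A": float("nan"),
                            "p": float("nan"),
                            "n_perm": 0,
                        }
                    )
                    continue
                mrpp_rows.append(
                    {
                        "solution": solution.name,
                        "scheme": scheme,
                        "metric": metric,
                        "delta": res.delta_obs,
                        "expected_delta": res.expected_delta,
                        "A": res.A,
                        "p": res.p_value,
                        "p_approx": res.p_approx,
                        "n_perm": res.n_perm,
                    }
                )
    mrpp_df = pd.DataFrame(mrpp_rows)

    kw = discrimination_table(matrix, groupings)
    kw_counts = kw.counts.copy()
    kw_counts[["scheme", "solution"]] = kw_counts["solution"].str.split(
        "-", n=1, expand=True
    )
    kw_counts = kw_counts[["solution", "scheme", "significant", "marginal", "total"]]

    ranking_rows = []
    for solution in solutions:
        for scheme in ("ML", "MP"):
            sel = mrpp_df[
                (mrpp_df.solution == solution.name) & (mrpp_df.scheme == scheme)
            ]
            ksel = kw_counts[
                (kw_counts.solution == solution.name) & (kw_counts.scheme == scheme)
            ]
            ranking_rows.append(
                {
                    "solution": solution.name,
                    "scheme": scheme,
                    "mrpp_min_p": float(sel.p.min()),
                    "kw_significant": int(ksel.significant.iloc[0]),
                    "conflicting": len(binning.conflicting(solution.name)),
                }
            )
    ranking = pd.DataFrame(ranking_rows).sort_values(
        by=["mrpp_min_p", "kw_significant", "conflicting", "solution", "scheme"],
        ascending=[True, False, True, True, True],
        kind="mergesort",
    ).reset_index(drop=True)
    ranking.insert(0, "rank", np.arange(1, len(ranking) + 1))
    best = ranking.iloc[0]
    verdict = f"{best.solution} ({best.scheme} weighting)"
    manifest["verdict"] = verdict
    manifest["queries"] = list(queries)

    return EvaluationReport(
        mrpp=mrpp_df,
        kw_counts=kw_counts,
        kw_pvalues=kw.pvalues.rename_axis("character").reset_index(),
        binning=binning,
        ranking=ranking,
        verdict=verdict,
        manifest=manifest,
    )


# -- report shaping ---------------------------------------------------------


def _table2(counts: pd.DataFrame) -> pd.DataFrame:
    """Placement counts: rows = group/Outside/Conflicting/Total,
    one column per scheme x solution."""
    out = counts.copy()
    out["column"] = out["scheme"] + " " + out["solution"]
    order = [g for g in out["group"].unique()
             if g not in (OUTSIDE, "Conflicting", "Total")]
    order += [OUTSIDE, "Conflicting", "Total"]
    pivot = out.pivot_table(
        index="group", columns="column", values="count", aggfunc="first",
        sort=False,
    ).reindex(order)
    pivot.columns.name = None
    return pivot.reset_index().fillna(0).astype(
        {c: int for c in pivot.columns}
    )


def _table3(mrpp_df: pd.DataFrame) -> pd.DataFrame:
    """MRPP p-value grid: rows scheme x solution, columns metrics."""
    out = mrpp_df.copy()
    out["row"] = out["scheme"] + " " + out["solution"]
    pivot = out.pivot_table(
        index="row", columns="metric", values="p", aggfunc="first", sort=False
    )
    pivot.columns.name = None
    return pivot.reset_index().rename(columns={"row": "classification"})


def _table5(kw_pvalues: pd.DataFrame) -> pd.DataFrame:
    """Per-character grid with p-values shown only when below 0.1."""
    out = kw_pvalues.copy()
    for col in out.columns:
        if col == "character":
            continue
        out[col] = out[col].map(lambda p: f"{p:.4f}" if p < 0.1 else "")
    return out
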