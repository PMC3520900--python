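"""Reading and writing of external artifacts.

Handles four kinds of files:

* Newick trees (parsed with dendropy, converted to the package's own
  :class:`~cladebin.tree.Phylogeny`, with polytomies resolved
  deterministically and missing branch lengths defaulted);
* morphological character matrices (CSV, or the CHARACTERS/MATRIX block
  of a NEXUS file with symbols ``0``-``9`` and ``?``);
* clade-solution files (two-column CSV ``taxon,group``);
* TSV reports (plain UTF-8, one header row).

Characters hold small integer states.  Missing cells are encoded ``?``
or ``NA`` on disk and :data:`MISSING` (-1) in memory.  State codes are
remapped per character to consecutive integers starting at 0; the remap
preserves the numeric order of the original codes, so ordered-character
step costs remain monotone in the original coding.
"""

from __future__ import annotations

import csv
import io
import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np

from .tree import Phylogeny, TreeNode

logger = logging.getLogger("cladebin")

MISSING: int = -1

BINARY = "binary"
ORDERED = "ordered"
UNORDERED = "unordered"
_KINDS = (BINARY, ORDERED, UNORDERED)


class NewickParseError(ValueError):
    """Raised for malformed Newick input."""


class MatrixFormatError(ValueError):
    """Raised for malformed character-matrix input."""


class SolutionFormatError(ValueError):
    """Raised for malformed clade-solution input."""


# ---------------------------------------------------------------------------
# Newick trees
# ---------------------------------------------------------------------------


def read_newick(text: str) -> Phylogeny:
    """Parse a single rooted Newick statement into a :class:`Phylogeny`.

    Polytomies are resolved to binary nodes with zero-length edges,
    deterministically by the smallest descendant leaf label of each
    child (logged).  Edges without a branch length default to 1.0
    (logged).  Unifurcations are suppressed, adding their lengths.
    """
    import dendropy

    text = text.strip()
    if not text:
        raise NewickParseError("empty tree")
    if text.count("(") != text.count(")"):
        raise NewickParseError(
            f"unbalanced parentheses: {text.count('(')} '(' vs {text.count(')')} ')'"
        )
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises many concrete types
        raise NewickParseError(f"Newick parse failed: {exc}") from exc

    def convert(dnode) -> TreeNode:
        label = dnode.taxon.label if dnode.taxon is not None else dnode.label
        node = TreeNode(label=label, length=dnode.edge.length)
        for dchild in dnode.child_nodes():
            node.add_child(convert(dchild))
        return node

    tree = Phylogeny(convert(dtree.seed_node))
    if tree.root.is_leaf and tree.root.label is None:
        raise NewickParseError("empty tree")

    _suppress_unifurcations(tree)
    labels = tree.leaf_labels
    if any(lab is None or lab == "" for lab in labels):
        raise NewickParseError("leaf with empty label")
    dupes = sorted({lab for lab in labels if labels.count(lab) > 1})
    if dupes:
        raise NewickParseError(f"duplicate leaf labels: {dupes}")
    _resolve_polytomies(tree)
    _default_lengths(tree)
    return tree


def _suppress_unifurcations(tree: Phylogeny) -> None:
    changed = True
    while changed:
        changed = False
        for node in list(tree.preorder()):
            if not node.is_leaf and len(node.children) == 1:
                child = node.children[0]
                if node.parent is None:
                    child.parent = None
                    child.length = None
                    tree.root = child
                else:
                    if node.length is not None and child.length is not None:
                        child.length = child.length + node.length
                    elif child.length is None:
                        child.length = node.length
                    idx = node.parent.children.index(node)
                    node.parent.children[idx] = child
                    child.parent = node.parent
                changed = True
                break


def _resolve_polytomies(tree: Phylogeny) -> None:
    sets = tree.leafsets()
    resolved = 0
    for node in list(tree.postorder()):
        while len(node.children) > 2:
            node.children.sort(key=lambda c: min(sets[c]))
            a, b = node.children[0], node.children[1]
            merged = TreeNode(length=0.0)
            merged.add_child(a)
            merged.add_child(b)
            sets[merged] = sets[a] | sets[b]
            node.children = [merged] + node.children[2:]
            merged.parent = node
            resolved += 1
    if resolved:
        logger.warning(
            "resolved %d polytomies to binary nodes with zero-length edges "
            "(deterministic by smallest descendant leaf label)",
            resolved,
        )


def _default_lengths(tree: Phylogeny) -> None:
    missing = 0
    for node in tree.preorder():
        if node.parent is not None:
            if node.length is None:
                node.length = 1.0
                missing += 1
            elif node.length < 0:
                raise NewickParseError(f"negative branch length {node.length}")
    if missing:
        logger.warning("defaulted %d missing branch lengths to 1.0", missing)


def write_newick(tree: Phylogeny) -> str:
    """Serialise a tree; branch lengths rendered to 10 significant digits."""
    return tree.to_newick(lengths=True)


# ---------------------------------------------------------------------------
# Morphological matrices
# ---------------------------------------------------------------------------


@dataclass
class MorphMatrix:
    """Taxa x characters matrix of small-integer states.

    ``states[i, c]`` is the consecutive re-coded state of taxon ``i``
    for character ``c``, or :data:`MISSING`.  ``state_maps[c]`` maps the
    original integer code to the consecutive code.  ``ks[c]`` is the
    state-space size used by scoring (2 for binary, otherwise the
    number of observed states, floored at 2).
    """

    taxa: list[str]
    characters: list[str]
    states: np.ndarray
    kinds: list[str]
    state_maps: list[dict[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=np.int16)
        if self.states.shape != (len(self.taxa), len(self.characters)):
            raise MatrixFormatError(
                f"state array shape {self.states.shape} does not match "
                f"{len(self.taxa)} taxa x {len(self.characters)} characters"
            )
        if not self.state_maps:
            self.state_maps = [
                {s: s for s in self._observed(c)} for c in range(self.n_chars)
            ]
        for c, kind in enumerate(self.kinds):
            if kind not in _KINDS:
                raise MatrixFormatError(f"unknown character kind {kind!r}")
            obs = self._observed(c)
            if len(obs) == 0:
                raise MatrixFormatError(
                    f"character {self.characters[c]!r} has no non-missing state"
                )
            if kind == BINARY and not obs.issubset({0, 1}):
                raise MatrixFormatError(
                    f"binary character {self.characters[c]!r} has states {sorted(obs)}"
                )

    def _observed(self, c: int) -> set[int]:
        col = self.states[:, c]
        return set(int(s) for s in col[col != MISSING])

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_chars(self) -> int:
        return len(self.characters)

    @property
    def ks(self) -> list[int]:
        out = []
        for c, kind in enumerate(self.kinds):
            if kind == BINARY:
                out.append(2)
            else:
                col = self.states[:, c]
                obs = col[col != MISSING]
                out.append(max(2, int(obs.max()) + 1 if obs.size else 2))
        return out

    def column(self, c: int) -> dict[str, int]:
        """Taxon -> state mapping for character ``c`` (missing omitted)."""
        col = self.states[:, c]
        return {
            t: int(s) for t, s in zip(self.taxa, col) if s != MISSING
        }

    def row(self, taxon: str) -> np.ndarray:
        return self.states[self.taxa.index(taxon)]

    def subset(self, taxa: Sequence[str]) -> "MorphMatrix":
        """Row subset preserving character coding and order."""
        index = {t: i for i, t in enumerate(self.taxa)}
        missing = [t for t in taxa if t not in index]
        if missing:
            raise MatrixFormatError(f"taxa not in matrix: {missing}")
        rows = [index[t] for t in taxa]
        return MorphMatrix(
            taxa=list(taxa),
            characters=list(self.characters),
            states=self.states[rows].copy(),
            kinds=list(self.kinds),
            state_maps=[dict(m) for m in self.state_maps],
        )

    def to_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["taxon"] + self.characters)
            w.writerow(["#kind"] + self.kinds)
            inv = [
                {code: orig for orig, code in m.items()} for m in self.state_maps
            ]
            for i, taxon in enumerate(self.taxa):
                row = [taxon]
                for c in range(self.n_chars):
                    s = int(self.states[i, c])
                    row.append("?" if s == MISSING else str(inv[c].get(s, s)))
                w.writerow(row)


def concat_matrices(a: MorphMatrix, b: MorphMatrix) -> MorphMatrix:
    """Stack two matrices row-wise; characters and coding must agree."""
    if a.characters != b.characters or a.kinds != b.kinds:
        raise MatrixFormatError("matrices have different characters or kinds")
    if a.state_maps != b.state_maps:
        raise MatrixFormatError("matrices use different state codings")
    overlap = set(a.taxa) & set(b.taxa)
    if overlap:
        raise MatrixFormatError(f"taxa present in both matrices: {sorted(overlap)}")
    return MorphMatrix(
        taxa=a.taxa + b.taxa,
        characters=list(a.characters),
        states=np.vstack([a.states, b.states]),
        kinds=list(a.kinds),
        state_maps=[dict(m) for m in a.state_maps],
    )


_MISSING_TOKENS = {"?", "NA", "na", "-", ""}


def read_morph_matrix(path, dialect: str = "csv") -> MorphMatrix:
    """Read a taxa x characters matrix.

    CSV dialect: first column taxon label, remaining columns characters,
    header row with character labels.  An optional row whose first cell
    is ``#kind`` declares ``binary``/``ordered``/``unordered`` per
    character; absent a declaration, a character is binary when exactly
    two states {0,1} are observed after remapping, else ordered.

    NEXUS dialect: only the CHARACTERS (or DATA) block with symbols
    ``0``-``9`` and ``?`` is supported.
    """
    if dialect == "csv":
        return _read_matrix_csv(path)
    if dialect == "nexus":
        return _read_matrix_nexus(path)
    raise MatrixFormatError(f"unknown dialect {dialect!r}")


def _open_text(path) -> io.TextIOBase:
    if hasattr(path, "read"):
        return path
    return open(path, "r", newline="")


def _read_matrix_csv(path) -> MorphMatrix:
    fh = _open_text(path)
    rows = list(csv.reader(fh))
    if hasattr(path, "read") is False:
        fh.close()
    rows = [r for r in rows if r and any(cell.strip() for cell in r)]
    if len(rows) < 2:
        raise MatrixFormatError("matrix needs a header row and at least one taxon")
    header = [c.strip() for c in rows[0]]
    characters = header[1:]
    if not characters:
        raise MatrixFormatError("no character columns")
    width = len(header)

    kinds_declared: Optional[list[str]] = None
    taxa: list[str] = []
    raw: list[list[Optional[int]]] = []
    for ridx, row in enumerate(rows[1:], start=2):
        if len(row) != width:
            raise MatrixFormatError(
                f"row {ridx}: expected {width} columns, found {len(row)}"
            )
        first = row[0].strip()
        if first.lower() in ("#kind", "#type"):
            kinds_declared = [k.strip().lower() for k in row[1:]]
            bad = [k for k in kinds_declared if k not in _KINDS]
            if bad:
                raise MatrixFormatError(f"row {ridx}: unknown kinds {bad}")
            continue
        if first in taxa:
            raise MatrixFormatError(f"row {ridx}: taxon {first!r} repeated")
        if not first:
            raise MatrixFormatError(f"row {ridx}: empty taxon label")
        taxa.append(first)
        states_row: list[Optional[int]] = []
        for cidx, cell in enumerate(row[1:], start=2):
            tok = cell.strip()
            if tok in _MISSING_TOKENS:
                states_row.append(None)
                continue
            try:
                states_row.append(int(tok))
            except ValueError:
                raise MatrixFormatError(
                    f"row {ridx}, column {cidx}: non-integer state {tok!r}"
                ) from None
        raw.append(states_row)
    if not taxa:
        raise MatrixFormatError("no taxon rows")
    return _assemble_matrix(taxa, characters, raw, kinds_declared)


def _assemble_matrix(
    taxa: list[str],
    characters: list[str],
    raw: list[list[Optional[int]]],
    kinds_declared: Optional[list[str]],
) -> MorphMatrix:
    n, C = len(taxa), len(characters)
    states = np.full((n, C), MISSING, dtype=np.int16)
    state_maps: list[dict[int, int]] = []
    kinds: list[str] = []
    for c in range(C):
        col = [raw[i][c] for i in range(n)]
        observed = sorted({v for v in col if v is not None})
        if not observed:
            raise MatrixFormatError(
                f"character {characters[c]!r} has no non-missing observation"
            )
        remap = {orig: code for code, orig in enumerate(observed)}
        if remap != {v: v for v in observed}:
            logger.info(
                "character %r: remapped states %s -> %s",
                characters[c],
                observed,
                list(remap.values()),
            )
        state_maps.append(remap)
        for i in range(n):
            if col[i] is not None:
                states[i, c] = remap[col[i]]
        if kinds_declared is not None:
            kinds.append(kinds_declared[c])
        else:
            kinds.append(BINARY if set(remap.values()) <= {0, 1} else ORDERED)
    return MorphMatrix(
        taxa=taxa, characters=characters, states=states,
        kinds=kinds, state_maps=state_maps,
    )


def _read_matrix_nexus(path) -> MorphMatrix:
    """Minimal NEXUS reader: the CHARACTERS/DATA MATRIX block only."""
    fh = _open_text(path)
    text = fh.read()
    if not hasattr(path, "read"):
        fh.close()
    low = text.lower()
    start = low.find("matrix")
    if start < 0:
        raise MatrixFormatError("no MATRIX block found")
    end = low.find(";", start)
    if end < 0:
        raise MatrixFormatError("MATRIX block not terminated by ';'")
    body = text[start + len("matrix"):end]
    taxa: list[str] = []
    raw: list[list[Optional[int]]] = []
    for line in body.splitlines():
        line = line.strip()
        if not line or line.startswith("["):
            continue
        parts = line.split(None, 1)
        if len(parts) != 2:
            raise MatrixFormatError(f"malformed MATRIX line: {line!r}")
        taxon, seq = parts[0].strip("'\""), parts[1].replace(" ", "")
        if taxon in taxa:
            raise MatrixFormatError(f"taxon {taxon!r} repeated")
        row: list[Optional[int]] = []
        for ch in seq:
            if ch == "?":
                row.append(None)
            elif ch.isdigit():
                row.append(int(ch))
            else:
                raise MatrixFormatError(
                    f"taxon {taxon!r}: unsupported symbol {ch!r}"
                )
        taxa.append(taxon)
        raw.append(row)
    if not taxa:
        raise MatrixFormatError("empty MATRIX block")
    widths = {len(r) for r in raw}
    if len(widths) != 1:
        raise MatrixFormatError(f"ragged MATRIX rows, widths {sorted(widths)}")
    C = widths.pop()
    characters = [f"char_{c + 1}" for c in range(C)]
    return _assemble_matrix(taxa, characters, raw, None)


# ---------------------------------------------------------------------------
# Clade solutions
# ---------------------------------------------------------------------------


@dataclass
class CladeSolution:
    """A named partition of reference taxa into >=2 non-empty groups."""

    name: str
    assignment: dict[str, str]
    groups: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.groups:
            seen: list[str] = []
            for g in self.assignment.values():
                if g not in seen:
                    seen.append(g)
            self.groups = seen
        if len(self.groups) < 2:
            raise SolutionFormatError(
                f"solution {self.name!r} needs >=2 groups, found {self.groups}"
            )
        for g in self.groups:
            if not any(v == g for v in self.assignment.values()):
                raise SolutionFormatError(f"group {g!r} has no members")

    def members(self, group: str) -> list[str]:
        return [t for t, g in self.assignment.items() if g == group]

    @property
    def taxa(self) -> list[str]:
        return list(self.assignment)

    def to_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["taxon", "group"])
            for taxon, group in self.assignment.items():
                w.writerow([taxon, group])


def read_clade_solution(
    path,
    name: Optional[str] = None,
    reference: Optional[Union[Phylogeny, Sequence[str]]] = None,
) -> CladeSolution:
    """Read a two-column ``taxon,group`` CSV.

    Groups are ordered by first appearance.  When ``reference`` (a tree
    or a label collection) is given, taxa outside it raise an error.
    """
    fh = _open_text(path)
    rows = list(csv.reader(fh))
    if not hasattr(path, "read"):
        fh.close()
    rows = [r for r in rows if r and any(cell.strip() for cell in r)]
    assignment: dict[str, str] = {}
    for ridx, row in enumerate(rows, start=1):
        if len(row) != 2:
            raise SolutionFormatError(f"row {ridx}: expected 2 columns")
        taxon, group = row[0].strip(), row[1].strip()
        if ridx == 1 and taxon.lower() == "taxon" and group.lower() == "group":
            continue
        if not taxon or not group:
            raise SolutionFormatError(f"row {ridx}: empty taxon or group")
        if taxon in assignment:
            raise SolutionFormatError(f"row {ridx}: taxon {taxon!r} assigned twice")
        assignment[taxon] = group
    if not assignment:
        raise SolutionFormatError("empty solution file")
    if reference is not None:
        ref_labels = (
            set(reference.leaf_labels)
            if isinstance(reference, Phylogeny)
            else set(reference)
        )
        unknown = sorted(set(assignment) - ref_labels)
        if unknown:
            raise SolutionFormatError(f"unknown taxa: {unknown}")
    if name is None:
        name = getattr(path, "name", None) or "solution"
    return CladeSolution(name=str(name), assignment=assignment)


# ---------------------------------------------------------------------------
# TSV reports
# ---------------------------------------------------------------------------


def write_tsv(df, path, float_format: str = "%.6g") -> None:
    """Write a DataFrame as a UTF-8 TSV with one header row."""
    df.to_csv(path, sep="\t", index=False, float_format=float_format,
              lineterminator="\n")
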