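"""Reading and writing character matrices and trees.

Supported formats:

* relaxed sequential PHYLIP (whitespace-delimited names of any length);
* a NEXUS subset: a DATA or CHARACTERS block with ``FORMAT SYMBOLS="01"
  MISSING=?`` -- enough for PAUP*-style binary matrices.  Anything beyond
  that subset raises :class:`UnsupportedFormatError`;
* newick, one tree per statement (parsed with dendropy; branch lengths are
  retained on the nodes but ignored by the parsimony code).

``-`` is accepted as a synonym for ``?`` and normalized silently (a count
is logged at DEBUG level).
"""

from __future__ import annotations

import logging
import re
from pathlib import Path
from typing import List, Optional, Tuple, Union

import dendropy
import numpy as np

from .characters import CharacterMatrix
from .taxa import TaxonSet
from .trees import Node, RootedTree

__all__ = [
    "FormatError",
    "UnsupportedFormatError",
    "read_character_matrix",
    "write_character_matrix",
    "read_newick_trees",
    "write_newick",
    "write_newick_trees",
]

log = logging.getLogger(__name__)

PathLike = Union[str, Path]


class FormatError(ValueError):
    """Malformed input file."""


class UnsupportedFormatError(FormatError):
    """Input uses a feature outside the supported dialect."""


# ---------------------------------------------------------------------- #
# character matrices


def _rows_to_matrix(
    names: List[str], rows: List[str], k: int, where: str
) -> CharacterMatrix:
    if len(set(names)) != len(names):
        dupes = sorted({x for x in names if names.count(x) > 1})
        raise FormatError(f"{where}: duplicate taxon name(s) {dupes}")
    taxa = TaxonSet(names)
    n_dash = sum(row.count("-") for row in rows)
    if n_dash:
        log.debug("%s: normalized %d '-' symbols to '?'", where, n_dash)
    ones = np.zeros((k, taxa.n), dtype=bool)
    missing = np.zeros((k, taxa.n), dtype=bool)
    for j, row in enumerate(rows):
        if len(row) != k:
            raise FormatError(
                f"{where}: row for {names[j]!r} has {len(row)} states, expected {k}"
            )
        for i, ch in enumerate(row):
            if ch == "1":
                ones[i, j] = True
            elif ch in "?-":
                missing[i, j] = True
            elif ch != "0":
                raise FormatError(
                    f"{where}: illegal symbol {ch!r} for taxon {names[j]!r}, column {i + 1}"
                )
    return CharacterMatrix(taxa, ones, missing)


def _read_phylip(text: str, where: str) -> CharacterMatrix:
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise FormatError(f"{where}: empty file")
    header = lines[0].split()
    if len(header) != 2:
        raise FormatError(f"{where}: header must be '<ntaxa> <nchar>'")
    try:
        n, k = int(header[0]), int(header[1])
    except ValueError:
        raise FormatError(f"{where}: non-integer header {lines[0]!r}") from None
    body = lines[1:]
    if len(body) != n:
        raise FormatError(f"{where}: expected {n} taxon rows, found {len(body)}")
    names, rows = [], []
    for ln in body:
        parts = ln.split()
        if len(parts) < 1 or (k > 0 and len(parts) < 2):
            raise FormatError(f"{where}: malformed row {ln!r}")
        names.append(parts[0])
        rows.append("".join(parts[1:]))
    return _rows_to_matrix(names, rows, k, where)


_NEXUS_BLOCK = re.compile(
    r"begin\s+(data|characters)\s*;(.*?)end\s*;", re.IGNORECASE | re.DOTALL
)


def _read_nexus(text: str, where: str) -> CharacterMatrix:
    if not text.lstrip().lower().startswith("#nexus"):
        raise FormatError(f"{where}: missing #NEXUS header")
    m = _NEXUS_BLOCK.search(text)
    if not m:
        raise FormatError(f"{where}: no DATA or CHARACTERS block found")
    block = m.group(2)

    dim = re.search(r"dimensions\s+([^;]*);", block, re.IGNORECASE)
    if not dim:
        raise FormatError(f"{where}: missing DIMENSIONS statement")
    fields = dict(
        (kv.split("=")[0].strip().lower(), kv.split("=")[1].strip())
        for kv in dim.group(1).split()
        if "=" in kv
    )
    try:
        n = int(fields["ntax"])
        k = int(fields["nchar"])
    except (KeyError, ValueError):
        raise FormatError(f"{where}: DIMENSIONS must give NTAX and NCHAR") from None

    fmt = re.search(r"format\s+([^;]*);", block, re.IGNORECASE)
    if fmt:
        spec = fmt.group(1)
        for kv in re.findall(r"(\w+)\s*=\s*(\"[^\"]*\"|\S+)", spec):
            key, val = kv[0].lower(), kv[1].strip('"')
            if key == "missing" and val not in ("?", "-"):
                raise UnsupportedFormatError(f"{where}: MISSING={val!r} unsupported")
            if key == "symbols" and set(val) - set("01 "):
                raise UnsupportedFormatError(f"{where}: SYMBOLS={val!r} unsupported")
            if key == "datatype" and val.lower() != "standard":
                raise UnsupportedFormatError(f"{where}: DATATYPE={val} unsupported")
            if key == "interleave" and val.lower() not in ("no", "false"):
                raise UnsupportedFormatError(f"{where}: interleaved NEXUS unsupported")

    mat = re.search(r"matrix(.*?);", block, re.IGNORECASE | re.DOTALL)
    if not mat:
        raise FormatError(f"{where}: missing MATRIX statement")
    names, rows = [], []
    for ln in mat.group(1).splitlines():
        ln = ln.strip()
        if not ln:
            continue
        parts = ln.split()
        if len(parts) < 1 or (k > 0 and len(parts) < 2):
            raise FormatError(f"{where}: malformed matrix row {ln!r}")
        names.append(parts[0].strip("'\""))
        rows.append("".join(parts[1:]))
    if len(names) != n:
        raise FormatError(f"{where}: NTAX={n} but matrix has {len(names)} rows")
    return _rows_to_matrix(names, rows, k, where)


def read_character_matrix(
    path: PathLike, format: Optional[str] = None
) -> CharacterMatrix:
    """Read a 0/1/? character matrix.

    ``format`` is ``"phylip"``, ``"nexus"`` or ``None`` (auto-detect from
    the ``#NEXUS`` header).
    """
    path = Path(path)
    text = path.read_text()
    where = path.name
    if format is None:
        format = "nexus" if text.lstrip().lower().startswith("#nexus") else "phylip"
    if format == "phylip":
        return _read_phylip(text, where)
    if format == "nexus":
        return _read_nexus(text, where)
    raise ValueError(f"unknown matrix format {format!r}")


def write_character_matrix(
    matrix: CharacterMatrix, path: PathLike, format: str = "phylip"
) -> None:
    """Write a matrix so that re-reading reproduces it exactly."""
    path = Path(path)
    name_w = max((len(x) for x in matrix.taxa.labels), default=1)
    lines: List[str] = []
    if format == "phylip":
        lines.append(f"{matrix.n} {matrix.k}")
        for j, name in enumerate(matrix.taxa.labels):
            lines.append(f"{name:<{name_w}} {matrix.row_string(j)}")
    elif format == "nexus":
        lines.append("#NEXUS")
        lines.append("BEGIN DATA;")
        lines.append(f"  DIMENSIONS NTAX={matrix.n} NCHAR={matrix.k};")
        lines.append('  FORMAT DATATYPE=STANDARD SYMBOLS="01" MISSING=?;')
        lines.append("  MATRIX")
        for j, name in enumerate(matrix.taxa.labels):
            lines.append(f"    {name:<{name_w}} {matrix.row_string(j)}")
        lines.append("  ;")
        lines.append("END;")
    else:
        raise ValueError(f"unknown matrix format {format!r}")
    path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------- #
# trees


def _from_dendropy(dtree: "dendropy.Tree", taxa: TaxonSet, where: str) -> RootedTree:
    def rec(dnode) -> Node:
        if dnode.is_leaf():
            label = dnode.taxon.label if dnode.taxon is not None else None
            if label is None:
                raise FormatError(f"{where}: unlabeled leaf")
            if label not in taxa:
                raise FormatError(f"{where}: leaf label {label!r} not in taxon set")
            return Node(taxon=taxa.index[label], length=dnode.edge.length)
        return Node(
            children=[rec(ch) for ch in dnode.child_nodes()],
            length=dnode.edge.length,
        )

    node = dtree.seed_node
    # dendropy reads unrooted newick with a trifurcating seed node; keep as-is
    # (rooting is the caller's concern, via treeops.root_at_outgroup).
    return RootedTree(rec(node), taxa)


def read_newick_trees(
    path: PathLike, taxa: Optional[TaxonSet] = None
) -> Tuple[List[RootedTree], TaxonSet]:
    """Read newick trees (one per statement) as provisionally-rooted trees.

    Multifurcations are permitted here; callers that require binary trees
    reject them downstream.  If ``taxa`` is None, a TaxonSet is built from
    the sorted union of leaf labels across all trees.

    Returns ``(trees, taxa)``.
    """
    path = Path(path)
    try:
        tlist = dendropy.TreeList.get(
            path=str(path),
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises various parse errors
        raise FormatError(f"{path.name}: newick parse failure: {exc}") from None
    if taxa is None:
        labels = sorted({t.label for t in tlist.taxon_namespace})
        taxa = TaxonSet(labels)
    trees = [_from_dendropy(t, taxa, path.name) for t in tlist]
    return trees, taxa


def write_newick(tree: RootedTree, lengths: bool = False) -> str:
    """Newick text for one rooted tree (canonical child order)."""
    return tree.copy().canonicalize().newick(lengths=lengths)


def write_newick_trees(trees: List[RootedTree], path: PathLike, lengths: bool = False) -> None:
    Path(path).write_text("".join(write_newick(t, lengths=lengths) + "\n" for t in trees))
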