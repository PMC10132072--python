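"""Alignment and tree post-processing for KS/CLF phylogenies.

Three operations mirror the usual pre-publication cleanup of a large
maximum-likelihood tree:

* gap-column trimming — alignment sites with more than 5 % gaps across all
  sequences are removed so indel-rich columns do not distort the tree;
* support collapse — internal nodes with less than 70 % support are
  contracted into polytomies, leaving only well-supported structure;
* outgroup rooting — the tree is rerooted on the edge subtending a named
  outgroup leaf (e.g. an E. coli FabF sequence), split at its midpoint.

Trees are dendropy objects; supports are read from internal node labels
(the FastTree dialect) with bracket-comment supports tolerated on input.
Support values may be fractions (0–1) or percentages (0–100); ``auto``
detects the scale from the data.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence, TextIO

import dendropy
from Bio import SeqIO

logger = logging.getLogger("ksclf")


class NewickParseError(ValueError):
    """Malformed Newick input (carries the offending position when known)."""


@dataclass(frozen=True)
class PhyloConfig:
    """Trimming and collapse parameters.

    ``max_gap_fraction`` — keep columns with gap fraction <= this ("more than
    5 % removed" is an exclusive boundary: exactly 5 % is kept).
    ``min_support`` — collapse internal edges with support < this (strict);
    expressed on the unit scale regardless of the tree's dialect.
    ``missing_support`` — policy for internal nodes without a support value:
    keep (default, warned), zero (collapse), or error.
    """

    max_gap_fraction: float = 0.05
    min_support: float = 0.70
    support_scale: str = "auto"      # unit | percent | auto
    missing_support: str = "keep"    # keep | zero | error

    def __post_init__(self) -> None:
        if not (0 <= self.max_gap_fraction < 1):
            raise ValueError("max_gap_fraction must be in [0, 1)")
        if self.support_scale not in ("unit", "percent", "auto"):
            raise ValueError(f"unknown support_scale {self.support_scale!r}")
        if self.missing_support not in ("keep", "zero", "error"):
            raise ValueError(f"unknown missing_support {self.missing_support!r}")


# ---------------------------------------------------------------------------
# alignments
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Alignment:
    """A gapped protein alignment ('-' gaps), rows in input order."""

    ids: tuple[str, ...]
    rows: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows must have equal length")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("alignment ids must be unique")
        if self.rows and any(len(r) != len(self.rows[0]) for r in self.rows):
            raise ValueError("alignment rows must have equal length")

    @property
    def width(self) -> int:
        return len(self.rows[0]) if self.rows else 0


def read_alignment(path: str | Path | TextIO) -> Alignment:
    ids, rows = [], []
    for rec in SeqIO.parse(path, "fasta"):
        ids.append(rec.id)
        rows.append(str(rec.seq).upper())
    return Alignment(ids=tuple(ids), rows=tuple(rows))


def write_alignment(aln: Alignment, path: str | Path | TextIO) -> None:
    own = hasattr(path, "write")
    fh = path if own else open(path, "w")
    try:
        for i, r in zip(aln.ids, aln.rows):
            fh.write(f">{i}\n{r}\n")
    finally:
        if not own:
            fh.close()


def trim_gap_columns(
    aln: Alignment, config: PhyloConfig | None = None
) -> tuple[Alignment, list[int]]:
    """Drop columns whose gap fraction exceeds ``max_gap_fraction``.

    Returns the trimmed alignment plus the kept original column indices for
    traceability.  Gap fractions count every row, including fully gapped
    ones.  A result of width zero is returned (with a warning), not raised.
    """
    config = config or PhyloConfig()
    n = len(aln.rows)
    if n == 0:
        return aln, []
    kept = [
        c
        for c in range(aln.width)
        if sum(r[c] == "-" for r in aln.rows) / n <= config.max_gap_fraction
    ]
    if not kept:
        logger.warning("all %d columns exceeded the gap threshold", aln.width)
    rows = tuple("".join(r[c] for c in kept) for r in aln.rows)
    return Alignment(ids=aln.ids, rows=rows), kept


# ---------------------------------------------------------------------------
# trees
# ---------------------------------------------------------------------------

#: branch-comment support, e.g. "):0.5[0.95]" or ")[&support=0.95]:0.5"
_BRACKET_SUPPORT = re.compile(
    r"\)(?P<label>[^:,()\[\]]*)(?P<len>:[0-9.eE+\-]+)?"
    r"\[&?(?:support=)?(?P<sup>[0-9.]+)\]"
)


def _check_balanced(text: str) -> None:
    depth = 0
    for pos, ch in enumerate(text):
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
            if depth < 0:
                raise NewickParseError(
                    f"unbalanced ')' at position {pos}")
    if depth != 0:
        raise NewickParseError(
            f"{depth} unclosed '(' at end of input")


def read_newick(source: str | Path) -> dendropy.Tree:
    """Parse Newick text (or a path to it) into a dendropy tree.

    Internal node labels are kept as labels (FastTree support dialect);
    bracket-comment supports are rewritten into labels on read.
    """
    def _looks_like_path(s: str) -> bool:
        if "(" in s or ";" in s or "\n" in s or len(s) > 4096:
            return False
        try:
            return Path(s).is_file()
        except OSError:
            return False

    if isinstance(source, Path) or (isinstance(source, str) and _looks_like_path(source)):
        text = Path(source).read_text()
    else:
        text = str(source)
    _check_balanced(text)
    text = _BRACKET_SUPPORT.sub(
        lambda m: ")" + (m.group("label") or m.group("sup")) + (m.group("len") or ""),
        text,
    )
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise NewickParseError(str(exc)) from exc
    labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
    if len(set(labels)) != len(labels):
        raise NewickParseError("duplicate leaf labels")
    return tree


def write_newick(tree: dendropy.Tree) -> str:
    """Serialize with internal labels as supports (FastTree dialect)."""
    return tree.as_string(
        schema="newick", suppress_rooting=True, unquoted_underscores=True
    ).strip()


def node_support(node: dendropy.Node) -> float | None:
    """Support value of an internal node, from its label, if parseable."""
    if node.label is None:
        return None
    try:
        return float(node.label)
    except ValueError:
        return None


def _unit_supports(tree: dendropy.Tree, scale: str) -> dict[int, float | None]:
    """Map node id -> support on the unit (0–1) scale."""
    raw: dict[int, float | None] = {}
    for nd in tree.preorder_node_iter():
        if nd.is_leaf() or nd.parent_node is None:
            continue
        raw[id(nd)] = node_support(nd)
    values = [v for v in raw.values() if v is not None]
    if scale == "auto":
        scale = "percent" if any(v > 1 for v in values) else "unit"
    if scale == "percent":
        raw = {k: (v / 100.0 if v is not None else None) for k, v in raw.items()}
    return raw


def collapse_low_support(
    tree: dendropy.Tree, config: PhyloConfig | None = None
) -> dendropy.Tree:
    """Contract internal edges whose child node's support is below threshold.

    The low-support node's children reattach to its parent, each branch
    length incremented by the contracted edge's length, so every
    root-to-leaf path length is preserved.  The leaf set never changes and
    the operation is idempotent.  Operates in place and returns the tree.
    """
    config = config or PhyloConfig()
    supports = _unit_supports(tree, config.support_scale)
    doomed: list[dendropy.Node] = []
    for nd in tree.preorder_node_iter():
        if nd.is_leaf() or nd.parent_node is None:
            continue
        s = supports.get(id(nd))
        if s is None:
            if config.missing_support == "error":
                raise ValueError("internal node without support value")
            if config.missing_support == "keep":
                logger.warning("keeping internal node with no support value")
                continue
            s = 0.0
        if s < config.min_support:
            doomed.append(nd)
    for nd in doomed:
        parent = nd.parent_node
        elen = nd.edge.length or 0.0
        for child in list(nd.child_nodes()):
            nd.remove_child(child)
            if child.edge.length is not None or elen:
                child.edge.length = (child.edge.length or 0.0) + elen
            parent.add_child(child)
        parent.remove_child(nd)
    return tree


def root_with_outgroup(tree: dendropy.Tree, leaf_label: str) -> dendropy.Tree:
    """Reroot on the edge subtending the named leaf, split at its midpoint.

    If the tree is already rooted with the outgroup as one of two root
    children the tree is returned unchanged (so the operation is
    idempotent).  Operates in place and returns the tree.
    """
    leaf = None
    for lf in tree.leaf_node_iter():
        if lf.taxon is not None and lf.taxon.label == leaf_label:
            leaf = lf
            break
    if leaf is None:
        raise KeyError(f"outgroup leaf {leaf_label!r} not found")
    root = tree.seed_node
    if leaf.parent_node is root and len(root.child_nodes()) == 2:
        return tree
    elen = leaf.edge.length
    half = None if elen is None else elen / 2.0
    tree.reroot_at_edge(leaf.edge, length1=half, length2=half,
                        update_bipartitions=False)
    tree.is_rooted = True
    return tree


def total_branch_length(tree: dendropy.Tree) -> float:
    return sum(e.length or 0.0 for e in tree.edges())


def leaf_depths(tree: dendropy.Tree) -> dict[str, float]:
    """Root-to-leaf path lengths keyed by leaf label."""
    out: dict[str, float] = {}
    for lf in tree.leaf_node_iter():
        d, nd = 0.0, lf
        while nd.parent_node is not None:
            d += nd.edge.length or 0.0
            nd = nd.parent_node
        out[lf.taxon.label] = d
    return out
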