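"""Rooted phylogenies and binary trait matrices.

This module is the substrate shared by the likelihood, mapping and matrix
stages: a light rooted-tree container with validated invariants (one root,
unique non-empty tip labels, finite non-negative branch lengths), Newick
read/write, taxon pruning, MRCA lookup, and a TSV trait-matrix reader.

Newick dialect
--------------
Internal node labels that parse as numbers are stored as *support values*
(the common phylogenomics convention for bootstrap / posterior annotations);
non-numeric internal labels are kept as clade names.  Trees are treated as
rooted exactly as written; no implicit re-rooting ever happens.  Branch
lengths absent from the input default to 0 and are counted on the returned
tree (``defaulted_lengths``).  The writer emits branch lengths with
``repr(float)`` (shortest exact decimal), so parse -> write -> parse is an
exact round trip.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import dendropy
import pandas as pd

logger = logging.getLogger(__name__)

MISSING = None  # trait state for '?'

_NEWICK_UNSAFE = set("(),:;'[]\t\n ")


class NewickParseError(ValueError):
    """Malformed Newick input (unbalanced parentheses, duplicate or empty
    tip labels, negative branch lengths)."""


class TreeError(ValueError):
    """Invalid operation on a Phylogeny (unknown taxa, too few tips left)."""


class Node:
    """One node of a rooted tree.

    ``length`` is the length of the branch subtending the node (None for a
    root without an explicit length); ``support`` is an optional numeric
    support value for internal nodes; ``label`` carries tip names and
    non-numeric internal (clade) names.
    """

    __slots__ = ("children", "parent", "length", "label", "support")

    def __init__(self, label=None, length=None, support=None):
        self.children: list[Node] = []
        self.parent: Node | None = None
        self.length = length
        self.label = label
        self.support = support

    def add_child(self, node: "Node") -> None:
        node.parent = self
        self.children.append(node)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def clade_tips(self) -> list["Node"]:
        """Tips of the clade induced by this node (stable child order)."""
        out, stack = [], [self]
        while stack:
            n = stack.pop()
            if n.is_leaf:
                out.append(n)
            else:
                stack.extend(reversed(n.children))
        return out


class Phylogeny:
    """A rooted tree with branch lengths, treated as immutable once built.

    Invariants enforced at construction: exactly one root (by construction),
    unique non-empty tip labels, every non-root branch length finite and
    >= 0.  Zero-length branches are legal.
    """

    def __init__(self, root: Node, defaulted_lengths: int = 0):
        self.root = root
        #: number of branches whose length was absent in the source and
        #: defaulted to 0 (a warning flag, not an error)
        self.defaulted_lengths = defaulted_lengths
        self._postorder: list[Node] | None = None
        self._validate()

    # -- traversal -------------------------------------------------------

    def postorder(self) -> list[Node]:
        """Nodes in postorder (children before parents, root last); cached."""
        if self._postorder is None:
            out: list[Node] = []
            stack: list[tuple[Node, bool]] = [(self.root, False)]
            while stack:
                node, expanded = stack.pop()
                if expanded or node.is_leaf:
                    out.append(node)
                else:
                    stack.append((node, True))
                    for c in reversed(node.children):
                        stack.append((c, False))
            self._postorder = out
        return self._postorder

    def preorder(self) -> list[Node]:
        return list(reversed(self.postorder()))

    def tips(self) -> list[Node]:
        return [n for n in self.postorder() if n.is_leaf]

    @property
    def tip_labels(self) -> list[str]:
        return [n.label for n in self.tips()]

    @property
    def n_tips(self) -> int:
        return len(self.tips())

    def tip(self, label: str) -> Node:
        for n in self.tips():
            if n.label == label:
                return n
        raise TreeError(f"unknown tip label: {label!r}")

    # -- maintenance -----------------------------------------------------

    def _validate(self) -> None:
        seen: set[str] = set()
        for n in self.postorder():
            if n.is_leaf:
                if not n.label:
                    raise NewickParseError("empty tip label")
                if n.label in seen:
                    raise NewickParseError(f"duplicate tip label: {n.label!r}")
                seen.add(n.label)
            if n is not self.root or n.length is not None:
                ln = n.length
                if ln is None:
                    raise TreeError("non-root node without a branch length")
                if not math.isfinite(ln):
                    raise NewickParseError(f"non-finite branch length on {n.label!r}")
                if ln < 0:
                    raise NewickParseError(
                        f"negative branch length {ln} on node {n.label!r}"
                    )
        if not seen:
            raise TreeError("tree has no tips")

    def copy(self) -> "Phylogeny":
        mapping: dict[int, Node] = {}
        for n in self.postorder():
            m = Node(n.label, n.length, n.support)
            mapping[id(n)] = m
            for c in n.children:
                m.add_child(mapping[id(c)])
        return Phylogeny(mapping[id(self.root)], self.defaulted_lengths)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"<Phylogeny with {self.n_tips} tips>"


# ---------------------------------------------------------------------------
# Newick I/O
# ---------------------------------------------------------------------------


def parse_newick(text: str) -> Phylogeny:
    """Parse a single Newick statement into a :class:`Phylogeny`.

    Numeric internal-node labels become support values; quoted labels are
    un-quoted; branches without a length default to 0 (counted on
    ``defaulted_lengths``).  Raises :class:`NewickParseError` for unbalanced
    parentheses, duplicate tip labels or negative branch lengths.
    """
    if not text or ";" not in text:
        raise NewickParseError("input is not a ';'-terminated Newick statement")
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several error classes
        raise NewickParseError(f"malformed Newick: {exc}") from exc

    defaulted = 0
    mapping: dict[int, Node] = {}
    for dnode in dtree.postorder_node_iter():
        if dnode.taxon is not None:
            label = dnode.taxon.label
        else:
            label = dnode.label
        node = Node(label=label)
        length = dnode.edge.length
        if length is None:
            if dnode.parent_node is not None:
                defaulted += 1
                node.length = 0.0
        else:
            node.length = float(length)
        if dnode.child_nodes() and label is not None:
            try:
                node.support = float(label)
                node.label = None
            except ValueError:
                pass  # non-numeric internal labels stay as clade names
        mapping[id(dnode)] = node
        for c in dnode.child_nodes():
            node.add_child(mapping[id(c)])

    tree = Phylogeny(mapping[id(dtree.seed_node)], defaulted_lengths=defaulted)
    if defaulted:
        logger.warning("parse_newick: %d branch length(s) missing, set to 0", defaulted)
    return tree


def _quote(label: str) -> str:
    if label and not (_NEWICK_UNSAFE & set(label)):
        return label
    return "'" + label.replace("'", "''") + "'"


def _fmt_len(x: float) -> str:
    return repr(float(x))


def write_newick(tree: Phylogeny) -> str:
    """Serialize a tree to Newick, deterministic given child order.

    Branch lengths are written with ``repr`` (exact round trip); support
    values are emitted as internal-node labels.
    """
    parts: dict[int, str] = {}
    for n in tree.postorder():
        if n.is_leaf:
            s = _quote(n.label)
        else:
            inner = ",".join(parts[id(c)] for c in n.children)
            if n.support is not None:
                lab = _fmt_len(n.support)
            elif n.label:
                lab = _quote(n.label)
            else:
                lab = ""
            s = f"({inner}){lab}"
        if n.length is not None:
            s += f":{_fmt_len(n.length)}"
        parts[id(n)] = s
    return parts[id(tree.root)] + ";"


# ---------------------------------------------------------------------------
# Tree surgery and queries
# ---------------------------------------------------------------------------


def prune_taxa(tree: Phylogeny, drop) -> Phylogeny:
    """Return a copy of *tree* with the tips in *drop* removed.

    Resulting degree-2 internal nodes are suppressed with their branch
    lengths summed, so all pairwise path lengths among the retained taxa are
    preserved.  Dropping unknown labels, or all but fewer than two tips, is
    an error.
    """
    drop = set(drop)
    labels = set(tree.tip_labels)
    unknown = drop - labels
    if unknown:
        raise TreeError(f"cannot drop unknown taxa: {sorted(unknown)}")
    if len(labels - drop) < 2:
        raise TreeError("pruning must leave at least 2 tips")
    if not drop:
        return tree.copy()

    new = tree.copy()
    # remove dropped tips, then cascade-remove emptied internals
    for node in new.tips():
        if node.label in drop:
            cur = node
            while cur.parent is not None and not cur.children:
                parent = cur.parent
                parent.children.remove(cur)
                cur.parent = None
                cur = parent

    root = new.root
    # suppress unifurcations bottom-up
    order: list[Node] = []
    stack = [root]
    while stack:
        n = stack.pop()
        order.append(n)
        stack.extend(n.children)
    for n in reversed(order):
        if len(n.children) == 1 and n.parent is not None:
            (child,) = n.children
            child.length = (child.length or 0.0) + (n.length or 0.0)
            parent = n.parent
            idx = parent.children.index(n)
            parent.children[idx] = child
            child.parent = parent
            n.parent = None
            n.children = []
    while len(root.children) == 1:
        (root,) = root.children
        root.parent = None
        root.length = None
    return Phylogeny(root, new.defaulted_lengths)


def mrca(tree: Phylogeny, taxa) -> Node:
    """Most recent common ancestor of a non-empty set of tip labels."""
    taxa = list(taxa)
    if not taxa:
        raise TreeError("mrca requires at least one taxon")
    by_label = {n.label: n for n in tree.tips()}
    unknown = [t for t in taxa if t not in by_label]
    if unknown:
        raise TreeError(f"unknown taxa: {sorted(unknown)}")
    first = by_label[taxa[0]]
    path: list[Node] = []
    cur: Node | None = first
    while cur is not None:
        path.append(cur)
        cur = cur.parent
    rank = {id(n): i for i, n in enumerate(path)}
    deepest = 0
    for t in taxa[1:]:
        cur = by_label[t]
        while id(cur) not in rank:
            cur = cur.parent
        deepest = max(deepest, rank[id(cur)])
    return path[deepest]


# ---------------------------------------------------------------------------
# Trait matrices
# ---------------------------------------------------------------------------


@dataclass
class TraitMatrix:
    """Binary/missing states for named characters over an ordered taxon set.

    Backed by a pandas DataFrame (index = taxa, columns = characters) with
    float values 0.0 / 1.0 / NaN (NaN = missing).
    """

    data: pd.DataFrame

    def __post_init__(self):
        if self.data.index.has_duplicates:
            raise ValueError("duplicate taxon rows in trait matrix")
        if self.data.columns.has_duplicates:
            raise ValueError("duplicate character names in trait matrix")
        if len(self.data.index) == 0:
            raise ValueError("trait matrix has no taxa")
        vals = self.data.to_numpy(dtype=float)
        ok = (vals == 0) | (vals == 1) | ~(vals == vals)  # NaN != NaN
        if not ok.all():
            raise ValueError("trait states must be 0, 1 or missing")

    @classmethod
    def from_dict(cls, states, character: str = "trait") -> "TraitMatrix":
        """Build a single-character matrix from ``{taxon: 0|1|None}``."""
        ser = pd.Series(
            {k: (float("nan") if v is None else float(v)) for k, v in states.items()},
            dtype=float,
            name=character,
        )
        return cls(ser.to_frame())

    @property
    def taxa(self) -> list[str]:
        return list(self.data.index)

    @property
    def characters(self) -> list[str]:
        return list(self.data.columns)

    def state(self, taxon: str, character: str):
        """Return 0, 1 or None (missing)."""
        v = self.data.at[taxon, character]
        return None if pd.isna(v) else int(v)

    def column(self, character: str | None = None) -> dict:
        """States of one character as ``{taxon: 0|1|None}``.

        With a single-character matrix the character may be omitted.
        """
        if character is None:
            if len(self.data.columns) != 1:
                raise ValueError("character name required for multi-character matrix")
            character = self.data.columns[0]
        col = self.data[character]
        return {t: (None if pd.isna(v) else int(v)) for t, v in col.items()}


def read_traits(path, tree: Phylogeny) -> TraitMatrix:
    """Read a trait TSV (``taxon<TAB>char1<TAB>char2...``, cells 0/1/?).

    Taxa present in the tree but absent from the file are added as missing;
    file taxa not on the tree are dropped.  Both cases are logged.  Cells
    outside {0,1,?} raise with their row/column location.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    taxon_col = df.columns[0]
    if df[taxon_col].duplicated().any():
        dup = df[taxon_col][df[taxon_col].duplicated()].iloc[0]
        raise ValueError(f"duplicated taxon row: {dup!r}")
    df = df.set_index(taxon_col)

    def convert(v, taxon, char):
        if isinstance(v, str):
            v = v.strip()
        if v in ("0", "1"):
            return float(v)
        if v == "?":
            return float("nan")
        raise ValueError(f"invalid state {v!r} at taxon {taxon!r}, character {char!r}")

    out = pd.DataFrame(
        {
            char: [convert(df.at[t, char], t, char) for t in df.index]
            for char in df.columns
        },
        index=df.index,
    )

    tree_taxa = tree.tip_labels
    extra = [t for t in out.index if t not in set(tree_taxa)]
    absent = [t for t in tree_taxa if t not in set(out.index)]
    if extra:
        logger.warning("read_traits: %d file taxa not on tree, ignored: %s",
                       len(extra), extra[:5])
    if absent:
        logger.warning("read_traits: %d tree taxa absent from file, set missing: %s",
                       len(absent), absent[:5])
    out = out.reindex(tree_taxa)
    logger.info("read_traits: %d taxa x %d characters read", *out.shape)
    return TraitMatrix(out)
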