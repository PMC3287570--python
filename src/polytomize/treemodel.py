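"""Rooted phylogenetic trees and pairwise genome distance matrices.

The tree container is a thin wrapper around :class:`dendropy.Tree` that
enforces the invariants the rest of the pipeline relies on (unique leaf
labels, non-negative branch lengths, multifurcation support) and adds the
small amount of tree algebra the polytomy classifier needs: patristic
distances, MRCA lookups and deep copies.  Distance matrices are plain
label-indexed numpy arrays with PHYLIP square-format readers/writers.

Conventions
-----------
* ``branch_length`` belongs to the edge *above* a node (toward the root);
  the root itself carries no meaningful length.
* Numeric internal-node labels in Newick input are interpreted as clade
  supports on a 0-100 scale (CONSENSE-style); non-numeric labels are kept
  as plain names.
"""

from __future__ import annotations

import math
from typing import Iterable, Iterator

import dendropy
import numpy as np

__all__ = [
    "PhyloTree",
    "DistanceMatrix",
    "TreeError",
    "NewickParseError",
    "MatrixFormatError",
    "MissingBranchLengthError",
    "parse_newick",
    "write_newick",
    "read_phylip_matrix",
    "write_phylip_matrix",
    "patristic_distance",
]


class TreeError(ValueError):
    """Invalid tree structure or content."""


class NewickParseError(TreeError):
    """Malformed Newick input."""


class MissingBranchLengthError(TreeError):
    """An operation required a branch length that is absent."""


class MatrixFormatError(ValueError):
    """Malformed or inconsistent distance-matrix input."""


def _leaf_label(node: dendropy.Node) -> str:
    if node.taxon is not None:
        return node.taxon.label
    return node.label


class PhyloTree:
    """A rooted phylogenetic tree, possibly multifurcating.

    Wraps a :class:`dendropy.Tree`; node handles exposed by iteration
    methods are dendropy ``Node`` objects (``.edge.length`` for the branch
    length above the node, ``.child_nodes()`` for children).
    """

    def __init__(self, tree: dendropy.Tree, validate: bool = True):
        self._t = tree
        if validate:
            self.validate()

    # -- construction ------------------------------------------------------

    @classmethod
    def from_newick(cls, text: str) -> "PhyloTree":
        return parse_newick(text)

    def copy(self) -> "PhyloTree":
        return PhyloTree(self._t.clone(depth=1), validate=False)

    # -- basic accessors ---------------------------------------------------

    @property
    def dendropy_tree(self) -> dendropy.Tree:
        return self._t

    @property
    def root(self) -> dendropy.Node:
        return self._t.seed_node

    def leaf_nodes(self) -> list[dendropy.Node]:
        return self._t.leaf_nodes()

    def leaf_labels(self) -> list[str]:
        return [_leaf_label(n) for n in self._t.leaf_node_iter()]

    def n_leaves(self) -> int:
        return sum(1 for _ in self._t.leaf_node_iter())

    def find_leaf(self, label: str) -> dendropy.Node:
        for node in self._t.leaf_node_iter():
            if _leaf_label(node) == label:
                return node
        raise TreeError(f"unknown leaf label: {label!r}")

    def preorder(self) -> Iterator[dendropy.Node]:
        return self._t.preorder_node_iter()

    def postorder(self) -> Iterator[dendropy.Node]:
        return self._t.postorder_node_iter()

    def internal_nodes(self, exclude_root: bool = False) -> list[dendropy.Node]:
        out = []
        for node in self._t.preorder_node_iter():
            if node.is_leaf():
                continue
            if exclude_root and node is self.root:
                continue
            out.append(node)
        return out

    def polytomy_count(self) -> int:
        return sum(1 for n in self.internal_nodes() if len(n.child_nodes()) > 2)

    # -- validation --------------------------------------------------------

    def validate(self) -> None:
        labels = self.leaf_labels()
        if len(set(labels)) != len(labels):
            seen, dups = set(), set()
            for x in labels:
                (dups if x in seen else seen).add(x)
            raise TreeError(f"duplicate leaf labels: {sorted(dups)}")
        for node in self._t.preorder_node_iter():
            length = node.edge.length
            if length is not None and length < 0:
                raise TreeError(
                    f"negative branch length {length} above node {_leaf_label(node)!r}"
                )

    # -- tree algebra ------------------------------------------------------

    def ancestors(self, node: dendropy.Node, include_self: bool = True) -> list[dendropy.Node]:
        out = [node] if include_self else []
        cur = node.parent_node
        while cur is not None:
            out.append(cur)
            cur = cur.parent_node
        return out

    def mrca(self, *labels: str) -> dendropy.Node:
        nodes = [self.find_leaf(x) for x in labels]
        common: set[int] | None = None
        for node in nodes[1:]:
            ids = {id(a) for a in self.ancestors(node)}
            common = ids if common is None else (common & ids)
        cur = nodes[0]
        while common is not None and id(cur) not in common:
            cur = cur.parent_node
        return cur

    def depth_of(self, node: dendropy.Node) -> float:
        """Sum of branch lengths from the root down to ``node``."""
        total = 0.0
        cur = node
        while cur.parent_node is not None:
            if cur.edge.length is None:
                raise MissingBranchLengthError("branch length missing on path to root")
            total += cur.edge.length
            cur = cur.parent_node
        return total

    def patristic_distance(self, a: str, b: str) -> float:
        return patristic_distance(self, a, b)

    def patristic_matrix(self) -> "DistanceMatrix":
        """All-pairs patristic distances, computed in one post-order sweep."""
        labels = sorted(self.leaf_labels())
        index = {lab: i for i, lab in enumerate(labels)}
        n = len(labels)
        d = np.zeros((n, n))
        # each node yields (leaf indices, distances from node to those leaves)
        stash: dict[int, tuple[np.ndarray, np.ndarray]] = {}
        for node in self._t.postorder_node_iter():
            if node.is_leaf():
                stash[id(node)] = (
                    np.array([index[_leaf_label(node)]], dtype=np.intp),
                    np.zeros(1),
                )
                continue
            parts = []
            for child in node.child_nodes():
                idx, dep = stash.pop(id(child))
                length = child.edge.length
                if length is None:
                    raise MissingBranchLengthError(
                        "patristic matrix requires branch lengths on all edges"
                    )
                parts.append((idx, dep + length))
            for i in range(len(parts)):
                for j in range(i + 1, len(parts)):
                    ia, da = parts[i]
                    ib, db = parts[j]
                    block = da[:, None] + db[None, :]
                    d[np.ix_(ia, ib)] = block
                    d[np.ix_(ib, ia)] = block.T
            stash[id(node)] = (
                np.concatenate([p[0] for p in parts]),
                np.concatenate([p[1] for p in parts]),
            )
        return DistanceMatrix(labels, d)

    # -- serialization -----------------------------------------------------

    def to_newick(self, precision: int = 6) -> str:
        return write_newick(self, precision=precision)

    def __repr__(self) -> str:  # pragma: no cover
        return f"<PhyloTree with {self.n_leaves()} leaves>"


def parse_newick(text: str) -> PhyloTree:
    """Parse a (possibly multifurcating) Newick string into a tree.

    Numeric internal-node labels in [0, 100] are moved into a ``support``
    attribute on the node; other labels remain as names.
    """
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises various DataError subclasses
        raise NewickParseError(f"malformed Newick: {exc}") from exc
    for node in tree.preorder_node_iter():
        node.support = None
        if node.is_leaf() or node.label is None:
            continue
        try:
            value = float(node.label)
        except ValueError:
            continue
        if 0.0 <= value <= 100.0:
            node.support = value
            node.label = None
    return PhyloTree(tree)


def write_newick(tree: PhyloTree, precision: int = 6) -> str:
    """Serialize to single-line Newick; supports become internal labels."""
    t = tree.dendropy_tree
    for node in t.preorder_node_iter():
        support = getattr(node, "support", None)
        if support is not None and not node.is_leaf():
            node.label = format(support, "g")
    out = t.as_string(
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
        real_value_format_specifier=f".{precision}f",
    )
    return out.strip() + "\n"


def patristic_distance(tree: PhyloTree, a: str, b: str) -> float:
    """Sum of branch lengths along the path between leaves ``a`` and ``b``."""
    if a == b:
        tree.find_leaf(a)
        return 0.0
    na, nb = tree.find_leaf(a), tree.find_leaf(b)
    anc_a = {id(x): x for x in tree.ancestors(na)}
    total_b = 0.0
    cur = nb
    while id(cur) not in anc_a:
        if cur.edge.length is None:
            raise MissingBranchLengthError(f"missing branch length on path {a}-{b}")
        total_b += cur.edge.length
        cur = cur.parent_node
    mrca = cur
    total_a = 0.0
    cur = na
    while cur is not mrca:
        if cur.edge.length is None:
            raise MissingBranchLengthError(f"missing branch length on path {a}-{b}")
        total_a += cur.edge.length
        cur = cur.parent_node
    return total_a + total_b


class DistanceMatrix:
    """Symmetric taxon-by-taxon distance matrix with label lookup."""

    def __init__(self, labels: Iterable[str], values: np.ndarray):
        self.labels = list(labels)
        self.values = np.asarray(values, dtype=float)
        n = len(self.labels)
        if len(set(self.labels)) != n:
            raise MatrixFormatError("duplicate taxon labels in distance matrix")
        if self.values.shape != (n, n):
            raise MatrixFormatError(
                f"matrix shape {self.values.shape} does not match {n} labels"
            )
        if not np.allclose(self.values, self.values.T, atol=1e-8, rtol=0):
            raise MatrixFormatError("matrix is not symmetric")
        if np.any(np.abs(np.diag(self.values)) > 1e-12):
            raise MatrixFormatError("matrix diagonal is not zero")
        self._index = {lab: i for i, lab in enumerate(self.labels)}

    def __len__(self) -> int:
        return len(self.labels)

    def __contains__(self, label: str) -> bool:
        return label in self._index

    def get(self, a: str, b: str) -> float:
        try:
            return float(self.values[self._index[a], self._index[b]])
        except KeyError as exc:
            raise KeyError(f"taxon not in distance matrix: {exc}") from exc

    def to_phylip(self, precision: int = 6) -> str:
        return write_phylip_matrix(self, precision=precision)


def read_phylip_matrix(text: str, asym_tol: float = 1e-6) -> DistanceMatrix:
    """Read a PHYLIP square distance matrix (relaxed labels).

    Format: first line is the taxon count *n*; then *n* records of a label
    followed by *n* numbers (line wrapping allowed).  Asymmetries up to
    ``asym_tol`` (relative to the matrix scale) are averaged away; larger
    ones raise :class:`MatrixFormatError`.
    """
    tokens = text.split()
    if not tokens:
        raise MatrixFormatError("empty distance-matrix input")
    try:
        n = int(tokens[0])
    except ValueError as exc:
        raise MatrixFormatError(f"bad taxon count {tokens[0]!r}") from exc
    pos = 1
    labels: list[str] = []
    rows: list[list[float]] = []
    for _ in range(n):
        if pos >= len(tokens):
            raise MatrixFormatError(f"expected {n} rows, found {len(rows)}")
        labels.append(tokens[pos])
        pos += 1
        if pos + n > len(tokens):
            raise MatrixFormatError(
                f"row for {labels[-1]!r} has fewer than {n} entries"
            )
        try:
            row = [float(x) for x in tokens[pos : pos + n]]
        except ValueError as exc:
            raise MatrixFormatError(f"non-numeric entry in row {labels[-1]!r}") from exc
        pos += n
        rows.append(row)
    if pos != len(tokens):
        raise MatrixFormatError("trailing content after the last matrix row")
    d = np.array(rows)
    scale = max(1.0, float(np.max(np.abs(d))))
    asym = np.max(np.abs(d - d.T))
    if asym > asym_tol * scale:
        raise MatrixFormatError(f"matrix asymmetry {asym:g} exceeds tolerance")
    d = 0.5 * (d + d.T)
    np.fill_diagonal(d, 0.0)
    if np.any(d < -asym_tol * scale):
        raise MatrixFormatError("negative distances in matrix")
    d[d < 0] = 0.0
    return DistanceMatrix(labels, d)


def write_phylip_matrix(matrix: DistanceMatrix, precision: int = 6) -> str:
    lines = [f"{len(matrix)}"]
    width = max(len(x) for x in matrix.labels) + 2
    for lab, row in zip(matrix.labels, matrix.values):
        nums = " ".join(format(v, f".{precision}f") for v in row)
        lines.append(f"{lab:<{width}}{nums}")
    return "\n".join(lines) + "\n"
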