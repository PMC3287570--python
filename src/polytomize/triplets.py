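"""Two-level bifurcations (triplets), their features, and gold-standard labels.

A *triplet* is the subtree pattern ``((A,B),C)`` in a rooted binary tree:
an internal node ``u`` whose two children are a cherry ``v = (A,B)`` of two
leaves and a third leaf ``C``, with ``u`` itself below the root so that the
edge above it exists.  Five branch lengths describe its geometry:

* ``S1``, ``S2`` — pendant edges of the cherry leaves A and B,
* ``S3`` — pendant edge of the outgroup leaf C,
* ``S4`` — internal edge from the cherry node ``v`` up to ``u``,
* ``S5`` — edge from ``u`` up to its parent,

and three pairwise genome distances come from a distance matrix:
``X1 = d(A,C)``, ``X2 = d(B,C)``, ``X3 = d(A,B)``.

Three scale-free features discriminate genuine dichotomies from polytomies
that were arbitrarily resolved into bifurcations:

* ``LR``     = (X1 + X2 - 2*X3) / ((X1 + X2 + X3) / 3)
* ``IntraR`` = (min(S1,S2)/max(S1,S2)) / (min(S3,S4)/max(S3,S4))
* ``InterR`` = max(S1,S2,S3,S4) / S5

At a polytomy the internal stem S4 contracts toward zero and the three
child branches equalize, driving LR toward 0 and IntraR far above 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np

from .treemodel import (
    DistanceMatrix,
    MissingBranchLengthError,
    PhyloTree,
)

__all__ = [
    "EPSILON",
    "TripletGeometry",
    "LabeledInstance",
    "InstanceDropped",
    "ExtractionReport",
    "extract_triplets",
    "leaf_rate",
    "intra_rate",
    "inter_rate",
    "featurize",
    "find_triplet",
    "label_from_reference",
    "feature_table",
]

#: floor applied to branch lengths before ratio features; consensus and NJ
#: trees legitimately contain zero-length edges.
EPSILON = 1e-9

FEATURE_NAMES = ("LR", "IntraR", "InterR")


class InstanceDropped(Exception):
    """A triplet could not be featurized against a source; carries the reason."""


@dataclass
class TripletGeometry:
    """One two-level bifurcation ((A,B),C) with its five branch lengths."""

    a: str
    b: str
    c: str
    s1: float
    s2: float
    s3: float
    s4: float
    s5: float
    u: dendropy.Node | None = field(default=None, repr=False, compare=False)
    v: dendropy.Node | None = field(default=None, repr=False, compare=False)

    @property
    def key(self) -> tuple[tuple[str, str], str]:
        """Order-free identity: (sorted cherry pair, outgroup)."""
        return (tuple(sorted((self.a, self.b))), self.c)

    @property
    def id(self) -> str:
        (p, q), c = self.key
        return f"{p}|{q}|{c}"


@dataclass
class LabeledInstance:
    triplet: TripletGeometry
    features: np.ndarray
    feature_names: list[str]
    label: int | None  # +1 dichotomy, -1 polytomy, None unlabeled


@dataclass
class ExtractionReport:
    n_internal: int = 0
    n_triplets: int = 0
    n_root_skipped: int = 0  # cherry+leaf pattern at the root: no S5


def _edge_length(node: dendropy.Node, what: str) -> float:
    if node.edge.length is None:
        raise MissingBranchLengthError(f"missing branch length for {what}")
    return float(node.edge.length)


def _triplet_at(u: dendropy.Node) -> TripletGeometry | None:
    """Return the triplet rooted at ``u`` if u matches the pattern, else None.

    Pattern: u has exactly two children, one an internal node with exactly
    two leaf children (the cherry) and the other a leaf.  S5 is not read
    here; callers decide how to treat the root.
    """
    kids = u.child_nodes()
    if len(kids) != 2:
        return None
    internal = [k for k in kids if not k.is_leaf()]
    leaves = [k for k in kids if k.is_leaf()]
    if len(internal) != 1 or len(leaves) != 1:
        return None
    v, c = internal[0], leaves[0]
    vkids = v.child_nodes()
    if len(vkids) != 2 or not all(k.is_leaf() for k in vkids):
        return None
    a, b = vkids

    def lab(n: dendropy.Node) -> str:
        return n.taxon.label if n.taxon is not None else n.label

    s5 = _edge_length(u, "S5") if u.parent_node is not None else float("nan")
    return TripletGeometry(
        a=lab(a),
        b=lab(b),
        c=lab(c),
        s1=_edge_length(a, "S1"),
        s2=_edge_length(b, "S2"),
        s3=_edge_length(c, "S3"),
        s4=_edge_length(v, "S4"),
        s5=s5,
        u=u,
        v=v,
    )


def extract_triplets(
    tree: PhyloTree, report: ExtractionReport | None = None
) -> list[TripletGeometry]:
    """Enumerate all two-level bifurcations of a rooted tree.

    Triplets whose parent node is the root have no S5 and are skipped (and
    counted in ``report`` when given): InterR is undefined for them.
    """
    out: list[TripletGeometry] = []
    rep = report if report is not None else ExtractionReport()
    for u in tree.internal_nodes():
        rep.n_internal += 1
        trip = _triplet_at(u)
        if trip is None:
            continue
        if u.parent_node is None:
            rep.n_root_skipped += 1
            continue
        out.append(trip)
    rep.n_triplets = len(out)
    return out


def leaf_rate(x1: float, x2: float, x3: float) -> float:
    """LR: excess of outgroup distances over twice the cherry distance,
    normalized by the mean pairwise distance."""
    total = x1 + x2 + x3
    if total <= 0:
        raise ValueError("leaf_rate undefined for all-zero distances")
    return (x1 + x2 - 2.0 * x3) / (total / 3.0)


def _floor(x: float) -> float:
    return x if x > EPSILON else EPSILON


def intra_rate(s1: float, s2: float, s3: float, s4: float) -> float:
    """IntraR: cherry-branch balance over (outgroup vs internal stem) balance."""
    s1, s2, s3, s4 = _floor(s1), _floor(s2), _floor(s3), _floor(s4)
    top = min(s1, s2) / max(s1, s2)
    bottom = min(s3, s4) / max(s3, s4)
    return top / bottom


def inter_rate(s1: float, s2: float, s3: float, s4: float, s5: float) -> float:
    """InterR: largest within-triplet branch relative to the edge above it."""
    return max(_floor(s1), _floor(s2), _floor(s3), _floor(s4)) / _floor(s5)


def find_triplet(tree: PhyloTree, a: str, b: str, c: str) -> TripletGeometry | None:
    """Locate the exact two-level pattern ((a,b),c) in ``tree``, if present."""
    try:
        na, nb = tree.find_leaf(a), tree.find_leaf(b)
    except Exception:
        return None
    v = na.parent_node
    if v is None or v is not nb.parent_node:
        return None
    u = v.parent_node
    if u is None:
        return None
    trip = _triplet_at(u)
    if trip is None:
        return None
    if tuple(sorted((trip.a, trip.b))) != tuple(sorted((a, b))) or trip.c != c:
        return None
    if u.parent_node is None:
        return None
    return trip


def _features_one_source(trip: TripletGeometry, matrix: DistanceMatrix) -> np.ndarray:
    for lab in (trip.a, trip.b, trip.c):
        if lab not in matrix:
            raise InstanceDropped(f"taxon {lab!r} absent from distance matrix")
    x1 = matrix.get(trip.a, trip.c)
    x2 = matrix.get(trip.b, trip.c)
    x3 = matrix.get(trip.a, trip.b)
    return np.array(
        [
            leaf_rate(x1, x2, x3),
            intra_rate(trip.s1, trip.s2, trip.s3, trip.s4),
            inter_rate(trip.s1, trip.s2, trip.s3, trip.s4, trip.s5),
        ]
    )


def featurize(
    triplet: TripletGeometry,
    sources: list[tuple[PhyloTree | None, DistanceMatrix]],
) -> tuple[np.ndarray, list[str]]:
    """Concatenated [LR, IntraR, InterR] per source, in source order.

    Each source is a ``(tree, matrix)`` pair.  When the source tree is the
    tree the triplet came from (or ``None``), the triplet's own geometry is
    used; otherwise the identical ((A,B),C) pattern must be present in the
    source tree or the instance is dropped (:class:`InstanceDropped`).
    """
    blocks: list[np.ndarray] = []
    names: list[str] = []
    for k, (tree, matrix) in enumerate(sources):
        if tree is None:
            local = triplet
        else:
            local = find_triplet(tree, triplet.a, triplet.b, triplet.c)
            if local is None:
                raise InstanceDropped(
                    f"triplet {triplet.id} absent or differently resolved in source {k}"
                )
        blocks.append(_features_one_source(local, matrix))
        suffix = "" if len(sources) == 1 else f"_{k}"
        names.extend(f"{f}{suffix}" for f in FEATURE_NAMES)
    vec = np.concatenate(blocks)
    if not np.all(np.isfinite(vec)):
        raise InstanceDropped(f"non-finite feature for triplet {triplet.id}")
    return vec, names


def label_from_reference(triplet: TripletGeometry, reference: PhyloTree) -> int | None:
    """Gold-standard label of ((A,B),C) against a reference taxonomy tree.

    +1 when the reference resolves the three taxa as ((A,B),C); -1 when the
    reference shows them as one polytomy *or* resolves them conflictingly;
    None when any of the three taxa is absent from the reference.
    """
    present = set(reference.leaf_labels())
    if not {triplet.a, triplet.b, triplet.c} <= present:
        return None
    m_ab = reference.mrca(triplet.a, triplet.b)
    m_abc = reference.mrca(triplet.a, triplet.b, triplet.c)
    if m_ab is m_abc:
        # MRCA(A,B) is already the three-taxon MRCA: either a polytomy or a
        # resolution favoring ((A,C),B) / ((B,C),A); both get -1.
        return -1
    return +1


def feature_table(instances: list[LabeledInstance]):
    """Feature/label table as a pandas DataFrame (one row per triplet)."""
    import pandas as pd

    if not instances:
        return pd.DataFrame(columns=["triplet_id", "A", "B", "C", "label"])
    names = instances[0].feature_names
    rows = []
    for inst in instances:
        row = {
            "triplet_id": inst.triplet.id,
            "A": inst.triplet.a,
            "B": inst.triplet.b,
            "C": inst.triplet.c,
        }
        row.update(dict(zip(names, inst.features)))
        row["label"] = inst.label if inst.label is not None else "NA"
        rows.append(row)
    return pd.DataFrame(rows)
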