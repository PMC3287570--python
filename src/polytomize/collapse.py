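"""Convert classified bifurcations into polytomies; agreement reporting.

Once the classifier has scored every two-level bifurcation of a binary
tree, the triplets predicted to be polytomies are collapsed: the internal
stem S4 is removed, the three taxa A, B, C become siblings under the
triplet's top node, and each of their branch lengths is set to the average
(S1 + S2 + S3) / 3.  Collapsing runs in a single pass over the triplets of
the *input* tree; no new triplets created by the edits are re-examined.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from .blr import BLRModel
from .treemodel import DistanceMatrix, PhyloTree, TreeError
from .triplets import (
    InstanceDropped,
    TripletGeometry,
    extract_triplets,
    featurize,
    find_triplet,
)

__all__ = [
    "ClassifiedTriplet",
    "ApplyReport",
    "collapse_triplet",
    "apply_model",
    "taxonomy_agreement",
]


@dataclass
class ClassifiedTriplet:
    triplet: TripletGeometry
    features: np.ndarray | None
    score: float | None  # P(dichotomy)
    label: int | None  # +1 dichotomy, -1 polytomy
    collapsed: bool = False
    dropped_reason: str | None = None


@dataclass
class ApplyReport:
    triplets: list[ClassifiedTriplet] = field(default_factory=list)

    @property
    def n_collapsed(self) -> int:
        return sum(1 for t in self.triplets if t.collapsed)

    @property
    def n_dropped(self) -> int:
        return sum(1 for t in self.triplets if t.dropped_reason is not None)

    def to_table(self):
        import pandas as pd

        rows = []
        for ct in self.triplets:
            row = {
                "triplet_id": ct.triplet.id,
                "A": ct.triplet.a,
                "B": ct.triplet.b,
                "C": ct.triplet.c,
                "score": ct.score,
                "decision": {1: "dichotomy", -1: "polytomy", None: "dropped"}[ct.label],
                "collapsed": ct.collapsed,
                "dropped_reason": ct.dropped_reason or "",
            }
            if ct.features is not None:
                for i, v in enumerate(ct.features):
                    row[f"feature_{i}"] = v
            rows.append(row)
        return pd.DataFrame(rows)


def collapse_triplet(
    tree: PhyloTree, triplet: TripletGeometry, add_stem: bool = False
) -> PhyloTree:
    """Collapse ((A,B),C) into the polytomy (A,B,C) in place.

    The stem S4 is deleted and the three child edges are set to the mean
    (S1+S2+S3)/3; with ``add_stem`` the removed S4 is added back onto each
    averaged edge (keeps root-to-leaf depths closer for ultrametric users).
    Returns the same tree object.
    """
    local = find_triplet(tree, triplet.a, triplet.b, triplet.c)
    if local is None:
        raise TreeError(
            f"triplet {triplet.id} is not present in the tree (already modified?)"
        )
    u, v = local.u, local.v
    mean = (local.s1 + local.s2 + local.s3) / 3.0
    if add_stem:
        mean += local.s4
    a, b = v.child_nodes()
    u.remove_child(v)
    for leaf in (a, b):
        v.remove_child(leaf)
        u.add_child(leaf)
        leaf.edge.length = mean
    for child in u.child_nodes():
        if child.is_leaf() and (child.taxon and child.taxon.label == local.c):
            child.edge.length = mean
    return tree


def apply_model(
    tree: PhyloTree,
    model: BLRModel,
    sources: list[tuple[PhyloTree | None, DistanceMatrix]],
    add_stem: bool = False,
) -> tuple[PhyloTree, ApplyReport]:
    """Score every two-level bifurcation and collapse predicted polytomies.

    ``sources`` pair trees with distance matrices for featurization; pass
    ``[(None, matrix)]`` to read the geometry off the classified tree
    itself.  Triplets that cannot be featurized (e.g. resolved differently
    in a source tree) are logged and left uncollapsed.  Returns a modified
    copy of the input tree plus a per-triplet report.
    """
    report = ApplyReport()
    out = tree.copy()
    for trip in extract_triplets(tree):
        try:
            feats, _ = featurize(trip, sources)
        except InstanceDropped as exc:
            report.triplets.append(
                ClassifiedTriplet(trip, None, None, None, dropped_reason=str(exc))
            )
            continue
        score = float(model.predict_prob(feats)[0])
        label = 1 if score >= model.threshold else -1
        ct = ClassifiedTriplet(trip, feats, score, label)
        if label == -1:
            collapse_triplet(out, trip, add_stem=add_stem)
            ct.collapsed = True
        report.triplets.append(ct)
    return out, report


def _induced_topology(tree: PhyloTree, cache: dict, a: str, b: str, c: str):
    """Induced topology of a leaf triple: the cherry pair, or None if a star."""
    anc, depth = cache["anc"], cache["depth"]

    def mrca_depth(x: str, y: str) -> int:
        ax, ay = anc[x], anc[y]
        i = 0
        limit = min(len(ax), len(ay))
        while i < limit and ax[i] is ay[i]:
            i += 1
        return i  # number of shared ancestors from the root down

    dab, dac, dbc = mrca_depth(a, b), mrca_depth(a, c), mrca_depth(b, c)
    top = min(dab, dac, dbc)
    if dab == dac == dbc:
        return None
    if dab > top:
        return tuple(sorted((a, b)))
    if dac > top:
        return tuple(sorted((a, c)))
    return tuple(sorted((b, c)))


def _triple_cache(tree: PhyloTree) -> dict:
    anc: dict[str, list] = {}
    for leaf in tree.leaf_nodes():
        lab = leaf.taxon.label if leaf.taxon else leaf.label
        chain = tree.ancestors(leaf, include_self=False)
        anc[lab] = list(reversed(chain))  # root first
    return {"anc": anc, "depth": None}


def taxonomy_agreement(
    tree: PhyloTree,
    reference: PhyloTree,
    max_triples: int = 20000,
    seed: int = 0,
) -> float:
    """Fraction of shared-leaf triples with identical induced topology.

    Each triple of shared leaves induces, in each tree, either one of the
    three resolved topologies or an unresolved star; agreement requires the
    two trees to induce the same outcome.  When the number of triples
    exceeds ``max_triples`` a seeded random sample of that size is scored.
    """
    shared = sorted(set(tree.leaf_labels()) & set(reference.leaf_labels()))
    if len(shared) < 3:
        raise TreeError("need at least 3 shared leaves for agreement")
    cache_t = _triple_cache(tree)
    cache_r = _triple_cache(reference)
    n = len(shared)
    total = n * (n - 1) * (n - 2) // 6
    if total <= max_triples:
        triples = combinations(shared, 3)
        count = total
    else:
        rng = np.random.default_rng(seed)
        picks = set()
        while len(picks) < max_triples:
            i, j, k = rng.choice(n, size=3, replace=False)
            picks.add(tuple(sorted((int(i), int(j), int(k)))))
        triples = ((shared[i], shared[j], shared[k]) for i, j, k in sorted(picks))
        count = max_triples
    agree = 0
    for a, b, c in triples:
        if _induced_topology(tree, cache_t, a, b, c) == _induced_topology(
            reference, cache_r, a, b, c
        ):
            agree += 1
    return agree / count
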