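"""Synthetic taxonomies, binary resolutions, and noisy distance matrices.

The generator emulates the situation the classifier is built for: a
clock-like multifurcating "true" taxonomy whose polytomies were arbitrarily
resolved into bifurcations by a tree-building program.  Trees are generated
on an age scale (every leaf at age 0, divergence times decreasing toward
the leaves), which plants the polytomy signal through exactly the two
mechanisms the features are designed to detect:

* a genuine dichotomy separates the divergence of C from that of (A, B) by
  a real time gap, so the internal stem S4 is a fixed fraction of the node
  age and LR stays bounded away from zero;
* an arbitrarily resolved polytomy packs its resolution nodes within an
  epsilon sliver of the true divergence time, so S4 collapses to near zero,
  the cherry branches equalize, IntraR explodes and LR vanishes.

Distance matrices are patristic distances perturbed by multiplicative
Gaussian noise (truncated above -0.9), which keeps distances positive and
respects the scale invariance of the features.
"""

from __future__ import annotations

import sys
from dataclasses import dataclass

import dendropy
import numpy as np

from .treemodel import DistanceMatrix, PhyloTree
from .triplets import (
    ExtractionReport,
    LabeledInstance,
    extract_triplets,
    featurize,
    label_from_reference,
)

__all__ = [
    "SimConfig",
    "SimDataset",
    "simulate_reference",
    "binarize",
    "simulate_matrix",
    "make_dataset",
]


@dataclass
class SimConfig:
    """Parameters of the synthetic taxonomy / tree / distance generator.

    The reference tree is ultrametric: the root sits at age 1, each
    internal child diverges at a uniformly drawn fraction of its parent's
    age, and leaves sit at age 0.  With probability ``polytomy_fraction``
    an internal node is a multifurcation of 3-5 children.  Multifurcations
    draw their age from ``polytomy_age_fraction`` (young relative to the
    parent: a radiation at the end of a long stem, the long-branch
    retraction / short-branch contraction picture), dichotomies from
    ``dichotomy_age_fraction``.  ``polytomy_stem_scale`` sets the stem
    length of the nodes introduced by arbitrary polytomy resolution, as a
    fraction of the polytomy's age.  ``noise_sd`` is the standard
    deviation of the multiplicative distance noise.
    """

    n_taxa: int = 3000
    polytomy_fraction: float = 0.35
    dichotomy_age_fraction: tuple[float, float] = (0.45, 0.8)
    polytomy_age_fraction: tuple[float, float] = (0.1, 0.4)
    polytomy_stem_scale: float = 1e-4
    noise_sd: float = 0.05
    balance_classes: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_taxa < 4:
            raise ValueError("need at least 4 taxa")
        if not 0.0 <= self.polytomy_fraction <= 1.0:
            raise ValueError("polytomy_fraction must be in [0, 1]")
        for name in ("dichotomy_age_fraction", "polytomy_age_fraction"):
            lo, hi = getattr(self, name)
            if not 0.0 < lo <= hi < 1.0:
                raise ValueError(f"{name} must satisfy 0 < lo <= hi < 1")
        if not 0.0 < self.polytomy_stem_scale < self.polytomy_age_fraction[0]:
            raise ValueError(
                "polytomy_stem_scale must be positive and well below the "
                "smallest polytomy age fraction"
            )
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.seed is None:
            raise ValueError("a seed is mandatory for dataset generation")


@dataclass
class SimDataset:
    reference: PhyloTree
    tree: PhyloTree  # binary resolution of the reference
    matrix: DistanceMatrix
    instances: list[LabeledInstance]
    truth: dict  # triplet key -> true label (+1/-1), before balancing


def simulate_reference(
    cfg: SimConfig, rng: np.random.Generator | None = None
) -> PhyloTree:
    """A rooted ultrametric taxonomy over ``n_taxa`` leaves.

    Each internal node is, with probability ``polytomy_fraction`` (when at
    least 3 leaves remain), a multifurcation of 3-5 children, else a
    bifurcation; all children of a node diverge at the node's age.
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    labels = [f"T{i:05d}" for i in range(cfg.n_taxa)]
    tns = dendropy.TaxonNamespace(labels)

    sys.setrecursionlimit(max(sys.getrecursionlimit(), 10 * cfg.n_taxa + 1000))

    def build(members: list[str], age: float, is_poly: bool) -> dendropy.Node:
        if len(members) == 1:
            node = dendropy.Node(taxon=tns.get_taxon(members[0]))
            node.age = 0.0
            return node
        k = len(members)
        c = int(rng.integers(3, min(5, k) + 1)) if is_poly else 2
        order = rng.permutation(k)
        cuts = np.sort(rng.choice(k - 1, size=c - 1, replace=False)) + 1
        groups = np.split(np.asarray(members, dtype=object)[order], cuts)
        node = dendropy.Node()
        node.age = age
        for grp in groups:
            grp = list(grp)
            child_poly = len(grp) >= 3 and rng.random() < cfg.polytomy_fraction
            lo, hi = (
                cfg.polytomy_age_fraction if child_poly else cfg.dichotomy_age_fraction
            )
            child_age = 0.0 if len(grp) == 1 else age * float(rng.uniform(lo, hi))
            child = build(grp, child_age, child_poly)
            child.edge.length = age - child.age
            node.add_child(child)
        return node

    root_poly = cfg.n_taxa >= 3 and rng.random() < cfg.polytomy_fraction
    root = build(labels, 1.0, root_poly)
    tree = dendropy.Tree(seed_node=root, taxon_namespace=tns)
    tree.is_rooted = True
    return PhyloTree(tree)


def _node_ages(tree: PhyloTree) -> dict[int, float]:
    ages: dict[int, float] = {}
    for node in tree.postorder():
        if node.is_leaf():
            ages[id(node)] = 0.0
        else:
            ages[id(node)] = max(
                ages[id(c)] + (c.edge.length or 0.0) for c in node.child_nodes()
            )
    return ages


def binarize(
    reference: PhyloTree,
    cfg: SimConfig,
    rng: np.random.Generator | None = None,
) -> tuple[PhyloTree, dict]:
    """Resolve every multifurcation into bifurcations with epsilon stems.

    Each multifurcation of age ``a`` is resolved by repeatedly joining two
    random children under a new node placed ``polytomy_stem_scale * a``
    below it, mimicking a tree builder forced to order simultaneous
    divergences.  Returns the binary tree and a truth table mapping every
    extracted triplet key to its true label: -1 when the cherry node and
    its parent stem from the *same* original multifurcation (the three taxa
    truly diverged simultaneously), else +1.
    """
    rng = np.random.default_rng(cfg.seed + 1) if rng is None else rng
    out = reference.copy()
    ages = _node_ages(out)
    for node in list(out.preorder()):
        node.origin = id(node)  # original nodes map to themselves
    for node in list(out.preorder()):
        kids = node.child_nodes()
        if len(kids) <= 2:
            continue
        a_node = ages[id(node)]
        eps = cfg.polytomy_stem_scale * a_node
        pool = list(kids)
        elem_age = {id(c): ages[id(c)] for c in pool}
        for child in pool:
            node.remove_child(child)
        # joints stack within a sliver of width (c-2)*eps below the
        # polytomy age; a joint created later may become the parent of an
        # earlier one, so later joints sit higher
        n_joints = len(pool) - 2
        made = 0
        while len(pool) > 2:
            made += 1
            a_joint = a_node - (n_joints - made + 1) * eps
            i, j = sorted(rng.choice(len(pool), size=2, replace=False))
            b = pool.pop(int(j))
            a = pool.pop(int(i))
            joint = dendropy.Node()
            joint.origin = node.origin
            for moved in (a, b):
                stem = a_joint - elem_age[id(moved)]
                if stem <= 0:
                    raise ValueError(
                        "polytomy_stem_scale too large for the configured "
                        "age fractions: resolution nodes would overlap children"
                    )
                moved.edge.length = stem
                joint.add_child(moved)
            elem_age[id(joint)] = a_joint
            pool.append(joint)
        for child in pool:
            child.edge.length = a_node - elem_age[id(child)]
            node.add_child(child)

    truth: dict = {}
    for trip in extract_triplets(out):
        same = trip.u.origin == trip.v.origin
        truth[trip.key] = -1 if same else +1
    return out, truth


def simulate_matrix(
    tree: PhyloTree,
    noise_sd: float,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> DistanceMatrix:
    """Patristic distances with multiplicative Gaussian noise.

    d(a,b) = patristic(a,b) * (1 + e_ab) with e_ab ~ N(0, noise_sd^2)
    truncated above -0.9 (resampled), symmetrized, zero diagonal.
    """
    rng = np.random.default_rng(seed) if rng is None else rng
    base = tree.patristic_matrix()
    d = base.values.copy()
    if noise_sd > 0:
        n = len(base.labels)
        iu = np.triu_indices(n, k=1)
        eps = rng.normal(0.0, noise_sd, size=len(iu[0]))
        bad = eps <= -0.9
        while np.any(bad):
            eps[bad] = rng.normal(0.0, noise_sd, size=int(bad.sum()))
            bad = eps <= -0.9
        d[iu] *= 1.0 + eps
        d.T[iu] = d[iu]
    return DistanceMatrix(base.labels, d)


def make_dataset(cfg: SimConfig) -> SimDataset:
    """End-to-end fixture: reference, binary tree, matrix, labeled triplets.

    Labels come from the binarize truth table and are asserted to agree
    with MRCA lookups against the reference tree.  With
    ``balance_classes`` the majority class is downsampled (seeded) to a
    50/50 split.
    """
    ss = np.random.SeedSequence(cfg.seed)
    rng_ref, rng_bin, rng_mat, rng_bal = (
        np.random.default_rng(s) for s in ss.spawn(4)
    )
    reference = simulate_reference(cfg, rng=rng_ref)
    tree, truth = binarize(reference, cfg, rng=rng_bin)
    matrix = simulate_matrix(tree, cfg.noise_sd, rng=rng_mat)

    report = ExtractionReport()
    instances: list[LabeledInstance] = []
    for trip in extract_triplets(tree, report=report):
        feats, names = featurize(trip, [(None, matrix)])
        label = truth[trip.key]
        ref_label = label_from_reference(trip, reference)
        if ref_label != label:
            raise AssertionError(
                f"truth-table label {label} disagrees with reference lookup "
                f"{ref_label} for triplet {trip.id}"
            )
        instances.append(LabeledInstance(trip, feats, names, label))

    pos = [x for x in instances if x.label == +1]
    neg = [x for x in instances if x.label == -1]
    if len(pos) < 2 or len(neg) < 2:
        raise ValueError(
            f"degenerate dataset: {len(pos)} dichotomies, {len(neg)} polytomies"
        )
    if cfg.balance_classes:
        k = min(len(pos), len(neg))
        if len(pos) > k:
            keep = rng_bal.choice(len(pos), size=k, replace=False)
            pos = [pos[i] for i in np.sort(keep)]
        if len(neg) > k:
            keep = rng_bal.choice(len(neg), size=k, replace=False)
            neg = [neg[i] for i in np.sort(keep)]
        instances = pos + neg
    return SimDataset(reference, tree, matrix, instances, truth)
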