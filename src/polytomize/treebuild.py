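"""Neighbor-joining, majority-rule consensus, and the ortholog jackknife.

The jackknife protocol builds replicate phylogenies from order-preserving
random subsamples of each genome's ortholog list: sample k% of orthologs
per genome (default 60%), compute a pairwise genome distance matrix, run
neighbor-joining, repeat R times (default 50), then summarize with a
majority-rule consensus tree carrying percentage supports.
"""

from __future__ import annotations

import math
import warnings
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Callable

import dendropy
import numpy as np

from .treemodel import DistanceMatrix, PhyloTree, TreeError

__all__ = [
    "OrthologTable",
    "JackknifeConfig",
    "neighbor_joining",
    "majority_consensus",
    "jackknife_trees",
    "builtin_distance",
]


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------


def neighbor_joining(D: DistanceMatrix, outgroup: str | None = None) -> PhyloTree:
    """Saitou-Nei neighbor joining with deterministic tie-breaking.

    Agglomeration ties (equal Q up to 1e-12 relative) are broken by the
    lexicographically smallest pair of cluster labels, where a cluster is
    labeled by its smallest member leaf.  Negative estimated branch lengths
    are clamped to zero.  The unrooted NJ tree is rooted on the outgroup's
    pendant edge when ``outgroup`` is given, else at the midpoint.
    """
    n = len(D)
    if n < 3:
        raise TreeError("neighbor joining needs at least 3 taxa")
    if outgroup is not None and outgroup not in D.labels:
        raise TreeError(f"outgroup {outgroup!r} not among matrix taxa")

    tns = dendropy.TaxonNamespace(list(D.labels))
    nodes: list[dendropy.Node] = []
    for lab in D.labels:
        node = dendropy.Node(taxon=tns.get_taxon(lab))
        nodes.append(node)
    tags = list(D.labels)  # tie-break label of each active cluster
    d = D.values.copy()
    active = list(range(n))

    while len(active) > 2:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        qmin = q.min()
        tol = 1e-12 * max(1.0, abs(qmin))
        cands = np.argwhere(q <= qmin + tol)
        best = None
        for ii, jj in cands:
            if ii >= jj:
                continue
            pair = tuple(sorted((tags[active[ii]], tags[active[jj]])))
            if best is None or pair < best[0]:
                best = (pair, int(ii), int(jj))
        _, i, j = best
        gi, gj = active[i], active[j]
        dij = sub[i, j]
        li = 0.5 * dij + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = dij - li
        li, lj = max(li, 0.0), max(lj, 0.0)
        parent = dendropy.Node()
        ci, cj = nodes[gi], nodes[gj]
        ci.edge.length = li
        cj.edge.length = lj
        parent.add_child(ci)
        parent.add_child(cj)
        # distances from the new cluster to the remaining ones
        new_row = np.zeros(d.shape[0])
        for k in active:
            if k in (gi, gj):
                continue
            new_row[k] = 0.5 * (d[gi, k] + d[gj, k] - dij)
        d[gi, :] = new_row
        d[:, gi] = new_row
        d[gi, gi] = 0.0
        nodes[gi] = parent
        tags[gi] = min(tags[gi], tags[gj])
        active.remove(gj)

    ga, gb = active
    root = dendropy.Node()
    half = 0.5 * d[ga, gb]
    nodes[ga].edge.length = half
    nodes[gb].edge.length = half
    root.add_child(nodes[ga])
    root.add_child(nodes[gb])
    tree = dendropy.Tree(seed_node=root, taxon_namespace=tns)
    tree.is_rooted = True

    if outgroup is not None:
        og = None
        for leaf in tree.leaf_node_iter():
            if leaf.taxon.label == outgroup:
                og = leaf
                break
        length = og.edge.length or 0.0
        tree.reroot_at_edge(og.edge, length1=length / 2.0, length2=length / 2.0)
    else:
        tree.reroot_at_midpoint()
    tree.seed_node.edge.length = None
    _suppress_root_unifurcation(tree)
    return PhyloTree(tree)


def _suppress_root_unifurcation(tree: dendropy.Tree) -> None:
    root = tree.seed_node
    while len(root.child_nodes()) == 1:
        child = root.child_nodes()[0]
        for grand in list(child.child_nodes()):
            child.remove_child(grand)
            root.add_child(grand)
        root.remove_child(child)


# ---------------------------------------------------------------------------
# Majority-rule consensus
# ---------------------------------------------------------------------------


def majority_consensus(trees: list[PhyloTree], threshold: float = 0.5) -> PhyloTree:
    """CONSENSE-style majority-rule consensus of rooted trees.

    Keeps exactly the clades present in strictly more than ``threshold`` of
    the input trees (``threshold`` in [0.5, 1)); supports are percentage
    occurrence, branch lengths the mean over the trees containing the clade.
    """
    if not trees:
        raise TreeError("no input trees")
    if not 0.5 <= threshold < 1.0:
        raise TreeError("consensus threshold must be in [0.5, 1)")
    leafset = frozenset(trees[0].leaf_labels())
    counts: Counter[frozenset] = Counter()
    lengths: defaultdict[frozenset, list[float]] = defaultdict(list)
    leaf_lengths: defaultdict[str, list[float]] = defaultdict(list)
    for tree in trees:
        if frozenset(tree.leaf_labels()) != leafset:
            raise TreeError("consensus input trees must share one leaf set")
        clades: dict[int, frozenset] = {}
        for node in tree.postorder():
            if node.is_leaf():
                lab = node.taxon.label if node.taxon else node.label
                clades[id(node)] = frozenset([lab])
                if node.edge.length is not None:
                    leaf_lengths[lab].append(node.edge.length)
                continue
            clade = frozenset().union(*(clades[id(c)] for c in node.child_nodes()))
            clades[id(node)] = clade
            if node.parent_node is not None:
                counts[clade] += 1
                if node.edge.length is not None:
                    lengths[clade].append(node.edge.length)
    R = len(trees)
    kept = [c for c, k in counts.items() if k / R > threshold and len(c) >= 2]
    kept.sort(key=lambda c: (-len(c), sorted(c)))

    tns = dendropy.TaxonNamespace(sorted(leafset))
    root = dendropy.Node()
    placed: list[tuple[frozenset, dendropy.Node]] = [(leafset, root)]
    for clade in kept:
        if clade == leafset:
            continue
        parent = min(
            (pc for pc in placed if clade < pc[0]), key=lambda pc: len(pc[0])
        )[1]
        node = dendropy.Node()
        node.edge.length = float(np.mean(lengths[clade])) if lengths[clade] else None
        node.support = 100.0 * counts[clade] / R
        parent.add_child(node)
        placed.append((clade, node))
    for lab in sorted(leafset):
        parent = min(
            (pc for pc in placed if lab in pc[0]), key=lambda pc: len(pc[0])
        )[1]
        leaf = dendropy.Node(taxon=tns.get_taxon(lab))
        if leaf_lengths[lab]:
            leaf.edge.length = float(np.mean(leaf_lengths[lab]))
        parent.add_child(leaf)
    tree = dendropy.Tree(seed_node=root, taxon_namespace=tns)
    tree.is_rooted = True
    return PhyloTree(tree)


# ---------------------------------------------------------------------------
# Ortholog tables and the jackknife protocol
# ---------------------------------------------------------------------------


@dataclass
class OrthologTable:
    """Ordered ortholog identifiers per genome (order = chromosome position)."""

    genomes: dict[str, list[str]]

    def __post_init__(self) -> None:
        for gid, orthologs in self.genomes.items():
            if len(set(orthologs)) != len(orthologs):
                raise ValueError(f"duplicate ortholog ids in genome {gid!r}")

    @classmethod
    def from_text(cls, text: str) -> "OrthologTable":
        genomes: dict[str, list[str]] = {}
        for line in text.strip().splitlines():
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.split()
            genomes[parts[0]] = parts[1:]
        return cls(genomes)

    def to_text(self) -> str:
        return (
            "\n".join(
                "\t".join([gid] + orthologs) for gid, orthologs in self.genomes.items()
            )
            + "\n"
        )


@dataclass
class JackknifeConfig:
    k: float = 60.0  # percentage of orthologs retained per replicate
    replicates: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.k < 100:
            raise ValueError("k must be a percentage in (0, 100)")
        if self.replicates < 1:
            raise ValueError("need at least 1 replicate")


def builtin_distance(g1: list[str], g2: list[str]) -> float:
    """Gene-content + breakpoint genome distance.

    0.5 * (1 - Jaccard similarity of ortholog content) plus 0.5 * the
    normalized breakpoint count between the two orderings restricted to
    shared orthologs.  A built-in stand-in for user-supplied genome
    distances; symmetric, zero for identical genomes, one for disjoint ones.
    """
    if not g1 or not g2:
        raise ValueError("empty ortholog list")
    s1, s2 = set(g1), set(g2)
    shared = s1 & s2
    if not shared:
        warnings.warn("no shared orthologs between genomes; distance set to 1")
        return 1.0
    jaccard = len(shared) / len(s1 | s2)
    content = 0.5 * (1.0 - jaccard)
    seq1 = [o for o in g1 if o in shared]
    seq2 = [o for o in g2 if o in shared]
    if len(shared) < 2:
        return content
    adj2 = {frozenset(p) for p in zip(seq2, seq2[1:])}
    breaks = sum(1 for p in zip(seq1, seq1[1:]) if frozenset(p) not in adj2)
    return content + 0.5 * breaks / (len(shared) - 1)


def distance_matrix_from_orthologs(
    genomes: dict[str, list[str]],
    distance_fn: Callable[[list[str], list[str]], float] = builtin_distance,
) -> DistanceMatrix:
    labels = sorted(genomes)
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = distance_fn(genomes[labels[i]], genomes[labels[j]])
    return DistanceMatrix(labels, d)


def jackknife_replicates(
    table: OrthologTable,
    cfg: JackknifeConfig,
    distance_fn: Callable[[list[str], list[str]], float] = builtin_distance,
    outgroup: str | None = None,
) -> list[tuple[PhyloTree, DistanceMatrix]]:
    """R (tree, distance matrix) replicate pairs from ortholog subsamples.

    Per replicate, each genome keeps ``floor(k% * m)`` of its m orthologs
    (sampled without replacement, original order preserved); the pairwise
    distance matrix is computed with ``distance_fn`` and fed to
    neighbor joining.
    """
    if len(table.genomes) < 3:
        raise TreeError("jackknife needs at least 3 genomes")
    for gid, orthologs in table.genomes.items():
        if math.floor(cfg.k / 100.0 * len(orthologs)) < 2:
            raise ValueError(
                f"genome {gid!r}: k={cfg.k}% retains fewer than 2 orthologs"
            )
    rng = np.random.default_rng(cfg.seed)
    out: list[tuple[PhyloTree, DistanceMatrix]] = []
    for _ in range(cfg.replicates):
        sub: dict[str, list[str]] = {}
        for gid in sorted(table.genomes):
            orthologs = table.genomes[gid]
            keep = math.floor(cfg.k / 100.0 * len(orthologs))
            idx = np.sort(rng.choice(len(orthologs), size=keep, replace=False))
            sub[gid] = [orthologs[i] for i in idx]
        D = distance_matrix_from_orthologs(sub, distance_fn)
        out.append((neighbor_joining(D, outgroup=outgroup), D))
    return out


def jackknife_trees(
    table: OrthologTable,
    cfg: JackknifeConfig,
    distance_fn: Callable[[list[str], list[str]], float] = builtin_distance,
    outgroup: str | None = None,
) -> list[PhyloTree]:
    """Replicate NJ trees only (see :func:`jackknife_replicates`)."""
    return [t for t, _ in jackknife_replicates(table, cfg, distance_fn, outgroup)]
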