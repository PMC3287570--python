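import numpy as np
import pytest

from polytomize.simdata import SimConfig, simulate_reference


def unrooted_splits(tree):
    """Map each non-trivial unrooted bipartition to its total edge length.

    The two root-child edges of a rooted tree belong to the same unrooted
    edge, so their lengths accumulate onto one split.
    """
    labs = frozenset(tree.leaf_labels())
    out = {}
    for node in tree.preorder():
        if node is tree.root:
            continue
        below = frozenset(
            (l.taxon.label if l.taxon else l.label) for l in node.leaf_iter()
        )
        side = min(below, labs - below, key=lambda s: (len(s), sorted(s)))
        out[side] = out.get(side, 0.0) + (node.edge.length or 0.0)
    return out


def random_binary_tree(n_leaves: int, seed: int):
    """A random strictly binary clock tree with positive branch lengths."""
    cfg = SimConfig(n_taxa=max(n_leaves, 4), polytomy_fraction=0.0, seed=seed)
    return simulate_reference(cfg, rng=np.random.default_rng(seed))


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)
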