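"""Independent brute-force oracles used by the test suite.

Everything here works from first principles on explicit root-to-leaf
paths, deliberately avoiding the package's own edge-table machinery, so
agreement between the two routes is meaningful.
"""

from __future__ import annotations

import itertools

import numpy as np

from phylodiv import PhyloTree, simulate_bd_tree


def random_tree(seed: int, n_min: int = 4, n_max: int = 10,
                ultrametric: bool = False) -> PhyloTree:
    """Small random tree; branch lengths jittered unless ultrametric."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(n_min, n_max + 1))
    tree = simulate_bd_tree(n, birth=1.0, death=0.2, seed=int(rng.integers(2**31)))
    if ultrametric:
        return tree
    dt = tree.dendropy_tree.clone(depth=1)
    for node in dt.preorder_node_iter():
        if node.parent_node is not None:
            node.edge.length *= float(rng.uniform(0.2, 2.0))
    return PhyloTree(dt)


def leaf_paths(tree: PhyloTree) -> dict[str, list]:
    """Root-to-leaf edge lists (edge = id(node) whose parent edge it is)."""
    paths = {}
    for leaf in tree.dendropy_tree.leaf_node_iter():
        path = []
        node = leaf
        while node.parent_node is not None:
            path.append(node)
            node = node.parent_node
        paths[leaf.taxon.label] = path
    return paths


def patristic_oracle(tree: PhyloTree, a: str, b: str) -> float:
    """Path-sum distance: shared root prefix subtracted from both paths."""
    paths = leaf_paths(tree)
    pa, pb = set(paths[a]), set(paths[b])
    return sum(n.edge.length for n in pa ^ pb)


def pd_oracle(tree: PhyloTree, taxa, rooted: bool = True) -> float:
    """Faith's PD as the union of root-to-leaf paths (minus the shared
    prefix of all paths for the unrooted variant)."""
    paths = leaf_paths(tree)
    union = set().union(*(paths[t] for t in taxa))
    if not rooted:
        shared = set.intersection(*(set(paths[t]) for t in taxa))
        union -= shared
    return sum(n.edge.length for n in union)


def mpd_oracle(tree: PhyloTree, taxa) -> float:
    taxa = sorted(taxa)
    ds = [patristic_oracle(tree, a, b)
          for a, b in itertools.combinations(taxa, 2)]
    return float(np.mean(ds))


def mntd_oracle(tree: PhyloTree, taxa) -> float:
    taxa = sorted(taxa)
    vals = []
    for a in taxa:
        vals.append(min(patristic_oracle(tree, a, b) for b in taxa if b != a))
    return float(np.mean(vals))


def dpw_oracle(tree: PhyloTree, site_a, site_b) -> float:
    return float(np.mean([
        patristic_oracle(tree, a, b) if a != b else 0.0
        for a in site_a for b in site_b
    ]))


def dnn_oracle(tree: PhyloTree, site_a, site_b) -> float:
    def directed(src, dst):
        return np.mean([
            min((patristic_oracle(tree, a, b) if a != b else 0.0) for b in dst)
            for a in src
        ])
    return float(0.5 * (directed(site_a, site_b) + directed(site_b, site_a)))


def unifrac_oracle(tree: PhyloTree, site_a, site_b) -> float:
    """Unique / union branch length over rooted path-union edge sets."""
    paths = leaf_paths(tree)
    ea = set().union(*(paths[t] for t in site_a))
    eb = set().union(*(paths[t] for t in site_b))
    union = sum(n.edge.length for n in ea | eb)
    unique = sum(n.edge.length for n in ea ^ eb)
    return unique / union if union else 0.0
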