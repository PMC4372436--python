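"""Between-site dissimilarity: Dpw, Dnn, unweighted UniFrac, Bray-Curtis.

All functions return a scikit-bio :class:`~skbio.DistanceMatrix` over site
IDs (symmetric, zero diagonal).  Conventions:

* Dpw(A, B) averages patristic distance over ALL cross pairs i in A, j in
  B -- taxa shared by both sites contribute zero-distance pairs, matching
  the ``comdist`` convention.
* Dnn(A, B) symmetrizes mean nearest-neighbour distance by averaging the
  two directed means; shared taxa give zero minima.
* UniFrac is the unweighted, presence/absence form on ROOTED spanning
  sets (each community's spanning subtree includes its root path, the
  same convention as Faith's PD here): unique branch length over union
  branch length, in [0, 1].
* Bray-Curtis in binary mode is the Sorensen complement
  1 - 2|A∩B| / (|A|+|B|); in count mode sum|x-y| / sum(x+y).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from skbio import DistanceMatrix

from .community import CommunityMatrix
from .tree import PhyloTree

logger = logging.getLogger(__name__)

__all__ = ["dpw", "dnn", "unifrac", "bray_curtis"]


def _drop_empty(cm: CommunityMatrix) -> CommunityMatrix:
    """Exclude taxa-less sites (their dissimilarities are undefined)."""
    pres = cm.presence()
    empty = [s for s, any_ in pres.any(axis=1).items() if not any_]
    if empty:
        logger.warning("dropping empty sites from dissimilarity: %s",
                       ", ".join(map(str, empty)))
        return CommunityMatrix(cm.table.drop(index=empty))
    return cm


def _site_index_lists(dist: DistanceMatrix, cm: CommunityMatrix) -> list[np.ndarray]:
    pos = {t: i for i, t in enumerate(dist.ids)}
    missing = sorted(set(cm.taxa) - set(pos))
    if missing:
        raise KeyError(f"community taxa missing from distance matrix: {missing}")
    pres = cm.presence().to_numpy()
    cols = np.array([pos[t] for t in cm.taxa])
    return [cols[row] for row in pres]


def dpw(dist: DistanceMatrix, cm: CommunityMatrix) -> DistanceMatrix:
    """Mean pairwise phylogenetic distance between communities (Dpw)."""
    cm = _drop_empty(cm)
    sites = cm.sites
    idx = _site_index_lists(dist, cm)
    n = len(sites)
    out = np.zeros((n, n))
    d = dist.data
    for a in range(n):
        for b in range(a + 1, n):
            ia, ib = idx[a], idx[b]
            out[a, b] = out[b, a] = d[np.ix_(ia, ib)].mean()
    return DistanceMatrix(out, ids=sites)


def dnn(dist: DistanceMatrix, cm: CommunityMatrix) -> DistanceMatrix:
    """Symmetrized mean nearest phylogenetic neighbour distance (Dnn)."""
    cm = _drop_empty(cm)
    sites = cm.sites
    idx = _site_index_lists(dist, cm)
    n = len(sites)
    out = np.zeros((n, n))
    d = dist.data
    for a in range(n):
        for b in range(a + 1, n):
            ia, ib = idx[a], idx[b]
            cross = d[np.ix_(ia, ib)]
            out[a, b] = out[b, a] = 0.5 * (
                cross.min(axis=1).mean() + cross.min(axis=0).mean()
            )
    return DistanceMatrix(out, ids=sites)


def unifrac(tree: PhyloTree, cm: CommunityMatrix) -> DistanceMatrix:
    """Unweighted UniFrac between all site pairs.

    For sites A, B with rooted spanning edge sets E_A, E_B:
    U = len(E_A xor E_B) / len(E_A or E_B), lengths branch-length
    weighted.  U = 0 iff the spanning sets coincide; U = 1 iff they share
    no branch.  Sites with no taxa are dropped (undefined).
    """
    cm = _drop_empty(cm)
    sites = cm.sites
    lengths, membership = tree.edge_table()
    pos = {t: i for i, t in enumerate(tree.leaf_labels)}
    missing = sorted(set(cm.taxa) - set(pos))
    if missing:
        raise KeyError(f"community taxa missing from tree: {missing}")
    pres = cm.presence().to_numpy()
    cols = np.array([pos[t] for t in cm.taxa])

    # edge x site: does the site's spanning set (rooted) include the edge?
    edge_in_site = np.zeros((len(lengths), len(sites)), dtype=bool)
    for s, row in enumerate(pres):
        edge_in_site[:, s] = membership[:, cols[row]].any(axis=1)

    n = len(sites)
    out = np.zeros((n, n))
    for a in range(n):
        for b in range(a + 1, n):
            ea, eb = edge_in_site[:, a], edge_in_site[:, b]
            union = float(lengths[ea | eb].sum())
            unique = float(lengths[ea ^ eb].sum())
            out[a, b] = out[b, a] = unique / union if union > 0 else 0.0
    return DistanceMatrix(out, ids=sites)


def bray_curtis(table: pd.DataFrame, binary: bool = False) -> DistanceMatrix:
    """Bray-Curtis dissimilarity between the rows of a site x feature table.

    binary=True reduces values to presence/absence first, giving the
    Sorensen complement; binary=False uses the counts as given (the mode
    used for family composition).
    """
    x = table.to_numpy(dtype=float)
    if (x < 0).any():
        raise ValueError("Bray-Curtis requires non-negative values")
    if binary:
        x = (x > 0).astype(float)
    n = x.shape[0]
    out = np.zeros((n, n))
    for a in range(n):
        for b in range(a + 1, n):
            denom = (x[a] + x[b]).sum()
            if denom == 0:
                raise ValueError("Bray-Curtis undefined for two all-zero rows")
            out[a, b] = out[b, a] = np.abs(x[a] - x[b]).sum() / denom
    return DistanceMatrix(out, ids=[str(i) for i in table.index])
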