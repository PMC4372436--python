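"""Alpha phylodiversity: Faith's PD, MPD, MNTD, and randomization SES.

Faith's PD is the summed branch length of the minimal subtree spanning a
taxon set; by default the subtree is anchored at the tree root ("rooted
PD", the convention of the community-phylogenetics software lineage this
package follows), so even a single taxon carries the PD of its root path.
MPD is the mean pairwise patristic distance within a community, MNTD the
mean distance from each member to its nearest co-occurring relative.

NRI and NTI are standardized effect sizes of MPD and MNTD against the
"sample.pool" null: null communities are uniform random subsets, of the
same richness as the observed site, drawn from the pool of taxa occurring
anywhere in the community matrix.  Sign convention: the z-scores are
reported raw, so POSITIVE values mean phylogenetic evenness (taxa more
distant than chance) and NEGATIVE values mean clustering.  Note this is
inverted relative to the common convention of negating the z-score --
callers comparing against other software should negate accordingly.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from skbio import DistanceMatrix

from .community import CommunityMatrix, TaxonomyMap, family_rollup, richness
from .tree import PhyloTree

__all__ = [
    "SESResult",
    "AlphaDiversityRecord",
    "faith_pd",
    "mpd",
    "mntd",
    "ses",
    "alpha_table",
    "derive_seed",
]


def derive_seed(master_seed: int, *parts: str) -> int:
    """Stable per-stream seed < 2^31 from a master seed and string parts.

    Hash-derived so that adding a site never perturbs another site's
    random stream.
    """
    digest = hashlib.sha256(
        ("|".join([str(master_seed), *parts])).encode()
    ).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass(frozen=True)
class SESResult:
    """Standardized effect size of a metric against a randomization null."""

    metric: str
    observed: float
    null_mean: float
    null_sd: float
    z: float | None          # None when the null is degenerate (sd == 0)
    p_rank: float            # two-tailed rank p, in [1/(n_rand+1), 1]
    n_rand: int
    seed: int
    degenerate: bool = False


@dataclass(frozen=True)
class AlphaDiversityRecord:
    site: str
    sr: int
    fam: int | None
    pd: float
    mpd: float | None
    mntd: float | None
    nri: float | None
    nri_p: float | None
    nti: float | None
    nti_p: float | None


def _taxon_indices(ids: Sequence[str], taxa: Iterable[str]) -> np.ndarray:
    pos = {t: i for i, t in enumerate(ids)}
    missing = sorted(set(taxa) - set(pos))
    if missing:
        raise KeyError(f"unknown taxa: {missing}")
    return np.array(sorted(pos[t] for t in set(taxa)), dtype=int)


def faith_pd(tree: PhyloTree, taxa: Iterable[str], rooted: bool = True) -> float:
    """Faith's phylogenetic diversity of a taxon set.

    rooted=True (default) includes the path to the tree root, so
    PD({single taxon}) is that taxon's root-to-tip depth and PD of the
    full leaf set equals the total branch length.  rooted=False sums only
    the minimal subtree connecting the taxa themselves.
    """
    taxa = set(taxa)
    if not taxa:
        raise ValueError("faith_pd of an empty taxon set")
    idx = _taxon_indices(tree.leaf_labels, taxa)
    lengths, membership = tree.edge_table()
    inside = membership[:, idx].any(axis=1)
    if rooted:
        keep = inside
    else:
        n_in = membership[:, idx].sum(axis=1)
        keep = inside & (n_in < len(idx))
    return float(lengths[keep].sum())


def mpd(dist: DistanceMatrix, taxa: Iterable[str]) -> float | None:
    """Mean pairwise distance over all unordered pairs within ``taxa``.

    Returns None (with no error) for fewer than two taxa, where the mean
    over pairs is undefined.
    """
    idx = _taxon_indices(dist.ids, taxa)
    k = len(idx)
    if k < 2:
        return None
    sub = dist.data[np.ix_(idx, idx)]
    return float(sub.sum() / (k * (k - 1)))


def mntd(dist: DistanceMatrix, taxa: Iterable[str]) -> float | None:
    """Mean distance from each taxon to its nearest other member."""
    idx = _taxon_indices(dist.ids, taxa)
    k = len(idx)
    if k < 2:
        return None
    sub = dist.data[np.ix_(idx, idx)].copy()
    np.fill_diagonal(sub, np.inf)
    return float(sub.min(axis=1).mean())


def _null_metric_batch(
    d: np.ndarray, idx: np.ndarray, metric: str
) -> np.ndarray:
    """Metric values for a batch of communities given as index rows."""
    sub = d[idx[:, :, None], idx[:, None, :]]
    k = idx.shape[1]
    if metric == "MPD":
        return sub.sum(axis=(1, 2)) / (k * (k - 1))
    eye = np.eye(k, dtype=bool)
    sub = np.where(eye[None, :, :], np.inf, sub)
    return sub.min(axis=2).mean(axis=1)


def _rank_p_two_tailed(observed: float, null: np.ndarray) -> float:
    """Two-tailed p from the 1-based mid-rank of observed among observed+null."""
    n = len(null)
    n_less = int((null < observed).sum())
    n_equal = int((null == observed).sum())
    r = n_less + (n_equal + 2) / 2.0  # mid-rank among ties, incl. observed
    p = 2.0 * min(r, n + 1 - r) / (n + 1)
    return float(min(max(p, 1.0 / (n + 1)), 1.0))


def ses(
    metric: str,
    dist: DistanceMatrix,
    taxa: Iterable[str],
    pool: Sequence[str],
    n_rand: int = 999,
    seed: int = 0,
    _chunk_elems: int = 20_000_000,
) -> SESResult:
    """Standardized effect size of MPD or MNTD under the sample.pool null.

    Null communities are drawn uniformly without replacement from ``pool``
    at the observed site's richness, independently per randomization.
    z = (observed - null mean) / null sd (sd over the null draws, ddof=1);
    p is the two-tailed rank p of the observed value among observed+null.
    A site equal to the whole pool makes every null draw identical: the
    result is flagged degenerate with z = None.
    """
    metric = metric.upper()
    if metric not in ("MPD", "MNTD"):
        raise ValueError(f"metric must be MPD or MNTD, got {metric!r}")
    taxa = set(taxa)
    if len(taxa) < 2:
        raise ValueError("SES needs site richness >= 2")
    missing = sorted(taxa - set(pool))
    if missing:
        raise ValueError(f"site taxa outside the pool: {missing}")

    obs_fn = mpd if metric == "MPD" else mntd
    observed = obs_fn(dist, taxa)
    assert observed is not None

    pool_idx = _taxon_indices(dist.ids, pool)
    d = dist.data
    k = len(taxa)
    p = len(pool_idx)
    rng = np.random.default_rng(seed)

    null = np.empty(n_rand)
    done = 0
    rows_per_chunk = max(1, _chunk_elems // (k * k))
    while done < n_rand:
        m = min(rows_per_chunk, n_rand - done)
        # random k-subsets of the pool, one per row
        draw = np.argsort(rng.random((m, p)), axis=1)[:, :k]
        null[done : done + m] = _null_metric_batch(d, pool_idx[draw], metric)
        done += m

    null_mean = float(null.mean())
    null_sd = float(null.std(ddof=1))
    degenerate = null_sd == 0.0 or k == p
    z = None if degenerate else (observed - null_mean) / null_sd
    return SESResult(
        metric=metric,
        observed=float(observed),
        null_mean=null_mean,
        null_sd=null_sd,
        z=z,
        p_rank=_rank_p_two_tailed(observed, null),
        n_rand=n_rand,
        seed=seed,
        degenerate=degenerate,
    )


def alpha_table(
    tree: PhyloTree,
    cm: CommunityMatrix,
    tax: TaxonomyMap | None = None,
    n_rand: int = 999,
    seed: int = 0,
    pool: Sequence[str] | None = None,
) -> list[AlphaDiversityRecord]:
    """Per-site diversity records plus the pooled "Total" record.

    Per site: SR, Fam (when a taxonomy is supplied), rooted PD, MPD, MNTD,
    and NRI/NTI (z of MPD/MNTD under the sample.pool null; positive =
    evenness) with two-tailed rank p-values.  Sites of richness < 2 get
    missing MPD/MNTD/SES fields.  The Total record pools all taxa: its PD
    and MPD describe the whole species pool; NRI/NTI are blank.
    """
    dist = tree.patristic_distances()
    sr = richness(cm)
    fam = None
    if tax is not None:
        fam, _ = family_rollup(cm, tax)
    if pool is None:
        pool = cm.pool()

    records: list[AlphaDiversityRecord] = []
    for site in cm.sites:
        taxa = cm.site_taxa(site)
        if not taxa:
            records.append(
                AlphaDiversityRecord(site, 0, 0 if fam is not None else None,
                                     0.0, None, None, None, None, None, None)
            )
            continue
        pd_val = faith_pd(tree, taxa)
        site_mpd = mpd(dist, taxa)
        site_mntd = mntd(dist, taxa)
        nri = nri_p = nti = nti_p = None
        if len(taxa) >= 2:
            site_seed = derive_seed(seed, "ses", site)
            r_mpd = ses("MPD", dist, taxa, pool, n_rand=n_rand, seed=site_seed)
            r_mntd = ses("MNTD", dist, taxa, pool, n_rand=n_rand,
                         seed=derive_seed(seed, "ses-mntd", site))
            nri, nri_p = r_mpd.z, r_mpd.p_rank
            nti, nti_p = r_mntd.z, r_mntd.p_rank
        records.append(
            AlphaDiversityRecord(
                site=site,
                sr=int(sr[site]),
                fam=int(fam[site]) if fam is not None else None,
                pd=pd_val,
                mpd=site_mpd,
                mntd=site_mntd,
                nri=nri,
                nri_p=nri_p,
                nti=nti,
                nti_p=nti_p,
            )
        )

    pool_set = set(pool)
    total_fam = None
    if tax is not None:
        total_fam = len({tax.family_of(t) for t in pool_set})
    records.append(
        AlphaDiversityRecord(
            site="Total",
            sr=len(pool_set),
            fam=total_fam,
            pd=faith_pd(tree, pool_set),
            mpd=mpd(dist, pool_set),
            mntd=mntd(dist, pool_set),
            nri=None, nri_p=None, nti=None, nti_p=None,
        )
    )
    return records


def records_to_frame(records: list[AlphaDiversityRecord]) -> pd.DataFrame:
    """Tabular (Table 1-style) view of alpha diversity records."""
    df = pd.DataFrame([r.__dict__ for r in records]).set_index("site")
    return df
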