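"""Rank statistics for the assessment: Spearman, Bonferroni, Mantel, OLS.

The Mantel variant here follows RELATE semantics: the statistic is the
Spearman correlation of the two matrices' corresponding upper-triangle
entries, and the null is built by jointly permuting the row/column IDs of
the second matrix; the test is one-tailed for positive association.  When
the site count is small enough that every permutation fits within the
requested ``n_perm`` (n! <= n_perm), the null is enumerated exhaustively
instead of sampled, giving an exact p.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats as sps
from skbio import DistanceMatrix

__all__ = [
    "MantelResult",
    "RegressionResult",
    "spearman",
    "bonferroni",
    "mantel_relate",
    "loglog_pd_sr",
    "correlation_suite",
]


@lru_cache(maxsize=4)
def _all_permutations(n: int) -> np.ndarray:
    """All n! permutations of range(n) as an (n!, n) index array."""
    return np.array(list(itertools.permutations(range(n))), dtype=np.int64)


@dataclass(frozen=True)
class MantelResult:
    rho: float
    p: float
    n_perm: int      # permutations actually used (n!-1 when exhaustive)
    seed: int
    exhaustive: bool = False


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r2: float
    n: int


def spearman(
    x, y, exact_max_n: int = 9
) -> tuple[float | None, float | None, int]:
    """Spearman rank correlation on pairwise-complete observations.

    Returns (rho, p, n_complete).  Ties get average ranks; p is two-tailed
    via the t approximation, or by exhaustive permutation of y for
    n <= ``exact_max_n``.  A constant vector leaves rho undefined (None).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = len(x)
    if n < 4:
        raise ValueError(f"need >= 4 complete pairs, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return None, None, n

    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])

    if n <= exact_max_n:
        # exact two-sided permutation null over all n! orderings of y
        rx_c = rx - rx.mean()
        ry_c = ry - ry.mean()
        scale = np.sqrt((rx_c**2).sum()) * np.sqrt((ry_c**2).sum())
        null = (ry_c[_all_permutations(n)] @ rx_c) / scale
        p = float((np.abs(null) >= abs(rho) - 1e-12).mean())
    else:
        t = rho * math.sqrt((n - 2) / max(1e-300, 1.0 - rho**2))
        p = float(2 * sps.t.sf(abs(t), df=n - 2))
    return rho, float(min(p, 1.0)), n


def bonferroni(pvals, m: int | None = None) -> np.ndarray:
    """Bonferroni adjustment: p_adj = min(1, m * p)."""
    p = np.asarray(pvals, dtype=float)
    if m is None:
        m = p.size
    return np.minimum(1.0, m * p)


def _triangle(d: DistanceMatrix) -> np.ndarray:
    i, j = np.triu_indices(d.shape[0], k=1)
    return d.data[i, j]


def mantel_relate(
    d1: DistanceMatrix,
    d2: DistanceMatrix,
    n_perm: int = 999,
    seed: int = 0,
) -> MantelResult:
    """RELATE-style Mantel test between two distance matrices.

    rho is the Spearman correlation of corresponding upper-triangle
    entries; the null permutes d2's IDs (rows and columns jointly);
    one-tailed p for positive association:
    p = (count of null rho >= observed + 1) / (n_perm + 1), or the exact
    enumeration fraction when n! <= n_perm.
    """
    ids1, ids2 = set(d1.ids), set(d2.ids)
    if ids1 != ids2:
        raise ValueError(
            f"ID mismatch: only in first {sorted(ids1 - ids2)}, "
            f"only in second {sorted(ids2 - ids1)}"
        )
    n = d1.shape[0]
    if n < 4:
        raise ValueError(f"Mantel needs >= 4 sites, got {n}")
    # align d2 to d1's ID order
    order = [list(d2.ids).index(i) for i in d1.ids]
    m1 = d1.data
    m2 = d2.data[np.ix_(order, order)]

    iu = np.triu_indices(n, k=1)
    r1 = sps.rankdata(m1[iu])

    def rho_of(mat: np.ndarray) -> float:
        r2 = sps.rankdata(mat[iu])
        return float(np.corrcoef(r1, r2)[0, 1])

    observed = rho_of(m2)

    if math.factorial(n) <= n_perm:
        count = 0
        total = 0
        for perm in itertools.permutations(range(n)):
            r = rho_of(m2[np.ix_(perm, perm)])
            if r >= observed - 1e-12:
                count += 1
            total += 1
        # identity permutation is the observed labelling itself
        return MantelResult(
            rho=observed, p=count / total, n_perm=total - 1, seed=seed,
            exhaustive=True,
        )

    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        if rho_of(m2[np.ix_(perm, perm)]) >= observed - 1e-12:
            count += 1
    return MantelResult(
        rho=observed, p=(count + 1) / (n_perm + 1), n_perm=n_perm, seed=seed
    )


def loglog_pd_sr(records) -> RegressionResult:
    """OLS of log10(PD) on log10(SR) across sites.

    ``records`` is an iterable of objects or mapping rows with ``sr`` and
    ``pd`` fields (Total/pooled rows should be excluded by the caller).
    All SR and PD must be positive.
    """
    rows = []
    for r in records:
        if isinstance(r, dict):
            rows.append((r["sr"], r["pd"]))
        else:
            rows.append((r.sr, r.pd))
    sr = np.array([a for a, _ in rows], dtype=float)
    pd_ = np.array([b for _, b in rows], dtype=float)
    if (sr <= 0).any() or (pd_ <= 0).any():
        raise ValueError("log-log regression requires SR > 0 and PD > 0")
    res = sps.linregress(np.log10(sr), np.log10(pd_))
    return RegressionResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r2=float(res.rvalue**2),
        n=len(sr),
    )


DIVERSITY_FIELDS = ["sr", "pd", "fam", "mpd", "mntd"]
ATTRIBUTE_FIELDS = [
    "area_ha", "pre_rf_ha", "rem_rf_ha", "pct_rem_rf", "rem_rf_pct_sub",
    "pre_rf_pct_sub", "re_count", "pct_pa", "pct_pa_and_f",
]


def correlation_suite(
    alpha_frame: pd.DataFrame,
    attrs: pd.DataFrame,
    exclude: set[str] = frozenset(),
    diversity_fields=DIVERSITY_FIELDS,
    attribute_fields=ATTRIBUTE_FIELDS,
) -> pd.DataFrame:
    """Spearman correlations of diversity metrics against site attributes.

    Computed on the full site set and again with ``exclude`` dropped (the
    depauperate-subregion sensitivity re-analysis); missing values are
    dropped pairwise and the Bonferroni factor is the number of tests in
    each subset.  Returns columns pair_x, pair_y, subset, n, rho, p, p_adj.
    """
    sites = [s for s in alpha_frame.index if s != "Total" and s in attrs.index]
    merged = alpha_frame.loc[sites, [c for c in diversity_fields
                                     if c in alpha_frame.columns]].join(
        attrs.loc[sites, [c for c in attribute_fields if c in attrs.columns]]
    )
    subsets = {"all": sites}
    kept = [s for s in sites if s not in exclude]
    if exclude:
        subsets["excluded"] = kept

    rows = []
    for name, subset in subsets.items():
        sub = merged.loc[subset]
        cells = []
        for dv in diversity_fields:
            for at in attribute_fields:
                if dv not in sub.columns or at not in sub.columns:
                    continue
                try:
                    rho, p, n = spearman(sub[dv], sub[at])
                except ValueError:
                    rho, p, n = None, None, int(
                        (sub[dv].notna() & sub[at].notna()).sum()
                    )
                cells.append([dv, at, name, n, rho, p])
        m = len(cells)
        for dv, at, sname, n, rho, p in cells:
            p_adj = None if p is None else float(min(1.0, m * p))
            rows.append(
                {"pair_x": dv, "pair_y": at, "subset": sname, "n": n,
                 "rho": rho, "p": p, "p_adj": p_adj}
            )
    return pd.DataFrame(rows)
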