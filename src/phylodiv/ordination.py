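"""Non-metric multidimensional scaling (NMDS) with Kruskal stress-1.

NMDS embeds sites in k dimensions so that the RANK order of configuration
distances matches the rank order of the input dissimilarities; the actual
dissimilarity values matter only through their ranks, which is what makes
the method appropriate for Bray-Curtis/UniFrac-type measures.  The loop
alternates

1. monotone (isotonic) regression of configuration distances on the
   dissimilarity ranks, pool-adjacent-violators with tied blocks averaged,
   giving fitted disparities d-hat; and
2. a Guttman-transform (majorization) update of the coordinates toward
   the disparities,

minimising Kruskal stress-1 = sqrt( sum (d - d_hat)^2 / sum d^2 ) over the
upper triangle.  The best of ``n_starts`` random initial configurations is
returned, centered, rotated to principal axes, and with each axis's sign
fixed so the first site's coordinate is non-negative -- orientation is
arbitrary in NMDS, so a deterministic convention is imposed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import isotonic_regression
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix

__all__ = ["NMDSResult", "nmds"]


@dataclass
class NMDSResult:
    """Best-of-starts NMDS configuration and its Kruskal stress-1."""

    ids: list[str]
    coordinates: np.ndarray  # (n_sites, k), centered, principal axes
    stress: float
    k: int
    n_starts: int
    best_start_seed: int
    converged: bool

    def as_frame(self):
        import pandas as pd

        return pd.DataFrame(
            self.coordinates,
            index=self.ids,
            columns=[f"axis{i + 1}" for i in range(self.k)],
        )


def _stress_and_disparities(
    dvec: np.ndarray, order: np.ndarray
) -> tuple[float, np.ndarray]:
    """Kruskal stress-1 and PAVA disparities for configuration distances."""
    fitted = np.empty_like(dvec)
    fitted[order] = isotonic_regression(dvec[order]).x
    denom = float((dvec**2).sum())
    if denom == 0:
        return 0.0, fitted
    return float(np.sqrt(((dvec - fitted) ** 2).sum() / denom)), fitted


def _single_run(
    delta: np.ndarray, k: int, seed: int, max_iter: int, tol: float
) -> tuple[np.ndarray, float, bool]:
    n = delta.shape[0]
    rng = np.random.default_rng(seed)
    dvec_in = squareform(delta, checks=False)

    x = rng.standard_normal((n, k))
    stress_prev = np.inf
    converged = False
    stress = np.inf
    for _ in range(max_iter):
        d = pdist(x)
        d[d == 0] = 1e-12
        # Kruskal's primary tie treatment: within tied dissimilarity
        # blocks, order by current configuration distance so ties do not
        # constrain each other; PAVA then averages only true violations
        order = np.lexsort((d, dvec_in))
        stress, disp = _stress_and_disparities(d, order)
        if stress_prev - stress < tol:
            converged = True
            break
        stress_prev = stress
        # Guttman transform toward the disparities
        ratio = squareform(disp / d, checks=False)
        b = -ratio
        np.fill_diagonal(b, ratio.sum(axis=1))
        x = b @ x / n
        x -= x.mean(axis=0)
    return x, stress, converged


def nmds(
    d: DistanceMatrix,
    k: int = 2,
    n_starts: int = 20,
    max_iter: int = 500,
    tol: float = 1e-6,
    seed: int = 0,
) -> NMDSResult:
    """Non-metric MDS of a distance matrix into k dimensions.

    Runs ``n_starts`` seeded random starts and keeps the minimum-stress
    configuration.  Degenerate all-equal inputs yield stress 0 with an
    arbitrary configuration (any layout preserves the single rank block).
    """
    n = d.shape[0]
    if n < k + 2:
        raise ValueError(f"NMDS needs at least k+2={k + 2} sites, got {n}")
    delta = d.data

    best: tuple[np.ndarray, float, bool] | None = None
    best_seed = -1
    for s in range(n_starts):
        start_seed = (seed * 100_003 + s) % (2**31)
        x, stress, conv = _single_run(delta, k, start_seed, max_iter, tol)
        if best is None or stress < best[1] - 1e-15:
            best = (x, stress, conv)
            best_seed = start_seed
    assert best is not None
    x, stress, conv = best

    # canonical orientation: centered, principal axes, fixed reflections
    x = x - x.mean(axis=0)
    _, _, vt = np.linalg.svd(x, full_matrices=False)
    x = x @ vt.T
    for j in range(x.shape[1]):
        pivot = np.flatnonzero(np.abs(x[:, j]) > 1e-12)
        if len(pivot) and x[pivot[0], j] < 0:
            x[:, j] = -x[:, j]

    return NMDSResult(
        ids=[str(i) for i in d.ids],
        coordinates=x,
        stress=stress,
        k=k,
        n_starts=n_starts,
        best_start_seed=best_seed,
        converged=conv,
    )
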