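"""Ordination and matrix-correlation analysis of population distances.

Nonmetric multidimensional scaling (Kruskal stress-1, best of several
seeded random starts) places populations in the plane so that the rank
order of their genetic distances is preserved as well as possible; a
Mantel test measures the correlation between genetic and geographic
distance matrices with significance from joint row/column permutations
(one-tailed for positive association, i.e. isolation by distance).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats
from sklearn.manifold import MDS

from .amova import DistanceMatrix

__all__ = ["MdsResult", "MantelResult", "nmds", "mantel"]


@dataclass
class MdsResult:
    populations: list[str]
    coordinates: np.ndarray  # (n, n_components), centroid at the origin
    stress: float            # Kruskal stress-1
    n_starts: int
    seed: int
    excluded: list[str] = field(default_factory=list)


@dataclass
class MantelResult:
    r: float
    p: float
    n_perm: int
    seed: int
    n: int


def nmds(d: DistanceMatrix, n_starts: int = 16, seed: int = 0,
         exclude: Sequence[str] = (), n_components: int = 2,
         max_iter: int = 500) -> MdsResult:
    """Nonmetric MDS of a distance matrix, minimising Kruskal stress-1.

    Listed outlier populations are removed before fitting (mirroring the
    usual practice of re-running an ordination without an inspected
    outlier).  The best of ``n_starts`` seeded random initialisations is
    returned; output coordinates are centred on the origin.
    """
    dm = d.exclude(exclude) if exclude else d
    n = len(dm.populations)
    if n < 3:
        raise ValueError("need at least 3 populations after exclusions")
    if np.allclose(dm.values, 0.0):
        raise ValueError("all-zero distance matrix cannot be ordinated")
    import inspect
    params = inspect.signature(MDS.__init__).parameters
    if "metric_mds" in params:
        kw = {"metric": "precomputed", "metric_mds": False}
    else:  # older scikit-learn API
        kw = {"dissimilarity": "precomputed", "metric": False}
    if "init" in params:
        kw["init"] = "random"  # seeded random starts, best-of-n_init
    est = MDS(n_components=n_components, n_init=n_starts, random_state=seed,
              max_iter=max_iter, eps=1e-9, normalized_stress=True, **kw)
    coords = est.fit_transform(dm.values)
    coords = coords - coords.mean(axis=0, keepdims=True)
    return MdsResult(list(dm.populations), coords, float(est.stress_),
                     n_starts, seed, list(exclude))


def mantel(d1: DistanceMatrix, d2: DistanceMatrix, n_perm: int = 1000,
           seed: int = 0) -> MantelResult:
    """Mantel correlation between two distance matrices.

    r is the Pearson correlation of the off-diagonal upper triangles; the
    permutation null jointly permutes rows and columns of the second matrix,
    and p is one-tailed for positive association,
    ``(#{r_perm >= r_obs} + 1)/(n_perm + 1)``.
    """
    if d1.populations != d2.populations:
        raise ValueError("matrices must be over the same populations in the same order")
    n = len(d1.populations)
    if n < 4:
        raise ValueError("need at least 4 populations")
    iu = np.triu_indices(n, k=1)
    x = d1.values[iu]
    y = d2.values[iu]
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("a matrix is constant off-diagonal; Mantel r is undefined")
    r_obs = float(stats.pearsonr(x, y).statistic)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        yp = d2.values[np.ix_(perm, perm)][iu]
        if np.ptp(yp) == 0:
            continue
        r_perm = float(stats.pearsonr(x, yp).statistic)
        if r_perm >= r_obs - 1e-12:
            count += 1
    return MantelResult(r=r_obs, p=(count + 1) / (n_perm + 1), n_perm=n_perm,
                        seed=seed, n=n)
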