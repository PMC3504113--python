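"""Marker-ascertainment experiments on STR locus pools.

Forensic STR panels are chosen to be maximally discriminating — i.e. for
high heterozygosity in a reference panel.  This module reproduces that
choice on a locus pool and quantifies its population-genetic consequences:
panels ascertained for high He tend to show (i) higher mean He, (ii) lower
variance of He across populations (every population sits near the diversity
ceiling) and therefore (iii) depressed multi-locus R_ST relative to
randomly chosen panels of the same size.

Panels are ranked either by the unweighted mean of per-population-sample He
(:func:`select_panel`) or by pooled-copies He in a reference panel of
populations (forensic-style, via
:func:`strpopgen.synthetic_data.build_ascertainment_pool`); the experiment
driver uses the pooled ranking.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .str_io import FrequencyTable, GenotypeTable
from .diversity import diversity_table

__all__ = [
    "LocusPanel",
    "DatasetComparison",
    "select_panel",
    "he_variance_profile",
    "levene_test",
    "ascertainment_experiment",
    "ascertainment_experiment_counts",
]


@dataclass
class LocusPanel:
    loci: list[str]
    criterion: str  # "highest" | "lowest" | "random" | "listed"
    k: int
    seed: int | None = None

    def __post_init__(self) -> None:
        if len(self.loci) != self.k:
            raise ValueError("panel size does not match k")
        if len(set(self.loci)) != self.k:
            raise ValueError("panel loci must be unique")


def mean_he_per_locus(d: FrequencyTable | GenotypeTable) -> pd.Series:
    """Unweighted mean over population samples of per-sample He, per locus."""
    per_locus = diversity_table(d).per_locus
    return per_locus.groupby("locus", sort=False)["He"].mean()


def select_panel(d: FrequencyTable | GenotypeTable, criterion: str, k: int,
                 seed: int | None = None) -> LocusPanel:
    """Choose a k-locus panel by mean-He ranking (ties broken by locus
    name), at random (seeded), or verbatim from a list."""
    if isinstance(criterion, (list, tuple)):
        return LocusPanel([str(l) for l in criterion], "listed", k)
    if k > len(d.loci):
        raise ValueError(f"k={k} exceeds the {len(d.loci)}-locus pool")
    if criterion == "random":
        rng = np.random.default_rng(seed)
        chosen = sorted(rng.choice(d.loci, size=k, replace=False).tolist())
        return LocusPanel(chosen, "random", k, seed)
    he = mean_he_per_locus(d)
    ranked = sorted(he.index, key=lambda l: (he[l], l))
    if criterion == "lowest":
        return LocusPanel(sorted(ranked[:k]), "lowest", k)
    if criterion == "highest":
        return LocusPanel(sorted(ranked[-k:]), "highest", k)
    raise ValueError(f"unknown criterion {criterion!r}")


def he_variance_profile(d: FrequencyTable | GenotypeTable,
                        panel: LocusPanel | Sequence[str]) -> tuple[float, float]:
    """Mean and across-population variance (n-1 denominator) of per-population
    panel-average He."""
    loci = list(panel.loci if isinstance(panel, LocusPanel) else panel)
    per_locus = diversity_table(d).per_locus
    sub = per_locus[per_locus["locus"].isin(loci)]
    per_pop = sub.groupby("population", sort=False)["He"].mean()
    if len(per_pop) < 2:
        raise ValueError("need at least 2 populations")
    return float(per_pop.mean()), float(per_pop.var(ddof=1))


def levene_test(values_a: Sequence[float], values_b: Sequence[float],
                centering: str = "mean") -> tuple[float, float]:
    """Levene's test for equality of variances between two samples
    (``centering='median'`` gives the Brown–Forsythe variant)."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs at least 2 values")
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        raise ValueError("degenerate: all values equal in both samples")
    w, p = stats.levene(a, b, center=centering)
    return float(w), float(p)


# ---------------------------------------------------------------------------
# Experiment driver
# ---------------------------------------------------------------------------


@dataclass
class DatasetComparison:
    """Panel comparison table plus the random-panel reference distribution.

    ``percentile_*`` is the percentage of random panels whose statistic lies
    at or below the ascertained (top-He) panel's value.
    """

    table: pd.DataFrame           # rows: pool / top / bottom / random panels summary
    random_panels: pd.DataFrame   # one row per random panel
    percentile_var_he: float
    percentile_rst: float
    tests: pd.DataFrame = field(default_factory=pd.DataFrame)


def _counts_from_genotypes(g: GenotypeTable) -> tuple[np.ndarray, np.ndarray, list[str]]:
    values = np.unique(g.calls)
    P, L = len(g.populations), len(g.loci)
    counts = np.zeros((P, L, len(values)), dtype=np.int64)
    pop_index = {p: i for i, p in enumerate(g.populations)}
    codes = np.searchsorted(values, g.calls)  # (n_ind, L, 2)
    pop_of = np.array([pop_index[p] for p in g.population_of])
    A = len(values)
    flat = (pop_of[:, None, None] * (L * A) + np.arange(L)[None, :, None] * A + codes).ravel()
    counts = np.bincount(flat, minlength=P * L * A).reshape(P, L, A)
    return values, counts, list(g.populations)


def _two_level_components_vec(values: np.ndarray, counts: np.ndarray,
                              ) -> tuple[np.ndarray, np.ndarray]:
    """Stepwise-model variance components per locus, vectorised.

    counts: (P, L, A) integer copy counts.  Returns (sigma_among,
    sigma_within), each (L,)."""
    n_k = counts.sum(axis=2).astype(float)  # (P, L)
    N = n_k.sum(axis=0)                     # (L,)
    P = counts.shape[0]
    s1 = counts @ values                    # (P, L)
    s2 = counts @ (values * values)
    ss_wp = (s2 - s1 * s1 / n_k).sum(axis=0)
    S1, S2 = s1.sum(axis=0), s2.sum(axis=0)
    ss_total = S2 - S1 * S1 / N
    sigma_w = ss_wp / (N - P)
    n_prime = (N - (n_k * n_k).sum(axis=0) / N) / (P - 1)
    sigma_a = ((ss_total - ss_wp) / (P - 1) - sigma_w) / n_prime
    return sigma_a, sigma_w


def ascertainment_experiment_counts(values: np.ndarray, counts: np.ndarray,
                                    panel_pop_idx: Sequence[int] | None = None,
                                    k: int = 13, n_random: int = 50,
                                    seed: int = 0,
                                    loci: Sequence[str] | None = None) -> DatasetComparison:
    """Ascertainment experiment on a (populations x loci x alleles) count
    array — the fast path used for replicated simulations.

    The top/bottom panels are ranked by the unweighted mean over the panel
    populations of per-sample He (pooling copies across populations would
    contaminate the ranking with the among-population component, the very
    quantity under study); comparison statistics (across-population variance
    of panel-mean He, multi-locus R_ST) are computed over all populations
    from per-locus variance components, so every panel's R_ST is exactly the
    summed-components ratio over its loci.
    """
    P, L, A = counts.shape
    if L < 3 * k:
        raise ValueError("locus pool must hold at least 3k loci")
    loci = list(loci) if loci is not None else [f"L{l:03d}" for l in range(L)]
    panel_pop_idx = list(panel_pop_idx) if panel_pop_idx is not None else list(range(P))

    n = counts.sum(axis=2).astype(float)          # (P, L)
    p2 = (counts / n[..., None]) ** 2
    he = n / (n - 1) * (1.0 - p2.sum(axis=2))     # (P, L) per-sample He
    k_counts = (counts > 0).sum(axis=2)

    he_rank = he[panel_pop_idx].mean(axis=0)      # (L,) mean per-sample He

    sigma_a, sigma_w = _two_level_components_vec(values, counts)

    order = np.lexsort((np.array(loci, dtype=object), he_rank))
    bottom = np.sort(order[:k])
    top = np.sort(order[-k:])
    rng = np.random.default_rng(seed)
    random_sets = [np.sort(rng.choice(L, size=k, replace=False)) for _ in range(n_random)]

    def panel_stats(idx: np.ndarray) -> dict[str, float]:
        per_pop = he[:, idx].mean(axis=1)
        tot = sigma_a[idx].sum() + sigma_w[idx].sum()
        return {
            "n_loci": len(idx),
            "mean_He": float(per_pop.mean()),
            "var_He": float(per_pop.var(ddof=1)),
            "mean_k": float(k_counts[:, idx].mean()),
            "R_ST": float(sigma_a[idx].sum() / tot) if tot != 0 else np.nan,
        }

    all_idx = np.arange(L)
    rows = {
        "pool": panel_stats(all_idx),
        "top_He": panel_stats(top),
        "bottom_He": panel_stats(bottom),
    }
    rand_rows = pd.DataFrame([panel_stats(s) for s in random_sets])
    rows["random_median"] = {
        "n_loci": k,
        "mean_He": float(rand_rows["mean_He"].median()),
        "var_He": float(rand_rows["var_He"].median()),
        "mean_k": float(rand_rows["mean_k"].median()),
        "R_ST": float(rand_rows["R_ST"].median()),
    }
    table = pd.DataFrame(rows).T

    # percentile of the ascertained panel inside the random-panel distribution
    pct_var = 100.0 * float((rand_rows["var_He"] <= rows["top_He"]["var_He"]).mean())
    pct_rst = 100.0 * float((rand_rows["R_ST"] <= rows["top_He"]["R_ST"]).mean())

    # Pairwise Wilcoxon (per-population panel-mean He) and Levene (its
    # spread) among the three named panels, Bonferroni over the pairs.
    named = {"pool": all_idx, "top_He": top, "bottom_He": bottom}
    pairs = list(combinations(named, 2))
    test_rows = []
    for a, b in pairs:
        xa, xb = he[:, named[a]].mean(axis=1), he[:, named[b]].mean(axis=1)
        wil = stats.mannwhitneyu(xa, xb, alternative="two-sided", method="asymptotic").pvalue \
            if np.ptp(np.concatenate([xa, xb])) > 0 else 1.0
        try:
            _, lev = levene_test(xa, xb)
        except ValueError:
            lev = np.nan
        test_rows.append({"pair": f"{a} vs {b}",
                          "wilcoxon_p_raw": float(wil),
                          "wilcoxon_p_bonferroni": min(1.0, float(wil) * len(pairs)),
                          "levene_p_raw": float(lev),
                          "levene_p_bonferroni": min(1.0, float(lev) * len(pairs))})
    return DatasetComparison(table=table, random_panels=rand_rows,
                             percentile_var_he=pct_var, percentile_rst=pct_rst,
                             tests=pd.DataFrame(test_rows))


def ascertainment_experiment(pool: GenotypeTable, panel_pops: Sequence[str] | None = None,
                             k: int = 13, n_random: int = 50,
                             seed: int = 0) -> DatasetComparison:
    """Run the marker-choice experiment on a genotype locus pool.

    Selects the k loci with highest pooled He over ``panel_pops`` (all
    populations by default) — mimicking forensic marker ascertainment — and
    compares their across-population He variance and multi-locus R_ST with
    the bottom-k panel, the full pool and ``n_random`` random k-panels.
    """
    values, counts, pops = _counts_from_genotypes(pool)
    if panel_pops is None:
        idx = None
    else:
        pos = {p: i for i, p in enumerate(pops)}
        unknown = [p for p in panel_pops if p not in pos]
        if unknown:
            raise ValueError(f"panel populations not in pool: {unknown}")
        idx = [pos[p] for p in panel_pops]
    return ascertainment_experiment_counts(values, counts, idx, k, n_random, seed,
                                           loci=list(pool.loci))
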