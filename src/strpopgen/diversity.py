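"""Within-population diversity indices and Hardy–Weinberg testing.

Indices follow the conventions of standard population-genetic software:

* He — unbiased expected heterozygosity, ``n/(n-1) * (1 - sum p_i^2)`` with
  n the number of gene copies (2 x individuals);
* Vp — sample variance (denominator n-1) of the repeat value over allele
  copies, in squared repeat units;
* k — observed allele count.

Group-level summaries are means and SDs over the member populations'
per-population averages.  Differences among groups are assessed with
Kruskal–Wallis and pairwise Wilcoxon rank-sum tests with Bonferroni
correction.  Hardy–Weinberg equilibrium is tested per population x locus
with a Monte-Carlo exact test: the observed allele copies are re-paired at
random and the conditional probability of each genotype array (Levene's
formula) is compared with the observed one.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

from .str_io import FrequencyTable, GenotypeTable, HierarchyConfig

__all__ = [
    "expected_heterozygosity",
    "repeat_variance",
    "DiversityTable",
    "diversity_table",
    "group_summary",
    "kruskal_wallis",
    "pairwise_wilcoxon",
    "HweResult",
    "hwe_test",
    "hwe_all",
]


def expected_heterozygosity(freqs: Mapping[float, float] | np.ndarray, n_copies: int) -> float:
    """Unbiased expected heterozygosity from allele frequencies."""
    if n_copies < 2:
        raise ValueError("n_copies must be >= 2")
    p = np.asarray(list(freqs.values()) if isinstance(freqs, Mapping) else freqs, dtype=float)
    return float(n_copies / (n_copies - 1) * (1.0 - np.sum(p * p)))


def repeat_variance(freqs_or_copies, n_copies: int | None = None) -> float:
    """Sample variance of the repeat value over allele copies.

    Accepts either an array of copies (repeat values, one per gene copy) or
    an allele->frequency map with ``n_copies``; the two paths agree exactly
    when the frequencies correspond to integer counts.
    """
    if isinstance(freqs_or_copies, Mapping):
        if n_copies is None or n_copies < 2:
            raise ValueError("frequency path needs n_copies >= 2")
        a = np.array(list(freqs_or_copies.keys()), dtype=float)
        f = np.array(list(freqs_or_copies.values()), dtype=float)
        mean = float(np.dot(f, a))
        return float(n_copies / (n_copies - 1) * (np.dot(f, a * a) - mean * mean))
    copies = np.asarray(freqs_or_copies, dtype=float)
    if copies.size < 2:
        raise ValueError("need at least 2 copies")
    return float(np.var(copies, ddof=1))


@dataclass
class DiversityTable:
    """Per population x locus diversity indices with per-population means."""

    per_locus: pd.DataFrame      # columns population, locus, He, Vp, k
    per_population: pd.DataFrame  # index population; columns He, Vp, k (means over loci)


def _cell_indices(data: FrequencyTable | GenotypeTable, pop: str, locus: str) -> tuple[float, float, int]:
    if isinstance(data, GenotypeTable):
        copies = data.copies(pop, locus)
        n = copies.size
        _, counts = np.unique(copies, return_counts=True)
        he = expected_heterozygosity(counts / n, n)
        vp = repeat_variance(copies)
        k = len(counts)
    else:
        freqs, n = data.cell(pop, locus)
        he = expected_heterozygosity(freqs, n)
        vp = repeat_variance(freqs, n)
        k = len(freqs)
    return he, vp, k


def diversity_table(data: FrequencyTable | GenotypeTable) -> DiversityTable:
    rows = []
    for pop in data.populations:
        for locus in data.loci:
            he, vp, k = _cell_indices(data, pop, locus)
            rows.append({"population": pop, "locus": locus, "He": he, "Vp": vp, "k": k})
    per_locus = pd.DataFrame(rows)
    per_population = per_locus.groupby("population", sort=False)[["He", "Vp", "k"]].mean()
    return DiversityTable(per_locus, per_population)


def group_summary(d: DiversityTable, hierarchy: HierarchyConfig,
                  group_order: Sequence[str] | None = None) -> pd.DataFrame:
    """Per-group mean and SD (over member populations) of the per-population
    mean indices.  Groups are reported in ``group_order`` (default: the
    hierarchy's own order, e.g. an Africa-to-America layout)."""
    order = list(group_order) if group_order is not None else list(hierarchy.group_order)
    rows = []
    for group in order:
        members = [p for p in d.per_population.index if hierarchy.assignment.get(p) == group]
        if not members:
            raise ValueError(f"group {group!r} has no member populations")
        sub = d.per_population.loc[members]
        row = {"group": group, "n_pops": len(members)}
        for col in ("He", "Vp", "k"):
            row[f"mean_{col}"] = float(sub[col].mean())
            row[f"sd_{col}"] = float(sub[col].std(ddof=1))  # NaN when a single member
        rows.append(row)
    return pd.DataFrame(rows).set_index("group")


def _values_by_group(d: DiversityTable, hierarchy: HierarchyConfig, index: str) -> dict[str, np.ndarray]:
    out: dict[str, list[float]] = {}
    for pop, row in d.per_population.iterrows():
        out.setdefault(hierarchy.assignment[pop], []).append(float(row[index]))
    return {g: np.asarray(v) for g, v in out.items()}


def kruskal_wallis(values_by_group: Mapping[str, Sequence[float]]) -> tuple[float, float]:
    """Kruskal–Wallis H (tie-corrected) and its chi-square p-value."""
    groups = [np.asarray(v, dtype=float) for v in values_by_group.values()]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if any(len(g) == 0 for g in groups):
        raise ValueError("a group has no observations")
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):  # degenerate: no variation at all
        return 0.0, 1.0
    h, p = stats.kruskal(*groups)
    return float(h), float(p)


def pairwise_wilcoxon(values_by_group: Mapping[str, Sequence[float]],
                      correction: str = "bonferroni") -> pd.DataFrame:
    """All pairwise two-sided Wilcoxon rank-sum tests between groups.

    Returns a symmetric matrix of p-values adjusted as
    ``min(1, raw p x number of pairs)`` (Bonferroni; ``correction=None``
    leaves raw p-values)."""
    names = list(values_by_group)
    n_pairs = len(names) * (len(names) - 1) // 2
    mat = pd.DataFrame(np.nan, index=names, columns=names, dtype=float)
    for a, b in combinations(names, 2):
        va, vb = np.asarray(values_by_group[a]), np.asarray(values_by_group[b])
        if len(va) == 0 or len(vb) == 0:
            raise ValueError("a group has no observations")
        pooled = np.concatenate([va, vb])
        if np.all(pooled == pooled[0]):
            raw = 1.0
        else:
            raw = float(stats.mannwhitneyu(va, vb, alternative="two-sided",
                                           method="asymptotic").pvalue)
        adj = min(1.0, raw * n_pairs) if correction == "bonferroni" else raw
        mat.loc[a, b] = mat.loc[b, a] = adj
    return mat


def group_tests(d: DiversityTable, hierarchy: HierarchyConfig, index: str = "He") -> dict:
    """Kruskal–Wallis plus the Bonferroni-corrected pairwise Wilcoxon matrix
    for one diversity index over groups."""
    by_group = _values_by_group(d, hierarchy, index)
    h, p = kruskal_wallis(by_group)
    return {"index": index, "kruskal_H": h, "kruskal_p": p,
            "pairwise_wilcoxon": pairwise_wilcoxon(by_group)}


# ---------------------------------------------------------------------------
# Hardy–Weinberg exact test (Monte-Carlo)
# ---------------------------------------------------------------------------


@dataclass
class HweResult:
    population: str
    locus: str
    p: float
    direction: str | None  # "excess" | "deficit" | None when undefined
    observed_het: int
    expected_het: float
    n_draws: int


def _genotype_log_prob_terms(codes: np.ndarray, n_alleles: int) -> tuple[np.ndarray, np.ndarray]:
    """Heterozygote counts and genotype-count factorial terms per array.

    codes has shape (n_arrays, n_individuals, 2); returns (h, sum log m_g!)
    with m_g the genotype counts.  Only these two terms of Levene's
    conditional probability vary across re-pairings of the same copies.
    """
    lo = codes.min(axis=2)
    hi = codes.max(axis=2)
    h = (lo != hi).sum(axis=1)
    gcode = lo * n_alleles + hi
    n_arrays = codes.shape[0]
    flat = (np.arange(n_arrays)[:, None] * (n_alleles * n_alleles) + gcode).ravel()
    gcounts = np.bincount(flat, minlength=n_arrays * n_alleles * n_alleles)
    gcounts = gcounts.reshape(n_arrays, n_alleles * n_alleles)
    return h, gammaln(gcounts + 1.0).sum(axis=1)


def hwe_test(g: GenotypeTable, population: str, locus: str,
             n_draws: int = 10000, seed: int = 0) -> HweResult:
    """Monte-Carlo exact test of Hardy–Weinberg proportions.

    The 2n observed allele copies are re-paired at random ``n_draws`` times;
    the test statistic is the conditional probability of the genotype array
    given the allele counts, and p is the proportion of arrays (observed
    included) whose probability is <= the observed one, so p has floor
    1/(n_draws + 1).  Direction compares the observed heterozygote count
    with its expectation under random pairing.
    """
    li = g.loci.index(locus)
    idx = g.individuals_in(population)
    if len(idx) < 2:
        raise ValueError("need at least 2 individuals")
    genotypes = g.calls[idx, li, :]
    values = np.unique(genotypes)
    if len(values) == 1:
        return HweResult(population, locus, 1.0, None, 0, 0.0, n_draws)
    codes = np.searchsorted(values, genotypes)
    n_ind = codes.shape[0]
    n_alleles = len(values)
    copies = codes.ravel()
    two_n = copies.size
    allele_counts = np.bincount(copies, minlength=n_alleles)

    h_obs, gterm_obs = _genotype_log_prob_terms(codes[None, :, :], n_alleles)
    logp_obs = h_obs[0] * math.log(2.0) - gterm_obs[0]

    rng = np.random.default_rng(seed)
    tiled = np.tile(copies, (n_draws, 1))
    shuffled = rng.permuted(tiled, axis=1).reshape(n_draws, n_ind, 2)
    h_draw, gterm_draw = _genotype_log_prob_terms(shuffled, n_alleles)
    logp_draw = h_draw * math.log(2.0) - gterm_draw
    count = int(np.sum(logp_draw <= logp_obs + 1e-9))
    p = (count + 1) / (n_draws + 1)

    exp_het = n_ind * (1.0 - np.sum(allele_counts * (allele_counts - 1.0))
                       / (two_n * (two_n - 1.0)))
    direction = "excess" if h_obs[0] > exp_het else "deficit"
    return HweResult(population, locus, float(p), direction, int(h_obs[0]),
                     float(exp_het), n_draws)


def hwe_all(g: GenotypeTable, n_draws: int = 10000, seed: int = 0) -> pd.DataFrame:
    """HWE tests for every population x locus; one row per test."""
    ss = np.random.SeedSequence(seed)
    seeds = iter(s % (2**31) for s in ss.generate_state(len(g.populations) * len(g.loci)))
    rows = []
    for pop in g.populations:
        for locus in g.loci:
            r = hwe_test(g, pop, locus, n_draws, next(seeds))
            rows.append({"population": r.population, "locus": r.locus, "p": r.p,
                         "direction": r.direction, "observed_het": r.observed_het,
                         "expected_het": r.expected_het})
    return pd.DataFrame(rows)


def hwe_rejection_summary(results: pd.DataFrame, n_loci: int) -> dict:
    """Counts of HWE rejections at nominal 5%/1% and with a per-locus
    Bonferroni correction, mirroring a standard data-quality report."""
    out = {
        "n_tests": len(results),
        "reject_05": int((results["p"] <= 0.05).sum()),
        "reject_01": int((results["p"] <= 0.01).sum()),
        "reject_05_bonferroni_loci": int((results["p"] <= 0.05 / n_loci).sum()),
        "reject_01_bonferroni_loci": int((results["p"] <= 0.01 / n_loci).sum()),
    }
    out["rate_05"] = out["reject_05"] / out["n_tests"] if out["n_tests"] else math.nan
    return out
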