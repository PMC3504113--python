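"""Analysis of molecular variance (AMOVA) for STR data.

Partitions the total molecular variance among hierarchical strata using
allele copies as the units of analysis.  Two allele-distance models are
supported:

* ``stepwise`` — d(i, j) = (a_i - a_j)^2 with a the repeat value, giving the
  R statistics (R_ST, R_SC, R_CT) appropriate under stepwise mutation;
* ``identity`` — d(i, j) = 0/1, giving the classical F statistics based on
  allele identity alone.

Computations run from allele *counts* per population x locus, so the same
code serves genotype tables (counts observed directly) and frequency-only
tables (integer counts reconstructed by rounding with largest-remainder
reconciliation); on matched data the two modes are exactly equal.  The
within-individual stratum is deliberately ignored (copies are exchangeable
within populations) so both modes are commensurable.

Multi-locus fixation indices follow the variance-component summation
approach: locus-specific components are summed over loci and the indices
recomputed from the summed components.  Significance comes from permutation
tests with scheme chosen per index, per-locus p-values can be combined with
Fisher's method, and pairwise index matrices can be transformed to Reynolds
coancestry distances D = -ln(1 - theta).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .str_io import FrequencyTable, GenotypeTable, HierarchyConfig, ValidationError

__all__ = [
    "AmovaResult",
    "Stratum",
    "DistanceMatrix",
    "PermutationResult",
    "two_level_amova",
    "three_level_amova",
    "multilocus_combine",
    "permutation_test",
    "fisher_combine",
    "pairwise_matrix",
    "reynolds_transform",
    "components_from_counts",
    "locus_counts",
]


# ---------------------------------------------------------------------------
# Result containers
# ---------------------------------------------------------------------------


@dataclass
class Stratum:
    name: str
    df: int
    ssd: float

    @property
    def ms(self) -> float:
        return self.ssd / self.df if self.df > 0 else math.nan


@dataclass
class AmovaResult:
    """Variance decomposition for one locus (or the multi-locus sum).

    sigma maps stratum key -> variance component; for the two-level design
    the keys are ``among_pops`` / ``within_pops``, for the three-level design
    ``among_groups`` / ``among_pops_within_groups`` / ``within_pops``.
    Fixation indices are keyed ST/SC/CT and prefixed R (stepwise) or F
    (identity) in reports.  Negative components are reported as computed.
    """

    locus: str | None
    model: str
    strata: list[Stratum]
    sigma: dict[str, float]
    n_pops: int
    n_copies: int
    n_groups: int | None = None
    p_values: dict[str, float] = field(default_factory=dict)
    degenerate: bool = False

    @property
    def prefix(self) -> str:
        return "R" if self.model == "stepwise" else "F"

    @property
    def total_variance(self) -> float:
        return float(np.nansum(list(self.sigma.values())))

    @property
    def indices(self) -> dict[str, float]:
        s = self.sigma
        total = self.total_variance
        out: dict[str, float] = {}
        if "among_groups" in s:
            a, b, c = s["among_groups"], s["among_pops_within_groups"], s["within_pops"]
            out["CT"] = a / total if total != 0 else math.nan
            out["SC"] = b / (b + c) if (b + c) != 0 else math.nan
            out["ST"] = (a + b) / total if total != 0 else math.nan
        else:
            a, c = s["among_pops"], s["within_pops"]
            out["ST"] = a / total if total != 0 else math.nan
        return out

    @property
    def percentages(self) -> dict[str, float]:
        total = self.total_variance
        if total == 0:
            return {k: math.nan for k in self.sigma}
        return {k: 100.0 * v / total for k, v in self.sigma.items()}

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for st in self.strata:
            key = st.name
            rows.append({
                "locus": self.locus or "ALL", "stratum": key, "df": st.df,
                "SSD": st.ssd, "MS": st.ms, "sigma2": self.sigma.get(key, math.nan),
                "percent": self.percentages.get(key, math.nan),
            })
        return pd.DataFrame(rows)


@dataclass
class PermutationResult:
    statistic: str
    observed: float
    p: float
    n_perm: int
    seed: int


@dataclass
class DistanceMatrix:
    """Symmetric nonnegative-diagonal-zero matrix over populations."""

    populations: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.populations)
        if self.values.shape != (n, n):
            raise ValidationError("matrix shape must match population count")
        if not np.allclose(self.values, self.values.T, equal_nan=True):
            raise ValidationError("matrix must be symmetric")
        if not np.allclose(np.diag(self.values), 0.0):
            raise ValidationError("diagonal must be zero")

    def exclude(self, populations: Iterable[str]) -> "DistanceMatrix":
        drop = set(populations)
        keep = [i for i, p in enumerate(self.populations) if p not in drop]
        return DistanceMatrix([self.populations[i] for i in keep],
                              self.values[np.ix_(keep, keep)])

    def condensed(self) -> np.ndarray:
        iu = np.triu_indices(len(self.populations), k=1)
        return self.values[iu]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.populations, columns=self.populations)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path) -> "DistanceMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls([str(p) for p in df.index], df.to_numpy(dtype=float))


# ---------------------------------------------------------------------------
# Sums of squared deviations from allele counts
# ---------------------------------------------------------------------------


def _ss_pool(values: np.ndarray, counts: np.ndarray, model: str) -> float:
    """SSD of one pool of copies: (1/2n) sum_ij d(i,j) over ordered pairs.

    For the stepwise model this equals the sum of squared deviations of
    repeat values from the pool mean; for identity, n(1 - sum p^2)/2.
    """
    n = counts.sum()
    if n == 0:
        return 0.0
    if model == "stepwise":
        s1 = float(np.dot(counts, values))
        s2 = float(np.dot(counts, values * values))
        return s2 - s1 * s1 / n
    if model == "identity":
        return (n * n - float(np.dot(counts, counts))) / (2.0 * n)
    raise ValueError(f"unknown allele distance model {model!r}")


def components_from_counts(values: np.ndarray, counts: np.ndarray, model: str = "stepwise",
                           group_idx: np.ndarray | None = None) -> dict:
    """Variance components from an allele-count matrix.

    Parameters
    ----------
    values : (A,) float repeat values of the alleles
    counts : (P, A) integer copy counts per population
    model : "stepwise" or "identity"
    group_idx : optional (P,) integer group assignment; if given (with >= 2
        distinct groups) the three-level decomposition is returned.

    Returns a dict with per-stratum (df, ssd) and the sigma components.
    """
    counts = np.asarray(counts)
    n_k = counts.sum(axis=1).astype(float)
    if (n_k < 2).any():
        raise ValidationError("every population needs at least 2 gene copies")
    P = counts.shape[0]
    if P < 2:
        raise ValidationError("need at least 2 populations")
    N = float(n_k.sum())
    ssd_wp = float(sum(_ss_pool(values, counts[k], model) for k in range(P)))
    ssd_total = _ss_pool(values, counts.sum(axis=0), model)
    df_wp = int(N - P)
    sigma_c = ssd_wp / df_wp if df_wp > 0 else math.nan

    if group_idx is None or len(np.unique(group_idx)) == 1:
        df_ap = P - 1
        ssd_ap = ssd_total - ssd_wp
        n_prime = (N - float(np.dot(n_k, n_k)) / N) / (P - 1)
        sigma_a = (ssd_ap / df_ap - sigma_c) / n_prime
        return {
            "strata": [Stratum("among_pops", df_ap, ssd_ap),
                       Stratum("within_pops", df_wp, ssd_wp)],
            "sigma": {"among_pops": sigma_a, "within_pops": sigma_c},
            "n_pops": P, "n_copies": int(N), "n_groups": None, "degenerate": df_wp <= 0,
        }

    group_idx = np.asarray(group_idx)
    groups = np.unique(group_idx)
    G = len(groups)
    N_g = np.array([n_k[group_idx == g].sum() for g in groups])
    ssd_wg = float(sum(_ss_pool(values, counts[group_idx == g].sum(axis=0), model)
                       for g in groups))
    ssd_ap_wg = ssd_wg - ssd_wp
    ssd_ag = ssd_total - ssd_wg
    df_ag, df_ap_wg = G - 1, P - G

    sum_npg2_over_Ng = float(sum(np.dot(n_k[group_idx == g], n_k[group_idx == g]) / N_g[i]
                                 for i, g in enumerate(groups)))
    n_coef = (N - sum_npg2_over_Ng) / (P - G) if P > G else math.nan
    n_prime = (sum_npg2_over_Ng - float(np.dot(n_k, n_k)) / N) / (G - 1)
    n_dprime = (N - float(np.dot(N_g, N_g)) / N) / (G - 1)

    degenerate = P == G
    if degenerate:
        sigma_b = math.nan
        sigma_a = (ssd_ag / df_ag - sigma_c) / n_dprime
    else:
        sigma_b = (ssd_ap_wg / df_ap_wg - sigma_c) / n_coef
        sigma_a = (ssd_ag / df_ag - sigma_c - n_prime * sigma_b) / n_dprime
    return {
        "strata": [Stratum("among_groups", df_ag, ssd_ag),
                   Stratum("among_pops_within_groups", df_ap_wg, ssd_ap_wg),
                   Stratum("within_pops", df_wp, ssd_wp)],
        "sigma": {"among_groups": sigma_a, "among_pops_within_groups": sigma_b,
                  "within_pops": sigma_c},
        "n_pops": P, "n_copies": int(N), "n_groups": G, "degenerate": degenerate,
    }


def locus_counts(data: FrequencyTable | GenotypeTable, locus: str,
                 populations: Sequence[str] | None = None) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Allele values and per-population copy counts for one locus.

    For frequency tables, integer counts are reconstructed from frequencies
    (largest-remainder rounding to n_copies).
    """
    pops = list(populations) if populations is not None else list(data.populations)
    per_pop = [data.allele_counts(p, locus) for p in pops]
    values = np.unique(np.concatenate([v for v, _ in per_pop]))
    counts = np.zeros((len(pops), len(values)), dtype=np.int64)
    for k, (v, c) in enumerate(per_pop):
        counts[k, np.searchsorted(values, v)] = c
    return values, counts, pops


def _as_result(parts: dict, locus: str | None, model: str) -> AmovaResult:
    return AmovaResult(locus=locus, model=model, strata=parts["strata"],
                       sigma=parts["sigma"], n_pops=parts["n_pops"],
                       n_copies=parts["n_copies"], n_groups=parts["n_groups"],
                       degenerate=parts["degenerate"])


def two_level_amova(data: FrequencyTable | GenotypeTable, model: str = "stepwise",
                    locus: str | None = None,
                    populations: Sequence[str] | None = None) -> AmovaResult:
    """Single-locus AMOVA: among populations vs within populations."""
    locus = locus if locus is not None else data.loci[0]
    values, counts, _ = locus_counts(data, locus, populations)
    return _as_result(components_from_counts(values, counts, model), locus, model)


def _group_index(pops: Sequence[str], hierarchy: HierarchyConfig | Mapping[str, str]) -> np.ndarray:
    if isinstance(hierarchy, HierarchyConfig):
        labels = hierarchy.groups_of(pops)
    else:
        labels = [hierarchy[p] for p in pops]
    _, idx = np.unique(np.asarray(labels, dtype=object), return_inverse=True)
    return idx


def three_level_amova(data: FrequencyTable | GenotypeTable,
                      hierarchy: HierarchyConfig | Mapping[str, str],
                      model: str = "stepwise", locus: str | None = None,
                      populations: Sequence[str] | None = None) -> AmovaResult:
    """Single-locus hierarchical AMOVA: groups / populations within groups /
    within populations, yielding R_CT, R_SC and R_ST (or F analogues)."""
    locus = locus if locus is not None else data.loci[0]
    values, counts, pops = locus_counts(data, locus, populations)
    gidx = _group_index(pops, hierarchy)
    return _as_result(components_from_counts(values, counts, model, gidx), locus, model)


def multilocus_combine(results: Sequence[AmovaResult]) -> AmovaResult:
    """Sum locus-specific variance components over loci and recompute the
    fixation indices from the summed components."""
    if not results:
        raise ValueError("no per-locus results to combine")
    first = results[0]
    names = [s.name for s in first.strata]
    for r in results[1:]:
        if [s.name for s in r.strata] != names or r.model != first.model:
            raise ValidationError("per-locus results have mismatched strata or models")
    strata = [Stratum(name,
                      sum(r.strata[i].df for r in results),
                      sum(r.strata[i].ssd for r in results))
              for i, name in enumerate(names)]
    sigma = {name: float(np.sum([r.sigma[name] for r in results])) for name in names}
    return AmovaResult(locus=None, model=first.model, strata=strata, sigma=sigma,
                       n_pops=first.n_pops, n_copies=first.n_copies,
                       n_groups=first.n_groups,
                       degenerate=any(r.degenerate for r in results))


def amova(data: FrequencyTable | GenotypeTable,
          hierarchy: HierarchyConfig | Mapping[str, str] | None = None,
          model: str = "stepwise", loci: Sequence[str] | None = None,
          populations: Sequence[str] | None = None) -> tuple[list[AmovaResult], AmovaResult]:
    """Per-locus AMOVA over all (or selected) loci plus the multi-locus
    combination.  Returns (per-locus results, combined result)."""
    loci = list(loci) if loci is not None else list(data.loci)
    per_locus = []
    for locus in loci:
        if hierarchy is None:
            per_locus.append(two_level_amova(data, model, locus, populations))
        else:
            per_locus.append(three_level_amova(data, hierarchy, model, locus, populations))
    return per_locus, multilocus_combine(per_locus)


# ---------------------------------------------------------------------------
# Permutation inference
# ---------------------------------------------------------------------------


def _multilocus_statistic(per_locus_counts: list[tuple[np.ndarray, np.ndarray]], model: str,
                          statistic: str, group_idx: np.ndarray | None) -> float:
    sigma_sums: dict[str, float] = {}
    for values, counts in per_locus_counts:
        parts = components_from_counts(values, counts, model, group_idx)
        for k, v in parts["sigma"].items():
            sigma_sums[k] = sigma_sums.get(k, 0.0) + (v if np.isfinite(v) else 0.0)
    total = sum(sigma_sums.values())
    if "among_groups" in sigma_sums:
        a = sigma_sums["among_groups"]
        b = sigma_sums["among_pops_within_groups"]
        c = sigma_sums["within_pops"]
        if statistic == "CT":
            return a / total if total != 0 else math.nan
        if statistic == "SC":
            return b / (b + c) if (b + c) != 0 else math.nan
        return (a + b) / total if total != 0 else math.nan
    return sigma_sums["among_pops"] / total if total != 0 else math.nan


def permutation_test(data: FrequencyTable | GenotypeTable, statistic: str = "ST",
                     scheme: str | None = None,
                     hierarchy: HierarchyConfig | Mapping[str, str] | None = None,
                     model: str = "stepwise", loci: Sequence[str] | None = None,
                     n_perm: int = 999, seed: int = 0) -> PermutationResult:
    """Permutation p-value for a (multi-locus) fixation index.

    Schemes (default chosen from data mode and statistic):

    * ``copies`` — permute gene copies among populations, per locus
      (frequency mode; also the hierarchical ST null of no structure at all);
    * ``individuals`` — permute whole individuals among populations
      (genotype mode; both copies at all loci travel together);
    * ``copies_within_groups`` / ``individuals_within_groups`` — same but
      restricted to populations of the same group (null for SC);
    * ``pops_among_groups`` — permute whole populations among groups
      (null for CT).

    p = (number of permuted statistics >= observed + 1) / (n_perm + 1).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    loci = list(loci) if loci is not None else list(data.loci)
    pops = list(data.populations)
    gidx = _group_index(pops, hierarchy) if hierarchy is not None else None
    if statistic in ("SC", "CT") and gidx is None:
        raise ValidationError(f"statistic {statistic} needs a hierarchy")
    if scheme is None:
        if statistic == "CT":
            scheme = "pops_among_groups"
        elif isinstance(data, GenotypeTable):
            scheme = "individuals_within_groups" if statistic == "SC" else "individuals"
        else:
            scheme = "copies_within_groups" if statistic == "SC" else "copies"

    per_locus = [locus_counts(data, l, pops)[:2] for l in loci]
    observed = _multilocus_statistic(per_locus, model, statistic, gidx)
    rng = np.random.default_rng(seed)
    count = 0

    if scheme == "pops_among_groups":
        for _ in range(n_perm):
            perm_gidx = rng.permutation(gidx)
            stat = _multilocus_statistic(per_locus, model, statistic, perm_gidx)
            if stat >= observed - 1e-12:
                count += 1
    elif scheme in ("copies", "copies_within_groups"):
        # Expanded copy codes per locus; permuted within the allowed blocks.
        blocks = _permutation_blocks(gidx, scheme, [c.sum(axis=1) for _, c in per_locus])
        expanded = []
        for (values, counts) in per_locus:
            codes = np.concatenate([np.repeat(np.arange(counts.shape[1]), counts[k])
                                    for k in range(counts.shape[0])])
            sizes = counts.sum(axis=1)
            block_idx = [np.concatenate([_pop_span(sizes, b) for b in block])
                         for block in blocks]
            expanded.append((values, codes, sizes, counts.shape[1], block_idx))
        for _ in range(n_perm):
            permuted = []
            for (values, codes, sizes, A, block_idx) in expanded:
                new_codes = codes.copy()
                for idx in block_idx:
                    new_codes[idx] = rng.permutation(codes[idx])
                permuted.append((values, _counts_from_codes(new_codes, sizes, A)))
            stat = _multilocus_statistic(permuted, model, statistic, gidx)
            if stat >= observed - 1e-12:
                count += 1
    elif scheme in ("individuals", "individuals_within_groups"):
        if not isinstance(data, GenotypeTable):
            raise ValidationError("individual permutation schemes need genotype data")
        pop_to_i = {p: i for i, p in enumerate(pops)}
        ind_pop = np.array([pop_to_i[p] for p in data.population_of])
        locus_codes = []
        for l in loci:
            li = data.loci.index(l)
            values = per_locus[loci.index(l)][0]
            codes = np.searchsorted(values, data.calls[:, li, :])
            locus_codes.append((values, codes))
        if scheme == "individuals_within_groups":
            ind_group = gidx[ind_pop]
            group_members = [np.flatnonzero(ind_group == g) for g in np.unique(gidx)]
        for _ in range(n_perm):
            perm_pop = ind_pop.copy()
            if scheme == "individuals":
                perm_pop = rng.permutation(ind_pop)
            else:
                for members in group_members:
                    perm_pop[members] = rng.permutation(ind_pop[members])
            permuted = []
            for values, codes in locus_codes:
                A = len(values)
                flat = (perm_pop[:, None] * A + codes).ravel()
                counts_p = np.bincount(flat, minlength=len(pops) * A).reshape(len(pops), A)
                permuted.append((values, counts_p))
            stat = _multilocus_statistic(permuted, model, statistic, gidx)
            if stat >= observed - 1e-12:
                count += 1
    else:
        raise ValidationError(f"unknown permutation scheme {scheme!r}")

    return PermutationResult(statistic=statistic, observed=observed,
                             p=(count + 1) / (n_perm + 1), n_perm=n_perm, seed=seed)


def _pop_span(sizes: np.ndarray, k: int) -> np.ndarray:
    starts = np.concatenate([[0], np.cumsum(sizes)])
    return np.arange(starts[k], starts[k + 1])


def _permutation_blocks(gidx: np.ndarray | None, scheme: str,
                        sizes_list: list[np.ndarray]) -> list[list[int]]:
    P = len(sizes_list[0])
    if scheme.endswith("within_groups"):
        if gidx is None:
            raise ValidationError("within-group permutation needs a hierarchy")
        return [[k for k in range(P) if gidx[k] == g] for g in np.unique(gidx)]
    return [list(range(P))]


def _counts_from_codes(codes: np.ndarray, sizes: np.ndarray, n_alleles: int) -> np.ndarray:
    pop_of_copy = np.repeat(np.arange(len(sizes)), sizes)
    flat = pop_of_copy * n_alleles + codes
    return np.bincount(flat, minlength=len(sizes) * n_alleles).reshape(len(sizes), n_alleles)


def fisher_combine(p_values: Sequence[float]) -> tuple[float, int, float]:
    """Fisher's combined probability: chi2 = -2 sum ln p on 2k df."""
    ps = np.asarray(p_values, dtype=float)
    if ps.size == 0:
        raise ValueError("no p-values to combine")
    if (ps <= 0).any() or (ps > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    chi2 = float(-2.0 * np.log(ps).sum())
    df = 2 * ps.size
    return chi2, df, float(stats.chi2.sf(chi2, df))


# ---------------------------------------------------------------------------
# Pairwise matrices and Reynolds distances
# ---------------------------------------------------------------------------


def pairwise_matrix(data: FrequencyTable | GenotypeTable, model: str = "stepwise",
                    loci: Sequence[str] | None = None, n_perm: int = 0,
                    seed: int = 0) -> tuple[DistanceMatrix, pd.DataFrame | None]:
    """Pairwise multi-locus fixation indices between all population pairs.

    Each entry is the two-level multi-locus index for that pair.  With
    n_perm > 0 a per-pair permutation p-value matrix is also returned
    (per-locus components recombined under copy/individual permutation).
    """
    pops = list(data.populations)
    loci = list(loci) if loci is not None else list(data.loci)
    n = len(pops)
    mat = np.zeros((n, n))
    pmat = np.full((n, n), np.nan) if n_perm > 0 else None
    ss = np.random.SeedSequence(seed)
    pair_seeds = iter(ss.generate_state(n * (n - 1) // 2).tolist())
    for i in range(n):
        for j in range(i + 1, n):
            pair = [pops[i], pops[j]]
            per_locus, combined = amova(data, None, model, loci, pair)
            mat[i, j] = mat[j, i] = combined.indices["ST"]
            if n_perm > 0:
                sub = _subset_pair(data, pair, loci)
                res = permutation_test(sub, "ST", None, None, model, loci, n_perm,
                                       next(pair_seeds) % (2**31))
                pmat[i, j] = pmat[j, i] = res.p
    dm_vals = mat.copy()
    np.fill_diagonal(dm_vals, 0.0)
    dm = DistanceMatrix(pops, dm_vals)
    pframe = pd.DataFrame(pmat, index=pops, columns=pops) if pmat is not None else None
    return dm, pframe


def _subset_pair(data, pair: list[str], loci: Sequence[str]):
    if isinstance(data, GenotypeTable):
        idx = np.concatenate([data.individuals_in(p) for p in pair])
        li = [data.loci.index(l) for l in loci]
        return GenotypeTable([data.individuals[i] for i in idx],
                             [data.population_of[i] for i in idx],
                             list(loci), data.calls[np.ix_(idx, li)])
    cells = {(p, l): data.cells[(p, l)] for p in pair for l in loci}
    return FrequencyTable(pair, list(loci), cells)


def reynolds_transform(m: DistanceMatrix, cap: float = 25.0) -> DistanceMatrix:
    """Reynolds coancestry distance D = -ln(1 - theta).

    Negative pairwise indices are clamped to 0 (D = 0); entries >= 1 map to
    ``cap`` so the matrix stays finite for downstream ordination.
    """
    theta = np.clip(m.values, 0.0, None)
    with np.errstate(divide="ignore"):
        d = np.where(theta >= 1.0, cap, -np.log1p(-np.minimum(theta, 1.0 - 1e-300)))
    d = np.minimum(d, cap)
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(list(m.populations), d)
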