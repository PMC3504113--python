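"""Property-based validation experiments.

The reference numbers of the analyses this package reimplements were
computed on large external databases; what is checkable on a desk is the
*behaviour* of the machinery.  This module bundles the validation
experiments the test suite and the reproduction script share:

* exact agreement of the AMOVA engine with a brute-force implementation
  built from the explicit copy-by-copy distance matrix;
* exact agreement between frequency-mode and genotype-mode analyses;
* closed-form limiting cases;
* parameter recovery of the fixation-index estimator on Balding–Nichols
  draws;
* reproduction of the serial-founder diversity gradient;
* the marker-ascertainment mechanism (high-He panels -> compressed He
  variance -> depressed R_ST) over replicated locus pools;
* type-I calibration of every inference procedure under its null.

Every function takes an integer seed and returns a flat dict of named
numbers; nothing here is read from disk.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import stats

from . import amova as am
from . import ascertainment as asc
from . import diversity as dv
from . import geodistance as gd
from . import spatial_structure as sp
from .str_io import GenotypeTable, frequencies_from_genotypes
from .synthetic_data import (BNParams, SimParams, locus_pool_params,
                             sample_deme_counts, simulate_balding_nichols,
                             simulate_serial_founder)

__all__ = [
    "oracle_agreement",
    "cross_mode_agreement",
    "limiting_cases",
    "balding_nichols_recovery",
    "founder_gradient",
    "ascertainment_mechanism",
    "inference_calibration",
    "waypoint_geometry",
]


# ---------------------------------------------------------------------------
# Brute-force AMOVA from the explicit distance matrix
# ---------------------------------------------------------------------------


def _brute_force_components(copies_by_pop, model, groups=None):
    copies_by_pop = [np.asarray(c, dtype=float) for c in copies_by_pop]
    x = np.concatenate(copies_by_pop)
    if model == "stepwise":
        dmat = (x[:, None] - x[None, :]) ** 2
    else:
        dmat = (x[:, None] != x[None, :]).astype(float)

    def ssd(idx):
        sub = dmat[np.ix_(idx, idx)]
        return float(sub.sum() / (2.0 * len(idx)))

    sizes = np.array([len(c) for c in copies_by_pop], dtype=float)
    starts = np.concatenate([[0], np.cumsum(sizes)]).astype(int)
    pop_idx = [np.arange(starts[k], starts[k + 1]) for k in range(len(sizes))]
    N, P = float(len(x)), len(sizes)
    ssd_total = ssd(np.arange(len(x)))
    ssd_wp = sum(ssd(ix) for ix in pop_idx)
    sigma_c = ssd_wp / (N - P)
    if groups is None:
        n_prime = (N - np.sum(sizes**2) / N) / (P - 1)
        sigma_a = ((ssd_total - ssd_wp) / (P - 1) - sigma_c) / n_prime
        return {"among_pops": sigma_a, "within_pops": sigma_c}
    groups = np.asarray(groups)
    glab = np.unique(groups)
    G = len(glab)
    ssd_wg = sum(ssd(np.concatenate([pop_idx[k] for k in range(P) if groups[k] == g]))
                 for g in glab)
    N_g = np.array([sizes[groups == g].sum() for g in glab])
    s_npg = sum((sizes[groups == g] ** 2).sum() / N_g[i] for i, g in enumerate(glab))
    n_c = (N - s_npg) / (P - G)
    n_p = (s_npg - np.sum(sizes**2) / N) / (G - 1)
    n_pp = (N - np.sum(N_g**2) / N) / (G - 1)
    sigma_b = ((ssd_wg - ssd_wp) / (P - G) - sigma_c) / n_c
    sigma_a = ((ssd_total - ssd_wg) / (G - 1) - sigma_c - n_p * sigma_b) / n_pp
    return {"among_groups": sigma_a, "among_pops_within_groups": sigma_b,
            "within_pops": sigma_c}


def _pack(copies_by_pop):
    inds, pops, rows = [], [], []
    for k, c in enumerate(copies_by_pop):
        for j in range(len(c) // 2):
            inds.append(f"p{k}_i{j}")
            pops.append(f"p{k}")
            rows.append([c[2 * j], c[2 * j + 1]])
    return GenotypeTable(inds, pops, ["L0"], np.asarray(rows, dtype=float)[:, None, :])


def oracle_agreement(seed: int, n_fixtures: int = 25) -> dict:
    """Worst absolute deviation of the count-algebra variance components
    from the brute-force distance-matrix oracle over random small fixtures
    (both distance models, two- and three-level designs)."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_fixtures):
        P = int(rng.integers(3, 6))
        copies = [rng.integers(8, 15, 2 * int(rng.integers(2, 7))).astype(float)
                  for _ in range(P)]
        groups = rng.integers(0, 2, P)
        if len(np.unique(groups)) == 1:
            groups[0] = 1 - groups[0]
        g = _pack(copies)
        hier = {f"p{k}": f"G{groups[k]}" for k in range(P)}
        for model in ("stepwise", "identity"):
            r2 = am.two_level_amova(g, model)
            o2 = _brute_force_components(copies, model)
            for key, val in o2.items():
                worst = max(worst, abs(r2.sigma[key] - val))
            r3 = am.three_level_amova(g, hier, model)
            o3 = _brute_force_components(copies, model, groups)
            for key, val in o3.items():
                if not (math.isnan(val) or math.isnan(r3.sigma[key])):
                    worst = max(worst, abs(r3.sigma[key] - val))
    return {"amova_oracle_max_abs_dev": worst, "n": n_fixtures}


def cross_mode_agreement(seed: int) -> dict:
    """|multi-locus R_ST(genotype mode) - R_ST(frequency mode)| on matched
    synthetic data (the frequency table is derived from the genotypes, so
    reconstructed copy counts are exact)."""
    params = SimParams(n_demes=6, deme_size=60, founder_size=10, mu=6e-3,
                       n_loci=13, sample_size=15, seed=seed,
                       burn_in_generations=300, generations_between_foundings=8,
                       demes_per_group=2)
    table, _ = simulate_serial_founder(params)
    ft = frequencies_from_genotypes(table)
    dev = 0.0
    for model in ("stepwise", "identity"):
        _, cg = am.amova(table, None, model)
        _, cf = am.amova(ft, None, model)
        dev = max(dev, abs(cg.indices["ST"] - cf.indices["ST"]))
    return {"cross_mode_rst_abs_dev": dev, "n": len(table.individuals)}


def limiting_cases() -> dict:
    """Exact limiting behaviours: fixed difference, identical populations,
    Reynolds closed form."""
    fixed = _pack([np.full(6, 10.0), np.full(6, 12.0)])
    rst_fixed = am.two_level_amova(fixed, "stepwise").indices["ST"]
    same = _pack([np.array([10, 10, 11, 11.0]), np.array([10, 10, 11, 11.0])])
    rst_same = am.two_level_amova(same, "stepwise").indices["ST"]
    dm = am.DistanceMatrix(["a", "b"], np.array([[0.0, 0.5], [0.5, 0.0]]))
    reyn = am.reynolds_transform(dm).values[0, 1]
    return {"rst_fixed_difference": rst_fixed,
            "rst_identical_pops": rst_same,
            "reynolds_at_half": reyn}


def balding_nichols_recovery(seed: int, n_loci: int = 400) -> dict:
    """Multi-locus F_ST estimates on Balding–Nichols draws at known F
    (10 populations, 200 copies per population)."""
    out: dict = {"n": n_loci}
    worst = 0.0
    for i, F in enumerate((0.05, 0.10, 0.20)):
        ft = simulate_balding_nichols(BNParams(n_pops=10, F=F, n_loci=n_loci,
                                               n_copies=200, seed=seed + i))
        _, combined = am.amova(ft, None, "identity")
        est = combined.indices["ST"]
        out[f"fst_hat_at_F_{F:.2f}"] = est
        worst = max(worst, abs(est - F))
    out["bn_recovery_max_abs_error"] = worst
    return out


def founder_gradient(seed: int) -> dict:
    """The serial-founder diversity gradient: 30 demes, N = 200, founders
    20, mu = 5e-3, 100 loci.  Reports the He-vs-distance OLS slope and p and
    the Spearman correlation of He with deme index."""
    params = SimParams(n_demes=30, deme_size=200, founder_size=20, mu=5e-3,
                       n_loci=100, sample_size=30, seed=seed)
    table, meta = simulate_serial_founder(params)
    d = dv.diversity_table(table)
    he = d.per_population["He"]
    dists = gd.distances_from_origin(meta, meta.coords(meta.populations[0]), "LINE")
    reg = gd.diversity_distance_regression(he.to_dict(), dists)
    rho, rho_p = stats.spearmanr(he.to_numpy(), np.arange(params.n_demes))
    return {"gradient_slope_per_km": reg.slope, "gradient_p": reg.p,
            "gradient_r_squared": reg.r_squared,
            "gradient_spearman_rho": float(rho), "gradient_spearman_p": float(rho_p),
            "n": params.n_demes}


def ascertainment_mechanism(seed: int, n_replicates: int = 100,
                            n_random: int = 50, k: int = 13) -> dict:
    """Fraction of replicated 400-locus pools in which the top-k-He panel
    shows (a) lower across-population variance of He and (b) lower
    multi-locus R_ST than the median of random k-locus panels."""
    ss = np.random.SeedSequence(seed)
    rep_seeds = [int(s % (2**31)) for s in ss.generate_state(n_replicates)]
    var_wins = rst_wins = 0
    for rs in rep_seeds:
        params = locus_pool_params(rs)
        values, counts = sample_deme_counts(params)
        cmp_ = asc.ascertainment_experiment_counts(values, counts, None, k,
                                                   n_random, rs)
        top = cmp_.table.loc["top_He"]
        med = cmp_.table.loc["random_median"]
        var_wins += top["var_He"] < med["var_He"]
        rst_wins += top["R_ST"] < med["R_ST"]
    return {"ascertainment_var_he_below_random_median_pct": 100.0 * var_wins / n_replicates,
            "ascertainment_rst_below_random_median_pct": 100.0 * rst_wins / n_replicates,
            "n": n_replicates}


def inference_calibration(seed: int, n_reps: int = 500) -> dict:
    """Type-I error at nominal alpha = 0.05 for every inference procedure
    under its null, plus a KS uniformity check of Fisher-combined uniform
    p-values."""
    rng = np.random.default_rng(seed)
    out: dict = {"n": n_reps}

    rej = 0
    for _ in range(n_reps):  # permutation AMOVA on exchangeable copies
        copies = [rng.integers(8, 12, 10).astype(float) for _ in range(4)]
        res = am.permutation_test(_pack(copies), "ST", scheme="copies",
                                  n_perm=99, seed=int(rng.integers(2**31)))
        rej += res.p <= 0.05
    out["typeI_amova_permutation"] = rej / n_reps

    rej = 0
    for _ in range(n_reps):  # Mantel on independent random matrices
        pts1, pts2 = rng.random((8, 3)), rng.random((8, 3))
        d1 = _euclidean_dm(pts1)
        d2 = _euclidean_dm(pts2)
        rej += sp.mantel(d1, d2, 99, int(rng.integers(2**31))).p <= 0.05
    out["typeI_mantel"] = rej / n_reps

    rej = 0
    for _ in range(n_reps):  # Kruskal-Wallis on identically distributed groups
        _, p = dv.kruskal_wallis({g: rng.normal(size=10) for g in "abc"})
        rej += p <= 0.05
    out["typeI_kruskal_wallis"] = rej / n_reps

    rej = 0
    for _ in range(n_reps):  # Levene on equal-variance samples
        _, p = asc.levene_test(rng.normal(size=20), rng.normal(size=20))
        rej += p <= 0.05
    out["typeI_levene"] = rej / n_reps

    rej = 0
    for _ in range(n_reps):  # HWE exact test on random-union genotypes
        calls = rng.choice([8., 9., 10., 11.], size=(30, 1, 2),
                           p=[0.4, 0.3, 0.2, 0.1])
        g = GenotypeTable([f"i{j}" for j in range(30)], ["P"] * 30, ["L0"], calls)
        r = dv.hwe_test(g, "P", "L0", 199, int(rng.integers(2**31)))
        rej += r.p <= 0.05
    out["typeI_hwe"] = rej / n_reps

    combined = [am.fisher_combine(rng.uniform(1e-12, 1.0, 13))[2]
                for _ in range(n_reps)]
    out["fisher_uniformity_ks_p"] = float(stats.kstest(combined, "uniform").pvalue)
    return out


def _euclidean_dm(points: np.ndarray) -> am.DistanceMatrix:
    diff = points[:, None, :] - points[None, :, :]
    vals = np.sqrt((diff**2).sum(axis=2))
    return am.DistanceMatrix([f"p{i}" for i in range(len(points))], vals)


def waypoint_geometry() -> dict:
    """Closed-form geometry checks: the three-leg route from North America
    to the East-African origin, and the antipodal half-circumference."""
    cfg = gd.WaypointConfig()
    pop = (49.25, -123.1)
    routed = gd.route_distance(pop, "NAM", gd.ADDIS_ABABA, "SAF", cfg)
    legs = (gd.haversine_km(pop, cfg.waypoints["Anadyr"])
            + gd.haversine_km(cfg.waypoints["Anadyr"], cfg.waypoints["Cairo"])
            + gd.haversine_km(cfg.waypoints["Cairo"], gd.ADDIS_ABABA))
    anti = gd.haversine_km((0.0, 0.0), (0.0, 180.0))
    return {"route_nam_to_addis_km": routed,
            "route_nam_to_addis_legs_km": legs,
            "route_minus_legs_km": routed - legs,
            "antipodal_km": anti,
            "antipodal_minus_pi_r_km": anti - math.pi * gd.EARTH_RADIUS_KM}
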