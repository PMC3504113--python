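"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from strpopgen.str_io import FrequencyTable, GenotypeTable, PopulationMetadata
from strpopgen.synthetic_data import SimParams, simulate_serial_founder


# ---------------------------------------------------------------------------
# Brute-force AMOVA oracle: explicit copy-by-copy distance matrix
# ---------------------------------------------------------------------------


def brute_force_amova(copies_by_pop: list[np.ndarray], model: str,
                      groups: list[int] | None = None) -> dict[str, float]:
    """Variance components computed from the explicit pairwise distance
    matrix over all allele copies — the independent check for the
    count-algebra implementation.

    SSD of a set of copies is (1/n) * sum_{i<j} d(i, j); everything else
    follows from the definitional degrees of freedom and expected-mean-
    square coefficients.
    """
    copies_by_pop = [np.asarray(c, dtype=float) for c in copies_by_pop]
    all_copies = np.concatenate(copies_by_pop)
    if model == "stepwise":
        dmat = (all_copies[:, None] - all_copies[None, :]) ** 2
    else:
        dmat = (all_copies[:, None] != all_copies[None, :]).astype(float)

    def ssd(idx: np.ndarray) -> float:
        sub = dmat[np.ix_(idx, idx)]
        return float(sub.sum() / (2.0 * len(idx)))

    sizes = np.array([len(c) for c in copies_by_pop], dtype=float)
    starts = np.concatenate([[0], np.cumsum(sizes)]).astype(int)
    pop_idx = [np.arange(starts[k], starts[k + 1]) for k in range(len(copies_by_pop))]
    N, P = float(len(all_copies)), len(copies_by_pop)

    ssd_total = ssd(np.arange(len(all_copies)))
    ssd_wp = sum(ssd(ix) for ix in pop_idx)
    sigma_c = ssd_wp / (N - P)

    if groups is None:
        ssd_ap = ssd_total - ssd_wp
        n_prime = (N - np.sum(sizes**2) / N) / (P - 1)
        sigma_a = (ssd_ap / (P - 1) - sigma_c) / n_prime
        return {"among_pops": sigma_a, "within_pops": sigma_c,
                "ssd_total": ssd_total, "ssd_within": ssd_wp}

    groups = np.asarray(groups)
    glabels = np.unique(groups)
    G = len(glabels)
    ssd_wg = sum(ssd(np.concatenate([pop_idx[k] for k in range(P) if groups[k] == g]))
                 for g in glabels)
    ssd_b = ssd_wg - ssd_wp
    ssd_a = ssd_total - ssd_wg
    N_g = np.array([sizes[groups == g].sum() for g in glabels])
    sum_npg2_over_Ng = sum((sizes[groups == g] ** 2).sum() / N_g[i]
                           for i, g in enumerate(glabels))
    n_c = (N - sum_npg2_over_Ng) / (P - G)
    n_p = (sum_npg2_over_Ng - np.sum(sizes**2) / N) / (G - 1)
    n_pp = (N - np.sum(N_g**2) / N) / (G - 1)
    sigma_b = (ssd_b / (P - G) - sigma_c) / n_c
    sigma_a = (ssd_a / (G - 1) - sigma_c - n_p * sigma_b) / n_pp
    return {"among_groups": sigma_a, "among_pops_within_groups": sigma_b,
            "within_pops": sigma_c}


def genotypes_from_copies(copies_by_pop: list[np.ndarray], locus: str = "L0") -> GenotypeTable:
    """Pack per-population copy lists (even length each) into a genotype table."""
    inds, pops, rows = [], [], []
    for k, copies in enumerate(copies_by_pop):
        c = np.asarray(copies, dtype=float)
        assert len(c) % 2 == 0
        for j in range(len(c) // 2):
            inds.append(f"p{k}_i{j}")
            pops.append(f"p{k}")
            rows.append([c[2 * j], c[2 * j + 1]])
    return GenotypeTable(inds, pops, [locus], np.asarray(rows)[:, None, :])


def random_copy_fixture(rng: np.random.Generator, max_pops: int = 5,
                        max_copies: int = 12) -> list[np.ndarray]:
    """Random small per-population copy sets (even sizes, >= 4 copies)."""
    P = rng.integers(2, max_pops + 1)
    out = []
    for _ in range(P):
        n = 2 * int(rng.integers(2, max_copies // 2 + 1))
        out.append(rng.integers(8, 15, size=n).astype(float))
    return out


# ---------------------------------------------------------------------------
# Fixtures
# ---------------------------------------------------------------------------


@pytest.fixture(scope="session")
def founder_fixture() -> tuple:
    """Small serial-founder dataset reused across tests (10 demes)."""
    params = SimParams(n_demes=10, deme_size=80, founder_size=8, mu=5e-3,
                       n_loci=30, sample_size=20, seed=123,
                       burn_in_generations=400, generations_between_foundings=8,
                       demes_per_group=2)
    return simulate_serial_founder(params)


@pytest.fixture()
def tiny_genotypes() -> GenotypeTable:
    calls = np.array([
        [[8, 8], [10, 12]],
        [[8, 10], [10, 10]],
        [[8, 8], [12, 12]],
        [[10, 10], [10, 12]],
        [[8, 10], [12, 12]],
        [[10, 10], [10, 10]],
    ], dtype=float)
    return GenotypeTable([f"i{j}" for j in range(6)],
                         ["A", "A", "A", "B", "B", "B"],
                         ["L1", "L2"], calls)


@pytest.fixture()
def small_metadata() -> PopulationMetadata:
    df = pd.DataFrame({
        "population": ["A", "B", "C"],
        "name": ["Pop A", "Pop B", "Pop C"],
        "group": ["G1", "G1", "G2"],
        "lat": [9.0, 30.0, 52.0],
        "lon": [38.7, 31.2, -106.0],
        "region": ["SAF", "NAF", "NAM"],
        "well_defined": [True, True, True],
    }).set_index("population")
    return PopulationMetadata(df)
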