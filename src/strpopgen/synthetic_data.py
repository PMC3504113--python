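"""Synthetic STR datasets with the structure the analyses assume.

Two generators:

* :func:`simulate_serial_founder` — a forward-time Wright–Fisher simulator
  under the strict stepwise mutation model.  Demes are founded sequentially
  along a line, each from a bottleneck sample of the previous deme, and then
  evolve in parallel until sampling.  Cumulative founder effects produce the
  canonical serial-founder signature: expected heterozygosity and repeat
  variance decline with distance from the origin deme, and contiguous blocks
  of demes form geographic groups with among-group structure.

* :func:`simulate_balding_nichols` — population allele frequencies drawn
  from the Balding–Nichols compound-Dirichlet around an ancestral spectrum
  with differentiation parameter F, then multinomially sampled to a finite
  number of gene copies.  Used for analytic parameter-recovery checks of the
  fixation-index estimators.

Internally the Wright–Fisher state is the allele *count* spectrum per deme x
locus over a bounded repeat grid (reflecting boundary at repeat 1 and at the
grid ceiling); one generation is a multinomial resampling of 2N copies
followed by binomial +/-1 stepwise mutation.  This is the exact individual-
copy model, just book-kept by counts.  Loci are simulated independently
(no linkage), which is immaterial for the single-locus and summed-over-loci
statistics computed downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .str_io import FrequencyTable, GenotypeTable, PopulationMetadata

__all__ = [
    "SimParams",
    "BNParams",
    "simulate_serial_founder",
    "simulate_balding_nichols",
    "build_ascertainment_pool",
]

KM_PER_DEGREE = 111.19  # great-circle km per degree at the equator, R = 6371 km


@dataclass
class SimParams:
    """Parameters of the serial-founder Wright–Fisher simulation.

    mu may be a scalar (shared by all loci) or a length-n_loci array of
    per-locus single-step mutation rates; heterogeneous rates give the locus
    pool the spread in diversity that marker-ascertainment experiments need.
    burn_in_generations evolves the origin deme before the first founding so
    that standing diversity builds up from the monomorphic ancestral state
    (default 10 x deme_size).
    """

    n_demes: int = 30
    deme_size: int = 200          # diploid individuals per deme (N)
    founder_size: int = 20        # diploid founders seeding each new deme
    generations_between_foundings: int = 10
    mu: float | np.ndarray = 5e-3
    n_loci: int = 100
    ancestral_repeat: int = 20
    sample_size: int = 30         # diploid individuals sampled per deme
    seed: int = 0
    km_per_deme: float = 500.0
    burn_in_generations: int | None = None
    demes_per_group: int = 5
    #: optional per-locus allele-range width (number of allowed repeat
    #: states, centred on ancestral_repeat, reflecting at both ends); None
    #: leaves the full grid [1, 2 x ancestral_repeat].  Real STR loci have
    #: characteristic bounded allele ranges; saturation of a bounded range
    #: caps both heterozygosity and among-population divergence.
    range_width: int | np.ndarray | None = None

    def __post_init__(self) -> None:
        counts = (self.n_demes, self.deme_size, self.founder_size, self.n_loci,
                  self.ancestral_repeat, self.sample_size, self.generations_between_foundings)
        if any(int(c) != c or c < 1 for c in counts):
            raise ValueError("all counts must be integers >= 1")
        if self.founder_size > self.deme_size:
            raise ValueError("founder_size must not exceed deme_size")
        mu = np.asarray(self.mu, dtype=float)
        if (mu < 0).any() or (mu > 0.5).any():
            raise ValueError("mu must lie in [0, 0.5]")
        if self.sample_size > self.deme_size:
            raise ValueError("sample_size must not exceed deme_size")
        if self.burn_in_generations is None:
            self.burn_in_generations = 10 * self.deme_size


def _mutate(counts: np.ndarray, mu: np.ndarray, rng: np.random.Generator,
            bounds: tuple[np.ndarray, np.ndarray] | None = None) -> np.ndarray:
    """One round of +/-1 stepwise mutation on a count spectrum.

    Steps off either end of the allowed repeat range are reflected in place
    (a down step at the range floor leaves the copy there).  ``bounds``
    gives per-locus (lo, hi) state indices; None means the full grid.
    """
    m = rng.binomial(counts, mu)
    up = rng.binomial(m, 0.5)
    down = m - up
    out = counts - m
    if bounds is None:
        out[..., 1:] += up[..., :-1]
        out[..., -1] += up[..., -1]
        out[..., :-1] += down[..., 1:]
        out[..., 0] += down[..., 0]
        return out
    lo, hi = bounds
    D, L, A = counts.shape
    s = np.arange(A)
    up_t = np.minimum(s[None, :] + 1, hi[:, None])    # (L, A) target states
    down_t = np.maximum(s[None, :] - 1, lo[:, None])
    base = (np.arange(D * L).reshape(D, L, 1)) * A
    flat = np.bincount((base + up_t[None]).ravel(), weights=up.ravel(), minlength=D * L * A)
    flat += np.bincount((base + down_t[None]).ravel(), weights=down.ravel(), minlength=D * L * A)
    return out + flat.astype(np.int64).reshape(D, L, A)


def _wf_generation(counts: np.ndarray, two_n: int, mu: np.ndarray,
                   rng: np.random.Generator,
                   bounds: tuple[np.ndarray, np.ndarray] | None = None) -> np.ndarray:
    resampled = rng.multinomial(two_n, counts / two_n)
    return _mutate(resampled, mu, rng, bounds)


def _bottleneck(source: np.ndarray, n_sample_copies: int, two_n: int,
                rng: np.random.Generator) -> np.ndarray:
    """Found a deme: sample copies without replacement, then regrow to 2N."""
    n_loci = source.shape[0]
    founder = np.empty_like(source)
    for l in range(n_loci):
        founder[l] = rng.multivariate_hypergeometric(source[l], n_sample_copies)
    return rng.multinomial(two_n, founder / n_sample_copies)


def _simulate_deme_counts(params: SimParams, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Run the simulation; return (repeat grid values, counts per deme).

    counts has shape (n_demes, n_loci, n_states) and holds the final 2N
    copies of every deme (before sampling).
    """
    n_states = 2 * params.ancestral_repeat
    values = np.arange(1, n_states + 1, dtype=float)
    two_n = 2 * params.deme_size
    mu = np.asarray(params.mu, dtype=float)
    if mu.ndim == 0:
        mu = np.full(params.n_loci, float(mu))
    if mu.shape != (params.n_loci,):
        raise ValueError("mu must be a scalar or a length-n_loci array")
    mu_col = mu[:, None]

    bounds = None
    if params.range_width is not None:
        w = np.broadcast_to(np.asarray(params.range_width, dtype=int),
                            (params.n_loci,)).copy()
        if (w < 2).any():
            raise ValueError("range_width must be >= 2")
        lo_val = np.maximum(params.ancestral_repeat - (w - 1) // 2, 1)
        hi_val = np.minimum(lo_val + w - 1, n_states)
        bounds = (lo_val - 1, hi_val - 1)  # state indices

    counts = np.zeros((params.n_demes, params.n_loci, n_states), dtype=np.int64)
    counts[0, :, params.ancestral_repeat - 1] = two_n  # monomorphic ancestor
    active = 1
    for _ in range(params.burn_in_generations):
        counts[:1] = _wf_generation(counts[:1], two_n, mu_col, rng, bounds)
    for k in range(1, params.n_demes):
        counts[k] = _bottleneck(counts[k - 1], 2 * params.founder_size, two_n, rng)
        active = k + 1
        for _ in range(params.generations_between_foundings):
            counts[:active] = _wf_generation(counts[:active], two_n, mu_col, rng, bounds)
    return values, counts


def sample_deme_counts(params: SimParams) -> tuple[np.ndarray, np.ndarray]:
    """Simulate and draw the per-deme samples, returned as count spectra.

    Returns (repeat values, sampled counts of shape (n_demes, n_loci,
    n_states)); each deme x locus cell sums to 2 x sample_size.  This is the
    fast path for experiments that only need allele counts.
    """
    rng = np.random.default_rng(params.seed)
    values, counts = _simulate_deme_counts(params, rng)
    n_copies = 2 * params.sample_size
    sampled = np.empty_like(counts)
    for d in range(params.n_demes):
        for l in range(params.n_loci):
            sampled[d, l] = rng.multivariate_hypergeometric(counts[d, l], n_copies)
    return values, sampled


def locus_pool_params(seed: int, n_loci: int = 400) -> SimParams:
    """Study conditions for the marker-ascertainment locus pool.

    Emulates a genome-wide pool of tetranucleotide STRs typed on a
    structured set of populations: 12 demes in 4 contiguous groups from a
    serial-founder expansion, per-locus mutation rates log-uniform on
    [1e-2, 3e-2] per copy per generation and bounded allele ranges of 8-14
    repeat states (drift and mutation are desk-scaled: at N = 100 diploids
    these rates give theta of roughly 4-12, i.e. sample heterozygosity
    around 0.7 with locus-to-locus spread, as genome-wide tetra STR panels
    show).  The bounded ranges matter: loci near range saturation sit at
    their diversity ceiling, which is what lets high-He ascertainment
    compress across-population He variance and depress R_ST.
    """
    rng = np.random.default_rng(seed)
    mu = np.exp(rng.uniform(np.log(1e-2), np.log(3e-2), n_loci))
    widths = rng.integers(8, 15, n_loci)
    return SimParams(n_demes=12, deme_size=100, founder_size=50, mu=mu,
                     n_loci=n_loci, ancestral_repeat=20, sample_size=30,
                     generations_between_foundings=5, burn_in_generations=500,
                     demes_per_group=3, range_width=widths, seed=seed)


def _metadata_for_line(params: SimParams, pops: list[str]) -> PopulationMetadata:
    deg = params.km_per_deme / KM_PER_DEGREE
    rows = []
    for k, pop in enumerate(pops):
        rows.append({
            "population": pop,
            "name": f"Deme {k}",
            "group": f"G{k // params.demes_per_group:02d}",
            "lat": 0.0,
            "lon": min(k * deg, 179.9),
            "region": "LINE",
            "well_defined": True,
        })
    return PopulationMetadata(pd.DataFrame(rows).set_index("population"))


def simulate_serial_founder(params: SimParams) -> tuple[GenotypeTable, PopulationMetadata]:
    """Simulate the serial-founder expansion and sample genotypes per deme.

    Sampled copies are paired at random into diploid individuals (random
    union of gametes, consistent with the Wright–Fisher model, so samples
    are in Hardy–Weinberg proportions in expectation).  Metadata places the
    demes on an equatorial line ``km_per_deme`` apart, grouped in contiguous
    blocks of ``demes_per_group``.
    """
    rng = np.random.default_rng(params.seed)
    values, counts = _simulate_deme_counts(params, rng)
    n_copies = 2 * params.sample_size

    pops = [f"deme{k:02d}" for k in range(params.n_demes)]
    loci = [f"L{l:03d}" for l in range(params.n_loci)]
    individuals: list[str] = []
    population_of: list[str] = []
    calls = np.empty((params.n_demes * params.sample_size, params.n_loci, 2), dtype=float)
    row = 0
    for d, pop in enumerate(pops):
        for j in range(params.sample_size):
            individuals.append(f"{pop}_i{j:03d}")
            population_of.append(pop)
        block = slice(row, row + params.sample_size)
        for l in range(params.n_loci):
            drawn = rng.multivariate_hypergeometric(counts[d, l], n_copies)
            copies = np.repeat(values, drawn)
            rng.shuffle(copies)
            calls[block, l, :] = copies.reshape(params.sample_size, 2)
        row += params.sample_size
    table = GenotypeTable(individuals, population_of, loci, calls)
    return table, _metadata_for_line(params, pops)


# ---------------------------------------------------------------------------
# Balding–Nichols generator
# ---------------------------------------------------------------------------


@dataclass
class BNParams:
    """Balding–Nichols generation: per population and locus, allele
    frequencies ~ Dirichlet(ancestral x (1-F)/F), then a multinomial sample
    of n_copies gene copies.  ancestral may be None (symmetric Dirichlet(1)
    spectra over n_alleles alleles are drawn per locus) or a list of
    per-locus frequency vectors."""

    n_pops: int = 10
    F: float = 0.1
    n_loci: int = 100
    n_copies: int = 200
    n_alleles: int = 6
    ancestral: list[np.ndarray] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.F < 1.0:
            raise ValueError("F must be strictly inside (0, 1)")
        if self.ancestral is not None:
            if len(self.ancestral) != self.n_loci:
                raise ValueError("need one ancestral spectrum per locus")
            for p in self.ancestral:
                if abs(float(np.sum(p)) - 1.0) > 1e-8:
                    raise ValueError("ancestral frequencies must sum to 1")


def simulate_balding_nichols(params: BNParams) -> FrequencyTable:
    rng = np.random.default_rng(params.seed)
    if params.ancestral is None:
        ancestral = [rng.dirichlet(np.ones(params.n_alleles)) for _ in range(params.n_loci)]
    else:
        ancestral = [np.asarray(p, dtype=float) for p in params.ancestral]
    scale = (1.0 - params.F) / params.F
    pops = [f"pop{k:02d}" for k in range(params.n_pops)]
    loci = [f"L{l:03d}" for l in range(params.n_loci)]
    cells: dict[tuple[str, str], tuple[dict[float, float], int]] = {}
    for l, locus in enumerate(loci):
        anc = ancestral[l]
        alleles = np.arange(8, 8 + len(anc), dtype=float)
        for pop in pops:
            p = rng.dirichlet(np.maximum(anc, 1e-12) * scale)
            counts = rng.multinomial(params.n_copies, p)
            keep = counts > 0
            cells[(pop, locus)] = (
                {float(a): c / params.n_copies for a, c in zip(alleles[keep], counts[keep])},
                params.n_copies,
            )
    return FrequencyTable(pops, loci, cells)


# ---------------------------------------------------------------------------
# Ascertainment pool statistics
# ---------------------------------------------------------------------------


def build_ascertainment_pool(base: GenotypeTable, panel_pops: Sequence[str]) -> pd.Series:
    """Pooled-panel expected heterozygosity per locus.

    Pools all gene copies of the panel populations per locus and computes
    unbiased expected heterozygosity on the pooled sample — the quantity a
    forensic marker-ascertainment step would rank loci by.  Returns a Series
    indexed by locus, in dataset locus order.
    """
    panel = list(panel_pops)
    if not panel:
        raise ValueError("panel_pops must not be empty")
    unknown = set(panel) - set(base.populations)
    if unknown:
        raise ValueError(f"panel populations not in dataset: {sorted(unknown)}")
    idx = np.concatenate([base.individuals_in(p) for p in panel])
    he = {}
    for li, locus in enumerate(base.loci):
        copies = base.calls[idx, li, :].ravel()
        n = copies.size
        _, counts = np.unique(copies, return_counts=True)
        p = counts / n
        he[locus] = n / (n - 1) * (1.0 - float(np.sum(p * p)))
    return pd.Series(he, name="pooled_He").loc[list(base.loci)]
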