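# Methods

`strpopgen` reimplements, as a tested library, the statistical workflow used
to analyse worldwide forensic STR datasets: within-population diversity and
its geographic gradient, hierarchical analysis of molecular variance (AMOVA)
under stepwise or identity allele distances, spatial-structure ordination
and matrix correlation, and a marker-ascertainment experiment on locus
pools. This note documents the models, the estimators, the synthetic data
that stand in for the (non-redistributable) source databases, and the design
choices made where the design was genuinely open.

## Data model

STR alleles are identified by repeat count; imperfect alleles (e.g. TH01
9.3, a partial repeat) are carried as their literal decimal value in all
repeat-number arithmetic. Two data modes are supported and kept exactly
commensurable:

* **frequency mode** — per (population, locus) allele-frequency maps with a
  gene-copy count `n` (2 × individuals). Analyses that need copies
  reconstruct integer counts as `round(f·n)` reconciled by largest
  remainder; frequencies that came from integer counts are recovered
  exactly, and reconstruction error is otherwise ≤ 0.5 copy per allele.
* **genotype mode** — diploid repeat-number pairs per individual
  (GenePop interchange or a long CSV). The within-individual stratum is
  deliberately ignored (copies are exchangeable within populations), so a
  genotype table and its derived frequency table give *identical* AMOVA
  results; this is what makes the two modes comparable.

A `--drop-complex-loci` style option removes FGA, D21S11 and TH01 (the loci
with complex imperfect-repeat structure) for robustness runs.

## Diversity indices

* He, unbiased expected heterozygosity: `He = n/(n−1)·(1 − Σ p_i²)`, n in
  gene copies.
* Vp, sample variance (denominator n−1) of the repeat value over copies;
  the frequency path `Vp = n/(n−1)·(Σ f_a a² − (Σ f_a a)²)` equals the copy
  path exactly for integral counts.
* Group summaries are means ± SD *over member populations* of per-population
  means over loci. Among-group differences use Kruskal–Wallis (tie-corrected,
  chi-square p) and pairwise two-sided Wilcoxon rank-sum tests with
  Bonferroni correction `min(1, p·#pairs)`.

Hardy–Weinberg equilibrium is tested per population × locus with a
Monte-Carlo exact test: the observed allele copies are re-paired at random
(default 10,000 draws; seeded), the statistic is Levene's conditional
probability of the genotype array given the allele counts, and
`p = (#{arrays no more probable than observed}+1)/(draws+1)`, so p has floor
`1/(draws+1)`. Direction (heterozygote excess/deficit) compares the observed
heterozygote count with its random-pairing expectation. Monomorphic cells
report p = 1 with undefined direction.

## Geography

Distances are great circles on a sphere of radius 6371 km (haversine; no
ellipsoid — at continental resolution the difference is irrelevant).
Cross-landmass distances pass through obligatory migration-gateway
waypoints: Anadyr, Cairo, Istanbul, Phnom Penh, Prince Rupert. For example,
North America → East Africa is population → Anadyr → Cairo → destination.
The shipped region→landmass→route table is a documented assumption (the
exact insertion rules for every pair are not published) and is fully
overridable in configuration; an unresolvable region raises a routing error
rather than silently falling back to the direct distance. The expansion
origin defaults to Addis Ababa (9.03 N, 38.74 E). The diversity–distance
relation is ordinary least squares with R² and a two-sided t-test on the
slope.

## AMOVA

Allele copies are the units. For a pool of copies the sum of squared
deviations is `SSD = (1/2n)·ΣΣ d(i,j)` with `d(i,j) = (a_i − a_j)²`
(stepwise; gives R statistics) or 0/1 identity (gives F statistics). The
implementation works on allele-count matrices — for the stepwise model the
within-pool SSD reduces to the sum of squared deviations of repeat values
from the pool mean — and is verified against a brute-force oracle that
builds the explicit copy-by-copy distance matrix (agreement to 1e-9 on
random fixtures).

Two-level design (populations/within): `df = P−1, N−P`;
`σ²_w = MS_within`; `σ²_a = (MS_among − σ²_w)/n'`,
`n' = (N − Σn_k²/N)/(P−1)`; index `ST = σ²_a/(σ²_a+σ²_w)`.

Three-level design (groups/populations-within-groups/within) uses the
standard expected-mean-square coefficients

```
n   = (N − Σ_g Σ_p n_pg²/N_g)/(P−G)
n'  = (Σ_g Σ_p n_pg²/N_g − Σ n_pg²/N)/(G−1)
n'' = (N − Σ_g N_g²/N)/(G−1)
```

solved top-down for σ²_c, σ²_b, σ²_a, with indices `CT = σ²_a/σ²_T`,
`SC = σ²_b/(σ²_b+σ²_c)`, `ST = (σ²_a+σ²_b)/σ²_T`. Negative variance-
component estimates are reported as computed (only the Reynolds transform
clamps). One population per group leaves the σ²_b stratum with zero degrees
of freedom and is flagged degenerate.

Multi-locus indices sum locus-specific components over loci and recompute
the ratios. Significance comes from permutation tests (default 10,000
iterations), `p = (#{perm ≥ obs}+1)/(B+1)` so p never reaches 0 before
Fisher combination. Permutation schemes per index: copies among populations
(frequency mode) or whole individuals among populations (genotype mode) for
ST; individuals/copies among populations *within* groups for SC; whole
populations among groups for CT. Per-locus p-values can be combined with
Fisher's method (`χ² = −2Σln p` on 2k df).

Pairwise population matrices apply the two-level multi-locus analysis to
every pair; Reynolds coancestry distances are `D = −ln(1−θ)` with θ clamped
to `[0, 1)` (θ ≥ 1 maps to a finite cap, default 25, to keep ordination
input finite).

## Spatial structure

Nonmetric MDS (rank-based, Kruskal stress-1) in two dimensions, best of 16
seeded random starts, via scikit-learn's SMACOF; nonmetric rather than
classical scaling because stress is the quantity reported for such
analyses. Outliers are removed only by explicit exclusion list. The Mantel
test correlates off-diagonal upper triangles (Pearson r), with significance
from joint row/column permutation of the second matrix, one-tailed for
positive association (the isolation-by-distance hypothesis).

## Synthetic data

No analysed genotypes or frequencies are redistributable, so generators
provide data with the structural features the analyses assume.

**Serial-founder Wright–Fisher simulator.** Haploid-copy Wright–Fisher
resampling (2N copies per deme) with strict single-step symmetric mutation
(±1 repeat, rate μ per copy per generation) on a bounded repeat grid with
reflecting ends; the state is the allele-count spectrum, which is the exact
copy-level model book-kept by counts. Demes are founded sequentially along
a line, each from a without-replacement sample of 2·founder_size copies of
the previous deme, then all demes evolve in parallel to a common end time;
loci are independent (no linkage, recombination, selection or admixture —
immaterial for the statistics computed, all of which are single-locus or
sums over loci). Coordinates place demes on an equatorial line, groups are
contiguous blocks. Defaults are the gradient study conditions: 30 demes,
N = 200 diploids, 20 founders, μ = 5e-3, 100 loci, 30 sampled individuals
per deme. The origin deme burns in for 10N generations from the monomorphic
ancestral state (near mutation-drift equilibrium, θ = 4Nμ ≈ 4, He ≈ 0.65);
foundings are 10 generations apart — colonization fast relative to the
mutation-drift recovery timescale, which is the regime a serial founder
effect describes (with long inter-founding intervals each deme
re-equilibrates and the gradient washes out). Under these conditions He
declines strongly along the line (Spearman ρ ≈ −0.9).

**Balding–Nichols generator.** Population allele frequencies drawn from
Dirichlet(ancestral × (1−F)/F) and multinomially sampled to n copies; used
to verify that the identity-model multi-locus estimator recovers F (bias
< 0.02 at F ∈ {0.05, 0.1, 0.2} with 400 loci). Per-locus expected
heterozygosity is (1−F)·He_ancestral, checked by averaging over loci.

**Ascertainment locus pools** (`locus_pool_params`) emulate a genome-wide
tetranucleotide STR pool typed on structured populations: 12 demes in 4
groups from a serial-founder expansion (N = 100, 50 founders, 5 generations
between foundings, burn-in 500), per-locus mutation rates log-uniform on
[1e-2, 3e-2] and per-locus allele ranges of 8–14 repeat states. Rates are
desk-scaled: at N = 100 they give θ ≈ 4–12, i.e. sample He around 0.7 with
locus-to-locus spread, matching genome-wide tetra-STR panels; it is θ, not
μ, that matters. The bounded ranges are the load-bearing realism: loci near
range saturation sit at their diversity ceiling, so selecting the top-He
panel both compresses the across-population variance of He and depresses
multi-locus R_ST relative to random panels — the mechanism by which
forensic marker choice understates population structure. Two modelling
points matter for reproducing it: (i) panels must be ranked by the
*unweighted mean of per-sample He* — ranking by He of copies pooled across
populations contaminates the criterion with the among-population component
and inverts the R_ST comparison; (ii) with unbounded allele ranges the
stepwise index is essentially mutation-rate-invariant and the R_ST side of
the mechanism disappears.

What the generators do **not** emulate: linkage, mutational complexity
beyond single steps (no multi-step or length-dependent mutation, no true
imperfect-allele process), admixture, real geography. Passing tests
therefore show that the *estimators and the mechanism* behave as described
under the stated model, not that any particular real-world value is
reproduced.

## Validation experiments and problem sizes

`strpopgen.validation` (driven by `scripts/acceptance.py` and the
acceptance tests) recomputes: oracle agreement on 25 random small fixtures;
cross-mode agreement on a 6-deme dataset; the closed-form limits; BN
recovery at 400 loci; the 30-deme gradient; the ascertainment mechanism
over 100 replicate pools with 50 random panels each; and type-I rates at
500 replicates per procedure (99 permutations / 199 HWE draws per
replicate, small fixtures). These sizes were chosen so the full battery
runs in a few minutes on one core while keeping Monte-Carlo error well
inside the asserted bands (e.g. binomial SE ≈ 1% for a 5% rate at 500
replicates).

## Numerical choices and degenerate inputs

* Frequency sums are validated to 1e-3 (published tables are rounded; the
  tolerance is flagged in validation errors).
* Tie-breaking in locus ranking is alphabetical by locus name; random
  panels are seeded.
* Permutation and Monte-Carlo p-values use the (x+1)/(B+1) estimator;
  statistic comparisons use a 1e-12 tolerance so exact ties count.
* Degenerate cases: monomorphic HWE cells (p = 1, no direction), constant
  Kruskal–Wallis input (H = 0, p = 1), zero-variance Mantel or regression
  input (explicit errors), all-equal Levene samples (explicit error),
  one-population-per-group AMOVA (flagged, σ²_b undefined).
* One global seed per run is split deterministically per stage
  (`numpy.random.SeedSequence`); equal seeds give byte-identical outputs.

## Known limitations

* Frequency-mode permutation tests shuffle *reconstructed* copies, so their
  null distribution inherits the (≤ 0.5 copy per allele) rounding of
  published frequency tables.
* No within-individual inbreeding stratum (F_IS), by design.
* The waypoint routing table is a plausible default, not a published
  standard; analyses sensitive to it should override it in configuration.
* The forward simulator is desk-scale; absolute values of He, Vp and R_ST
  depend on the scaled parameters and are not calibrated to any particular
  empirical dataset.
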