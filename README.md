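# strpopgen

Population-genetic structure analysis for forensic-style STR (microsatellite)
datasets.

Forensic genetics has produced worldwide collections of STR data — allele
frequency tables and genotype profiles at the 13 CODIS loci — far larger in
samples and individuals than most datasets assembled to study human
diversity. `strpopgen` implements the statistical toolkit needed to mine
such data for population structure, and to quantify the *ascertainment
bias* built into them: forensic markers are chosen to be maximally
discriminating (high heterozygosity), which compresses the variance of
heterozygosity across populations and depresses fixation-index estimates of
population differentiation.

The package covers:

* **Diversity** — unbiased expected heterozygosity
  `He = n/(n−1)(1 − Σp_i²)`, repeat-number variance `Vp`, group summaries,
  Kruskal–Wallis and Bonferroni-corrected Wilcoxon comparisons, Monte-Carlo
  exact Hardy–Weinberg tests.
* **Geographic gradients** — great-circle distances with obligatory
  migration-gateway waypoints (Anadyr, Cairo, Istanbul, Phnom Penh, Prince
  Rupert) and OLS regression of diversity on distance from an origin
  (default Addis Ababa), the serial-founder-effect signature.
* **AMOVA** — two- and three-level analysis of molecular variance with
  stepwise (`R_ST`, `R_SC`, `R_CT`) or identity (`F_ST`) allele distances,
  from genotypes *or from allele frequencies alone* (exact integer-count
  reconstruction), multi-locus variance-component summation, permutation
  tests, Fisher's combined probability, pairwise matrices and Reynolds
  distances `D = −ln(1−θ)`.
* **Spatial structure** — nonmetric MDS (Kruskal stress-1) and one-tailed
  Mantel tests of genetic vs geographic distances.
* **Ascertainment experiments** — rank loci by heterozygosity, extract
  extreme panels, and compare their He variance and multi-locus R_ST
  against random panels.
* **Synthetic data** — a forward Wright–Fisher serial-founder simulator
  under strict stepwise mutation (with bounded allele ranges) and a
  Balding–Nichols frequency generator, so every stage is testable without
  any database download.

See `docs/methods.md` for models, estimator formulas and design choices.

## Worked example

Simulate a 10-deme serial-founder expansion and analyse its structure:

```python
import numpy as np
from scipy import stats
import strpopgen as sg

params = sg.SimParams(n_demes=10, deme_size=80, founder_size=8, mu=5e-3,
                      n_loci=30, sample_size=20, seed=123,
                      burn_in_generations=400, generations_between_foundings=8,
                      demes_per_group=2)
genotypes, meta = sg.simulate_serial_founder(params)

# diversity gradient
div = sg.diversity_table(genotypes)
dists = sg.geodistance.distances_from_origin(meta, meta.coords("deme00"), "LINE")
reg = sg.diversity_distance_regression(div.per_population["He"].to_dict(), dists)
print(f"He slope {reg.slope:.3e} per km, R^2 {reg.r_squared:.3f}, p {reg.p:.2e}")

# hierarchical AMOVA
hier = sg.HierarchyConfig.from_metadata(meta)
per_locus, combined = sg.amova.amova(genotypes, hier, "stepwise")
print({k: round(v, 4) for k, v in combined.indices.items()})
p = sg.permutation_test(genotypes, "ST", hierarchy=hier, n_perm=999, seed=1).p
print(f"R_ST permutation p = {p:.4f}")
```

prints

```
He slope -3.332e-05 per km, R^2 0.710, p 2.20e-03
{'CT': 0.0312, 'SC': 0.2213, 'ST': 0.2455}
R_ST permutation p = 0.0010
```

i.e. heterozygosity declines significantly along the expansion axis
(distance explains ~71% of the He variation in this small fixture), and
about 24.6% of the molecular variance lies among demes — mostly among
neighbouring demes within the contiguous two-deme groups (R_SC 0.22)
rather than among the groups themselves — highly significant by
permutation.

The same analyses run from the shell:

```sh
strpopgen simulate founder --demes 10 --loci 30 --outdir sim/
strpopgen amova sim/genotypes.csv sim/metadata.csv --mode genotype
strpopgen run --config analysis.yaml     # full pipeline, YAML-configured
```

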