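"""Config-driven orchestration of the full analysis workflow.

``run_all`` sequences the stages the analyses comprise — validation,
within-population diversity and group tests, distance-from-origin
regressions, hierarchical AMOVA with permutation significance, pairwise
fixation indices and Reynolds distances, nonmetric MDS and the Mantel test
— writing every table to the output directory plus a JSON summary.  A
single global seed is split deterministically per stage, so a rerun with
the same config and seed is byte-identical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import amova as am
from . import ascertainment as asc
from . import diversity as dv
from . import geodistance as gd
from . import spatial_structure as sp
from . import str_io

__all__ = ["RunConfig", "run_all"]


@dataclass
class RunConfig:
    data: str
    metadata: str
    mode: str = "frequency"              # "frequency" | "genotype"
    outdir: str = "strpopgen_out"
    loci: list[str] | None = None
    drop_loci: list[str] = field(default_factory=list)
    model: str = "stepwise"
    group_order: list[str] | None = None
    origin: tuple[float, float] = gd.ADDIS_ABABA
    origin_region: str = "SAF"
    permutations_amova: int = 10000
    permutations_mantel: int = 1000
    pairwise_permutations: int = 0
    mds_starts: int = 16
    mds_exclude: list[str] = field(default_factory=list)
    include_not_well_defined: bool = False
    hwe: bool = True
    hwe_draws: int = 10000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("frequency", "genotype"):
            raise ValueError("mode must be 'frequency' or 'genotype'")
        if self.permutations_amova < 1 or self.permutations_mantel < 1:
            raise ValueError("permutation counts must be >= 1")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "origin" in raw:
            raw["origin"] = tuple(raw["origin"])
        return cls(**raw)


def _stage_seeds(seed: int, names: Sequence[str]) -> dict[str, int]:
    states = np.random.SeedSequence(seed).generate_state(len(names))
    return {n: int(s % (2**31)) for n, s in zip(names, states)}


def run_all(config: RunConfig) -> dict:
    """Run every stage on the configured dataset; returns the summary dict
    (also written to ``summary.json`` in the output directory)."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed, ["hwe", "amova", "pairwise", "mds", "mantel"])
    summary: dict = {"seed": config.seed, "stage_seeds": seeds, "mode": config.mode}

    # --- load and filter ---------------------------------------------------
    meta = str_io.read_metadata(config.metadata)
    if config.mode == "frequency":
        data = str_io.read_frequency_table(config.data)
    else:
        if str(config.data).endswith(".csv"):
            data = str_io.read_genotypes_csv(config.data)
        else:
            res = str_io.read_genotypes_genepop(config.data)
            data = res.table
            summary["dropped_individuals"] = res.n_dropped
    if config.loci:
        keep = set(data.loci) - (set(data.loci) - set(config.loci))
        data = str_io.drop_loci(data, [l for l in data.loci if l not in keep])
    if config.drop_loci:
        data = str_io.drop_loci(data, config.drop_loci)
    pops = [p for p in data.populations if p in meta.populations]
    if not config.include_not_well_defined:
        pops = [p for p in pops if meta.well_defined(p)]
    if config.mode == "frequency":
        cells = {(p, l): data.cells[(p, l)] for p in pops for l in data.loci}
        data = str_io.FrequencyTable(pops, list(data.loci), cells)
    else:
        idx = np.concatenate([data.individuals_in(p) for p in pops])
        data = str_io.GenotypeTable([data.individuals[i] for i in idx],
                                    [data.population_of[i] for i in idx],
                                    list(data.loci), data.calls[idx])
    meta = meta.restrict(pops)
    hierarchy = str_io.HierarchyConfig.from_metadata(meta, pops, config.group_order)
    summary["n_populations"] = len(pops)
    summary["n_loci"] = len(data.loci)

    # --- diversity ---------------------------------------------------------
    dtab = dv.diversity_table(data)
    dtab.per_locus.to_csv(out / "diversity_per_locus.tsv", sep="\t", index=False)
    dtab.per_population.to_csv(out / "diversity_per_population.tsv", sep="\t")
    gsum = dv.group_summary(dtab, hierarchy)
    gsum.to_csv(out / "diversity_groups.tsv", sep="\t")
    group_tests = {}
    for index in ("He", "Vp"):
        t = dv.group_tests(dtab, hierarchy, index)
        t["pairwise_wilcoxon"].to_csv(out / f"wilcoxon_{index}.tsv", sep="\t")
        group_tests[index] = {"kruskal_H": t["kruskal_H"], "kruskal_p": t["kruskal_p"]}
    summary["group_tests"] = group_tests

    if config.mode == "genotype" and config.hwe:
        hwe = dv.hwe_all(data, config.hwe_draws, seeds["hwe"])
        hwe.to_csv(out / "hwe_tests.tsv", sep="\t", index=False)
        summary["hwe"] = dv.hwe_rejection_summary(hwe, len(data.loci))

    # --- distance from origin and regressions ------------------------------
    wcfg = gd.WaypointConfig()
    dists = gd.distances_from_origin(meta, config.origin, config.origin_region, wcfg)
    with open(out / "distance_from_origin.tsv", "w") as fh:
        fh.write("population\tkm\n")
        for p in pops:
            fh.write(f"{p}\t{dists[p]:.3f}\n")
    regressions = {}
    for index in ("He", "Vp"):
        vals = dtab.per_population[index].to_dict()
        r = gd.diversity_distance_regression(vals, dists)
        regressions[index] = asdict(r)
    summary["regressions"] = regressions

    # --- AMOVA -------------------------------------------------------------
    per_locus, combined = am.amova(data, hierarchy, config.model)
    pd.concat([r.to_frame() for r in [*per_locus, combined]]).to_csv(
        out / "amova.tsv", sep="\t", index=False)
    amova_block = {
        "indices": combined.indices,
        "percent": combined.percentages,
        "sigma": combined.sigma,
    }
    perm_seeds = _stage_seeds(seeds["amova"], ["ST", "SC", "CT"])
    for statistic in ("ST", "SC", "CT"):
        res = am.permutation_test(data, statistic, None, hierarchy, config.model,
                                  n_perm=config.permutations_amova,
                                  seed=perm_seeds[statistic])
        amova_block[f"p_{statistic}"] = res.p
    locus_ps = []
    locus_seeds = _stage_seeds(seeds["amova"] + 1, list(data.loci))
    for locus in data.loci:
        res = am.permutation_test(data, "ST", None, hierarchy, config.model,
                                  [locus], n_perm=min(config.permutations_amova, 999),
                                  seed=locus_seeds[locus])
        locus_ps.append(res.p)
    chi2, dof, p_comb = am.fisher_combine(locus_ps)
    amova_block["fisher_combined"] = {"chi2": chi2, "df": dof, "p": p_comb,
                                      "per_locus_p": dict(zip(data.loci, locus_ps))}
    summary["amova"] = amova_block

    # --- pairwise indices, Reynolds, MDS, Mantel ---------------------------
    pw, pmat = am.pairwise_matrix(data, config.model,
                                  n_perm=config.pairwise_permutations,
                                  seed=seeds["pairwise"])
    pw.to_tsv(out / "pairwise_index.tsv")
    if pmat is not None:
        pmat.to_csv(out / "pairwise_index_p.tsv", sep="\t")
    reyn = am.reynolds_transform(pw)
    reyn.to_tsv(out / "reynolds.tsv")

    mds = sp.nmds(reyn, config.mds_starts, seeds["mds"], config.mds_exclude)
    with open(out / "mds_coordinates.tsv", "w") as fh:
        fh.write("population\tdim1\tdim2\n")
        for p, (x, y) in zip(mds.populations, mds.coordinates):
            fh.write(f"{p}\t{x:.6f}\t{y:.6f}\n")
    summary["mds"] = {"stress": mds.stress, "excluded": mds.excluded,
                      "n_starts": mds.n_starts}

    geo = gd.pairwise_geo_matrix(meta, wcfg, pops)
    geo.to_tsv(out / "geographic_distance.tsv")
    man = sp.mantel(reyn.exclude(config.mds_exclude) if config.mds_exclude else reyn,
                    geo.exclude(config.mds_exclude) if config.mds_exclude else geo,
                    config.permutations_mantel, seeds["mantel"])
    summary["mantel"] = {"r": man.r, "p": man.p, "n_perm": man.n_perm}

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=float)
    return summary
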