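"""Diversity indices, group comparisons and Hardy–Weinberg testing."""

import itertools
import math

import numpy as np
import pytest
from scipy.special import gammaln

from strpopgen import diversity as dv
from strpopgen.str_io import GenotypeTable, HierarchyConfig, frequencies_from_genotypes


class TestHe:
    def test_monomorphic_zero(self):
        assert dv.expected_heterozygosity({8.0: 1.0}, 50) == 0.0

    def test_unbiased_form(self):
        he = dv.expected_heterozygosity({8.0: 0.5, 10.0: 0.5}, 100)
        assert he == pytest.approx(100 / 99 * 0.5)
        assert he == pytest.approx(0.505051, abs=1e-6)

    def test_uniform_four_alleles_limit(self):
        he = dv.expected_heterozygosity({a: 0.25 for a in (8., 9., 10., 11.)}, 10**7)
        assert he == pytest.approx(0.75, abs=1e-5)

    def test_relabeling_invariance(self):
        a = dv.expected_heterozygosity({8.0: 0.3, 9.0: 0.7}, 40)
        b = dv.expected_heterozygosity({21.0: 0.3, 5.3: 0.7}, 40)
        assert a == b

    def test_needs_two_copies(self):
        with pytest.raises(ValueError):
            dv.expected_heterozygosity({8.0: 1.0}, 1)


class TestVp:
    def test_hand_computation(self):
        assert dv.repeat_variance(np.array([8, 8, 10, 10.0])) == pytest.approx(4 / 3)

    def test_constant_copies_zero(self):
        assert dv.repeat_variance(np.full(6, 9.3)) == pytest.approx(0.0, abs=1e-12)

    def test_frequency_path_equals_copy_path(self):
        assert dv.repeat_variance({8.0: 0.5, 10.0: 0.5}, 4) == pytest.approx(4 / 3)
        rng = np.random.default_rng(0)
        for _ in range(10):
            copies = rng.integers(5, 20, size=2 * rng.integers(2, 10)).astype(float)
            values, counts = np.unique(copies, return_counts=True)
            freqs = dict(zip(values, counts / len(copies)))
            assert dv.repeat_variance(freqs, len(copies)) == pytest.approx(
                dv.repeat_variance(copies), abs=1e-9)

    def test_shift_invariance(self):
        copies = np.array([8, 9, 11, 14.0])
        assert dv.repeat_variance(copies + 7) == pytest.approx(dv.repeat_variance(copies))


class TestTables:
    def test_genotype_and_derived_frequency_tables_agree(self, founder_fixture):
        table, _ = founder_fixture
        ft = frequencies_from_genotypes(table)
        dg = dv.diversity_table(table).per_locus.set_index(["population", "locus"])
        df = dv.diversity_table(ft).per_locus.set_index(["population", "locus"])
        assert np.allclose(dg["He"], df["He"]) and np.allclose(dg["Vp"], df["Vp"])
        assert (dg["k"] == df["k"]).all()

    def test_group_summary_bounds_and_order(self, founder_fixture):
        table, meta = founder_fixture
        hier = HierarchyConfig.from_metadata(meta)
        d = dv.diversity_table(table)
        gs = dv.group_summary(d, hier)
        assert list(gs.index) == hier.group_order
        for group in gs.index:
            members = [p for p, g in hier.assignment.items() if g == group]
            vals = d.per_population.loc[members, "He"]
            assert vals.min() - 1e-12 <= gs.loc[group, "mean_He"] <= vals.max() + 1e-12

    def test_group_means_decline_along_founder_line(self, founder_fixture):
        table, meta = founder_fixture
        hier = HierarchyConfig.from_metadata(meta)
        gs = dv.group_summary(dv.diversity_table(table), hier)
        means = gs["mean_He"].to_numpy()
        assert means[0] > means[-1]  # origin block more diverse than far end


class TestRankTests:
    def test_kruskal_degenerate_constant(self):
        h, p = dv.kruskal_wallis({"a": [1.0, 1.0], "b": [1.0, 1.0]})
        assert h == 0.0 and p == 1.0

    def test_identical_groups_nonsignificant(self):
        vals = list(np.linspace(0, 1, 12))
        h, p = dv.kruskal_wallis({"a": vals, "b": vals})
        assert p > 0.9

    def test_kruskal_type_one_error(self):
        rng = np.random.default_rng(5)
        rej = 0
        reps = 1000
        for _ in range(reps):
            groups = {g: rng.normal(size=10) for g in "abc"}
            _, p = dv.kruskal_wallis(groups)
            rej += p <= 0.05
        assert 0.03 <= rej / reps <= 0.07

    def test_wilcoxon_bonferroni_properties(self):
        rng = np.random.default_rng(6)
        groups = {g: rng.normal(size=8) for g in "abcd"}
        adj = dv.pairwise_wilcoxon(groups)
        raw = dv.pairwise_wilcoxon(groups, correction=None)
        n_pairs = 6
        for a, b in itertools.combinations("abcd", 2):
            assert adj.loc[a, b] == adj.loc[b, a]
            assert adj.loc[a, b] >= raw.loc[a, b] - 1e-15
            assert adj.loc[a, b] <= 1.0
            assert adj.loc[a, b] == pytest.approx(min(1.0, raw.loc[a, b] * n_pairs))

    def test_two_groups_no_adjustment(self):
        rng = np.random.default_rng(7)
        groups = {"a": rng.normal(size=9), "b": rng.normal(size=9)}
        adj = dv.pairwise_wilcoxon(groups)
        raw = dv.pairwise_wilcoxon(groups, correction=None)
        assert adj.loc["a", "b"] == raw.loc["a", "b"]

    def test_wilcoxon_power_on_shifted_groups(self):
        rng = np.random.default_rng(8)
        hits = 0
        reps = 200
        for _ in range(reps):
            groups = {"a": rng.normal(0, 1, 20), "b": rng.normal(2, 1, 20)}
            p = dv.pairwise_wilcoxon(groups).loc["a", "b"]
            hits += p < 0.05
        assert hits / reps >= 0.95


def _hw_pop(rng, n_ind, freqs, alleles=(8., 9., 10., 11.)):
    copies = rng.choice(alleles, size=(n_ind, 1, 2), p=freqs)
    return GenotypeTable([f"i{j}" for j in range(n_ind)], ["P"] * n_ind,
                         ["L0"], copies)


class TestHwe:
    def test_monomorphic(self):
        g = GenotypeTable(["i0", "i1", "i2"], ["P"] * 3, ["L0"], np.full((3, 1, 2), 9.0))
        r = dv.hwe_test(g, "P", "L0", 100, 0)
        assert r.p == 1.0 and r.direction is None

    def test_all_heterozygous_excess(self):
        calls = np.tile(np.array([[8.0, 10.0]]), (50, 1))[:, None, :]
        g = GenotypeTable([f"i{j}" for j in range(50)], ["P"] * 50, ["L0"], calls)
        r = dv.hwe_test(g, "P", "L0", 2000, 3)
        assert r.direction == "excess"
        assert r.p < 0.01

    def test_against_exact_enumeration_two_alleles(self):
        # 4 individuals, allele counts 4/4: enumerate all pairings by their
        # heterozygote count h in {0, 2, 4}; conditional P(h) follows
        # Levene's formula.  The MC p for the all-het array must match the
        # exact tail probability of arrays no more probable than it.
        def levene_prob(h, n=4, na=4, nb=4):
            # genotype counts: haa=(na-h)/2, hbb=(nb-h)/2
            num = (gammaln(n + 1) + h * math.log(2) + gammaln(na + 1) + gammaln(nb + 1))
            den = (gammaln(2 * n + 1) + gammaln((na - h) / 2 + 1)
                   + gammaln((nb - h) / 2 + 1) + gammaln(h + 1))
            return math.exp(num - den)
        probs = {h: levene_prob(h) for h in (0, 2, 4)}
        assert sum(probs.values()) == pytest.approx(1.0)
        p_allhet_exact = sum(v for h, v in probs.items()
                             if probs[h] <= probs[4] + 1e-12)
        calls = np.tile(np.array([[8.0, 10.0]]), (4, 1))[:, None, :]
        g = GenotypeTable([f"i{j}" for j in range(4)], ["P"] * 4, ["L0"], calls)
        r = dv.hwe_test(g, "P", "L0", 20000, 1)
        assert r.p == pytest.approx(p_allhet_exact, abs=0.02)

    def test_type_one_error_under_hw(self):
        rng = np.random.default_rng(21)
        rej = 0
        reps = 400
        for _ in range(reps):
            g = _hw_pop(rng, 30, [0.4, 0.3, 0.2, 0.1])
            r = dv.hwe_test(g, "P", "L0", 199, int(rng.integers(2**31)))
            rej += r.p <= 0.05
        assert 0.03 <= rej / reps <= 0.07

    def test_seed_reproducible(self):
        rng = np.random.default_rng(2)
        g = _hw_pop(rng, 25, [0.5, 0.2, 0.2, 0.1])
        assert dv.hwe_test(g, "P", "L0", 500, 9).p == dv.hwe_test(g, "P", "L0", 500, 9).p
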