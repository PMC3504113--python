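"""Variance decomposition, permutation inference and pairwise matrices."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats

from conftest import brute_force_amova, genotypes_from_copies, random_copy_fixture
from strpopgen import amova as am
from strpopgen.str_io import FrequencyTable, frequencies_from_genotypes


class TestTwoLevel:
    def test_fixed_difference_pair_gives_one(self):
        g = genotypes_from_copies([np.full(4, 10.0), np.full(4, 12.0)])
        for model in ("stepwise", "identity"):
            r = am.two_level_amova(g, model)
            assert r.indices["ST"] == pytest.approx(1.0)
            assert r.strata[1].ssd == 0.0

    def test_identical_populations_nonpositive(self):
        g = genotypes_from_copies([np.array([10, 10, 11, 11.0]),
                                   np.array([10, 10, 11, 11.0])])
        r = am.two_level_amova(g, "stepwise")
        assert r.indices["ST"] <= 0.0  # reported as computed

    def test_hand_fixture_matches_oracle(self):
        copies = [np.array([10, 10, 11, 11.0]), np.array([12, 12, 13, 13.0])]
        g = genotypes_from_copies(copies)
        r = am.two_level_amova(g, "stepwise")
        oracle = brute_force_amova(copies, "stepwise")
        assert r.sigma["among_pops"] == pytest.approx(oracle["among_pops"], abs=1e-12)
        assert r.sigma["within_pops"] == pytest.approx(oracle["within_pops"], abs=1e-12)
        # direct SSD check on this fixture: within-pop SS = 1 + 1
        assert r.strata[1].ssd == pytest.approx(2.0)

    @pytest.mark.parametrize("model", ["stepwise", "identity"])
    def test_random_fixtures_match_oracle(self, model):
        rng = np.random.default_rng(42)
        for _ in range(25):
            copies = random_copy_fixture(rng)
            g = genotypes_from_copies(copies)
            r = am.two_level_amova(g, model)
            oracle = brute_force_amova(copies, model)
            for key in ("among_pops", "within_pops"):
                assert r.sigma[key] == pytest.approx(oracle[key], abs=1e-9)

    def test_df_sum_to_n_minus_one(self):
        g = genotypes_from_copies([np.array([8, 9, 10, 11.0]),
                                   np.array([9, 9, 12, 13, 8, 9.0])])
        r = am.two_level_amova(g, "stepwise")
        assert sum(s.df for s in r.strata) == 10 - 1


class TestThreeLevel:
    @pytest.mark.parametrize("model", ["stepwise", "identity"])
    def test_random_fixtures_match_oracle(self, model):
        rng = np.random.default_rng(7)
        for _ in range(25):
            copies = random_copy_fixture(rng, max_pops=5)
            P = len(copies)
            if P < 3:
                copies.append(rng.integers(8, 15, size=6).astype(float))
                P += 1
            groups = rng.integers(0, 2, size=P)
            if len(np.unique(groups)) == 1 or (np.bincount(groups) == 1).all():
                groups[0] = 1 - groups[0]
            g = genotypes_from_copies(copies)
            hier = {f"p{k}": f"G{groups[k]}" for k in range(P)}
            r = am.three_level_amova(g, hier, model)
            oracle = brute_force_amova(copies, model, groups=list(groups))
            for key in oracle:
                if math.isnan(oracle[key]):
                    assert math.isnan(r.sigma[key])
                else:
                    assert r.sigma[key] == pytest.approx(oracle[key], abs=1e-9)

    def test_identical_populations_among_ssd_zero_components_nonpositive(self):
        copies = [np.array([8, 8, 9, 9, 10, 10.0])] * 4
        g = genotypes_from_copies(copies)
        r = am.three_level_amova(g, {"p0": "A", "p1": "A", "p2": "B", "p3": "B"},
                                 "stepwise")
        # literally identical populations: zero among-strata SSD, so the
        # among-component estimates are <= 0 (reported as computed)
        assert r.strata[0].ssd == pytest.approx(0.0, abs=1e-9)
        assert r.strata[1].ssd == pytest.approx(0.0, abs=1e-9)
        assert r.sigma["among_groups"] <= 1e-9
        assert r.sigma["among_pops_within_groups"] <= 1e-9

    def test_one_population_per_group_is_degenerate(self):
        copies = [np.array([8, 9, 8, 9.0]), np.array([10, 11, 10, 11.0])]
        g = genotypes_from_copies(copies)
        r = am.three_level_amova(g, {"p0": "A", "p1": "B"}, "stepwise")
        assert r.degenerate
        assert r.strata[1].df == 0

    def test_single_group_collapses_to_two_level(self):
        rng = np.random.default_rng(3)
        copies = random_copy_fixture(rng)
        g = genotypes_from_copies(copies)
        hier = {f"p{k}": "ALL" for k in range(len(copies))}
        three = am.three_level_amova(g, hier, "stepwise")
        two = am.two_level_amova(g, "stepwise")
        assert three.sigma["among_pops"] == pytest.approx(two.sigma["among_pops"], abs=1e-9)
        assert three.sigma["within_pops"] == pytest.approx(two.sigma["within_pops"], abs=1e-9)


class TestModes:
    def test_frequency_mode_equals_genotype_mode(self, founder_fixture):
        table, _ = founder_fixture
        ft = frequencies_from_genotypes(table)
        for model in ("stepwise", "identity"):
            _, cg = am.amova(table, None, model)
            _, cf = am.amova(ft, None, model)
            assert cf.indices["ST"] == pytest.approx(cg.indices["ST"], abs=1e-9)

    def test_identity_equals_stepwise_on_adjacent_diallelic(self):
        # two alleles one repeat apart: the distance scale cancels
        g = genotypes_from_copies([np.array([10, 10, 11, 10.0]),
                                   np.array([11, 11, 10, 11.0])])
        r_r = am.two_level_amova(g, "stepwise")
        r_f = am.two_level_amova(g, "identity")
        assert r_r.indices["ST"] == pytest.approx(r_f.indices["ST"], abs=1e-12)


class TestMultilocus:
    def test_single_locus_identity(self, tiny_genotypes):
        per, combined = am.amova(tiny_genotypes, None, "stepwise", ["L1"])
        assert combined.indices["ST"] == pytest.approx(per[0].indices["ST"])

    def test_duplicated_locus_leaves_indices_unchanged(self, tiny_genotypes):
        one = am.two_level_amova(tiny_genotypes, "stepwise", "L1")
        many = am.multilocus_combine([one] * 13)
        assert many.indices["ST"] == pytest.approx(one.indices["ST"], abs=1e-12)

    def test_combined_equals_component_ratio(self, founder_fixture):
        table, _ = founder_fixture
        per, combined = am.amova(table, None, "stepwise")
        a = sum(r.sigma["among_pops"] for r in per)
        c = sum(r.sigma["within_pops"] for r in per)
        assert combined.indices["ST"] == pytest.approx(a / (a + c), abs=1e-12)

    def test_mismatched_strata_rejected(self, tiny_genotypes):
        two = am.two_level_amova(tiny_genotypes, "stepwise", "L1")
        three = am.three_level_amova(tiny_genotypes, {"A": "X", "B": "Y"},
                                     "stepwise", "L1")
        with pytest.raises(Exception):
            am.multilocus_combine([two, three])


class TestPermutation:
    def test_minimum_p_when_observed_strictly_extreme(self):
        # distinct copy values: only the exact observed partition reaches the
        # observed statistic, and this seed produces no such tie
        g = genotypes_from_copies([np.array([1, 2, 3, 4, 5, 6.0]),
                                   np.array([101, 102, 103, 104, 105, 106.0])])
        res = am.permutation_test(g, "ST", scheme="copies", n_perm=49, seed=1)
        assert res.p == pytest.approx(1 / 50)

    def test_exhaustive_enumeration_tiny_case(self):
        # 4 copies split 2/2: compare the permutation null against complete
        # enumeration of the 4!/(2!2!) assignments of copies to populations
        copies = np.array([10.0, 10.0, 12.0, 13.0])
        stats_all = []
        for pick in itertools.combinations(range(4), 2):
            a = copies[list(pick)]
            b = copies[[i for i in range(4) if i not in pick]]
            oracle = brute_force_amova([a, b], "stepwise")
            tot = oracle["among_pops"] + oracle["within_pops"]
            stats_all.append(oracle["among_pops"] / tot)
        g = genotypes_from_copies([copies[:2], copies[2:]])
        obs = am.two_level_amova(g, "stepwise").indices["ST"]
        exact_p = np.mean([s >= obs - 1e-12 for s in stats_all])
        res = am.permutation_test(g, "ST", scheme="copies", n_perm=2000, seed=5)
        assert res.p == pytest.approx(exact_p, abs=0.05)

    def test_null_type_one_error(self):
        rng = np.random.default_rng(99)
        rej = 0
        reps = 200
        for _ in range(reps):
            copies = [rng.integers(8, 12, 10).astype(float) for _ in range(4)]
            g = genotypes_from_copies(copies)
            res = am.permutation_test(g, "ST", n_perm=99,
                                      seed=int(rng.integers(2**31)))
            rej += res.p <= 0.05
        assert 0.02 <= rej / reps <= 0.09

    def test_fixed_seed_reproducible(self, tiny_genotypes):
        a = am.permutation_test(tiny_genotypes, "ST", n_perm=99, seed=11)
        b = am.permutation_test(tiny_genotypes, "ST", n_perm=99, seed=11)
        assert a.p == b.p


class TestFisher:
    def test_all_ones(self):
        chi2, df, p = am.fisher_combine([1.0, 1.0, 1.0])
        assert chi2 == pytest.approx(0.0) and p == pytest.approx(1.0)

    def test_single_p_is_identity(self):
        for p0 in (0.03, 0.2, 0.77):
            _, df, p = am.fisher_combine([p0])
            assert df == 2 and p == pytest.approx(p0, rel=1e-12)

    def test_two_halves(self):
        chi2, df, p = am.fisher_combine([0.5, 0.5])
        assert chi2 == pytest.approx(-2 * math.log(0.25), rel=1e-12)
        assert df == 4
        assert p == pytest.approx(stats.chi2.sf(chi2, 4), rel=1e-12)
        assert p == pytest.approx(0.5966, abs=5e-4)

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            am.fisher_combine([0.5, 0.0])


class TestPairwiseReynolds:
    def test_pairwise_entries_match_direct_runs(self, founder_fixture):
        table, _ = founder_fixture
        pops = table.populations[:4]
        idx = np.concatenate([table.individuals_in(p) for p in pops])
        from strpopgen.str_io import GenotypeTable
        sub = GenotypeTable([table.individuals[i] for i in idx],
                            [table.population_of[i] for i in idx],
                            list(table.loci), table.calls[idx])
        dm, _ = am.pairwise_matrix(sub, "stepwise")
        for i, j in itertools.combinations(range(4), 2):
            _, combined = am.amova(sub, None, "stepwise",
                                   populations=[pops[i], pops[j]])
            assert dm.values[i, j] == pytest.approx(combined.indices["ST"], abs=1e-12)
        assert np.allclose(dm.values, dm.values.T)
        assert np.all(np.diag(dm.values) == 0.0)

    def test_reynolds_closed_forms(self):
        dm = am.DistanceMatrix(["a", "b", "c"],
                               np.array([[0, 0.5, -0.1], [0.5, 0, 0.0],
                                         [-0.1, 0.0, 0]]))
        out = am.reynolds_transform(dm)
        assert out.values[0, 1] == pytest.approx(math.log(2))
        assert out.values[0, 2] == 0.0  # negative index clamps to distance 0
        assert out.values[1, 2] == 0.0

    def test_reynolds_cap_for_fixed_pairs(self):
        dm = am.DistanceMatrix(["a", "b"], np.array([[0.0, 1.0], [1.0, 0.0]]))
        out = am.reynolds_transform(dm, cap=9.0)
        assert out.values[0, 1] == 9.0
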