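"""I/O, validation and conversion between the two data modes."""

import numpy as np
import pytest

from strpopgen import str_io
from strpopgen.str_io import (FrequencyTable, GenotypeTable, HierarchyConfig,
                              ParseError, ValidationError,
                              frequencies_from_genotypes)


def _write(tmp_path, name, text):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestFrequencyTable:
    def test_exact_sum_accepted_and_zero_freq_dropped(self, tmp_path):
        path = _write(tmp_path, "f.csv",
                      "population,locus,allele,frequency,n_copies\n"
                      "A,L1,8,0.5,100\nA,L1,10,0.5,100\nA,L1,12,0.0,100\n")
        ft = str_io.read_frequency_table(path)
        freqs, n = ft.cell("A", "L1")
        assert freqs == {8.0: 0.5, 10.0: 0.5} and n == 100

    def test_sum_violation_names_cell(self, tmp_path):
        path = _write(tmp_path, "f.csv",
                      "population,locus,allele,frequency,n_copies\n"
                      "A,L1,8,0.6,100\nA,L1,10,0.6,100\n")
        with pytest.raises(ValidationError, match=r"\(A, L1\)"):
            str_io.read_frequency_table(path)

    def test_imperfect_allele_label_retained(self, tmp_path):
        path = _write(tmp_path, "f.csv",
                      "population,locus,allele,frequency,n_copies\n"
                      "A,TH01,9,0.4,50\nA,TH01,9.3,0.2,50\nA,TH01,10,0.4,50\n")
        ft = str_io.read_frequency_table(path)
        assert 9.3 in ft.cell("A", "TH01")[0]

    def test_duplicate_allele_rejected(self, tmp_path):
        path = _write(tmp_path, "f.csv",
                      "population,locus,allele,frequency,n_copies\n"
                      "A,L1,8,0.5,100\nA,L1,8,0.5,100\n")
        with pytest.raises(ValidationError, match="duplicate allele"):
            str_io.read_frequency_table(path)

    def test_malformed_row_names_line(self, tmp_path):
        path = _write(tmp_path, "f.csv",
                      "population,locus,allele,frequency,n_copies\n"
                      "A,L1,eight,0.5,100\n")
        with pytest.raises(ParseError, match=":2"):
            str_io.read_frequency_table(path)

    def test_roundtrip_lossless(self, tmp_path):
        cells = {("A", "L1"): ({8.0: 0.25, 9.3: 0.5, 31.2: 0.25}, 40),
                 ("B", "L1"): ({10.0: 1.0}, 20)}
        ft = FrequencyTable(["A", "B"], ["L1"], cells).validate()
        path = tmp_path / "rt.tsv"
        str_io.write_frequency_table(ft, path)
        back = str_io.read_frequency_table(path)
        assert back.populations == ["A", "B"] and back.loci == ["L1"]
        for key, (freqs, n) in cells.items():
            bf, bn = back.cells[key]
            assert bn == n
            assert set(bf) == set(freqs)
            for a in freqs:
                assert bf[a] == pytest.approx(freqs[a], abs=1e-6)

    def test_largest_remainder_count_reconstruction(self):
        # frequencies from integer counts 33/66/1 of 100 come back exactly
        ft = FrequencyTable(["A"], ["L1"],
                            {("A", "L1"): ({8.0: 0.33, 9.0: 0.66, 10.0: 0.01}, 100)})
        values, counts = ft.allele_counts("A", "L1")
        assert counts.sum() == 100
        assert dict(zip(values, counts)) == {8.0: 33, 9.0: 66, 10.0: 1}


class TestGenepop:
    def test_read_basic_and_missing_dropped(self, tmp_path):
        text = ("title\nL1\nL2\nPOP\n"
                "a1 ,  008009 010010\n"
                "a2 ,  009009 010011\n"
                "a3 ,  008008 000010\n"
                "POP\n"
                "b1 ,  010010 011011\n"
                "b2 ,  008010 010010\n"
                "b3 ,  009010 011010\n")
        res = str_io.read_genotypes_genepop(_write(tmp_path, "g.gen", text))
        assert len(res.table.individuals) == 5
        assert res.n_dropped == 1 and res.dropped_ids == ["a3"]
        assert res.table.populations == ["a1", "b1"]

    def test_no_pop_block_raises(self, tmp_path):
        with pytest.raises(ParseError, match="POP"):
            str_io.read_genotypes_genepop(_write(tmp_path, "g.gen", "title\nL1\n"))

    def test_odd_code_raises(self, tmp_path):
        text = "title\nL1\nPOP\na1 ,  00809\n"
        with pytest.raises(ParseError, match="odd"):
            str_io.read_genotypes_genepop(_write(tmp_path, "g.gen", text))

    def test_roundtrip_identity(self, tmp_path, founder_fixture):
        table, _ = founder_fixture
        path = tmp_path / "rt.gen"
        str_io.write_genotypes_genepop(table, path)
        back = str_io.read_genotypes_genepop(path).table
        assert back.loci == table.loci
        assert len(back.individuals) == len(table.individuals)
        np.testing.assert_array_equal(np.sort(back.calls, axis=2),
                                      np.sort(table.calls, axis=2))

    def test_extended_code_roundtrips_microvariants(self, tmp_path):
        g = GenotypeTable(["i0", "i1"], ["A", "A"], ["TH01"],
                          np.array([[[9.0, 9.3]], [[9.3, 10.0]]]))
        path = tmp_path / "mv.gen"
        str_io.write_genotypes_genepop(g, path)
        back = str_io.read_genotypes_genepop(path).table
        np.testing.assert_allclose(np.sort(back.calls, axis=2),
                                   np.sort(g.calls, axis=2))


class TestConversion:
    def test_frequencies_from_genotypes_counts(self):
        g = GenotypeTable(["i0", "i1"], ["A", "A"], ["L1"],
                          np.array([[[8.0, 8.0]], [[8.0, 10.0]]]))
        ft = frequencies_from_genotypes(g)
        freqs, n = ft.cell("A", "L1")
        assert n == 4 and freqs == {8.0: 0.75, 10.0: 0.25}

    def test_monomorphic_population(self):
        g = GenotypeTable(["i0", "i1"], ["A", "A"], ["L1"],
                          np.full((2, 1, 2), 9.0))
        freqs, _ = frequencies_from_genotypes(g).cell("A", "L1")
        assert freqs == {9.0: 1.0}

    def test_frequencies_always_sum_to_one(self, founder_fixture):
        table, _ = founder_fixture
        ft = frequencies_from_genotypes(table)
        for pop in ft.populations:
            for locus in ft.loci:
                freqs, _ = ft.cell(pop, locus)
                assert sum(freqs.values()) == pytest.approx(1.0, abs=1e-12)

    def test_native_csv_roundtrip(self, tmp_path, tiny_genotypes):
        path = tmp_path / "g.csv"
        str_io.write_genotypes_csv(tiny_genotypes, path)
        back = str_io.read_genotypes_csv(path)
        assert back.loci == tiny_genotypes.loci
        np.testing.assert_allclose(back.calls, tiny_genotypes.calls)

    def test_drop_loci(self, tiny_genotypes):
        out = str_io.drop_loci(tiny_genotypes, ["L1"])
        assert out.loci == ["L2"]
        with pytest.raises(ValidationError):
            str_io.drop_loci(tiny_genotypes, ["L1", "L2"])


class TestMetadataHierarchy:
    def test_metadata_validation(self, small_metadata):
        assert small_metadata.coords("A") == (9.0, 38.7)
        bad = small_metadata.table.copy()
        bad.loc["A", "lat"] = 95.0
        with pytest.raises(ValidationError):
            str_io.PopulationMetadata(bad)

    def test_hierarchy_from_metadata(self, small_metadata):
        h = HierarchyConfig.from_metadata(small_metadata)
        assert h.assignment == {"A": "G1", "B": "G1", "C": "G2"}
        assert h.members("G1") == ["A", "B"]

    def test_hierarchy_needs_two_groups(self):
        with pytest.raises(ValidationError):
            HierarchyConfig({"A": "G1", "B": "G1"})
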