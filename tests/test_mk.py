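"""McDonald-Kreitman tests, Fisher exact engine, Nei-Gojobori dN/dS."""

import math

import numpy as np
import pytest

from popsweep.alignio import classify_sites
from popsweep.mk import (
    DnDsResult,
    MkTable,
    dn_ds_ratio,
    fisher_exact_two_sided,
    mk_test,
    nei_gojobori_dnds,
    polarized_substitution_counts,
)
from popsweep.synth import plant_mk_table

from oracles import fisher_two_sided_enum


class TestFisherExact:
    @pytest.mark.parametrize("table,expected", [
        ((79, 24, 94, 53), 0.0369),   # replacement excess in divergence
        ((0, 6, 15, 4), 0.0012),      # replacement deficit in divergence
        ((2, 2, 17, 17), 1.0),        # proportional rows
    ])
    def test_published_scale_tables(self, table, expected):
        assert fisher_exact_two_sided(*table) == pytest.approx(expected, abs=5e-5)

    def test_proportional_rows_give_one(self):
        assert fisher_exact_two_sided(4, 8, 2, 4) == pytest.approx(1.0)

    def test_diagonal_table(self):
        # [[5,0],[0,5]]: the two extreme tables, each 1/C(10,5)
        assert fisher_exact_two_sided(5, 0, 0, 5) == pytest.approx(
            2 / math.comb(10, 5))

    def test_zero_margin_degenerate(self):
        assert fisher_exact_two_sided(0, 0, 5, 7) == 1.0

    def test_exhaustive_small_tables_vs_enumeration(self):
        for a in range(0, 7):
            for b in range(0, 7):
                for c in range(0, 7):
                    for d in range(0, 7):
                        if min(a + b, c + d, a + c, b + d) == 0:
                            continue
                        assert fisher_exact_two_sided(a, b, c, d) == \
                            pytest.approx(fisher_two_sided_enum(a, b, c, d),
                                          abs=1e-9), (a, b, c, d)

    def test_random_tables_up_to_n300_vs_enumeration(self, rng):
        for _ in range(150):
            cells = rng.integers(0, 76, size=4)
            if min(cells[0] + cells[1], cells[2] + cells[3],
                   cells[0] + cells[2], cells[1] + cells[3]) == 0:
                continue
            ours = fisher_exact_two_sided(*cells)
            enum = fisher_two_sided_enum(*[int(x) for x in cells])
            assert ours == pytest.approx(enum, abs=1e-9), cells


class TestMkTest:
    def test_symmetry_under_row_and_column_swap(self):
        p1 = mk_test(MkTable(7, 12, 3, 9)).p_value
        p2 = mk_test(MkTable(9, 3, 12, 7)).p_value  # both rows and cols swapped
        assert p1 == pytest.approx(p2, abs=1e-12)

    def test_ratios_with_zero_denominator_undefined(self):
        res = mk_test(MkTable(3, 0, 2, 5))
        assert res.da_ds is None
        assert res.pa_ps == pytest.approx(0.4)

    def test_all_zero_cells_error(self):
        with pytest.raises(ValueError, match="zero"):
            mk_test(MkTable(0, 0, 0, 0))


class TestDnDs:
    def test_identical_sequences(self):
        res = nei_gojobori_dnds("ATGGGGAAA", "ATGGGGAAA")
        assert res.dN == 0.0 and res.dS == 0.0
        assert res.ratio is None

    def test_single_synonymous_difference(self):
        a = "ATG" + "GGT" * 9
        b = "ATG" + "GGC" + "GGT" * 8
        res = nei_gojobori_dnds(a, b)
        assert res.dN == 0.0
        assert res.dS > 0.0
        assert res.ratio == 0.0

    def test_ratio_reporting_contract(self):
        assert dn_ds_ratio(0.0318, 0.1404) == pytest.approx(0.2265, abs=5e-5)
        assert dn_ds_ratio(0.1, 0.0) is None

    def test_jukes_cantor_saturation(self):
        # wildly divergent sequences saturate the synonymous class
        a = "GGT" * 40
        b = "GGC" * 40
        with pytest.raises(ValueError, match="saturat"):
            nei_gojobori_dnds(a, b)

    def test_matches_biopython_on_random_coding_pairs(self):
        """Cross-check counting dN/dS against Biopython's NG86."""
        from Bio import Align
        from Bio.Align import analysis
        from Bio.Seq import Seq

        rng = np.random.default_rng(6)
        nonstop = [c for c in
                   __import__("popsweep.alignio", fromlist=["GENETIC_CODE"])
                   .GENETIC_CODE if __import__(
                       "popsweep.alignio", fromlist=["GENETIC_CODE"])
                   .GENETIC_CODE[c] != "*"]
        for trial in range(5):
            codons_a = rng.choice(nonstop, size=60)
            codons_b = codons_a.copy()
            # mutate ~10% of codons at one position
            for idx in rng.choice(60, size=6, replace=False):
                cod = list(codons_b[idx])
                p = rng.integers(3)
                cod[p] = rng.choice([x for x in "ACGT" if x != cod[p]])
                if __import__("popsweep.alignio", fromlist=["GENETIC_CODE"]) \
                        .GENETIC_CODE["".join(cod)] == "*":
                    continue
                codons_b[idx] = "".join(cod)
            seq_a, seq_b = "".join(codons_a), "".join(codons_b)
            ours = nei_gojobori_dnds(seq_a, seq_b)
            aln = Align.Alignment([Seq(seq_a), Seq(seq_b)])
            dn, ds = analysis.calculate_dn_ds(aln, method="NG86")
            assert ours.dN == pytest.approx(dn, abs=5e-3)
            assert ours.dS == pytest.approx(ds, abs=5e-3)


class TestPolarizedCounts:
    def test_fixed_synonymous_at_fourfold_site(self):
        aln, gene = plant_mk_table(0, 1, 0, 0, gene_length=30, seed=0)
        cm = classify_sites(aln, [gene])
        t = polarized_substitution_counts(aln, cm)
        assert (t.Da, t.Ds, t.Pa, t.Ps) == (0, 1, 0, 0)

    def test_replacement_polymorphism(self):
        aln, gene = plant_mk_table(0, 0, 1, 0, gene_length=30, seed=0)
        cm = classify_sites(aln, [gene])
        t = polarized_substitution_counts(aln, cm)
        assert (t.Da, t.Ds, t.Pa, t.Ps) == (0, 0, 1, 0)

    @pytest.mark.parametrize("counts", [
        (5, 10, 3, 12),
        (0, 0, 0, 1),
        (79, 94, 24, 53),  # focal-gene scale in a 3564-bp coding sequence
    ])
    def test_planted_tables_recovered_exactly(self, counts):
        aln, gene = plant_mk_table(*counts, gene_length=3564, seed=1)
        cm = classify_sites(aln, [gene])
        t = polarized_substitution_counts(aln, cm)
        assert (t.Da, t.Ds, t.Pa, t.Ps) == counts

    def test_infeasible_counts_error(self):
        with pytest.raises(ValueError, match="exceed"):
            plant_mk_table(10, 10, 10, 10, gene_length=30)

    def test_polymorphic_and_divergent_counted_as_polymorphic_only(self):
        # build by hand: ingroup segregating GGT/GGC, outgroup GGA
        from popsweep.alignio import GeneAnnotation, HaplotypeAlignment
        rows = ["ATGGGT", "ATGGGT", "ATGGGC", "ATGGGC", "ATGGGA"]
        ids = ["a", "b", "c", "d", "og"]
        aln = HaplotypeAlignment(ids, np.array([list(r) for r in rows]),
                                 outgroup_id="og")
        cm = classify_sites(aln, [GeneAnnotation("g", "+", [(1, 6, 0)])])
        t = polarized_substitution_counts(aln, cm)
        assert (t.Da, t.Ds, t.Pa, t.Ps) == (0, 0, 0, 1)
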