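"""Alignment/annotation input and Nei-Gojobori site classification."""

import numpy as np
import pytest

from popsweep import alignio
from popsweep.alignio import (
    CODING,
    GENETIC_CODE,
    INTERGENIC,
    INTRONIC,
    FormatError,
    GeneAnnotation,
    HaplotypeAlignment,
    classify_sites,
    read_annotation,
    read_fasta_alignment,
    read_population_map,
    revcomp,
    synonymous_weights,
)


def write(tmp_path, name, text):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestFastaReading:
    def test_reads_equal_length_records(self, tmp_path):
        seqs = "".join(f">s{i}\n{'ACGT' * 25}\n" for i in range(4))
        aln = read_fasta_alignment(write(tmp_path, "a.fa", seqs))
        assert aln.n == 4
        assert aln.L == 100

    def test_length_mismatch_rejected(self, tmp_path):
        text = ">a\n" + "A" * 100 + "\n>b\n" + "A" * 99 + "\n"
        with pytest.raises(FormatError, match="unequal"):
            read_fasta_alignment(write(tmp_path, "b.fa", text))

    def test_ambiguity_code_names_record_and_column(self, tmp_path):
        text = ">a\nACGTACGT\n>b\nACGRACGT\n"
        with pytest.raises(FormatError, match=r"'b'.*column 4.*phase"):
            read_fasta_alignment(write(tmp_path, "c.fa", text))

    def test_duplicate_ids_rejected(self, tmp_path):
        text = ">a\nACGT\n>a\nACGT\n"
        with pytest.raises(FormatError, match="duplicate"):
            read_fasta_alignment(write(tmp_path, "d.fa", text))

    def test_outgroup_excluded_from_ingroup(self, tmp_path):
        text = ">a\nACGT\n>b\nACGT\n>og\nACGA\n"
        aln = read_fasta_alignment(write(tmp_path, "e.fa", text), outgroup_id="og")
        assert aln.n == 2
        assert list(aln.outgroup_row) == list("ACGA")


GFF = """##gff-version 3
region\tx\tgene\t11\t313\t.\t+\t.\tID=g1
region\tx\tCDS\t11\t160\t.\t+\t0\tParent=g1
region\tx\tCDS\t171\t323\t.\t+\t2\tParent=g1
"""


class TestAnnotationReading:
    def test_two_exon_gene_with_intron(self, tmp_path):
        genes = read_annotation(write(tmp_path, "a.gff3", GFF))
        (g,) = genes
        assert g.total_cds_length() == 150 + 153
        assert g.introns == [(161, 170)]

    def test_empty_file_is_empty_collection(self, tmp_path):
        assert read_annotation(write(tmp_path, "e.gff3", "##gff-version 3\n")) == []

    def test_frame_divisibility_enforced(self):
        with pytest.raises(FormatError, match="divisible"):
            GeneAnnotation("g", "+", [(1, 301, 0)])

    def test_overlapping_cds_rejected(self):
        with pytest.raises(FormatError, match="overlap"):
            GeneAnnotation("g", "+", [(1, 90, 0), (60, 150, 0)])


class TestSynonymousWeights:
    # frozen by enumerating all 9 single-base mutants of each codon
    @pytest.mark.parametrize("codon,expected", [
        ("TTT", (0, 0, 1 / 3)),   # Phe: only 3rd-position TTC is synonymous
        ("ATG", (0, 0, 0)),       # Met: no synonymous single-base change
        ("GGG", (0, 0, 1)),       # Gly: 4-fold degenerate 3rd position
        ("CTA", (1 / 3, 0, 1)),   # Leu: TTA at position 1 also Leu
    ])
    def test_frozen_values(self, codon, expected):
        assert synonymous_weights(codon) == pytest.approx(expected)

    def test_against_enumeration_for_all_codons(self):
        for codon, aa in GENETIC_CODE.items():
            if aa == "*":
                continue
            for pos in range(3):
                syn = sum(
                    GENETIC_CODE[codon[:pos] + b + codon[pos + 1:]] == aa
                    for b in "ACGT" if b != codon[pos]
                )
                assert synonymous_weights(codon)[pos] == pytest.approx(syn / 3)

    def test_genetic_code_against_biopython(self):
        from Bio.Seq import Seq
        for codon, aa in GENETIC_CODE.items():
            assert str(Seq(codon).translate()) == aa


def _simple_gene_alignment(codons: str, n: int = 4):
    seq = codons
    matrix = np.array([list(seq)] * n, dtype="<U1")
    aln = HaplotypeAlignment([f"s{i}" for i in range(n)], matrix)
    gene = GeneAnnotation("g", "+", [(1, len(seq), 0)])
    return aln, gene


class TestClassifySites:
    def test_codon_weights_assigned_per_column(self):
        aln, gene = _simple_gene_alignment("TTTATG")
        cm = classify_sites(aln, [gene])
        assert cm.syn_weight.tolist() == pytest.approx([0, 0, 1 / 3, 0, 0, 0])
        assert cm.synonymous_sites == pytest.approx(1 / 3)

    def test_silent_is_synonymous_plus_intronic(self):
        # gene: codon TTT, 5-bp intron, codon ATG
        matrix = np.array([list("TTTAAAAAATG")] * 4, dtype="<U1")
        aln = HaplotypeAlignment([f"s{i}" for i in range(4)], matrix)
        gene = GeneAnnotation("g", "+", [(1, 3, 0), (9, 11, 0)])
        cm = classify_sites(aln, [gene])
        assert cm.intronic_sites == 5
        assert cm.silent_sites == pytest.approx(1 / 3 + 5)
        assert set(cm.labels) == {CODING, INTRONIC}

    def test_every_column_has_one_class(self, swept_region):
        sim = swept_region
        cm = classify_sites(sim.alignment, sim.annotations)
        assert set(cm.labels) <= {CODING, INTRONIC, INTERGENIC}

    def test_weight_sum_equals_unmasked_coding_columns(self, swept_region):
        cm = classify_sites(swept_region.alignment, swept_region.annotations)
        m = cm.class_mask(CODING)
        total = cm.syn_weight[m].sum() + np.sum(1.0 - cm.syn_weight[m])
        assert total == pytest.approx(m.sum())

    def test_strand_consistency(self):
        # a minus-strand gene yields the same aggregate counts as its
        # reverse-complemented plus-strand twin
        rng = np.random.default_rng(7)
        codons = "ATG" + "".join(
            np.random.default_rng(3).choice(
                [c for c, a in GENETIC_CODE.items() if a != "*"], size=20))
        flank = "".join(rng.choice(list("ACGT"), size=10))
        fwd_seq = flank + codons + flank
        fwd = np.array([list(fwd_seq)] * 4, dtype="<U1")
        aln_f = HaplotypeAlignment([f"s{i}" for i in range(4)], fwd)
        gene_f = GeneAnnotation("g", "+", [(11, 10 + len(codons), 0)])
        cm_f = classify_sites(aln_f, [gene_f])

        rev_seq = revcomp(fwd_seq)
        rev = np.array([list(rev_seq)] * 4, dtype="<U1")
        aln_r = HaplotypeAlignment([f"s{i}" for i in range(4)], rev)
        start = len(fwd_seq) - (10 + len(codons)) + 1
        gene_r = GeneAnnotation("g", "-", [(start, start + len(codons) - 1, 0)])
        cm_r = classify_sites(aln_r, [gene_r])

        assert cm_f.synonymous_sites == pytest.approx(cm_r.synonymous_sites)
        assert cm_f.nonsynonymous_sites == pytest.approx(cm_r.nonsynonymous_sites)

    def test_internal_stop_masks_codon_with_warning(self):
        aln, gene = _simple_gene_alignment("ATGTAAGGG")
        with pytest.warns(UserWarning, match="stop"):
            cm = classify_sites(aln, [gene])
        assert cm.masked[3:6].all()
        assert not cm.masked[0:3].any()

    def test_gap_column_masks_whole_codon(self):
        matrix = np.array([list("TTTATG"), list("TT-ATG"),
                           list("TTTATG")], dtype="<U1")
        aln = HaplotypeAlignment(["a", "b", "c"], matrix)
        gene = GeneAnnotation("g", "+", [(1, 6, 0)])
        cm = classify_sites(aln, [gene])
        assert cm.masked[:3].all()
        assert not cm.masked[3:].any()


class TestPopulationMap:
    def test_roundtrip_and_groupings(self, tmp_path):
        text = "sample_id\tpopulation\na\tX\nb\tX\nc\tY\n"
        pmap = read_population_map(write(tmp_path, "p.tsv", text))
        groups = pmap.groupings()
        assert groups["X"] == ["a", "b"]
        assert groups["pooled"] == ["a", "b", "c"]

    def test_missing_assignment_detected(self, tmp_path):
        text = "sample_id\tpopulation\na\tX\n"
        pmap = read_population_map(write(tmp_path, "p.tsv", text))
        aln = HaplotypeAlignment(["a", "b"], np.array([list("AC"), list("AC")]))
        with pytest.raises(FormatError, match="b"):
            pmap.validate_against(aln)
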