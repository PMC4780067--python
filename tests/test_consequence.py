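"""Codon arithmetic, coding consequences and the mutation spectrum."""

import math

import pytest

from casevar import (
    GeneModel,
    annotate,
    codon_of,
    indel_class,
    spectrum_summary,
    substitution_class,
)

COMPLEMENT = str.maketrans("ACGT", "TGCA")


def revcomp(s):
    return s.translate(COMPLEMENT)[::-1]


class TestCodonArithmetic:
    @pytest.mark.parametrize("cds_pos,codon", [(601, 201), (3, 1), (604, 202), (1, 1)])
    def test_codon_index(self, cds_pos, codon):
        assert codon_of(cds_pos) == codon

    def test_nonpositive_position_rejected(self):
        with pytest.raises(ValueError):
            codon_of(0)

    def test_matches_triplet_counting_and_increments_at_frame_starts(self):
        prev = 0
        for pos in range(1, 301):
            by_counting = (pos - 1) // 3 + 1  # independent enumeration
            idx = codon_of(pos)
            assert idx == by_counting
            assert idx - prev == (1 if pos % 3 == 1 else 0)
            prev = idx


def toy_model(seq, strand="+", start=11, gene="TOY"):
    """Single-CDS model embedded in a padded contig; seq is the
    coding-strand CDS."""
    genomic = seq if strand == "+" else revcomp(seq)
    contig = "T" * (start - 1) + genomic + "T" * 10
    model = GeneModel(
        gene=gene, transcript="T1", chrom="c", strand=strand,
        cds_segments=((start, start + len(seq) - 1),),
    )
    return model, {"c": contig}


class TestAnnotate:
    def test_stop_gain_from_arginine_codon(self):
        # CGA -> TGA at codon position 1 creates a stop
        model, genome = toy_model("ATGCGAAAA")
        c = annotate("c", 14, "C", "T", model, genome)
        assert c.kind == "stop_gain"
        assert (c.cds_pos, c.codon_index) == (4, 2)
        assert (c.ref_aa, c.alt_aa) == ("R", "*")
        assert c.hgvs_p == "p.Arg2*"

    def test_synonymous_when_amino_acid_unchanged(self):
        # GGA -> GGG, both glycine
        model, genome = toy_model("ATGGGAAAA")
        c = annotate("c", 16, "A", "G", model, genome)
        assert c.kind == "synonymous"

    def test_missense_with_protein_notation(self):
        # ACG -> ATG, Thr -> Met
        model, genome = toy_model("ATGACGAAA")
        c = annotate("c", 15, "C", "T", model, genome)
        assert c.kind == "missense"
        assert c.hgvs_p == "p.Thr2Met"

    def test_single_base_deletion_is_frameshift(self):
        model, genome = toy_model("ATGCGAAAA")
        ref = genome["c"][12:14]  # anchor + deleted base
        c = annotate("c", 13, ref, ref[0], model, genome)
        assert c.kind == "frameshift"
        assert c.hgvs_p.endswith("fs")

    def test_single_base_insertion_is_frameshift(self):
        model, genome = toy_model("ATGCGAAAA")
        ref = genome["c"][12]
        c = annotate("c", 13, ref, ref + "A", model, genome)
        assert c.kind == "frameshift"

    def test_three_base_deletion_in_frame(self):
        model, genome = toy_model("ATGCGATTTAAA")
        ref = genome["c"][12:16]
        c = annotate("c", 13, ref, ref[0], model, genome)
        assert c.kind == "inframe_indel"

    def test_outside_cds_is_noncoding(self):
        model, genome = toy_model("ATGCGAAAA")
        c = annotate("c", 2, "T", "A", model, genome)
        assert c.kind == "noncoding"

    def test_indel_spanning_cds_boundary_flags_splice_region(self):
        model, genome = toy_model("ATGCGAAAA", start=11)
        # anchor on the last CDS base; the deleted base falls outside
        ref = genome["c"][18:20]
        c = annotate("c", 19, ref, ref[0], model, genome)
        assert c.kind == "noncoding"
        assert c.splice_region

    def test_reverse_strand_equals_forward_on_palindromic_cds(self):
        """On a reverse-complement-palindromic CDS, a variant and its
        mirror-image complement must annotate identically on the two strands."""
        seq = "ATGCGATCGCAT"  # revcomp(seq) == seq
        assert revcomp(seq) == seq
        start = 11
        fwd, genome = toy_model(seq, "+", start=start)
        rev = GeneModel(
            gene="TOY", transcript="T1", chrom="c", strand="-",
            cds_segments=fwd.cds_segments,
        )
        end = start + len(seq) - 1
        for pos in range(start, end + 1):
            ref = genome["c"][pos - 1]
            for alt in "ACGT":
                if alt == ref:
                    continue
                a = annotate("c", pos, ref, alt, fwd, genome)
                mirror = start + end - pos
                b = annotate(
                    "c", mirror,
                    genome["c"][mirror - 1].translate(COMPLEMENT),
                    alt.translate(COMPLEMENT),
                    rev, genome,
                )
                assert (a.kind, a.cds_pos, a.codon_index, a.ref_aa, a.alt_aa) == (
                    b.kind, b.cds_pos, b.codon_index, b.ref_aa, b.alt_aa,
                )


class TestSpectrum:
    @pytest.mark.parametrize("ref,alt", [("C", "T"), ("G", "A"), ("A", "G"), ("T", "C")])
    def test_transitions(self, ref, alt):
        assert substitution_class(ref, alt) == "transition"

    @pytest.mark.parametrize("ref,alt", [("G", "T"), ("A", "T"), ("A", "C"), ("C", "G")])
    def test_transversions(self, ref, alt):
        assert substitution_class(ref, alt) == "transversion"

    def test_indel_classes(self):
        assert indel_class("TG", "T") == "deletion"
        assert indel_class("T", "TA") == "insertion"

    def test_case_spectrum_two_ti_three_tv_one_ins_one_del(self):
        # the seven somatic mutations of the analysed case:
        # delG, C>T, insA, G>T, A>T, A>C, G>A
        pairs = [
            ("TG", "T"), ("C", "T"), ("T", "TA"), ("G", "T"),
            ("A", "T"), ("A", "C"), ("G", "A"),
        ]
        assert spectrum_summary(pairs) == (2, 3, 1, 1)

    def test_empty_and_homogeneous_inputs(self):
        assert spectrum_summary([]) == (0, 0, 0, 0)
        assert spectrum_summary([("C", "T")] * 10) == (10, 0, 0, 0)

    def test_counts_partition_snvs_and_indels(self):
        pairs = [("C", "T"), ("A", "C"), ("T", "TA"), ("AC", "A"), ("G", "A")]
        ti, tv, ins, dele = spectrum_summary(pairs)
        n_snv = sum(1 for r, a in pairs if len(r) == len(a) == 1)
        assert ti + tv == n_snv
        assert ins + dele == len(pairs) - n_snv
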