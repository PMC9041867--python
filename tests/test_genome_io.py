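"""Sequence extraction, encoding and haplotype-reconstruction contracts."""

import numpy as np
import pytest

from peabrain import genome_io as gio

COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def rc_oracle(seq):
    """Independent hand-rolled reverse complement."""
    return "".join(COMP[b] for b in reversed(seq))


@pytest.fixture()
def random_genome():
    rng = np.random.default_rng(7)
    return {"chr1": "".join(np.array(list("ACGT"))[rng.integers(0, 4, 6000)])}


class TestExtractPromoterWindow:
    def test_plus_strand_4kb_window(self, random_genome):
        gene = gio.GeneModel("g", "chr1", tss=2001, strand="+")
        seq, (chrom, start, end) = gio.extract_promoter_window(
            gene, random_genome, halfwidth=2000)
        assert (start, end) == (0, 4000)
        assert len(seq) == 4000
        assert seq == random_genome["chr1"][:4000]

    def test_palindrome_strand_invariant(self):
        half = "ACGTGGCC"
        window = half + rc_oracle(half)  # reverse-complement palindrome
        genome = {"c": "AA" + window + "AA"}
        plus = gio.GeneModel("p", "c", tss=2 + 8 + 1, strand="+")
        minus = gio.GeneModel("m", "c", tss=2 + 8 + 1, strand="-")
        sp, _ = gio.extract_promoter_window(plus, genome, 8)
        sm, _ = gio.extract_promoter_window(minus, genome, 8)
        assert sp == sm == window

    def test_minus_strand_manual_oracle(self):
        genome = {"c": "AACCGGTTAA"}
        gene = gio.GeneModel("g", "c", tss=6, strand="-")
        seq, (chrom, start, end) = gio.extract_promoter_window(gene, genome, 2)
        # + strand window is positions [3, 7) = "CGGT"
        assert (start, end) == (3, 7)
        assert seq == rc_oracle("CGGT")

    def test_unknown_chromosome_errors(self, random_genome):
        gene = gio.GeneModel("g", "chrX", tss=100, strand="+")
        with pytest.raises(KeyError):
            gio.extract_promoter_window(gene, random_genome, 10)

    def test_off_end_errors_unless_clipped(self, random_genome):
        gene = gio.GeneModel("g", "chr1", tss=5, strand="+")
        with pytest.raises(ValueError):
            gio.extract_promoter_window(gene, random_genome, 10)
        seq, _ = gio.extract_promoter_window(gene, random_genome, 10, clip=True)
        assert len(seq) == 20 and seq.startswith("NNNNNN")


class TestOneHotEncode:
    def test_acgt_identity_pattern(self):
        enc = gio.one_hot_encode("ACGT")
        assert np.array_equal(enc.matrix, np.eye(4, dtype=np.float32))
        assert enc.channel_names == ("A", "C", "G", "T")

    def test_n_encodes_as_zeros(self):
        enc = gio.one_hot_encode("AN")
        assert enc.matrix[:, :4].sum(axis=1).tolist() == [1.0, 0.0]

    def test_annotation_channel_interval_overlap(self):
        track = gio.AnnotationTrack.from_intervals("t", [("c", 1, 3)])
        enc = gio.one_hot_encode("AAAA", tracks=[track], window=("c", 0, 4))
        assert enc.matrix[:, 4].tolist() == [0.0, 1.0, 1.0, 0.0]

    def test_length_mismatch_errors(self):
        with pytest.raises(ValueError):
            gio.one_hot_encode("ACGT", window=("c", 0, 5))

    def test_roundtrip_argmax_recovers_sequence(self):
        rng = np.random.default_rng(0)
        seq = "".join(np.array(list("ACGTN"))[rng.integers(0, 5, 300)])
        enc = gio.one_hot_encode(seq)
        letters = np.array(list("ACGT"))
        for i, base in enumerate(seq):
            col = enc.matrix[i, :4]
            if base == "N":
                assert col.sum() == 0
            else:
                assert letters[col.argmax()] == base

    def test_minus_strand_encoding_is_revcomp_permutation(self, random_genome):
        plus = gio.GeneModel("g", "chr1", tss=301, strand="+")
        minus = gio.GeneModel("g", "chr1", tss=301, strand="-")
        track = gio.AnnotationTrack.from_intervals("t", [("chr1", 250, 270)])
        ep = gio.encode_gene(plus, random_genome, 100, tracks=[track])
        em = gio.encode_gene(minus, random_genome, 100, tracks=[track])
        # reverse positions, swap A<->T and C<->G channels, flip annotations
        expected = ep.matrix[::-1][:, [3, 2, 1, 0, 4]]
        assert np.array_equal(em.matrix, expected)

    def test_annotation_channels_match_bruteforce_membership(self):
        rng = np.random.default_rng(5)
        ivs = [("c", int(s), int(s) + int(rng.integers(1, 30)))
               for s in rng.integers(0, 480, 25)]
        track = gio.AnnotationTrack.from_intervals("t", ivs)
        seq = "A" * 400
        enc = gio.one_hot_encode(seq, tracks=[track], window=("c", 50, 450))
        for offset in range(400):
            pos = 50 + offset
            member = any(s <= pos < e for _, s, e in ivs)
            assert enc.matrix[offset, 4] == float(member)


class TestReconstructHaplotypes:
    genome = {"c": "ACGTACGTACGTACGTACGT"}
    gene = gio.GeneModel("g", "c", tss=11, strand="+")  # tss0 = 10

    def test_hom_ref_equals_reference_window(self):
        ref, _ = gio.extract_promoter_window(self.gene, self.genome, 5)
        h1, h2 = gio.reconstruct_haplotypes(self.gene, self.genome, [], 5)
        assert h1 == h2 == ref

    def test_het_snp_differs_at_single_offset(self):
        ref, _ = gio.extract_promoter_window(self.gene, self.genome, 5)
        call = gio.VariantCall("c", pos=8, ref="T", alt="A", gt=(0, 1))
        h1, h2 = gio.reconstruct_haplotypes(self.gene, self.genome, [call], 5)
        # unphased het: alt deterministically on haplotype 1
        assert h2 == ref
        diffs = [i for i, (a, b) in enumerate(zip(h1, ref)) if a != b]
        assert diffs == [8 - 1 - 5]  # offset of pos within the window
        assert h1[diffs[0]] == "A"

    def test_upstream_deletion_shifts_and_pads_left_flank(self):
        # 2-bp deletion upstream of the TSS on haplotype 1
        call = gio.VariantCall("c", pos=7, ref="GTA", alt="G", gt=(1, 0))
        h1, h2 = gio.reconstruct_haplotypes(self.gene, self.genome, [call], 5)
        ref, _ = gio.extract_promoter_window(self.gene, self.genome, 5)
        assert h2 == ref
        # independent realignment oracle: apply deletion to the left flank
        left = self.genome["c"][5:10]          # "CGTAC"
        mutated = left[:1] + "G" + left[4:]    # "GTA" -> "G" leaves "CGC"
        expected_left = ("N" * 2 + mutated)[-5:]
        assert h1 == expected_left + ref[5:]
        assert h1[5:] == ref[5:]  # post-TSS content unchanged

    def test_overlapping_variants_error(self):
        calls = [gio.VariantCall("c", 7, "GTA", "G", (1, 1)),
                 gio.VariantCall("c", 8, "T", "C", (1, 1))]
        with pytest.raises(ValueError, match="overlapping"):
            gio.reconstruct_haplotypes(self.gene, self.genome, calls, 5)

    def test_reference_mismatch_reports_position(self):
        call = gio.VariantCall("c", 8, "G", "C", (1, 1))
        with pytest.raises(ValueError, match="c:8"):
            gio.reconstruct_haplotypes(self.gene, self.genome, [call], 5)

    def test_variant_outside_window_errors(self):
        call = gio.VariantCall("c", 20, "T", "A", (1, 1))
        with pytest.raises(ValueError, match="outside"):
            gio.reconstruct_haplotypes(self.gene, self.genome, [call], 4)


class TestDiploidAndDifference:
    def test_identical_haplotypes_double_channels(self):
        enc = gio.encode_diploid("AC", "AC")
        assert enc.matrix[:, 0].tolist() == [2.0, 0.0]
        assert enc.matrix[:, 1].tolist() == [0.0, 2.0]

    def test_het_site_splits_channels(self):
        enc = gio.encode_diploid("A", "G")
        assert enc.matrix[0, 0] == 1.0 and enc.matrix[0, 2] == 1.0

    def test_phase_swap_invariance(self):
        rng = np.random.default_rng(1)
        h1 = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 50)])
        h2 = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 50)])
        a = gio.encode_diploid(h1, h2)
        b = gio.encode_diploid(h2, h1)
        assert np.array_equal(a.matrix, b.matrix)
        sums = a.matrix[:, :4].sum(axis=1)
        assert set(sums.tolist()) <= {0.0, 1.0, 2.0}

    def test_difference_of_identical_is_zero(self):
        a = gio.encode_diploid("ACGT", "ACGT")
        b = gio.encode_diploid("ACGT", "ACGT")
        assert not gio.difference_sequence(a, b).matrix.any()

    def test_hom_snp_difference_two_entries(self):
        a = gio.encode_diploid("AAA", "AAA")
        b = gio.encode_diploid("AGA", "AGA")
        d = gio.difference_sequence(a, b).matrix
        assert d[1, 0] == 2.0 and d[1, 2] == -2.0
        assert np.count_nonzero(d) == 2

    def test_antisymmetry(self):
        rng = np.random.default_rng(2)
        seqs = ["".join(np.array(list("ACGT"))[rng.integers(0, 4, 30)])
                for _ in range(4)]
        a = gio.encode_diploid(seqs[0], seqs[1])
        b = gio.encode_diploid(seqs[2], seqs[3])
        d1 = gio.difference_sequence(a, b).matrix
        d2 = gio.difference_sequence(b, a).matrix
        assert np.array_equal(d1, -d2)
        assert d1.min() >= -2 and d1.max() <= 2

    def test_shape_mismatch_errors(self):
        a = gio.encode_diploid("ACGT", "ACGT")
        b = gio.encode_diploid("ACG", "ACG")
        with pytest.raises(ValueError):
            gio.difference_sequence(a, b)
        with pytest.raises(ValueError):
            gio.encode_diploid("ACGT", "ACG")


class TestVcfIO:
    def test_cohort_calls_and_dosages(self, tiny_stage2_world):
        world = tiny_stage2_world
        samples, dosages, meta = gio.load_dosage_matrix(world.vcf_path)
        assert samples == world.individual_ids
        assert dosages.shape == (24, 12)
        assert set(np.unique(dosages)) <= {0.0, 1.0, 2.0}
        truth = world.load_truth()
        assert meta["pos"].tolist() == truth["pos"].tolist()
        _, calls = gio.load_cohort_calls(world.vcf_path)
        # per-individual alt-allele counts agree with the dosage matrix
        for i, s in enumerate(samples):
            assert sum(sum(c.gt) for c in calls[s]) == dosages[i].sum()
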