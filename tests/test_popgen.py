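"""Diversity statistics: allele frequencies, Ho/He, HWE exact test,
haplotype and nucleotide diversity."""

import numpy as np
import pytest

from parkviable.popgen import (
    GenotypeMatrix,
    SequenceSet,
    allele_frequencies,
    haplotype_diversity,
    heterozygosity,
    hwe_exact_test,
    nucleotide_diversity,
    unbiased_gene_diversity,
)
from parkviable.synth import freqs_from_target_he, synth_genotypes, synth_sequences


def matrix_from(genos, locus="L1"):
    inds = [f"i{k}" for k in range(len(genos))]
    return GenotypeMatrix(
        individuals=inds,
        loci=[locus],
        genotypes={i: {locus: g} for i, g in zip(inds, genos)},
    )


class TestAlleleFrequencies:
    def test_single_heterozygote(self):
        t = allele_frequencies(matrix_from([("A", "B")]))
        assert t.freqs["L1"] == {"A": 0.5, "B": 0.5}

    def test_gene_counting(self):
        t = allele_frequencies(matrix_from([("A", "A"), ("A", "B"), ("B", "B")]))
        assert t.freqs["L1"] == {"A": 0.5, "B": 0.5}

    def test_missing_entries_excluded_per_locus(self):
        t = allele_frequencies(matrix_from([("A", "A"), None, ("A", "B")]))
        assert t.n_genotyped["L1"] == 2
        assert t.freqs["L1"]["A"] == pytest.approx(0.75)

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            allele_frequencies(GenotypeMatrix([], [], {}))

    def test_recovers_truth_from_large_sample(self):
        truth = freqs_from_target_he([0.465, 0.232])
        g = synth_genotypes(truth, n=500, seed=11)
        est = allele_frequencies(g)
        for locus in truth.loci:
            for allele, p in truth.freqs[locus].items():
                se = np.sqrt(p * (1 - p) / 1000)  # 2n allele copies
                assert abs(est.freqs[locus][allele] - p) < 3 * se


class TestHeterozygosity:
    def test_monomorphic_locus_flagged_with_zero_he(self):
        rows = heterozygosity(matrix_from([("A", "A"), ("A", "A")]))
        assert rows[0].ho == 0 and rows[0].he == 0 and rows[0].monomorphic

    def test_unbiased_correction_two_heterozygotes(self):
        rows = heterozygosity(matrix_from([("A", "B"), ("A", "B")]))
        assert rows[0].ho == 1.0
        assert rows[0].he == pytest.approx(4 / 3 * 0.5)

    def test_equifrequent_alleles_closed_form(self):
        # k equifrequent alleles: unbiased He = 2n/(2n-1) (1 - 1/k)
        assert unbiased_gene_diversity([0.25] * 4, n=10) == pytest.approx(
            20 / 19 * 0.75
        )

    def test_invariant_under_allele_relabeling(self):
        a = heterozygosity(matrix_from([("A", "B"), ("B", "C"), ("A", "A")]))
        b = heterozygosity(matrix_from([("x", "y"), ("y", "z"), ("x", "x")]))
        assert a[0].ho == b[0].ho and a[0].he == pytest.approx(b[0].he)


class TestHWEExactTest:
    def test_monomorphic_locus_p_is_one(self):
        assert hwe_exact_test({("A", "A"): 5}).p_value == 1.0

    def test_enumeration_oracle_3_0_3(self):
        # brute force over the 4 tables with allele counts (6, 6): p = 5/231
        res = hwe_exact_test({("A", "A"): 3, ("A", "B"): 0, ("B", "B"): 3})
        assert res.method == "enumeration" and res.n_tables == 4
        assert res.p_value == pytest.approx(5 / 231, abs=1e-12)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            hwe_exact_test({("A", "A"): -1, ("A", "B"): 2})

    @pytest.mark.parametrize(
        "table",
        [
            {("A", "A"): 3, ("A", "B"): 0, ("B", "B"): 3},
            {("A", "A"): 10, ("A", "B"): 4, ("B", "B"): 8},
            {("A", "A"): 2, ("A", "B"): 3, ("B", "C"): 4, ("C", "C"): 1},
        ],
    )
    def test_monte_carlo_agrees_with_enumeration(self, table, rng):
        exact = hwe_exact_test(table)
        mc = hwe_exact_test(table, max_enumeration=1, mc_rounds=40_000, rng=rng)
        assert mc.method == "monte-carlo" and mc.mc_se is not None
        assert abs(mc.p_value - exact.p_value) < 3 * mc.mc_se + 1e-4

    def test_heterozygote_excess_is_detected(self):
        res = hwe_exact_test({("A", "B"): 20})
        assert res.p_value < 0.01


class TestSequenceDiversity:
    def test_identical_sequences_have_zero_diversity(self):
        seqs = synth_sequences([1.0], n=5, length=60, divergence_positions=[], seed=0)
        assert haplotype_diversity(seqs).haplotype_diversity == 0.0
        assert nucleotide_diversity(seqs).nucleotide_diversity == 0.0

    def test_two_haplotypes_half_and_half(self):
        seqs = synth_sequences([0.5, 0.5], n=4, length=100,
                               divergence_positions=[[7]], seed=2)
        assert haplotype_diversity(seqs).haplotype_diversity == pytest.approx(
            4 / 3 * 0.5
        )

    def test_pi_two_sequences_one_difference(self):
        seqs = synth_sequences([0.5, 0.5], n=2, length=100,
                               divergence_positions=[[42]], seed=3)
        assert nucleotide_diversity(seqs).nucleotide_diversity == pytest.approx(0.01)

    def test_pi_equals_all_pairs_brute_force(self, rng):
        seqs = synth_sequences(
            [0.4, 0.3, 0.3], n=10, length=120,
            divergence_positions=[[0, 1, 2, 3], [50, 51]], seed=4,
            exact_counts=False,
        )
        strings = seqs.as_strings()
        diffs = []
        for i in range(len(strings)):
            for j in range(i + 1, len(strings)):
                diffs.append(
                    sum(a != b for a, b in zip(strings[i], strings[j])) / 120
                )
        assert nucleotide_diversity(seqs).nucleotide_diversity == pytest.approx(
            np.mean(diffs)
        )

    def test_order_invariance(self):
        seqs = synth_sequences([0.6, 0.4], n=10, length=80,
                               divergence_positions=[[1, 2]], seed=5)
        rev = SequenceSet(records=list(reversed(seqs.records)))
        assert haplotype_diversity(rev).haplotype_diversity == pytest.approx(
            haplotype_diversity(seqs).haplotype_diversity
        )
        assert nucleotide_diversity(rev).nucleotide_diversity == pytest.approx(
            nucleotide_diversity(seqs).nucleotide_diversity
        )

    def test_ragged_alignment_rejected(self):
        from Bio.Seq import Seq
        from Bio.SeqRecord import SeqRecord

        with pytest.raises(ValueError, match="ragged"):
            SequenceSet(records=[SeqRecord(Seq("ACGT"), id="a"),
                                 SeqRecord(Seq("ACG"), id="b")])
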