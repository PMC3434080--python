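"""Personalized references, allele counting, and the binomial bias test."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import binom

from asbcall.bias import (assign_read_haplotype, bias_table,
                          binomial_bias_test, count_alleles,
                          personalize_reference)
from asbcall.core import HET, HOM_ALT, VariantCall

from conftest import make_read


def het(pos, ref, alt, chrom="chr1"):
    return VariantCall(chrom, pos, ref, alt, HET, 100.0, 99, 20, (10, 10))


def hom(pos, ref, alt, chrom="chr1"):
    return VariantCall(chrom, pos, ref, alt, HOM_ALT, 100.0, 99, 20, (0, 20))


class TestPersonalizeReference:
    def test_het_substitution(self):
        ref = {"chr1": "ACGTACGT"}
        hap_r, hap_a = personalize_reference(ref, [het(1, "C", "T")])
        assert hap_r["chr1"] == "ACGTACGT"
        assert hap_a["chr1"] == "ATGTACGT"

    def test_hom_alt_on_both(self):
        ref = {"chr1": "ACGTACGT"}
        hap_r, hap_a = personalize_reference(ref, [hom(4, "A", "G")])
        assert hap_r["chr1"][4] == hap_a["chr1"][4] == "G"

    def test_no_variants_identity(self):
        ref = {"chr1": "ACGTACGT"}
        hap_r, hap_a = personalize_reference(ref, [])
        assert hap_r == ref and hap_a == ref

    def test_ref_mismatch_names_position(self):
        with pytest.raises(ValueError, match="chr1:2"):
            personalize_reference({"chr1": "ACGTACGT"}, [het(1, "G", "T")])


class TestAssignReadHaplotype:
    ref = "ACGTACGTACGT"
    hap_a = "ACGTTCGTACGT"  # het A>T at index 4

    def test_clean_alt_read(self):
        r = make_read("r", 2, self.hap_a[2:10])
        assert assign_read_haplotype(r, self.ref, self.hap_a, 4) == "alt"

    def test_clean_ref_read(self):
        r = make_read("r", 2, self.ref[2:10])
        assert assign_read_haplotype(r, self.ref, self.hap_a, 4) == "ref"

    def test_tie_resolved_by_site_base(self):
        # error at a non-SNP position -> one mismatch against both
        seq = list(self.hap_a[2:10])
        seq[6 - 2] = "A"  # error at index 6 (G on both haplotypes)
        r = make_read("r", 2, "".join(seq))
        assert assign_read_haplotype(r, self.ref, self.hap_a, 4) == "alt"

    def test_tie_with_third_base_dropped(self):
        seq = list(self.ref[2:10])
        seq[4 - 2] = "G"  # neither allele at the het site
        r = make_read("r", 2, "".join(seq))
        assert assign_read_haplotype(r, self.ref, self.hap_a, 4) == "dropped"

    def test_non_overlapping_rejected(self):
        r = make_read("r", 6, self.ref[6:12])
        with pytest.raises(ValueError):
            assign_read_haplotype(r, self.ref, self.hap_a, 4)


class TestCountAlleles:
    def test_site_base_counting(self):
        site = [("chr1", 4, "A", "G")]
        reads = []
        base_plan = ["A"] * 7 + ["G"] * 3 + ["T"]
        for i, b in enumerate(base_plan):
            seq = "CC" + b + "CC"
            reads.append(make_read(f"r{i}", 2, seq))
        counts = count_alleles(reads, site, dedup=False)
        row = counts.iloc[0]
        assert (row.ref_count, row.alt_count, row.other_count) == (7, 3, 1)

    def test_quality_gates(self):
        site = [("chr1", 4, "A", "G")]
        good = make_read("good", 2, "CCACC")
        low_mapq = make_read("lowm", 2, "CCGCC", mapq=0)
        low_bq = make_read("lowq", 2, "CCGCC", bq=10)
        counts = count_alleles([good, low_mapq, low_bq], site, dedup=False)
        row = counts.iloc[0]
        assert (row.ref_count, row.alt_count) == (1, 0)

    def test_duplicates_excluded(self):
        site = [("chr1", 4, "A", "G")]
        reads = [make_read("r1", 2, "CCACC"), make_read("r1dup", 2, "CCACC")]
        counts = count_alleles(reads, site, dedup=True)
        assert counts.iloc[0].ref_count == 1

    def test_homozygous_site_skipped(self):
        counts = count_alleles([make_read("r", 2, "CCACC")],
                               [hom(4, "A", "G")])
        assert len(counts) == 0

    def test_dual_haplotype_matches_site_base_on_surviving_reads(self):
        """Re-scoring already-aligned reads classifies like the site base."""
        from asbcall.sim_data import SimConfig, simulate

        cfg = SimConfig(genome_length=30_000, n_snps=120, het_fraction=1.0,
                        n_clustered=0, min_spacing=60, n_peaks=4,
                        peak_width=2000, enrichment_fold=40,
                        ref_bias_drop=0.3, seed=31)
        truth, reads = simulate(cfg)
        sites = truth.het_sites()
        site_base = count_alleles(reads, sites, mode="site-base")
        dual = count_alleles(reads, sites, mode="dual-haplotype",
                             haplotypes=({truth.chrom: truth.haplotypes[0]},
                                         {truth.chrom: truth.haplotypes[1]}))
        # the dual-haplotype assignment may rescue reads whose base at the
        # site was sequenced wrong, so ref+alt may grow, but never shrink
        agree = (site_base.ref_count <= dual.ref_count + 1) \
            & (site_base.alt_count <= dual.alt_count + 1)
        assert agree.all()
        both = site_base.merge(dual, on="pos", suffixes=("_s", "_d"))
        assert (both.ref_count_s - both.ref_count_d).abs().max() <= 2


class TestBinomialBiasTest:
    def test_balanced_counts_p_one(self):
        assert binomial_bias_test(5, 5) == 1.0

    def test_extreme_tail(self):
        assert binomial_bias_test(10, 0) == pytest.approx(2 / 1024, abs=1e-12)

    def test_mid_tail(self):
        assert binomial_bias_test(8, 2) == pytest.approx(112 / 1024,
                                                         abs=1e-12)

    def test_symmetry(self):
        for a, b in [(10, 0), (8, 2), (3, 9), (1, 1)]:
            assert binomial_bias_test(a, b) == binomial_bias_test(b, a)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            binomial_bias_test(-1, 5)
        with pytest.raises(ValueError):
            binomial_bias_test(0, 0)

    @settings(max_examples=200, derandomize=True)
    @given(a=st.integers(0, 500), b=st.integers(0, 500))
    def test_properties_hold_for_arbitrary_counts(self, a, b):
        """Symmetry, range, and the balanced-null maximum, for any counts."""
        if a + b == 0:
            return
        p = binomial_bias_test(a, b)
        assert 0.0 < p <= 1.0
        assert p == binomial_bias_test(b, a)
        if a == b:
            assert p == 1.0

    @settings(max_examples=50, derandomize=True)
    @given(st.lists(st.floats(1e-12, 1.0), min_size=1, max_size=200))
    def test_bh_qvalues_dominate_pvalues_and_stay_in_range(self, pvals):
        from asbcall.bias import bh_qvalues

        q = bh_qvalues(pvals)
        assert np.all(q >= np.asarray(pvals) - 1e-15)
        assert np.all((q > 0) & (q <= 1))

    def test_matches_minimum_likelihood_enumeration(self):
        """At p0=0.5 the doubled tail equals the min-likelihood two-sided p."""
        for n in (1, 2, 7, 12):
            for k in range(n + 1):
                pmf = binom.pmf(np.arange(n + 1), n, 0.5)
                enum = pmf[pmf <= pmf[k] * (1 + 1e-12)].sum()
                assert binomial_bias_test(k, n - k) == pytest.approx(
                    min(1.0, enum), abs=1e-12)


def brute_force_bh(pvals):
    """Textbook BH: q_(i) = min_{j >= i} p_(j) * m / j, monotone from above."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        q[i] = running
    return q


class TestBiasTable:
    def test_worked_example(self):
        counts = pd.DataFrame({
            "chrom": ["chr1"] * 3, "pos": [10, 20, 30],
            "ref": ["A"] * 3, "alt": ["G"] * 3,
            "ref_count": [10, 5, 8], "alt_count": [0, 5, 2],
            "other_count": [0, 0, 0],
        })
        table = bias_table(counts)
        assert list(table.tested) == [True, False, True]
        qs = table.q_value.tolist()
        assert qs[0] == pytest.approx(2 * 2 / 1024, abs=1e-9)   # 0.003906
        assert qs[2] == pytest.approx(112 / 1024, abs=1e-9)     # 0.109375
        assert math.isnan(qs[1])
        assert list(table.significant) == [True, False, False]

    def test_min_diff_gate(self):
        counts = pd.DataFrame({
            "chrom": ["chr1"], "pos": [10], "ref": ["A"], "alt": ["G"],
            "ref_count": [7], "alt_count": [2], "other_count": [0],
        })
        table = bias_table(counts)
        assert not table.tested.iloc[0]
        assert math.isnan(table.q_value.iloc[0])

    def test_all_balanced_none_significant(self):
        counts = pd.DataFrame({
            "chrom": ["chr1"] * 4, "pos": [10, 20, 30, 40],
            "ref": ["A"] * 4, "alt": ["G"] * 4,
            "ref_count": [5, 8, 12, 30], "alt_count": [5, 8, 12, 30],
            "other_count": [0] * 4,
        })
        table = bias_table(counts)
        assert not table.significant.any()
        assert not table.tested.any()

    def test_pct_ref_excludes_other(self):
        counts = pd.DataFrame({
            "chrom": ["chr1"], "pos": [10], "ref": ["A"], "alt": ["G"],
            "ref_count": [6], "alt_count": [2], "other_count": [4],
        })
        table = bias_table(counts)
        assert table.pct_ref.iloc[0] == pytest.approx(6 / 8)

    def test_bh_matches_brute_force(self):
        rng = np.random.default_rng(3)
        counts = pd.DataFrame({
            "chrom": "chr1", "pos": np.arange(60),
            "ref": "A", "alt": "G",
            "ref_count": rng.integers(0, 40, 60),
            "alt_count": rng.integers(0, 40, 60),
            "other_count": 0,
        })
        counts = counts[(counts.ref_count + counts.alt_count) > 0]
        table = bias_table(counts)
        tested = table[table.tested]
        expected = brute_force_bh(tested.p_value.to_numpy())
        assert np.allclose(tested.q_value.to_numpy(), expected)
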