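"""Generator contracts: determinism, planted truth, coverage, bias knobs."""

import numpy as np
import pytest

from asbcall.core import HET, HOM_ALT
from asbcall.bias import count_alleles
from asbcall.sim_data import (SimConfig, make_genome, make_peaks,
                              plant_variants, simulate, simulate_chip_reads)


class TestMakeGenome:
    def test_length_and_alphabet(self):
        seq = make_genome(1000, 0.41, seed=7)
        assert len(seq) == 1000
        assert set(seq) <= set("ACGT")

    def test_seed_determinism(self):
        assert make_genome(1000, 0.41, 7) == make_genome(1000, 0.41, 7)
        assert make_genome(1000, 0.41, 7) != make_genome(1000, 0.41, 8)

    def test_gc_zero_limit(self):
        seq = make_genome(1000, 0.0, seed=7)
        assert "G" not in seq and "C" not in seq

    def test_rejects_nonpositive_length(self):
        with pytest.raises(ValueError):
            make_genome(0, 0.4, 1)


class TestPlantVariants:
    def test_het_fraction_and_counts(self):
        ref = make_genome(20_000, 0.4, 1)
        genotypes, (hap_r, hap_a) = plant_variants(
            ref, n_snps=50, het_fraction=0.6, min_spacing=100, seed=2)
        assert len(genotypes) == 50
        zyg = [z for _, _, z in genotypes.values()]
        assert zyg.count(HET) == 30 and zyg.count(HOM_ALT) == 20
        for pos, (r, a, z) in genotypes.items():
            assert ref[pos] == r and a != r

    def test_haplotype_structure(self):
        ref = make_genome(20_000, 0.4, 3)
        genotypes, (hap_r, hap_a) = plant_variants(
            ref, n_snps=40, het_fraction=0.5, min_spacing=100, seed=4)
        diffs = {i for i, (x, y) in enumerate(zip(hap_r, hap_a)) if x != y}
        het_pos = {p for p, (_, _, z) in genotypes.items() if z == HET}
        assert diffs == het_pos  # haplotypes differ exactly at het sites
        for pos, (r, a, z) in genotypes.items():
            if z == HOM_ALT:
                assert hap_r[pos] == hap_a[pos] == a

    def test_spacing_and_cluster(self):
        ref = make_genome(30_000, 0.4, 5)
        genotypes, _ = plant_variants(ref, n_snps=53, het_fraction=0.5,
                                      min_spacing=80, n_clustered=3, seed=6)
        pos = np.array(sorted(genotypes))
        gaps = np.diff(pos)
        # exactly one 3-site cluster inside a 10 bp window
        close = np.flatnonzero(gaps < 10)
        assert len(close) == 2 and close[1] == close[0] + 1
        cluster = pos[close[0]:close[0] + 3]
        assert cluster[-1] - cluster[0] < 10
        spaced = np.diff(np.delete(pos, [close[0] + 1, close[0] + 2]))
        assert (spaced >= 80).all()

    def test_genome_too_small(self):
        with pytest.raises(ValueError):
            plant_variants("ACGT" * 50, n_snps=50, het_fraction=0.5,
                           min_spacing=100, seed=1)


class TestSimulateReads:
    def test_seed_determinism(self, small_sim):
        cfg, truth, reads = small_sim
        truth2, reads2 = simulate(cfg)
        assert truth2.genotypes == truth.genotypes
        assert truth2.reference == truth.reference
        assert [(r.name, r.start, r.seq, r.mapq, r.strand) for r in reads2] \
            == [(r.name, r.start, r.seq, r.mapq, r.strand) for r in reads]

    def test_coverage_enrichment_contract(self, small_sim):
        cfg, truth, reads = small_sim
        depth = np.zeros(cfg.genome_length)
        for r in reads:
            if not r.name.endswith(".dup"):
                depth[r.start:r.ref_end] += 1
        in_peak = np.zeros(cfg.genome_length, dtype=bool)
        near_peak = np.zeros(cfg.genome_length, dtype=bool)
        for p in truth.peaks:
            # coverage ramps over a read length around each boundary; compare
            # the flat interior against background clear of the ramps
            in_peak[p.start + cfg.read_length:p.end - cfg.read_length] = True
            near_peak[max(0, p.start - cfg.read_length):
                      p.end + cfg.read_length] = True
        ratio = depth[in_peak].mean() / depth[~near_peak].mean()
        assert ratio == pytest.approx(cfg.enrichment_fold, rel=0.15)

    def test_error_free_reads_match_haplotype(self):
        cfg = SimConfig(genome_length=20_000, n_snps=60, n_peaks=3,
                        peak_width=800, min_spacing=60,
                        base_error_rate=0.0, seed=9)
        truth, reads = simulate(cfg)
        hap_r, hap_a = truth.haplotypes
        for r in reads[:500]:
            span_r = hap_r[r.start:r.ref_end]
            span_a = hap_a[r.start:r.ref_end]
            assert r.seq in (span_r, span_a)

    def test_mapq_and_duplicate_fractions(self, small_sim):
        cfg, truth, reads = small_sim
        primaries = [r for r in reads if not r.name.endswith(".dup")]
        dups = [r for r in reads if r.name.endswith(".dup")]
        assert len(dups) == round(cfg.duplicate_fraction * len(primaries))
        by_name = {r.name: r for r in primaries}
        for d in dups:
            src = by_name[d.name[:-4]]
            assert (d.start, d.strand) == (src.start, src.strand)
        mapq0 = sum(r.mapq == 0 for r in primaries) / len(primaries)
        assert mapq0 == pytest.approx(cfg.nonunique_fraction, abs=0.01)

    def test_unbiased_het_fraction_near_half(self):
        """With beta=0.5 and no drop, pooled pct_ref ~ Binomial(N, 0.5)/N."""
        cfg = SimConfig(genome_length=60_000, n_snps=500, het_fraction=1.0,
                        min_spacing=60, n_clustered=0, n_peaks=5,
                        peak_width=6000, enrichment_fold=50,
                        base_error_rate=0.0, seed=21)
        truth, reads = simulate(cfg)
        counts = count_alleles(reads, truth.het_sites())
        n = (counts.ref_count + counts.alt_count).sum()
        pooled = counts.ref_count.sum() / n
        assert abs(pooled - 0.5) <= 3 * np.sqrt(0.25 / n)

    def test_planted_beta_recovered(self):
        """Sites with beta=0.8 show ~80% reference reads."""
        nb = 150
        cfg = SimConfig(genome_length=50_000, n_snps=200, het_fraction=1.0,
                        min_spacing=60, n_clustered=0, n_peaks=4,
                        peak_width=6000, enrichment_fold=60,
                        base_error_rate=0.0,
                        bias_sites=tuple((i, 0.8) for i in range(nb)),
                        seed=13)
        truth, reads = simulate(cfg)
        biased = [s for s in truth.het_sites() if s[1] in truth.bias]
        counts = count_alleles(reads, biased)
        informative = counts[(counts.ref_count + counts.alt_count) >= 20]
        pct = informative.ref_count / (informative.ref_count
                                       + informative.alt_count)
        assert pct.mean() == pytest.approx(0.8, abs=0.03)

    def test_ref_bias_drop_retention_algebra(self):
        """With beta=0.5 and drop delta, alt fraction -> (1-d)/(2-d)."""
        delta = 0.2
        cfg = SimConfig(genome_length=60_000, n_snps=500, het_fraction=1.0,
                        min_spacing=60, n_clustered=0, n_peaks=5,
                        peak_width=6000, enrichment_fold=50,
                        base_error_rate=0.0, ref_bias_drop=delta, seed=17)
        truth, reads = simulate(cfg)
        counts = count_alleles(reads, truth.het_sites())
        n = (counts.ref_count + counts.alt_count).sum()
        alt_frac = counts.alt_count.sum() / n
        expected = (1 - delta) / (2 - delta)
        assert alt_frac == pytest.approx(expected, abs=3 * np.sqrt(0.25 / n))

    def test_config_validation(self):
        with pytest.raises(ValueError):
            SimConfig(het_fraction=1.5).validate()
        with pytest.raises(ValueError):
            SimConfig(read_length=0).validate()
        with pytest.raises(ValueError):
            SimConfig(n_snps=5, n_clustered=6).validate()


class TestPeaks:
    def test_non_overlapping_with_centered_summits(self):
        peaks = make_peaks(100_000, 10, 1000, seed=3)
        assert len(peaks) == 10
        for a, b in zip(peaks, peaks[1:]):
            assert a.end <= b.start
        for p in peaks:
            assert p.start <= p.summit < p.end


class TestTruthBundle:
    def test_round_trips(self, small_sim, tmp_path):
        from asbcall import io as aio
        from asbcall.sim_data import write_truth_bundle

        cfg, truth, reads = small_sim
        paths = write_truth_bundle(truth, reads, tmp_path)
        assert aio.read_fasta(paths["reference"])[truth.chrom] \
            == truth.reference
        reads2 = aio.read_sam(paths["reads"])
        assert [(r.name, r.start, r.seq, r.mapq, r.strand, tuple(r.cigar))
                for r in reads2] \
            == [(r.name, r.start, r.seq, r.mapq, r.strand, tuple(r.cigar))
                for r in reads]
        calls = aio.read_vcf(paths["truth_vcf"])
        assert {(c.pos, c.ref, c.alt, c.genotype) for c in calls} \
            == {(p, r, a, z) for p, (r, a, z) in truth.genotypes.items()}
        peaks = aio.read_bed_peaks(paths["peaks"])
        assert len(peaks) == cfg.n_peaks
        assert [(p.chrom, p.start, p.end, p.summit) for p in peaks] \
            == [(p.chrom, p.start, p.end, p.summit) for p in truth.peaks]
        assert aio.read_bias_truth(paths["bias_tsv"]) == truth.bias
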