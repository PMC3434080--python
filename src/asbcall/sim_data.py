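"""Synthetic ChIP-seq data generator.

Produces a random genome, planted heterozygous/homozygous SNPs, and
peak-enriched aligned reads with configurable per-site allelic bias,
reference-mapping bias (alternate-haplotype read loss), sequencing error,
multi-mapping (MAPQ 0) reads and PCR duplicates. Reads are emitted directly
as alignments - no aligner is involved - so mapping bias is modelled
explicitly through ``ref_bias_drop`` rather than through alignment
heuristics.

The planted truth (:class:`SimTruth`) carries the two individual
haplotypes, the genotype at every planted site, the per-site reference
sampling probability beta, and the peak intervals, so every downstream
stage of the pipeline can be scored against ground truth.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .core import BASES, TRANSITION_PARTNER, HET, HOM_ALT, Peak, Read

log = logging.getLogger(__name__)

CLUSTER_SPAN = 10  # bp window that defines a SNP cluster


@dataclass
class SimConfig:
    """Study conditions for one simulated ChIP-seq experiment.

    Defaults emulate a desk-scale version of a single-individual CTCF
    ChIP-seq genotyping experiment: ~1x genomic background with 30x
    coverage inside peaks, 50 bp single-end reads, a 0.5% per-base error
    rate reported as constant Q30, a roughly 2:1 transition:transversion
    ratio among planted SNPs, and two heterozygous sites for every
    homozygous-alternate one.
    """

    genome_length: int = 200_000
    gc_fraction: float = 0.41          # human-like GC content
    n_snps: int = 1000
    het_fraction: float = 0.67
    min_spacing: int = 50              # between non-clustered planted sites
    n_clustered: int = 3               # sites planted < 10 bp apart
    n_peaks: int = 40
    peak_width: int = 1000
    background_depth: float = 1.0      # mean reads/base off-peak
    enrichment_fold: float = 30.0
    read_length: int = 50
    base_error_rate: float = 0.005
    base_quality: int = 30             # constant reported Phred quality
    bias_sites: tuple = ()             # ((het site index, beta), ...)
    ref_bias_drop: float = 0.0         # P(discard an alt-haplotype read)
    nonunique_fraction: float = 0.02   # reads emitted with MAPQ 0
    duplicate_fraction: float = 0.05
    transition_fraction: float = 0.68  # P(planted alt is a transition)
    del_fraction: float = 0.0          # reads carrying a short deletion
    del_length: int = 3
    chrom: str = "chr1"
    seed: int = 0

    def validate(self) -> None:
        probs = {
            "gc_fraction": self.gc_fraction,
            "het_fraction": self.het_fraction,
            "base_error_rate": self.base_error_rate,
            "ref_bias_drop": self.ref_bias_drop,
            "nonunique_fraction": self.nonunique_fraction,
            "duplicate_fraction": self.duplicate_fraction,
            "transition_fraction": self.transition_fraction,
            "del_fraction": self.del_fraction,
        }
        for name, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name}={p} outside [0, 1]")
        for idx, beta in self.bias_sites:
            if not 0.0 <= beta <= 1.0:
                raise ValueError(f"bias beta {beta} outside [0, 1]")
        if self.genome_length <= 0:
            raise ValueError("genome_length must be positive")
        if not 0 < self.read_length < self.genome_length:
            raise ValueError("read_length must be in (0, genome_length)")
        if self.n_clustered > self.n_snps:
            raise ValueError("n_clustered cannot exceed n_snps")
        if self.n_clustered == 1:
            raise ValueError("a cluster needs 0 or >= 2 sites")


@dataclass
class SimTruth:
    """Planted ground truth emitted alongside the simulated reads."""

    chrom: str
    reference: str
    genotypes: dict          # pos -> (ref, alt, HET | HOM_ALT)
    bias: dict               # pos -> beta (reference-haplotype probability)
    peaks: list
    haplotypes: tuple        # (haplotype R, haplotype A), full sequences

    @property
    def het_positions(self) -> list[int]:
        return sorted(p for p, (_, _, z) in self.genotypes.items() if z == HET)

    def het_sites(self) -> list[tuple]:
        """(chrom, pos, ref, alt) for every heterozygous planted site."""
        return [
            (self.chrom, p, self.genotypes[p][0], self.genotypes[p][1])
            for p in self.het_positions
        ]


def make_genome(length: int, gc_fraction: float, seed: int) -> str:
    """Random genome with the requested GC content."""
    if length <= 0:
        raise ValueError(f"genome length must be positive, got {length}")
    if not 0.0 <= gc_fraction <= 1.0:
        raise ValueError("gc_fraction outside [0, 1]")
    rng = np.random.default_rng(seed)
    p = np.array([
        (1 - gc_fraction) / 2,  # A
        gc_fraction / 2,        # C
        gc_fraction / 2,        # G
        (1 - gc_fraction) / 2,  # T
    ])
    idx = rng.choice(4, size=length, p=p)
    return "".join(BASES[i] for i in idx)


def _draw_alt(ref: str, transition_fraction: float, rng) -> str:
    if rng.random() < transition_fraction:
        return TRANSITION_PARTNER[ref]
    tv = [b for b in BASES if b != ref and b != TRANSITION_PARTNER[ref]]
    return tv[rng.integers(len(tv))]


def plant_variants(
    reference: str,
    n_snps: int,
    het_fraction: float,
    min_spacing: int,
    n_clustered: int = 0,
    seed: int = 0,
    transition_fraction: float = 0.68,
) -> tuple[dict, tuple[str, str]]:
    """Plant SNPs on a reference and build the two haplotypes.

    Non-clustered sites are at least ``min_spacing`` bases apart;
    ``n_clustered`` additional sites are packed into a single 10 bp
    window to exercise the cluster hard filter. Haplotype R carries the
    reference base at heterozygous sites, haplotype A the alternate;
    homozygous-alternate sites differ from the reference on both.

    Returns ``(genotypes, (hap_r, hap_a))`` with ``genotypes`` mapping
    position to ``(ref, alt, zygosity)``.
    """
    rng = np.random.default_rng(seed)
    L = len(reference)
    n_spaced = n_snps - n_clustered
    if n_spaced < 0:
        raise ValueError("n_clustered cannot exceed n_snps")
    span = L - (n_spaced - 1) * min_spacing
    if n_spaced > 0 and span < n_spaced:
        raise ValueError(
            f"genome of {L} bp too small for {n_spaced} sites "
            f"spaced >= {min_spacing} bp"
        )
    if n_spaced > 0:
        draws = np.sort(rng.choice(span, size=n_spaced, replace=False))
        positions = draws + np.arange(n_spaced) * min_spacing
    else:
        positions = np.array([], dtype=np.int64)

    cluster: list[int] = []
    if n_clustered:
        # drop the cluster into the widest gap between spaced sites so it
        # never collides with them
        bounds = np.concatenate(([0], positions, [L - 1]))
        gaps = np.diff(bounds)
        g = int(np.argmax(gaps))
        if gaps[g] < CLUSTER_SPAN + 4:
            raise ValueError("no room left to place the clustered sites")
        anchor = int(bounds[g]) + int(gaps[g]) // 2 - CLUSTER_SPAN // 2
        offsets = rng.choice(CLUSTER_SPAN - 1, size=n_clustered, replace=False)
        cluster = sorted(anchor + int(o) for o in offsets)

    all_pos = np.concatenate((positions, np.array(cluster, dtype=np.int64)))
    all_pos = np.sort(all_pos).astype(int)

    n_het = int(round(het_fraction * n_snps))
    het_mask = np.zeros(n_snps, dtype=bool)
    het_mask[rng.permutation(n_snps)[:n_het]] = True

    hap_r = list(reference)
    hap_a = list(reference)
    genotypes: dict = {}
    for pos, is_het in zip(all_pos, het_mask):
        ref = reference[pos]
        alt = _draw_alt(ref, transition_fraction, rng)
        zyg = HET if is_het else HOM_ALT
        genotypes[int(pos)] = (ref, alt, zyg)
        hap_a[pos] = alt
        if zyg == HOM_ALT:
            hap_r[pos] = alt
    return genotypes, ("".join(hap_r), "".join(hap_a))


def make_peaks(
    genome_length: int, n_peaks: int, peak_width: int, seed: int, chrom: str = "chr1"
) -> list[Peak]:
    """Non-overlapping peaks with the summit at the interval centre."""
    rng = np.random.default_rng(seed)
    slot = peak_width + peak_width // 2  # guaranteed inter-peak gap
    span = genome_length - (n_peaks - 1) * slot - peak_width
    if span < n_peaks:
        raise ValueError("genome too small for the requested peaks")
    draws = np.sort(rng.choice(span, size=n_peaks, replace=False))
    starts = draws + np.arange(n_peaks) * slot
    return [
        Peak(chrom, int(s), int(s) + peak_width, int(s) + peak_width // 2,
             name=f"peak{i + 1}", score=1000.0)
        for i, s in enumerate(starts)
    ]


def simulate_chip_reads(truth: SimTruth, config: SimConfig) -> list[Read]:
    """Draw peak-enriched reads from the planted haplotypes.

    Fragment centres are drawn with density ``background_depth`` reads/bp
    of coverage off-peak and ``background_depth * enrichment_fold`` inside
    peaks. Each fragment is assigned a haplotype: when it overlaps a
    designated bias site (the nearest one if several) the reference
    haplotype is chosen with probability beta, otherwise with probability
    0.5. Alternate-haplotype fragments are then discarded with probability
    ``ref_bias_drop`` (the reference-mapping-bias knob). Bases are copied
    from the assigned haplotype and flipped to a uniformly chosen other
    base with probability ``base_error_rate``. ``nonunique_fraction`` of
    reads get MAPQ 0 (the rest MAPQ 37) and ``duplicate_fraction`` of the
    retained reads are emitted twice at identical coordinates and strand.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    L = len(truth.reference)
    rl = config.read_length

    weights = np.full(L, config.background_depth, dtype=float)
    for pk in truth.peaks:
        weights[pk.start:pk.end] *= config.enrichment_fold
    lam = weights / rl  # expected fragment centres per base
    n_frags = rng.poisson(lam.sum())
    centers = rng.choice(L, size=n_frags, p=lam / lam.sum())
    centers.sort()

    bias_pos = np.array(sorted(truth.bias), dtype=np.int64)
    bias_beta = np.array([truth.bias[int(p)] for p in bias_pos])

    hap_r, hap_a = truth.haplotypes
    reads: list[Read] = []
    quals = np.full(rl, config.base_quality, dtype=np.uint8)
    for i, c in enumerate(centers):
        has_del = config.del_fraction > 0 and rng.random() < config.del_fraction
        ref_span = rl + (config.del_length if has_del else 0)
        start = int(np.clip(c - ref_span // 2, 0, L - ref_span))

        # haplotype assignment at fragment level
        p_ref = 0.5
        if bias_pos.size:
            inside = (bias_pos >= start) & (bias_pos < start + ref_span)
            if inside.any():
                cand = bias_pos[inside]
                nearest = int(np.argmin(np.abs(cand - c)))
                p_ref = float(bias_beta[inside][nearest])
        use_ref = rng.random() < p_ref
        if not use_ref and config.ref_bias_drop > 0:
            if rng.random() < config.ref_bias_drop:
                continue  # alt-haplotype fragment lost to mapping bias
        hap = hap_r if use_ref else hap_a

        if has_del:
            m1 = int(rng.integers(5, rl - 5))
            cigar = (("M", m1), ("D", config.del_length), ("M", rl - m1))
            seq = hap[start:start + m1] + \
                hap[start + m1 + config.del_length:start + ref_span]
        else:
            cigar = (("M", rl),)
            seq = hap[start:start + rl]

        if config.base_error_rate > 0:
            err = np.flatnonzero(rng.random(rl) < config.base_error_rate)
            if err.size:
                seq_l = list(seq)
                for j in err:
                    others = [b for b in BASES if b != seq_l[j]]
                    seq_l[j] = others[rng.integers(3)]
                seq = "".join(seq_l)

        mapq = 0 if rng.random() < config.nonunique_fraction else 37
        strand = "+" if rng.random() < 0.5 else "-"
        reads.append(Read(
            name=f"r{i:07d}", chrom=truth.chrom, start=start, mapq=mapq,
            strand=strand, seq=seq, quals=quals.copy(), cigar=cigar,
        ))

    # PCR duplicates: exact copies at identical coordinates and strand
    n_dup = int(round(config.duplicate_fraction * len(reads)))
    if n_dup:
        for k in rng.choice(len(reads), size=n_dup, replace=False):
            src = reads[int(k)]
            reads.append(replace(src, name=src.name + ".dup",
                                 quals=src.quals.copy()))
    reads.sort(key=lambda r: (r.start, r.name))
    return reads


def simulate(config: SimConfig) -> tuple[SimTruth, list[Read]]:
    """Run the full generator: genome, variants, peaks, reads."""
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    s_genome, s_var, s_peaks = (int(c.generate_state(1)[0] % 2**31)
                                for c in ss.spawn(3))
    reference = make_genome(config.genome_length, config.gc_fraction, s_genome)
    genotypes, haplotypes = plant_variants(
        reference, config.n_snps, config.het_fraction, config.min_spacing,
        config.n_clustered, s_var, config.transition_fraction,
    )
    peaks = make_peaks(config.genome_length, config.n_peaks,
                       config.peak_width, s_peaks, config.chrom)
    het = sorted(p for p, (_, _, z) in genotypes.items() if z == HET)
    bias = {}
    for idx, beta in config.bias_sites:
        bias[het[idx]] = float(beta)
    truth = SimTruth(config.chrom, reference, genotypes, bias, peaks,
                     haplotypes)
    reads = simulate_chip_reads(truth, config)
    log.info("simulated %d reads over %d bp (%d planted SNPs, %d peaks)",
             len(reads), config.genome_length, config.n_snps, config.n_peaks)
    return truth, reads


def write_truth_bundle(truth: SimTruth, reads: list[Read], outdir) -> dict:
    """Write reference FASTA, sorted SAM, truth VCF, bias TSV and peaks BED.

    Returns a mapping of logical name to path. Re-reading each file with
    the paired reader in :mod:`asbcall.io` reproduces the in-memory
    objects.
    """
    from pathlib import Path

    from . import io as aio
    from .core import VariantCall

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "reference": out / "reference.fa",
        "reads": out / "reads.sam",
        "truth_vcf": out / "truth.vcf",
        "bias_tsv": out / "truth_bias.tsv",
        "peaks": out / "peaks.bed",
    }
    reference = {truth.chrom: truth.reference}
    aio.write_fasta(reference, paths["reference"])
    aio.write_sam(reads, reference, paths["reads"])
    truth_calls = [
        VariantCall(truth.chrom, pos, ref, alt, zyg, qual=0.0, gq=0,
                    depth=0, allele_depths=(0, 0))
        for pos, (ref, alt, zyg) in sorted(truth.genotypes.items())
    ]
    aio.write_vcf(truth_calls, reference, paths["truth_vcf"])
    aio.write_bias_truth(truth.bias, truth.chrom, paths["bias_tsv"])
    aio.write_bed_peaks(truth.peaks, paths["peaks"])
    return paths
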