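"""Descriptive quality metrics for a de novo ChIP-seq call set.

Covers the standard QC surfaces for this kind of experiment: the
transition/transversion ratio, heterozygosity rates under depth
filtering, location versus genotype overlap with an external call set,
regions of assayable coverage (depth >= k, "Ht-k" regions), recovery of
known SNPs inside them, summit-relative SNP/score profiles, per-chromosome
SNP density, and depth-saturation curves from seeded read subsampling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import HET, Peak, VariantCall, merge_positions

log = logging.getLogger(__name__)


@dataclass
class ProfileResult:
    """Offset-binned profile around peak summits."""

    edges: np.ndarray   # bin edges in bp relative to the summit
    values: np.ndarray  # per-bin SNP count (point mode) or mean (track mode)

    @property
    def centers(self) -> np.ndarray:
        return (self.edges[:-1] + self.edges[1:]) / 2.0


def titv_ratio(calls) -> float | None:
    """Transition/transversion ratio; ``None`` when no transversions."""
    calls = list(calls)
    ti = sum(1 for c in calls if c.is_transition)
    tv = len(calls) - ti
    if tv == 0:
        log.warning("Ti/Tv undefined: call set has no transversions")
        return None
    return ti / tv


def heterozygosity_rate(calls, min_depth_filter: int | None = None) -> float:
    """Fraction of calls that are heterozygous, optionally depth-filtered."""
    kept = [c for c in calls
            if min_depth_filter is None or c.depth >= min_depth_filter]
    if not kept:
        raise ValueError("no calls left after depth filtering")
    return sum(c.genotype == HET for c in kept) / len(kept)


def genotype_overlap(set_a, set_b, mode: str = "location"):
    """Overlap of call set A with B as a percentage of A.

    ``location`` mode matches on (chrom, pos, allele pair as a set);
    ``genotype`` mode additionally requires identical zygosity. Returns
    ``(percentage, matched calls from A)``.
    """
    if mode not in ("location", "genotype"):
        raise ValueError(f"unknown overlap mode {mode!r}")
    if not set_a:
        raise ValueError("overlap undefined for an empty call set A")
    key = (VariantCall.location_key if mode == "location"
           else VariantCall.genotype_key)
    b_keys = {key(c) for c in set_b}
    matched = [c for c in set_a if key(c) in b_keys]
    return 100.0 * len(matched) / len(set_a), matched


def ht_regions(depths: dict, k: int = 5, reference: dict | None = None):
    """Maximal intervals with depth >= k and the genome fraction covered.

    ``depths`` maps chrom to a per-position depth array. The fraction
    denominator is the non-N genome length when ``reference`` is given,
    otherwise the total length of the depth arrays.
    """
    if k < 1:
        raise ValueError("coverage threshold k must be >= 1")
    intervals = []
    covered = 0
    for chrom, d in depths.items():
        pos = np.flatnonzero(np.asarray(d) >= k)
        covered += pos.size
        intervals.extend((chrom, s, e) for s, e in merge_positions(pos))
    if reference is not None:
        denom = sum(len(s) - s.upper().count("N") for s in reference.values())
    else:
        denom = sum(len(d) for d in depths.values())
    return intervals, (covered / denom if denom else 0.0)


def _in_regions(chrom: str, pos: int, regions) -> bool:
    return any(c == chrom and s <= pos < e for c, s, e in regions)


def recovery_rate(reference_calls, discovered_calls, regions,
                  mode: str = "location") -> float:
    """Percent of in-region reference calls matched by the discovered set."""
    in_region = [c for c in reference_calls
                 if _in_regions(c.chrom, c.pos, regions)]
    if not in_region:
        raise ValueError("no reference calls inside the given regions")
    pct, _ = genotype_overlap(in_region, discovered_calls, mode=mode)
    return pct


def summit_profile(data, peaks: list, bin: int = 10,
                   window: int = 1000) -> ProfileResult:
    """Offset-binned profile of SNP positions or a score track around summits.

    ``data`` is either a mapping chrom -> sorted position iterable /
    array of SNP positions (point mode: counts summed over peaks) or a
    mapping chrom -> per-base float track (track mode: per-bin means
    averaged over peaks). Offsets are signed, relative to each summit,
    spanning ``[-window, window)`` in ``bin`` bp bins.
    """
    if not peaks:
        raise ValueError("summit_profile requires at least one peak")
    if window % bin != 0:
        raise ValueError("window must be a multiple of the bin width")
    edges = np.arange(-window, window + bin, bin)
    n_bins = len(edges) - 1

    sample = next(iter(data.values())) if isinstance(data, dict) else None
    track_mode = isinstance(sample, np.ndarray) and \
        np.issubdtype(sample.dtype, np.floating)

    if track_mode:
        acc = np.zeros(n_bins)
        n_terms = np.zeros(n_bins)
        for pk in peaks:
            track = data[pk.chrom]
            for i in range(n_bins):
                lo = pk.summit + int(edges[i])
                hi = pk.summit + int(edges[i + 1])
                lo_c, hi_c = max(lo, 0), min(hi, len(track))
                if hi_c > lo_c:
                    acc[i] += float(np.mean(track[lo_c:hi_c]))
                    n_terms[i] += 1
        values = np.divide(acc, n_terms, out=np.full(n_bins, np.nan),
                           where=n_terms > 0)
    else:
        values = np.zeros(n_bins)
        for pk in peaks:
            positions = np.asarray(list(data.get(pk.chrom, [])))
            if positions.size == 0:
                continue
            offsets = positions - pk.summit
            inside = (offsets >= -window) & (offsets < window)
            values += np.histogram(offsets[inside], bins=edges)[0]
    return ProfileResult(edges=edges, values=values)


def chromosomal_density(calls, chrom_lengths: dict) -> dict:
    """SNPs per megabase for every chromosome in ``chrom_lengths``."""
    counts: dict = {c: 0 for c in chrom_lengths}
    for call in calls:
        if call.chrom not in chrom_lengths:
            raise ValueError(f"call on unknown chromosome {call.chrom}")
        counts[call.chrom] += 1
    return {c: counts[c] / (chrom_lengths[c] / 1e6) for c in chrom_lengths}


def saturation_curve(
    reads,
    reference: dict,
    fractions,
    seed: int,
    genotyper_config=None,
    filter_config=None,
    known_sites: set | None = None,
    ht_k: int = 5,
) -> pd.DataFrame:
    """SNP discovery as a function of sequencing depth.

    For each fraction, ``floor(fraction * N)`` reads are subsampled
    without replacement (seeded; fraction 1.0 is exactly the full set),
    the full genotype + filter pipeline is run, and passing SNPs are
    counted in total and within the assayable (depth >= ``ht_k``) regions
    computed once from the *full* read set. Returns a DataFrame with
    columns fraction, n_reads, total_snps, ht_snps.
    """
    from .pipeline import genotype_and_filter

    fractions = list(fractions)
    for f in fractions:
        if not 0.0 < f <= 1.0:
            raise ValueError(f"fraction {f} outside (0, 1]")

    full = genotype_and_filter(reads, reference, genotyper_config,
                               filter_config, known_sites)
    regions, _ = ht_regions(full.coverage.usable_depth, k=ht_k)

    rng = np.random.default_rng(seed)
    rows = []
    n = len(reads)
    for f in fractions:
        m = int(f * n)
        if m == n:
            subset = list(reads)
        else:
            keep = rng.choice(n, size=m, replace=False)
            subset = [reads[i] for i in sorted(keep)]
        subset.sort(key=lambda r: (r.chrom, r.start, r.name))
        res = genotype_and_filter(subset, reference, genotyper_config,
                                  filter_config, known_sites)
        passing = [c for c in res.calls if c.passing]
        rows.append({
            "fraction": f,
            "n_reads": m,
            "total_snps": len(passing),
            "ht_snps": sum(_in_regions(c.chrom, c.pos, regions)
                           for c in passing),
        })
    return pd.DataFrame(rows)


def annotation_class_counts(calls, annotation_intervals: dict) -> dict:
    """Count calls per annotation class from a BED-style class map.

    ``annotation_intervals`` maps a class name (e.g. exon, intron,
    5'UTR) to a list of ``(chrom, start, end)`` intervals. Calls matching
    no class are reported under ``"intergenic"``. A convenience for
    genomic-distribution summaries; classes are checked in dict order and
    a call counts once, under the first matching class.
    """
    counts = {name: 0 for name in annotation_intervals}
    counts["intergenic"] = 0
    for call in calls:
        for name, ivs in annotation_intervals.items():
            if _in_regions(call.chrom, call.pos, ivs):
                counts[name] += 1
                break
        else:
            counts["intergenic"] += 1
    return counts
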