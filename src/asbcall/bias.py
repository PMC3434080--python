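"""Allele-specific binding analysis at heterozygous SNPs.

Builds individual-specific reference haplotypes from the filtered call
set, counts allele-supporting reads at heterozygous sites, and tests each
site for allelic imbalance with an exact two-sided binomial test under the
null that both alleles are equally represented in the ChIP DNA. P-values
are corrected with Benjamini-Hochberg FDR, restricted to sites where the
two allele counts differ by at least ``min_diff`` (default 6) reads.

To counter reference-mapping bias without an aligner in the loop, the
module writes both haplotype FASTAs for external realignment and offers a
built-in dual-haplotype mode that re-scores each already-aligned read
against both personalized haplotypes.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.stats import binom
from statsmodels.stats.multitest import multipletests

from .core import HET, Read, VariantCall
from .genotyper import mark_duplicates

log = logging.getLogger(__name__)

COUNT_COLUMNS = ["chrom", "pos", "ref", "alt",
                 "ref_count", "alt_count", "other_count"]
BIAS_COLUMNS = COUNT_COLUMNS + ["pct_ref", "p_value", "q_value",
                                "tested", "significant"]


def personalize_reference(
    reference: dict, calls: list[VariantCall]
) -> tuple[dict, dict]:
    """Build the two individual-specific haplotype genomes.

    Haplotype R keeps the reference base at heterozygous sites, haplotype
    A carries the alternate; homozygous-alternate sites carry the
    alternate on both. Calls are expected to be the filter-passing
    biallelic SNVs of one individual.
    """
    hap_r = {c: list(s) for c, s in reference.items()}
    hap_a = {c: list(s) for c, s in reference.items()}
    for call in calls:
        if call.chrom not in reference:
            raise ValueError(f"call on unknown contig {call.chrom}")
        if reference[call.chrom][call.pos] != call.ref:
            raise ValueError(
                f"{call.chrom}:{call.pos + 1}: call ref {call.ref} does not "
                f"match reference base {reference[call.chrom][call.pos]}"
            )
        hap_a[call.chrom][call.pos] = call.alt
        if call.genotype != HET:
            hap_r[call.chrom][call.pos] = call.alt
    return ({c: "".join(s) for c, s in hap_r.items()},
            {c: "".join(s) for c, s in hap_a.items()})


def assign_read_haplotype(
    read: Read, hap_r: str, hap_a: str, pos: int
) -> str:
    """Assign a read to a haplotype by mismatch re-scoring.

    Mismatches of the read against both haplotypes are counted over the
    read's aligned span; strictly fewer mismatches wins. Ties are decided
    by the read's base at the heterozygous site: the reference allele
    votes ``"ref"``, the alternate ``"alt"``, and any other base returns
    ``"dropped"``.
    """
    if not read.overlaps(pos):
        raise ValueError(
            f"read {read.name} does not overlap position {pos}")
    mm_r = mm_a = 0
    for q, r, n in read.aligned_blocks():
        for k in range(n):
            b = read.seq[q + k]
            mm_r += b != hap_r[r + k]
            mm_a += b != hap_a[r + k]
    if mm_r < mm_a:
        return "ref"
    if mm_a < mm_r:
        return "alt"
    at_site = read.base_at(pos)
    if at_site is None:
        return "dropped"
    base = at_site[0]
    if base == hap_r[pos]:
        return "ref"
    if base == hap_a[pos]:
        return "alt"
    return "dropped"


def count_alleles(
    reads: list[Read],
    sites,
    mode: str = "site-base",
    min_bq: int = 20,
    min_mapq: int = 10,
    haplotypes: tuple | None = None,
    dedup: bool = True,
) -> pd.DataFrame:
    """Count reads supporting each allele at heterozygous sites.

    ``sites`` is a sequence of ``(chrom, pos, ref, alt)`` tuples or
    :class:`VariantCall` objects (homozygous calls are skipped with a
    warning). ``site-base`` mode classifies each read by its base at the
    site; ``dual-haplotype`` mode classifies by
    :func:`assign_read_haplotype` and requires ``haplotypes=(hap_r,
    hap_a)`` genome dicts. Reads below ``min_mapq``, bases below
    ``min_bq`` at the site, and duplicate reads are excluded.
    """
    if mode not in ("site-base", "dual-haplotype"):
        raise ValueError(f"unknown counting mode {mode!r}")
    if mode == "dual-haplotype" and haplotypes is None:
        raise ValueError("dual-haplotype mode requires the haplotype pair")

    norm_sites = []
    for s in sites:
        if isinstance(s, VariantCall):
            if s.genotype != HET:
                log.warning("skipping homozygous site %s:%d in allele "
                            "counting", s.chrom, s.pos + 1)
                continue
            norm_sites.append((s.chrom, s.pos, s.ref, s.alt))
        else:
            norm_sites.append(tuple(s))

    if dedup:
        reads = mark_duplicates(sorted(reads, key=lambda r: (r.chrom, r.start)))

    by_chrom: dict = {}
    for i, (chrom, pos, _, _) in enumerate(norm_sites):
        by_chrom.setdefault(chrom, []).append((pos, i))
    for chrom in by_chrom:
        by_chrom[chrom].sort()
    site_pos = {c: np.array([p for p, _ in v]) for c, v in by_chrom.items()}
    site_idx = {c: [i for _, i in v] for c, v in by_chrom.items()}

    counts = np.zeros((len(norm_sites), 3), dtype=np.int64)  # ref, alt, other
    for read in reads:
        if read.chrom not in site_pos or read.mapq < min_mapq:
            continue
        pos_arr = site_pos[read.chrom]
        lo = int(np.searchsorted(pos_arr, read.start, side="left"))
        hi = int(np.searchsorted(pos_arr, read.ref_end, side="left"))
        for j in range(lo, hi):
            i = site_idx[read.chrom][j]
            chrom, pos, ref, alt = norm_sites[i]
            at_site = read.base_at(pos)
            if at_site is None or at_site[1] < min_bq:
                continue
            if mode == "site-base":
                base = at_site[0]
                col = 0 if base == ref else 1 if base == alt else 2
            else:
                outcome = assign_read_haplotype(
                    read, haplotypes[0][chrom], haplotypes[1][chrom], pos)
                col = {"ref": 0, "alt": 1, "dropped": 2}[outcome]
            counts[i, col] += 1

    return pd.DataFrame({
        "chrom": [s[0] for s in norm_sites],
        "pos": [s[1] for s in norm_sites],
        "ref": [s[2] for s in norm_sites],
        "alt": [s[3] for s in norm_sites],
        "ref_count": counts[:, 0],
        "alt_count": counts[:, 1],
        "other_count": counts[:, 2],
    })


def binomial_bias_test(ref_count: int, alt_count: int) -> float:
    """Exact two-sided binomial p-value for allelic imbalance.

    Under the null both alleles are equally represented, so the count of
    the rarer allele ``k = min(ref, alt)`` follows the lower tail of
    Binomial(n, 0.5); the two-sided p-value doubles that tail and is
    clipped at 1 (equal counts give exactly 1). At p0 = 0.5 this equals
    the minimum-likelihood two-sided convention.
    """
    if ref_count < 0 or alt_count < 0:
        raise ValueError("allele counts must be non-negative")
    n = ref_count + alt_count
    if n < 1:
        raise ValueError("at least one allele-supporting read required")
    if ref_count == alt_count:
        return 1.0
    k = min(ref_count, alt_count)
    return float(min(1.0, 2.0 * binom.cdf(k, n, 0.5)))


def bh_qvalues(pvals) -> np.ndarray:
    """Benjamini-Hochberg q-values for a vector of p-values."""
    return multipletests(np.asarray(pvals, dtype=float),
                         method="fdr_bh")[1]


def bias_table(
    counts: pd.DataFrame, min_diff: int = 6, alpha: float = 0.05
) -> pd.DataFrame:
    """Binomial test + gated BH FDR over a table of allele counts.

    Every site with at least one informative read gets a p-value and
    ``pct_ref = ref/(ref+alt)``; only sites whose allele counts differ by
    at least ``min_diff`` enter the FDR set and receive a q-value.
    ``significant`` is ``tested and q < alpha``.
    """
    df = counts.copy()
    n = df["ref_count"] + df["alt_count"]
    with np.errstate(invalid="ignore"):
        df["pct_ref"] = np.where(n > 0, df["ref_count"] / n.replace(0, 1),
                                 np.nan)
    df["p_value"] = [
        binomial_bias_test(int(r), int(a)) if r + a >= 1 else np.nan
        for r, a in zip(df["ref_count"], df["alt_count"])
    ]
    df["tested"] = ((df["ref_count"] - df["alt_count"]).abs() >= min_diff) \
        & (n >= 1)
    df["q_value"] = np.nan
    df["significant"] = False
    tested = df["tested"].to_numpy()
    if tested.any():
        q = bh_qvalues(df.loc[tested, "p_value"])
        df.loc[tested, "q_value"] = q
        df.loc[tested, "significant"] = q < alpha
    return df[ [c for c in BIAS_COLUMNS if c in df.columns]
               + [c for c in df.columns if c not in BIAS_COLUMNS] ]
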