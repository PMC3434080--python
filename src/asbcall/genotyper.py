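"""Pileup construction and diploid genotype calling.

The caller implements the standard diploid Bayesian model: for a candidate
genotype ``g = {a1, a2}`` the likelihood of an observed base ``b`` with
error probability ``e = 10**(-q/10)`` is

    P(b | g) = 0.5 * P(b | a1) + 0.5 * P(b | a2),
    P(b | a) = 1 - e  if b == a  else  e / 3,

with genotype priors ``P(hom-ref) = 1 - 3*theta/2``, ``P(het) = theta``,
``P(hom-alt) = theta/2`` for a per-site heterozygosity ``theta``. The site
quality is the Phred-scaled posterior of hom-ref; the genotype quality the
Phred-scaled posterior that the call is wrong. Only biallelic SNVs are
emitted: at multiallelic columns the single best-supported non-reference
base is considered.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import groupby
from typing import Iterator

import numpy as np
from scipy.special import logsumexp

from .core import (BASE_INDEX, BASES, HET, HOM_ALT, HOM_REF, Observation,
                   PileupColumn, Read, VariantCall)

log = logging.getLogger(__name__)

LOG10 = math.log(10.0)


@dataclass
class GenotyperConfig:
    min_depth: int = 5       # usable depth required to consider a site
    min_bq: int = 20         # bases below never enter likelihoods
    min_mapq: int = 10       # reads below are "non-unique"
    theta: float = 0.001     # heterozygosity prior (human scale)
    max_qual: float = 9999.0


@dataclass
class CoverageSummary:
    """Per-position depth tracks retained by :func:`call_variants`."""

    usable_depth: dict = field(default_factory=dict)  # chrom -> int32 array
    raw_depth: dict = field(default_factory=dict)
    gap_events: dict = field(default_factory=dict)    # (chrom, pos) -> support


def mark_duplicates(reads: list[Read]) -> list[Read]:
    """Collapse duplicate reads, keeping one per (chrom, 5' start, strand).

    Among duplicates the read with the highest summed base quality wins;
    ties break to the lexicographically first read name. Input must be
    coordinate sorted.
    """
    last: dict[str, int] = {}
    for r in reads:
        if r.start < last.get(r.chrom, -1):
            raise ValueError("mark_duplicates requires coordinate-sorted reads")
        last[r.chrom] = r.start
    best: dict[tuple, Read] = {}
    for r in reads:
        key = (r.chrom, r.five_prime, r.strand)
        cur = best.get(key)
        if cur is None:
            best[key] = r
        else:
            r_sum, c_sum = int(r.quals.sum()), int(cur.quals.sum())
            # higher summed quality wins; ties keep the first read name
            if r_sum > c_sum or (r_sum == c_sum and r.name < cur.name):
                best[key] = r
    out = list(best.values())
    out.sort(key=lambda r: (r.chrom, r.start, r.name))
    return out


def collect_gap_events(reads: list[Read]) -> dict:
    """Count reads supporting an insertion/deletion at each start position."""
    events: dict[tuple, int] = {}
    for r in reads:
        ref = r.start
        for op, n in r.cigar:
            if op == "M":
                ref += n
            elif op == "D":
                events[(r.chrom, ref)] = events.get((r.chrom, ref), 0) + 1
                ref += n
            elif op == "I":
                events[(r.chrom, ref)] = events.get((r.chrom, ref), 0) + 1
    return events


def build_pileups(
    reads: list[Read],
    reference: dict,
    region: tuple | None = None,
    min_bq: int = 20,
    min_mapq: int = 10,
) -> Iterator[PileupColumn]:
    """Yield one :class:`PileupColumn` per covered position.

    Observations failing the ``min_bq``/``min_mapq`` gates are retained in
    the column (they count toward ``raw_depth``) but flagged unusable for
    genotype likelihoods. Positions covered by no read are skipped.
    Intended for region-scale work; :func:`call_variants` uses a
    vectorised scan for whole-genome calling.
    """
    columns: dict[tuple, list] = {}
    for r in reads:
        if r.chrom not in reference:
            raise ValueError(f"read {r.name} on unknown contig {r.chrom}")
        if len(r.seq) != sum(n for op, n in r.cigar if op in ("M", "I")):
            log.warning("skipping read %s: CIGAR/sequence mismatch", r.name)
            continue
        for q, ref_pos, n in r.aligned_blocks():
            for k in range(n):
                pos = ref_pos + k
                if region is not None:
                    chrom, rs, re_ = region
                    if r.chrom != chrom or not rs <= pos < re_:
                        continue
                bq = int(r.quals[q + k])
                obs = Observation(
                    base=r.seq[q + k], bq=bq, mapq=r.mapq, strand=r.strand,
                    read_id=r.name,
                    usable=bq >= min_bq and r.mapq >= min_mapq,
                )
                columns.setdefault((r.chrom, pos), []).append(obs)
    for (chrom, pos) in sorted(columns):
        yield PileupColumn(chrom, pos, reference[chrom][pos],
                           columns[(chrom, pos)])


def _genotype_loglik(column: PileupColumn, alt: str) -> tuple:
    """Log-likelihoods (hom-ref, het, hom-alt) over usable observations."""
    ref = column.ref_base
    ll = np.zeros(3)
    for o in column.usable:
        e = 10.0 ** (-o.bq / 10.0)
        p_ref = (1.0 - e) if o.base == ref else e / 3.0
        p_alt = (1.0 - e) if o.base == alt else e / 3.0
        ll[0] += math.log(p_ref)
        ll[1] += math.log(0.5 * p_ref + 0.5 * p_alt)
        ll[2] += math.log(p_alt)
    return ll


def genotype_site(
    column: PileupColumn,
    theta: float = 0.001,
    min_depth: int = 5,
    min_mapq: int = 10,
    max_qual: float = 9999.0,
) -> VariantCall | None:
    """Call the max-posterior diploid genotype at one pileup column.

    Returns ``None`` for no-calls: columns with fewer than ``min_depth``
    usable observations, columns with no usable non-reference base, and
    columns whose best genotype is homozygous reference.
    """
    usable = column.usable
    if len(usable) < min_depth:
        return None
    ref = column.ref_base
    counts = {b: 0 for b in BASES}
    for o in usable:
        if o.base in counts:
            counts[o.base] += 1
    nonref = {b: c for b, c in counts.items() if b != ref and c > 0}
    if not nonref:
        return None
    alt = max(sorted(nonref), key=lambda b: nonref[b])

    ll = _genotype_loglik(column, alt)
    log_prior = np.log([1.0 - 1.5 * theta, theta, theta / 2.0])
    log_post = ll + log_prior
    norm = logsumexp(log_post)
    log_post -= norm
    best = int(np.argmax(log_post))
    if best == 0:
        return None

    qual = min(max_qual, -10.0 * log_post[0] / LOG10)
    others = logsumexp([log_post[i] for i in range(3) if i != best])
    gq = int(round(min(max_qual, -10.0 * others / LOG10)))

    n_fwd = sum(1 for o in usable if o.strand == "+")
    obs = column.observations
    ann = {
        "qd": qual / len(usable),
        "dp": float(len(usable)),
        "sb": n_fwd / len(usable),
        "mq": float(np.mean([o.mapq for o in obs])),
        "gq": float(gq),
        "nonunique_frac": sum(o.mapq < min_mapq for o in obs) / len(obs),
    }
    return VariantCall(
        chrom=column.chrom, pos=column.pos, ref=ref, alt=alt,
        genotype=HET if best == 1 else HOM_ALT,
        qual=qual, gq=gq, depth=len(usable),
        allele_depths=(counts[ref], counts[alt]),
        annotations=ann,
    )


def call_variants(
    reads: list[Read],
    reference: dict,
    config: GenotyperConfig | None = None,
) -> tuple[list[VariantCall], CoverageSummary]:
    """Genome-wide variant calling: dedup -> pileup -> genotype.

    Uses a two-pass scan: a vectorised pass accumulates per-position
    usable base counts and depth, then full pileup columns are built only
    at candidate positions (usable depth >= ``min_depth`` with at least
    one usable non-reference base) and genotyped with
    :func:`genotype_site`. Returns the biallelic SNV calls and a
    :class:`CoverageSummary` with per-position usable/raw depth and the
    indel gap events needed by the proximity filter.
    """
    cfg = config or GenotyperConfig()
    for r in reads:
        if r.chrom not in reference:
            raise ValueError(f"read {r.name} on unknown contig {r.chrom}")
    reads = mark_duplicates(reads)
    summary = CoverageSummary(gap_events=collect_gap_events(reads))
    calls: list[VariantCall] = []

    for chrom, group in groupby(reads, key=lambda r: r.chrom):
        chrom_reads = list(group)
        seq = reference[chrom]
        L = len(seq)
        ref_idx = np.frombuffer(seq.encode(), dtype=np.uint8)
        code = np.full(256, 4, dtype=np.uint8)
        for b, i in BASE_INDEX.items():
            code[ord(b)] = i
        ref_code = code[ref_idx]

        usable_cnt = np.zeros((L, 4), dtype=np.int32)
        raw = np.zeros(L, dtype=np.int32)
        for r in chrom_reads:
            r_usable = r.mapq >= cfg.min_mapq
            bases = code[np.frombuffer(r.seq.encode(), dtype=np.uint8)]
            for q, ref_pos, n in r.aligned_blocks():
                idx = np.arange(ref_pos, ref_pos + n)
                raw[idx] += 1
                if not r_usable:
                    continue
                mask = (r.quals[q:q + n] >= cfg.min_bq) & (bases[q:q + n] < 4)
                np.add.at(usable_cnt, (idx[mask], bases[q:q + n][mask]), 1)

        usable_depth = usable_cnt.sum(axis=1)
        ref_cnt = np.where(ref_code < 4,
                           usable_cnt[np.arange(L), np.minimum(ref_code, 3)], 0)
        cand = ((usable_depth - ref_cnt) >= 1) & (usable_depth >= cfg.min_depth)
        cand &= ref_code < 4  # never call on N reference bases
        summary.usable_depth[chrom] = usable_depth.astype(np.int32)
        summary.raw_depth[chrom] = raw

        cand_pos = np.flatnonzero(cand)
        if cand_pos.size == 0:
            continue
        obs_at: dict[int, list] = {int(p): [] for p in cand_pos}
        cand_mask = cand
        for r in chrom_reads:
            for q, ref_pos, n in r.aligned_blocks():
                hits = np.flatnonzero(cand_mask[ref_pos:ref_pos + n])
                for h in hits:
                    bq = int(r.quals[q + h])
                    obs_at[ref_pos + int(h)].append(Observation(
                        base=r.seq[q + h], bq=bq, mapq=r.mapq,
                        strand=r.strand, read_id=r.name,
                        usable=bq >= cfg.min_bq and r.mapq >= cfg.min_mapq,
                    ))
        for p in cand_pos:
            col = PileupColumn(chrom, int(p), seq[p], obs_at[int(p)])
            vc = genotype_site(col, cfg.theta, cfg.min_depth, cfg.min_mapq,
                               cfg.max_qual)
            if vc is not None:
                calls.append(vc)

    calls.sort(key=lambda c: (c.chrom, c.pos))
    log.info("called %d biallelic SNVs from %d reads", len(calls), len(reads))
    return calls, summary
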