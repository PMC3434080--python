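"""Shared data containers for the ChIP-seq genotyping / allelic-bias pipeline.

Coordinate conventions: every in-memory position is 0-based; BED output is
0-based half-open; SAM and VCF are converted to 1-based only at I/O
boundaries (see :mod:`asbcall.io`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}

#: transition partners; every other substitution is a transversion
TRANSITION_PARTNER = {"A": "G", "G": "A", "C": "T", "T": "C"}

HOM_REF = "hom_ref"
HET = "het"
HOM_ALT = "hom_alt"


@dataclass
class Read:
    """A single-end aligned read (alignment coordinates, not FASTQ).

    ``cigar`` is a tuple of ``(op, length)`` with ops restricted to
    ``M`` (aligned match/mismatch), ``I`` (insertion to the reference)
    and ``D`` (deletion from the reference).
    """

    name: str
    chrom: str
    start: int            # 0-based leftmost reference position
    mapq: int
    strand: str           # '+' or '-'
    seq: str
    quals: np.ndarray     # Phred base qualities, uint8, len == len(seq)
    cigar: tuple = (("M", 0),)

    def __post_init__(self) -> None:
        self.quals = np.asarray(self.quals, dtype=np.uint8)
        if sum(n for op, n in self.cigar if op in ("M", "I")) != len(self.seq):
            raise ValueError(
                f"read {self.name}: CIGAR consumes a different number of "
                f"query bases than the sequence length {len(self.seq)}"
            )

    @property
    def ref_end(self) -> int:
        """One past the last reference base consumed by the alignment."""
        return self.start + sum(n for op, n in self.cigar if op in ("M", "D"))

    @property
    def five_prime(self) -> int:
        """5' alignment coordinate used for duplicate grouping."""
        return self.start if self.strand == "+" else self.ref_end - 1

    def aligned_blocks(self) -> Iterator[tuple[int, int, int]]:
        """Yield ``(query_offset, ref_position, length)`` per M block."""
        q, r = 0, self.start
        for op, n in self.cigar:
            if op == "M":
                yield q, r, n
                q += n
                r += n
            elif op == "I":
                q += n
            elif op == "D":
                r += n
            else:  # pragma: no cover - constructor restricts ops
                raise ValueError(f"unsupported CIGAR op {op!r}")

    def base_at(self, pos: int) -> tuple[str, int] | None:
        """Base and quality aligned to reference position ``pos``.

        Returns ``None`` when ``pos`` falls in a deletion or outside the
        read span.
        """
        for q, r, n in self.aligned_blocks():
            if r <= pos < r + n:
                i = q + (pos - r)
                return self.seq[i], int(self.quals[i])
        return None

    def overlaps(self, pos: int) -> bool:
        return self.start <= pos < self.ref_end


@dataclass
class Observation:
    """One read's base call stacked at a pileup column."""

    base: str
    bq: int
    mapq: int
    strand: str
    read_id: str
    usable: bool  # passes the base- and mapping-quality gates


@dataclass
class PileupColumn:
    chrom: str
    pos: int
    ref_base: str
    observations: list
    raw_depth: int = 0

    def __post_init__(self) -> None:
        if not self.raw_depth:
            self.raw_depth = len(self.observations)

    @property
    def usable(self) -> list:
        return [o for o in self.observations if o.usable]


@dataclass
class VariantCall:
    """A biallelic SNV call with Phred-scaled confidence scores.

    ``qual`` is the Phred-scaled probability that the site is *not*
    polymorphic (posterior of the homozygous-reference genotype);
    ``gq`` the Phred-scaled probability that the called genotype is
    wrong. ``filter_flags`` empty means PASS.
    """

    chrom: str
    pos: int              # 0-based
    ref: str
    alt: str
    genotype: str         # HET or HOM_ALT (HOM_REF is never emitted)
    qual: float
    gq: int
    depth: int            # usable depth
    allele_depths: tuple  # (ref_count, alt_count) among usable bases
    annotations: dict = field(default_factory=dict)
    filter_flags: set = field(default_factory=set)

    @property
    def passing(self) -> bool:
        return not self.filter_flags

    @property
    def is_transition(self) -> bool:
        return TRANSITION_PARTNER[self.ref] == self.alt

    def location_key(self) -> tuple:
        return (self.chrom, self.pos, frozenset((self.ref, self.alt)))

    def genotype_key(self) -> tuple:
        return self.location_key() + (self.genotype,)


@dataclass
class Peak:
    """A ChIP peak interval with its summit (highest point of coverage)."""

    chrom: str
    start: int
    end: int
    summit: int
    name: str = "."
    score: float = 0.0

    def __post_init__(self) -> None:
        if not (self.start <= self.summit < self.end):
            raise ValueError(
                f"peak {self.name}: summit {self.summit} outside "
                f"[{self.start}, {self.end})"
            )


def merge_positions(positions) -> list[tuple[int, int]]:
    """Collapse a set of integer positions into maximal half-open intervals."""
    pos = np.unique(np.asarray(list(positions), dtype=np.int64))
    if pos.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(pos) > 1)
    starts = np.concatenate(([0], breaks + 1))
    ends = np.concatenate((breaks, [pos.size - 1]))
    return [(int(pos[s]), int(pos[e]) + 1) for s, e in zip(starts, ends)]


def in_intervals(pos: int, intervals) -> bool:
    """Membership of a position in a list of half-open ``(start, end)``."""
    return any(s <= pos < e for s, e in intervals)
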