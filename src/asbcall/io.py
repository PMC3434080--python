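"""Readers and writers for the standard formats the pipeline touches.

FASTA, SAM, and VCF go through pysam/pyfaidx; BED, bedGraph, and the TSV
tables through pandas. Internal coordinates are 0-based half-open; SAM and
VCF records are converted to/from 1-based exactly once, here.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import pysam
from pyfaidx import Fasta

from .core import HET, HOM_ALT, Peak, Read, VariantCall
from .filters import ALL_FLAGS

log = logging.getLogger(__name__)

_CIGAR_OPS = {"M": 0, "I": 1, "D": 2}
_CIGAR_OPS_REV = {v: k for k, v in _CIGAR_OPS.items()}

FILTER_DESCRIPTIONS = {
    "cluster": "More than the allowed number of SNPs in a short window",
    "nonunique": "Too large a fraction of overlapping reads not uniquely aligned",
    "low_qual": "Site quality below the minimum",
    "repeat": "Position inside the repeat mask",
    "near_indel": "Within the exclusion distance of a read-supported indel",
    "high_cov": "Inside a region of exceptionally high read coverage",
    "model": "Below the Gaussian-mixture model score threshold",
}

INFO_FIELDS = {
    "QD": "Site quality divided by usable depth",
    "MQ": "Mean mapping quality of overlapping reads",
    "SBF": "Fraction of usable reads on the forward strand",
    "NUF": "Fraction of overlapping reads not uniquely aligned",
}
_INFO_TO_ANN = {"QD": "qd", "MQ": "mq", "SBF": "sb", "NUF": "nonunique_frac"}


def _wrap_io(path, exc: Exception) -> OSError:
    return OSError(f"while accessing {path}: {exc}")


# ---------------------------------------------------------------------------
# FASTA

def write_fasta(reference: dict, path, width: int = 70) -> None:
    try:
        with open(path, "w") as fh:
            for name, seq in reference.items():
                fh.write(f">{name}\n")
                for i in range(0, len(seq), width):
                    fh.write(seq[i:i + width] + "\n")
    except OSError as exc:
        raise _wrap_io(path, exc) from exc


def read_fasta(path) -> dict:
    try:
        fa = Fasta(str(path), as_raw=True)
        return {name: str(fa[name][:]).upper() for name in fa.keys()}
    except OSError as exc:
        raise _wrap_io(path, exc) from exc


# ---------------------------------------------------------------------------
# SAM

def _sam_header(reference: dict) -> dict:
    return {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": name, "LN": len(seq)}
               for name, seq in reference.items()],
    }


def write_sam(reads, reference: dict, path) -> None:
    header = pysam.AlignmentHeader.from_dict(_sam_header(reference))
    try:
        with pysam.AlignmentFile(str(path), "wh", header=header) as out:
            for r in reads:
                a = pysam.AlignedSegment(header)
                a.query_name = r.name
                a.reference_name = r.chrom
                a.reference_start = r.start
                a.mapping_quality = r.mapq
                a.flag = 16 if r.strand == "-" else 0
                a.query_sequence = r.seq
                a.query_qualities = pysam.qualitystring_to_array(
                    "".join(chr(q + 33) for q in r.quals))
                a.cigartuples = [(_CIGAR_OPS[op], n) for op, n in r.cigar]
                out.write(a)
    except OSError as exc:
        raise _wrap_io(path, exc) from exc


def read_sam(path) -> list:
    reads = []
    try:
        with pysam.AlignmentFile(str(path), "r") as fh:
            for a in fh:
                if a.is_unmapped:
                    continue
                reads.append(Read(
                    name=a.query_name,
                    chrom=a.reference_name,
                    start=a.reference_start,
                    mapq=a.mapping_quality,
                    strand="-" if a.is_reverse else "+",
                    seq=a.query_sequence,
                    quals=np.array(a.query_qualities, dtype=np.uint8),
                    cigar=tuple((_CIGAR_OPS_REV[op], n)
                                for op, n in a.cigartuples),
                ))
    except OSError as exc:
        raise _wrap_io(path, exc) from exc
    return reads


# ---------------------------------------------------------------------------
# VCF

def _vcf_header(reference: dict) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    for name, seq in reference.items():
        header.contigs.add(name, length=len(seq))
    for flag in ALL_FLAGS:
        header.filters.add(flag, None, None, FILTER_DESCRIPTIONS[flag])
    for key, desc in INFO_FIELDS.items():
        header.info.add(key, 1, "Float", desc)
    header.formats.add("GT", 1, "String", "Genotype")
    header.formats.add("DP", 1, "Integer", "Usable read depth")
    header.formats.add("AD", "R", "Integer", "Usable depth per allele")
    header.formats.add("GQ", 1, "Integer", "Genotype quality")
    header.add_sample("SAMPLE")
    return header


def write_vcf(calls, reference: dict, path) -> None:
    """Write calls as VCF v4.2 (1-based; FILTER semicolon-joins the flags)."""
    order = [(c.chrom, c.pos) for c in calls]
    if order != sorted(order):
        raise ValueError("VCF output requires calls sorted by position")
    header = _vcf_header(reference)
    try:
        with pysam.VariantFile(str(path), "w", header=header) as out:
            for c in calls:
                rec = out.new_record(
                    contig=c.chrom, start=c.pos, stop=c.pos + 1,
                    alleles=(c.ref, c.alt),
                    qual=round(float(c.qual), 2),
                )
                if c.filter_flags:
                    for f in sorted(c.filter_flags):
                        rec.filter.add(f)
                else:
                    rec.filter.add("PASS")
                for info_key, ann_key in _INFO_TO_ANN.items():
                    if ann_key in c.annotations:
                        rec.info[info_key] = round(
                            float(c.annotations[ann_key]), 4)
                sample = rec.samples["SAMPLE"]
                sample["GT"] = (0, 1) if c.genotype == HET else (1, 1)
                sample["DP"] = int(c.depth)
                sample["AD"] = (int(c.allele_depths[0]),
                                int(c.allele_depths[1]))
                sample["GQ"] = int(c.gq)
                out.write(rec)
    except OSError as exc:
        raise _wrap_io(path, exc) from exc


def read_vcf(path) -> list:
    calls = []
    try:
        with pysam.VariantFile(str(path)) as fh:
            for rec in fh:
                sample = rec.samples[0] if rec.samples else None
                gt = sample["GT"] if sample and "GT" in sample else (0, 1)
                genotype = HET if tuple(gt) == (0, 1) else HOM_ALT
                ad = tuple(sample["AD"]) if sample and sample.get("AD") \
                    and sample["AD"][0] is not None else (0, 0)
                ann = {}
                for info_key, ann_key in _INFO_TO_ANN.items():
                    if info_key in rec.info:
                        ann[ann_key] = float(rec.info[info_key])
                if sample and sample.get("DP") is not None:
                    ann["dp"] = float(sample["DP"])
                if sample and sample.get("GQ") is not None:
                    ann["gq"] = float(sample["GQ"])
                flags = {f for f in rec.filter.keys() if f != "PASS"}
                calls.append(VariantCall(
                    chrom=rec.chrom, pos=rec.start,
                    ref=rec.ref, alt=rec.alts[0],
                    genotype=genotype,
                    qual=float(rec.qual) if rec.qual is not None else 0.0,
                    gq=int(sample["GQ"]) if sample
                    and sample.get("GQ") is not None else 0,
                    depth=int(sample["DP"]) if sample
                    and sample.get("DP") is not None else 0,
                    allele_depths=ad,
                    annotations=ann,
                    filter_flags=flags,
                ))
    except OSError as exc:
        raise _wrap_io(path, exc) from exc
    return calls


# ---------------------------------------------------------------------------
# BED / bedGraph / TSV tables

def write_bed_peaks(peaks, path) -> None:
    """Peaks BED: chrom, start, end, name, score, strand, summit offset."""
    try:
        with open(path, "w") as fh:
            for p in peaks:
                fh.write(f"{p.chrom}\t{p.start}\t{p.end}\t{p.name}\t"
                         f"{int(p.score)}\t.\t{p.summit - p.start}\n")
    except OSError as exc:
        raise _wrap_io(path, exc) from exc


def read_bed_peaks(path) -> list:
    """Read the 7-column peaks dialect or 10-column narrowPeak."""
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#")
    except OSError as exc:
        raise _wrap_io(path, exc) from exc
    peaks = []
    for row in df.itertuples(index=False):
        chrom, start, end = row[0], int(row[1]), int(row[2])
        name = str(row[3]) if len(row) > 3 else "."
        score = float(row[4]) if len(row) > 4 else 0.0
        offset_col = 9 if len(row) >= 10 else 6 if len(row) >= 7 else None
        offset = int(row[offset_col]) if offset_col is not None else \
            (end - start) // 2
        if offset < 0:  # narrowPeak convention for "no summit"
            offset = (end - start) // 2
        peaks.append(Peak(chrom, start, end, start + offset, name, score))
    return peaks


def read_bedgraph(path, reference: dict) -> dict:
    """Per-base float track from a bedGraph, zero-filled off the records."""
    tracks = {c: np.zeros(len(s)) for c, s in reference.items()}
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["chrom", "start", "end", "value"])
    for row in df.itertuples(index=False):
        if row.chrom in tracks:
            tracks[row.chrom][int(row.start):int(row.end)] = float(row.value)
    return tracks


def write_bias_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_bias_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    for col in ("tested", "significant"):
        if col in df.columns:
            df[col] = df[col].astype(bool)
    return df


def write_bias_truth(bias: dict, chrom: str, path) -> None:
    pd.DataFrame(
        {"chrom": chrom, "pos": sorted(bias),
         "beta": [bias[p] for p in sorted(bias)]}
    ).to_csv(path, sep="\t", index=False)


def read_bias_truth(path) -> dict:
    df = pd.read_csv(path, sep="\t")
    return {int(p): float(b) for p, b in zip(df["pos"], df["beta"])}


def load_known_sites(path) -> set:
    """Known polymorphic sites as {(chrom, pos, alt)} from VCF or TSV.

    The TSV form requires columns chrom, pos (1-based), ref, alt.
    """
    path = Path(path)
    if path.suffix in (".vcf", ".bcf") or str(path).endswith(".vcf.gz"):
        return {(c.chrom, c.pos, c.alt) for c in read_vcf(path)}
    df = pd.read_csv(path, sep="\t")
    return {(row.chrom, int(row.pos) - 1, row.alt)
            for row in df.itertuples(index=False)}


def read_gwas_catalog(path) -> pd.DataFrame:
    """GWAS catalog TSV with required header chrom, pos, rsid, trait."""
    df = pd.read_csv(path, sep="\t")
    missing = {"chrom", "pos", "rsid", "trait"} - set(df.columns)
    if missing:
        raise ValueError(
            f"GWAS catalog {path} lacks columns: {', '.join(sorted(missing))}")
    df["pos"] = df["pos"].astype(int) - 1  # catalog is 1-based
    return df


def write_gwas_catalog(df: pd.DataFrame, path) -> None:
    out = df.copy()
    out["pos"] = out["pos"].astype(int) + 1
    out.to_csv(path, sep="\t", index=False)
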