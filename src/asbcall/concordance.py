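"""Cross-individual bias concordance and disease-SNP enrichment.

Concordance compares percent-reference-allele values at heterozygous SNPs
shared between two individuals (Spearman rank correlation plus a quadrant
test of bias direction). Enrichment relates a de novo call set to a GWAS
catalog: exact-position overlap rates per 10,000 SNPs, an upper-tail
hypergeometric enrichment p-value, and a windowed proximity table of
significantly biased sites near catalog loci.
"""

from __future__ import annotations

import itertools
import logging

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import rankdata, spearmanr

log = logging.getLogger(__name__)

EXACT_SPEARMAN_MAX_N = 10


def shared_het_join(
    table_a: pd.DataFrame,
    table_b: pd.DataFrame,
    require_significant: bool = True,
) -> pd.DataFrame:
    """Inner-join two bias tables on shared heterozygous sites.

    Keeps sites present in both tables with identical ref/alt alleles.
    With ``require_significant`` (the default, matching the pairwise
    scatter convention) only sites significantly biased in at least one
    individual are retained.
    """
    merged = table_a.merge(
        table_b, on=["chrom", "pos", "ref", "alt"], suffixes=("_a", "_b"))
    if require_significant:
        merged = merged[merged["significant_a"] | merged["significant_b"]]
    return merged.reset_index(drop=True)


def _exact_spearman_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided exact permutation p-value for Spearman's rho."""
    rx = rankdata(x)
    ry = rankdata(y)
    rxc = rx - rx.mean()
    ryc = ry - ry.mean()
    # permutation invariance of the rank norms makes the centred dot
    # product an equivalent test statistic to rho itself
    obs = float(np.dot(rxc, ryc))
    hits = total = 0
    chunk = []

    def flush(chunk):
        nonlocal hits, total
        P = np.asarray(chunk)
        stats = P @ rxc
        hits += int(np.sum(np.abs(stats) >= abs(obs) - 1e-9))
        total += P.shape[0]

    for perm in itertools.permutations(ryc):
        chunk.append(perm)
        if len(chunk) == 100_000:
            flush(chunk)
            chunk = []
    if chunk:
        flush(chunk)
    return hits / total


def bias_concordance(shared: pd.DataFrame) -> tuple[float, float, float]:
    """(Spearman rho, p-value, quadrant concordance) over shared sites.

    Rho and p are computed on the paired ``pct_ref`` values; the p-value
    uses exact rank permutation for n <= 10 and the t-approximation above.
    Quadrant concordance is the fraction of sites whose bias deviates from
    0.5 in the same direction in both individuals, among sites where
    neither value equals 0.5.
    """
    if len(shared) < 3:
        raise ValueError("concordance requires at least 3 shared sites")
    a = shared["pct_ref_a"].to_numpy(dtype=float)
    b = shared["pct_ref_b"].to_numpy(dtype=float)
    rho, p = spearmanr(a, b)
    if len(a) <= EXACT_SPEARMAN_MAX_N:
        p = _exact_spearman_p(a, b)
    da, db = a - 0.5, b - 0.5
    informative = (da != 0) & (db != 0)
    if informative.any():
        quadrant = float(np.mean((da[informative] * db[informative]) > 0))
    else:
        quadrant = np.nan
    return float(rho), float(p), quadrant


def gwas_overlap_rate(calls, catalog: pd.DataFrame):
    """Exact-position overlap of a call set with a GWAS catalog.

    Returns ``(rate per 10,000 calls, overlap table)``; positions compare
    0-based against the catalog's ``pos`` column.
    """
    if not len(calls):
        raise ValueError("empty call set")
    catalog_pos = set(zip(catalog["chrom"], catalog["pos"]))
    hits = [c for c in calls if (c.chrom, c.pos) in catalog_pos]
    rate = len(hits) / len(calls) * 10_000
    overlap = catalog.merge(
        pd.DataFrame({"chrom": [c.chrom for c in hits],
                      "pos": [c.pos for c in hits]}),
        on=["chrom", "pos"])
    return rate, overlap


def hypergeometric_enrichment(
    universe: int, disease_in_universe: int, drawn: int, disease_and_drawn: int
) -> float:
    """Upper-tail hypergeometric p-value, P(X >= k).

    ``universe`` (M) SNPs of which ``disease_in_universe`` (m) are
    disease-associated; ``drawn`` (N) SNPs observed in the ChIP set, of
    which ``disease_and_drawn`` (k) are disease-associated. The tail is an
    exact sum of log-space pmf terms, so it stays accurate far below
    floating-point underflow of the individual terms.
    """
    M, m, N, k = universe, disease_in_universe, drawn, disease_and_drawn
    if not (0 <= m <= M and 0 <= N <= M and 0 <= k <= min(m, N)):
        raise ValueError("inconsistent hypergeometric counts")
    if k <= max(0, N + m - M):
        return 1.0
    ks = np.arange(k, min(m, N) + 1)
    from scipy.special import gammaln

    def logc(n, r):
        return gammaln(n + 1) - gammaln(r + 1) - gammaln(n - r + 1)

    logpmf = logc(m, ks) + logc(M - m, N - ks) - logc(M, N)
    return float(np.exp(logsumexp(logpmf)))


def biased_near_gwas(
    bias_records: pd.DataFrame, catalog: pd.DataFrame, window: int = 500
) -> pd.DataFrame:
    """Significant allele-specific sites within ``window`` bp of GWAS loci.

    Emits one row per (significant bias record, catalog site) pair with
    the signed distance (bias position minus GWAS position), inclusive at
    exactly ``window``.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    sig = bias_records[bias_records["significant"]]
    rows = []
    cat_by_chrom = {c: g for c, g in catalog.groupby("chrom")}
    for _, rec in sig.iterrows():
        cat = cat_by_chrom.get(rec["chrom"])
        if cat is None:
            continue
        dist = rec["pos"] - cat["pos"]
        near = cat[dist.abs() <= window]
        for _, g in near.iterrows():
            rows.append({
                "chrom": rec["chrom"], "pos": int(rec["pos"]),
                "ref": rec["ref"], "alt": rec["alt"],
                "gwas_pos": int(g["pos"]), "rsid": g.get("rsid", "."),
                "trait": g.get("trait", "."),
                "distance": int(rec["pos"] - g["pos"]),
            })
    return pd.DataFrame(
        rows, columns=["chrom", "pos", "ref", "alt", "gwas_pos", "rsid",
                       "trait", "distance"])
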