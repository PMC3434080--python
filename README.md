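# asbcall

**De novo SNP identification and allele-specific transcription-factor
binding analysis from ChIP-seq alignments.**

ChIP-seq read pileups are deep exactly where a transcription factor (or
histone mark) binds, which makes them good enough for genotyping the bound
regions even though genome-wide coverage is far too thin for conventional
variant calling. `asbcall` exploits this: it calls diploid SNVs directly
from ChIP-seq alignments, filters them the way a production variant
pipeline would, and then asks — at every heterozygous site — whether the
immunoprecipitated DNA covers the two alleles equally. Unequal coverage is
evidence of allele-specific binding (ASB), the molecular signature by which
a non-coding variant can alter transcription-factor occupancy. Because the
genotypes come from the ChIP experiment itself, the analysis needs no prior
genotyping, which is what makes it applicable to primary patient samples.

The package is aimed at regulatory-genomics researchers who have
coordinate-sorted alignments, peak calls, and a reference genome, and want
genotypes plus ASB calls plus the standard QC around them.

## The model

**Genotyping.** For each pileup column with reference base *r* and
best-supported alternate *a*, the diploid genotype *g* = {a₁, a₂} has
per-read likelihood

    P(b | g) = ½ P(b | a₁) + ½ P(b | a₂),   P(b | a) = 1 − e  if b = a,  else e/3

with *e* = 10^(−q/10) from the base quality, and priors
P(hom-ref) = 1 − 3θ/2, P(het) = θ, P(hom-alt) = θ/2 (θ = 10⁻³ by default).
The site quality is the Phred-scaled posterior of hom-ref; the genotype
quality is the Phred-scaled posterior that the call is wrong.

**Filtering** is two-stage. A Gaussian-mixture model over call annotations
(QD, depth, strand balance, mean MAPQ, GQ) is trained on calls that overlap
a known-sites list and thresholded to retain 99% of them; independently,
six hard rules flag calls with >2 SNPs per 10 bp, >10% non-uniquely aligned
overlapping reads, quality < 50, repeat overlap, an indel within 5 bp, or
exceptionally high coverage. A SNP passes only if it passes both stages.

**Allelic bias.** At each passing heterozygous SNP the reads supporting
each allele are counted (`pct_ref` = ref/(ref+alt)) and tested against
Binomial(n, ½) with an exact two-sided p-value. Benjamini–Hochberg FDR is
applied within the set of sites whose allele counts differ by ≥ 6 reads; a
site is called allele-specific at q < 0.05. To counter reference-mapping
bias, the package builds the individual's two haplotype genomes (reference
and alternate alleles substituted at the called SNPs) and can either write
them out for realignment or re-score each read against both in place.

Downstream utilities compute cross-individual bias concordance (Spearman's
ρ and quadrant agreement at shared heterozygous sites), GWAS-catalog
overlap rates per 10,000 SNPs with an exact hypergeometric enrichment
p-value, summit-relative SNP/conservation profiles, Ti/Tv, Ht5 (≥5×)
assayable regions and recovery rates, per-chromosome SNP density, and
depth-saturation curves. A bundled simulator generates peak-enriched reads
from planted haplotypes — with configurable per-site bias β, alternate-read
loss (mapping bias), sequencing error, multi-mapping reads, and PCR
duplicates — so the whole pipeline is testable against ground truth.

## Worked example

```python
from asbcall.sim_data import SimConfig, simulate
from asbcall.pipeline import genotype_and_filter
from asbcall.bias import count_alleles, bias_table
from asbcall.qc import ht_regions, titv_ratio
from asbcall.core import HET

cfg = SimConfig(
    genome_length=100_000, n_snps=500, n_peaks=10, peak_width=3000,
    min_spacing=60, enrichment_fold=30,
    bias_sites=tuple((i, 0.85) for i in range(0, 335, 4)),  # beta=0.85 at 84 het sites
    seed=7,
)
truth, reads = simulate(cfg)
reference = {truth.chrom: truth.reference}

result = genotype_and_filter(reads, reference)
passing = result.passing
regions, frac = ht_regions(result.coverage.usable_depth, k=5)
print(f"calls: {len(result.calls)}  pass: {len(passing)}  "
      f"Ti/Tv: {titv_ratio(passing):.2f}  Ht5: {frac:.3f}")

hets = [c for c in passing if c.genotype == HET]
table = bias_table(count_alleles(reads, hets))
print(f"het sites: {len(table)}  tested: {int(table.tested.sum())}  "
      f"significant: {int(table.significant.sum())}")
print(table[table.significant].head(4)[
    ["pos", "ref", "alt", "ref_count", "alt_count",
     "pct_ref", "p_value", "q_value"]].to_string(index=False))
```

prints

```
calls: 141  pass: 127  Ti/Tv: 2.34  Ht5: 0.306
het sites: 77  tested: 28  significant: 7
  pos ref alt  ref_count  alt_count  pct_ref  p_value  q_value
 8059   C   T         22          5 0.814815 0.001514 0.010596
24150   C   T         22          6 0.785714 0.003719 0.017356
31536   T   C         24          5 0.827586 0.000546 0.005097
32802   G   C         27          6 0.818182 0.000324 0.004537
```

Reading: of 141 SNVs called inside the ~31% of the genome with ≥5×
coverage, 127 pass both filter stages with a transition/transversion ratio
near the mammalian expectation. Of the 77 passing heterozygous sites, 28
have allele counts differing by ≥6 reads and enter FDR correction; 7 are
significantly allele-specific at q < 0.05, with `pct_ref` ≈ 0.8 matching
the planted binding bias (6 of the 7 are planted-biased sites; one is a
false positive, consistent with the 5% FDR).

The same pipeline is available from the shell:

```sh
asbcall simulate --seed 7 --out sim/
asbcall genotype --sam sim/reads.sam --ref sim/reference.fa --out calls.vcf
asbcall filter   --vcf calls.vcf --ref sim/reference.fa --sam sim/reads.sam --out filtered.vcf
asbcall bias     --sam sim/reads.sam --vcf filtered.vcf --ref sim/reference.fa --out bias.tsv
asbcall run-all  --seed 7 --out run/        # the whole chain in one step
```

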