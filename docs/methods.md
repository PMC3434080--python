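# Methods

This note documents the models, parameter choices, and numerical details
behind `asbcall`, and what the simulation-based tests do and do not
establish about behaviour on real data.

## Genotyping model

Variant calling uses the standard diploid Bayesian model on pileup
columns. For a column with reference base *r*, the candidate alternate is
the most frequent usable non-reference base (ties broken alphabetically);
only biallelic SNVs are considered, since downstream allele-specific
analysis is defined for two alleles. For genotype *g* = {a₁, a₂}:

- per-read likelihood `P(b|g) = ½·P(b|a₁) + ½·P(b|a₂)` with
  `P(b|a) = 1−e` if `b = a`, else `e/3`, where `e = 10^(−q/10)` from the
  reported base quality;
- genotype priors `P(hom-ref) = 1 − 3θ/2`, `P(het) = θ`,
  `P(hom-alt) = θ/2`, with θ = 10⁻³ (the human per-site heterozygosity
  scale) by default;
- site quality QUAL = −10·log₁₀ P(hom-ref | data) and genotype quality
  GQ = −10·log₁₀(1 − P(called genotype | data)), both computed in log
  space via logsumexp and capped at 9999 to keep them finite when the
  posterior saturates.

A column is a no-call when fewer than `min_depth` (default 5) usable
observations remain, when no usable non-reference base exists, or when the
max-posterior genotype is hom-ref. "Usable" means base quality ≥ 20 and
MAPQ ≥ 10; sub-threshold observations still count toward raw depth and the
non-unique-fraction annotation. Reads sharing (chromosome, 5′ start,
strand) are collapsed before pileup, keeping the copy with the highest
summed base quality (ties: first read name).

`call_variants` runs a vectorised two-pass scan (per-position usable base
counts first, full pileup columns only at candidate positions); it is
verified in the test suite to produce identical output to the generic
column-by-column path.

## Filtering

**Model filter.** A full-covariance Gaussian mixture (2 components by
default, `sklearn.mixture.GaussianMixture`, fixed random state) is fitted
to the annotation vectors (QD, depth, strand balance, mean MAPQ, GQ) of
calls overlapping a known-sites list, requiring at least 50 training calls
(otherwise the filter deactivates with a warning). The score threshold is
the (1 − sensitivity) quantile of training log-densities with the `higher`
quantile rule, so the retained fraction is 99% to within one part in the
training-set size by construction. Zero-variance annotation dimensions are
dropped with a warning before fitting. This is deliberately smaller than a
full variant-recalibration stack (no tranches, no annotation whitening, at
most a handful of Gaussians): the smallest mixture that separates a core
from an outlier cloud at this scale.

**Hard filters.** Six independent rules, each setting its own FILTER flag
(no call is deleted): `cluster` (> 2 calls in any 10 bp window flags every
call in the window), `nonunique` (> 10% of overlapping reads below the
MAPQ cutoff — "not uniquely aligned" is operationalised as MAPQ < 10),
`low_qual` (QUAL strictly < 50), `repeat` (position in the supplied repeat
mask), `near_indel` (within 5 bp, inclusive, of a position where ≥ 2 reads
show an insertion/deletion gap), and `high_cov` (inside a region above the
99.9th percentile of depth over covered positions — the threshold is a
quantile because no absolute cutoff generalises across enrichment levels).
A SNP passes only with an empty flag set, i.e. it must survive both the
model filter and every hard rule. Filters are idempotent and independent;
both properties are tested.

## Allelic-bias test

At each passing heterozygous SNP, reads are counted per allele after the
same MAPQ/base-quality gates and duplicate removal. Two counting modes:

- `site-base`: classify each read by its base at the site (ref / alt /
  other);
- `dual-haplotype`: re-score the read against the individual's two
  personalized haplotype genomes (reference allele at het sites on one,
  alternate on the other; hom-alt substitutions on both) and assign it to
  the haplotype with strictly fewer mismatches, falling back to the base
  at the site on ties. This is the built-in, aligner-free counter to
  reference-mapping bias; both haplotype FASTAs can also be written out
  for users who prefer a genuine second alignment round.

The null hypothesis is equal representation of both alleles. With
n = ref + alt and k = min(ref, alt), the p-value is `min(1, 2·P(X ≤ k))`
for X ~ Binomial(n, ½), exactly 1 at equal counts. At p₀ = ½ this doubled
smaller tail coincides with the minimum-likelihood two-sided convention
(property-tested against full enumeration), so the choice of convention is
immaterial here. Benjamini–Hochberg q-values are computed *within* the set
of sites whose allele counts differ by at least `min_diff = 6` reads —
sites below the gate never receive a q-value — and significance means
q < α = 0.05. `pct_ref` excludes other-allele reads from the denominator.

The mapping-bias artifact itself is demonstrated by simulation: dropping a
fraction δ of alternate-haplotype reads shifts the expected alternate
share of surviving reads to (1−δ)/(2−δ), and the measured mean `pct_ref`
tracks 1/(2−δ) across δ ∈ {0, 0.1, 0.2, 0.3}.

## Concordance and enrichment

Shared heterozygous sites between two individuals (same position and
allele pair, by default restricted to sites significant in at least one
individual) are compared by Spearman rank correlation of `pct_ref` and by
quadrant concordance — the fraction of sites deviating from 0.5 in the
same direction in both individuals, excluding sites at exactly 0.5. The
Spearman p-value is an exact rank-permutation test for n ≤ 10 (chunked
enumeration of all n! permutations) and the t-approximation above.

GWAS-catalog overlap is an exact position match, reported per 10,000
calls. Enrichment is the upper-tail hypergeometric probability P(X ≥ k)
computed as an explicit log-space sum of log-pmf terms (log-gamma
binomials + logsumexp), which stays accurate for tail probabilities far
smaller than any individual pmf term; it is cross-checked against
scipy's survival function and against exact rational enumeration in the
tests. The four counts (universe, disease-in-universe, drawn,
disease-and-drawn) are taken explicitly rather than inferred, because the
appropriate universe depends on the study design. Proximity of significant
ASB sites to catalog loci is a separate windowed query (default ±500 bp,
inclusive, configurable up to any range) emitting signed distances.

## QC metrics

Ti/Tv counts A↔G and C↔T as transitions (undefined, with a warning, when
there are no transversions). Ht*k* regions are maximal runs of positions
with usable depth ≥ k (k = 5 by default, the conventional assayability
cutoff for this analysis); genome fractions exclude N bases. Overlap
between call sets is reported in two modes — location (position + allele
pair) and genotype (additionally identical zygosity) — and location
overlap bounds genotype overlap from above by construction. Summit
profiles bin SNP positions (counts summed over peaks) or a per-base score
track (means averaged over peaks) into 10 bp bins of signed offsets from
each peak summit, default window ±1000 bp.

Saturation curves subsample ⌊f·N⌋ reads without replacement (seeded;
f = 1 is exactly the identity), rerun genotyping + filtering, and count
passing SNPs in total and inside the Ht5 regions of the *full* read set.
One analysis choice matters here: the caller's depth gate must sit below
the Ht5 threshold (the saturation analyses use `min_depth = 3`), because
with the gate at 5 every called SNP lies inside full-set Ht5 by
construction and the two curves could never separate. With the gate
decoupled, deeply covered peak regions saturate early while totals keep
growing as marginally covered background crosses callability — the
expected plateau-versus-linear contrast.

## Simulator

The generator emulates a single-individual ChIP-seq genotyping experiment:
a random genome (41% GC), planted SNPs with a 2:1 het:hom-alt ratio and a
0.68 transition fraction (Ti/Tv ≈ 2.1), non-overlapping peaks with
box-car enrichment and centred summits, and single-end 50 bp reads drawn
with coverage density `background_depth` off-peak (default 1×) and
`background_depth × enrichment_fold` in peaks (default 30×). Fragments are
assigned a haplotype at fragment level (probability β of the reference
haplotype at designated bias sites, ½ elsewhere), alternate-haplotype
fragments are discarded with probability `ref_bias_drop`, bases are
flipped uniformly at the error rate (default 0.005) with constant reported
quality Q30, 2% of reads get MAPQ 0, and 5% are duplicated at identical
coordinates. A deliberate 3-SNP cluster inside one 10 bp window exercises
the cluster filter. An option injects short deletions to exercise the
indel-proximity rule. All outputs are byte-reproducible for a fixed
(config, seed).

What the simulator does **not** model — and hence what passing tests do
not establish about real data: indel and structural variation beyond the
deletion knob, realistic quality-score profiles and error biases
(substitution-context effects, quality decay along the read), genuine
alignment artifacts (the mapping-bias knob is a read-loss abstraction),
PCR amplification beyond exact duplicates, paired-end information, GC or
mappability coverage waves, triangular/asymmetric peak shapes, aneuploidy
or copy-number variation, and population structure in the planted
variants. In particular, real-data recovery rates are dominated by repeat
regions, mapping errors, and coverage heterogeneity that the simulator
intentionally idealises, so simulated recovery (~96–97% of planted sites
in Ht5 regions) is an upper bound, not a forecast.

## Numerical and design details

- Internal coordinates are 0-based half-open; SAM/VCF conversion happens
  exactly once at the I/O boundary. BED output is 0-based.
- Genotype posteriors are normalised in log space; QUAL/GQ capped at 9999.
- Multiallelic columns keep only the best-supported alternate.
- The GMM threshold uses the `higher` quantile rule (retention never drops
  below the calibrated sensitivity minus one part in the training size).
- Duplicate-marking ties break on read name to make the operation a pure
  function of the read set.
- `high_cov` and cluster rules flag entire offending windows, not just
  excess calls, matching exclusion semantics rather than trimming.
- Degenerate inputs: empty read sets yield empty call lists; an empty FDR
  set yields all-untested bias records; concordance requires ≥ 3 shared
  sites; Ti/Tv is reported absent when transversions are zero.
- Problem sizes in the test and acceptance suites (200 kb genomes, ~30–70 k
  reads, ≤ 3000 planted SNPs) were chosen as the smallest scales at which
  the binomial/FDR statistics and the GMM calibration are well conditioned;
  all stochastic assertions were checked for stability across seeds before
  being frozen.

## Known limitations

- The allelic-bias null is Binomial(n, ½); overdispersion (e.g.
  copy-number changes, extreme PCR duplication surviving dedup) is not
  modelled — a beta-binomial extension would be the natural upgrade.
- The dual-haplotype re-scorer reclassifies already-aligned reads; it
  cannot resurrect alternate-allele reads that were never aligned. True
  correction of mapping loss requires realignment to the personalized
  genomes (the haplotype FASTAs are written for exactly that).
- Indels are detected only as filter evidence, never emitted as calls.
- No multi-sample joint calling, phasing, or base-quality recalibration.
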