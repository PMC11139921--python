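# Methods

`pollenpipe` re-implements, as a tested and reusable pipeline, the
computational analysis used to study siRNA suppression in Arabidopsis
pollen and its consequences for DNA methylation and the triploid block:
multimapper-weighted small-RNA quantification, negative-binomial
differential abundance, a binned context-specific DMR caller, multi-set
overlap and TE-superfamily enrichment statistics, and collapsed-seed
phenotype statistics. Every stage is exercisable on synthetic data with
known ground truth; no sequencing downloads are required.

All genomic coordinates in memory are 0-based half-open. Conversions to
1-based external conventions (bismark cytosine reports, GFF3, SAM) happen
only at the I/O boundary.

## Small-RNA quantification

Collapsed reads (distinct sequences with a multiplicity, the
"non-redundant read count") are filtered to 18–30 nt and, by default, to
perfect genomic matches. Each distinct read with multiplicity *c* and *h*
genomic hits contributes weight *c/h* to every one of its placements, so
that the total placement weight equals the total filtered read count
exactly — a conservation identity asserted on every run of the test
suite. Per-locus counts use an any-overlap rule, strand-agnostic by
default (siRNA loci are double-stranded; a strand-aware flag exists). A
placement overlapping several annotated loci counts fully in each: the
1/h weighting already accounts for genomic multiplicity, and annotation
overlap is a property of the annotation, not of the read. Library-size
normalization is reads per million (RPM) of filtered, perfectly mapped
weighted reads. Size-class profiles partition kept lengths into 21/22-nt,
24-nt, and other; loci without any assigned weight report NaN fractions,
not zeros.

## Differential abundance

A compact NB core applied to both siRNA locus counts and mRNA gene
counts:

- **Size factors** by the median-of-ratios method: the reference is the
  per-feature geometric mean across samples over features with all counts
  positive; a sample's factor is the median count/reference ratio.
  Columns that are exact scalar multiples recover the scalars to machine
  precision.
- **Dispersion** (NB variance μ + αμ²). Two modes. The default "common"
  mode estimates one α shared across features by Cox–Reid-adjusted
  profile likelihood (group means profiled out with plug-in sample means;
  half log-determinant penalty). The adjustment matters: at n = 2 per
  group, per-feature method-of-moments estimates clip to zero for more
  than half the features, and an unpenalized profile likelihood is biased
  downward, both of which inflate the Wald test. The
  "per-feature-moments-with-shrinkage" mode uses α̂ = max(0, (s²−m)/m²)
  per feature, shrunk halfway (log scale) toward a rolling-median trend
  over mean-ranked features, floored at 1e-8; it requires ≥2 replicates
  per group.
- **Wald test**: per-feature two-group log-link NB GLM with size-factor
  offsets, fitted by vectorized IRLS; the Wald statistic is the group
  coefficient over its Fisher-information SE, referred to the standard
  normal, two-sided. Fold changes are reported in log2 units. All-zero
  features are excluded and reported with NA statistics.
- **FDR**: Benjamini–Hochberg at 0.05 (configurable); `significant` means
  adjusted p < α.
- **VST + PCA** for sample-level QC: log2(x + 1) of normalized counts
  (a pragmatic variance stabilizer; the closed-form NB VST is an
  extension hook), per-feature centering, SVD projection of samples, with
  per-axis variance explained.

This is deliberately the minimal defensible core — median-of-ratios + NB
Wald + BH — not a re-implementation of any full DE framework's shrinkage
machinery; the analysis contract is "NB differential abundance at a
stated FDR".

## DMR caller

The genome is tiled into fixed 100-bp bins anchored at coordinate 0 (not
sliding windows). Replicates are pooled by summing counts per cytosine
before comparison. A cytosine is differentially methylated when both
pooled conditions cover it with ≥ 4 reads (`min_coverage`) and the
absolute level difference reaches the context threshold: 0.4 (CG), 0.2
(CHG), 0.1 (CHH). A bin is a candidate for (context, direction) when it
holds at least 4 (CG), 5 (CHG) or 6 (CHH) such cytosines of the same
direction; both directions are evaluated independently. Candidate bins
whose gap is ≤ 200 bp ("within 200 bp", read inclusively; the boundary is
unit-tested) merge transitively into one DMR. "hypo" means the test
condition is less methylated than the reference; swapping the conditions
exactly exchanges hypo and hyper labels (a tested invariant). DMRs are
annotated TE / gene / intergenic with TE priority, carrying the family
and superfamily of the leftmost overlapping TE.

Design choices made where the definition was genuinely open:

- the level-difference criterion is applied **per cytosine** (which
  implies the supporting-cytosine bin average also passes); a stricter
  flag (`require_bin_mean_diff`) additionally requires the bin-average
  difference over all covered cytosines of the context;
- an alternative per-cytosine criterion (`diff_method="fisher"`) gates
  differential status on a two-sided Fisher exact test (p < 0.05) in
  addition to the level threshold;
- symmetric CG positions on opposite strands are kept separate;
- merged DMR mean levels are supporting-cytosine-weighted means.

An independent brute-force caller (explicit loops over cytosines and
bins, pairwise merge closure) lives in the test suite and must produce
byte-identical DMR sets on 50 seeded 50-kb genomes.

## Overlap and enrichment statistics

For the significance of a multi-set DMR overlap, region lists are mapped
to sets of genome bins (any-overlap, DMR bin size), the universe being
all bins, optionally restricted to a callable subset. The statistic is
the exact upper tail P(X ≥ k) of the total intersection X of m
independent uniform random subsets of fixed sizes n₁..n_m from N
elements. Two exact routes are implemented and cross-checked:

- a **chained hypergeometric mixture**: the intersection of the first i
  sets, conditioned on its size s, intersects the next set
  Hypergeom(N, s, n_{i+1}); iterating gives the full pmf with
  all-positive terms (numerically robust; default for N ≤ 4096);
- the **inclusion–exclusion tail**
  P(X ≥ k) = Σ_{j≥k} (−1)^{j−k} C(j−1, k−1) C(N, j) Π_i C(N−j, n_i−j)/C(N, n_i),
  evaluated with log-domain binomial coefficients and max-shifted signed
  summation, for large universes where the O(N²) mixture is too slow.

For m = 2 both reduce to the hypergeometric survival function (verified
against enumeration and scipy for 1000 random parameter draws); for small
universes both match exhaustive enumeration exactly.

TE-superfamily enrichment is the classical hypergeometric
over-representation test per category (uncategorized elements pooled as
"other"), with fold enrichment (hits/list size)/(category
frequency in universe) and BH adjustment across categories.

## Phenotype statistics

Per-plant collapse percentage is 100 · collapsed/(normal + collapsed);
zero-total plants are excluded with a log entry. Genotypes are compared
by one-way ANOVA (between/within decomposition, F reference) and a
post hoc Dunnett many-to-one comparison against the reference genotype.
The Dunnett family-wise adjustment uses the max-modulus distribution of
the multivariate t implied by the shared reference: with group sizes n_i
and reference size n₀, T_i = (λ_i Z₀ + √(1−λ_i²) Z_i)/√(W/df) with
λ_i = √(n_i/(n_i+n₀)) and shared W ~ χ²_df, evaluated by seeded
Monte-Carlo integration with ≥ 10⁵ draws (p values stable to about
±0.005 across seeds at that size; the two-group case reduces to the
pooled two-sample t-test, and scipy's Dunnett implementation serves as an
independent cross-check in the tests). Percentages are analyzed
untransformed by default, matching the standard presentation; arcsine and
logit transforms are available via a flag. Significance stars follow the
convention ns ≥ 0.05 > * > 0.01 > ** > 0.001 > ***. Box/whisker summaries
use the quartiles with whiskers at Q1 − 1.5·IQR and Q3 + 1.5·IQR. Each
generation of a multi-generation experiment is analyzed independently
(tables are per-experiment; no pooled mixed model).

## Synthetic data and what it does (not) show

Generators are deterministic under a master seed; each stage draws from
its own stream keyed by (seed, stage name), so results do not depend on
call order. Every generator emits its ground truth machine-readably, and
generated files pass the corresponding readers unchanged.

- **Genome**: 2 × 50 kb chromosomes by default with non-overlapping genes
  (0.8–2.5 kb) and TEs (0.3–1.2 kb) drawn from a family→superfamily
  catalog in TAIR10 nomenclature (ATGP1 → LTR/Gypsy, …). Copies of a TE
  family share a length so family reads can be placed at the same offset
  in every copy. Cytosines are laid down per 100-bp bin at fixed
  per-context counts (CG 3, CHG 3, CHH 10 — CHH-dominated, as in the
  A/C/T-rich Arabidopsis genome), guaranteeing a uniform ≥ 8 CHH
  sites/100 bp.
- **Methylome**: coverage ~ Poisson(20 by default) per cytosine,
  methylated counts ~ Binomial(coverage, level). Baselines default to
  CG 0.85, CHG 0.35, CHH 0.10. Planted regions are methylated islands: a
  region-level reference level (e.g. CHH 0.40, TE-like) plus a signed
  delta in the test condition (e.g. −0.3), so a hypomethylation deeper
  than the genomic background baseline remains expressible; levels are
  validated to stay in [0, 1]. No bisulfite non-conversion error model.
- **Small RNA**: distinct reads with Poisson multiplicities, lengths from
  gene-biased (21/22-nt) or TE-biased (24-nt) distributions, placed once
  per gene or at every family copy (hit count = copy number by
  construction); group-specific depletion applied as 2^log2FC in
  condition B; out-of-window lengths and imperfect matches planted at low
  rates as negative controls for the filter. No nucleotide-level realism.
- **Counts**: NB matrices via gamma-Poisson mixing with per-feature mean,
  shared or per-feature dispersion, planted log2 fold changes and sample
  size factors.
- **Seeds**: collapsed counts per plant ~ beta-binomial(n, p, ρ), ρ = 0
  degenerating to binomial; the reference genotype defaults to a collapse
  probability of 0.35 (inside the 30–40% band expected for a *jas-3*-like
  triploid-block background), a suppressor to 0.15.

The planted-DMR recovery study uses a TE-dense, pericentromere-like 50-kb
segment (40 TE fragments of 0.3–0.6 kb, all planted with CHH loss),
reflecting the heterochromatic context in which CHH hypomethylation
concentrates. This choice also gives the DMR-level false-discovery
proportion a stable denominator: at coverage 20 the CHH per-cytosine
threshold (0.1) is about one binomial standard deviation, so a background
false-candidate rate of roughly 1.5 bins per 50 kb is inherent to the
caller definition, not a bug; "no false hyper calls inside planted
regions" is evaluated for DMRs *contained* in a planted region, since a
boundary-clipping 100-bp bin can be supported entirely by outside
cytosines.

Passing these tests shows the implementation is faithful to its stated
definitions and calibrated on its own generative model. It does not show
robustness to features of real data the generators omit: mapping bias,
bisulfite conversion failure, coverage heterogeneity, adapter artifacts,
batch effects, or annotation error.

## Numerical choices and problem sizes

- Dispersion floor 1e-8; IRLS run to a 1e-10 coefficient tolerance with
  means clipped away from zero; threshold comparisons use a 1e-12 slack
  so exact-boundary level differences (e.g. 0.10 at coverage 20) are not
  lost to floating-point rounding.
- The intersection test switches from the mixture to inclusion–exclusion
  above N = 4096; the signed summation is max-shifted and the result
  clamped to [0, 1].
- Monte-Carlo sizes: 1e5–2e5 draws for Dunnett adjustments; 2000
  replicates for the family-wise error-rate study; 2000 features at
  n = 2/group for differential-abundance calibration; 20 simulated
  methylomes for planted-region recovery and 50 genomes for brute-force
  oracle equivalence. These sizes keep the full suite to well under a
  minute while leaving Monte-Carlo error small against the tested
  tolerances.

## Known limitations

- The DE core omits LFC shrinkage, outlier replacement and independent
  filtering; on real data it will not match DESeq2 defaults
  feature-for-feature, only the contract (NB Wald at BH FDR 0.05).
- The Wald normal reference at n = 2 per group is mildly anticonservative
  (the null p < 0.05 fraction centers near 0.053 rather than 0.050 in the
  calibration study); with the shared dispersion estimate, the rejection
  fraction also varies slightly more across datasets than a binomial
  count would.
- The intersection test assumes sets are uniform random draws from the
  bin universe; spatial autocorrelation of DMRs (clustering in
  heterochromatin) violates this, as it does for any test of this family,
  and the callable-universe restriction flag is the provided sensitivity
  control.
- The DMR caller's per-cytosine threshold interpretation is one of two
  defensible readings of the bin definition; the other (bin-mean) is
  behind a flag, and on noisy backgrounds the default is the more
  permissive of the two.
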