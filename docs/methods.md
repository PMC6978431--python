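# Methods

## Problem setting

The toolkit operates entirely on GWAS summary statistics: for each trait, a
table of per-variant effect sizes, standard errors, and p-values, plus a
trait metadata table with partitioned-heritability estimates and a square
trait × trait phenotypic correlation matrix. Individual-level genotypes are
never required. The analysis asks which variants are associated with
several genuinely distinct groups of phenotypes ("biological", horizontal
pleiotropy) as opposed to several renamings or close correlates of one
phenotype (vertical pleiotropy), and what functional classes of genes and
variants the pleiotropic loci implicate.

## Pipeline stages and their assumptions

### 1. Ingestion and filtering

Traits are kept when their heritability p-value is strictly below 0.05;
associations are kept when the p-value is strictly below 5×10⁻⁹ (a
conservative genome-wide threshold appropriate for dense imputed data).
Both cutoffs are strict inequalities and configurable. Variant identity is
the coordinate tuple (chrom, pos, ref, alt); textual variant ids are carried
through output tables but never trusted for joins, and the ingester raises
an error when one id maps to two coordinate tuples. Positions are 1-based
in all input and output tables (GWAS convention) and converted to 0-based
half-open coordinates inside interval code. Each alt allele of a
multi-allelic site is a distinct variant.

The phenome summary reports, over variants with at least one association,
the total count, mean associations per variant, and the percentage with
more than *t* associations, computed as plain division rounded to two
decimals. Note that two of the corresponding published percentages (4.27%
of all variants associated; 49.21% with more than one association) do not
reproduce from the published counts by plain division (which gives 4.31%
and 49.10%); the summary deliberately reports plain division and makes no
attempt to match those two figures. The three that do reproduce (12.34%,
1.5%, 1.76 traits/cluster) are pinned in the acceptance tests.

### 2. Trait clustering

Traits are clustered agglomeratively on the dissimilarity 1 − |corr|, which
is symmetric, non-negative, and zero only for perfectly correlated traits.
The absolute value matters: a trait measured on a reversed scale is the
same phenotype. Defaults: average linkage (robust for correlation-derived
distances; single and complete linkage are accepted), cluster count chosen
by maximizing the mean silhouette width over k = 2 … n−1, ties broken
toward smaller k. Perfectly correlated trait groups (distance 0) are
pre-merged before the scan so silhouettes are well defined; if only two
distinct groups remain the cut k = 2 is returned directly. A constant
off-diagonal distance matrix is rejected as degenerate. If the best mean
silhouette is below 0.1 the structure is weak; a warning is logged but the
argmax is still returned (k = 1 is never produced).

Where no externally reconstructed phenotypic correlation matrix is
available, the toolkit estimates one as the correlation of association
z-scores across traits at null variants (variants with no signal in any
trait). Under fully overlapping cohort samples the null z-score correlation
equals the phenotypic correlation; the estimator requires at least 30 null
variants and its sampling error scales as 1/√n_null, so a few thousand null
variants give ±0.05 accuracy. The pipeline's default null mask is "best
p-value across traits ≥ 10⁻⁴".

The cluster-pair correlation corr(Cₙ, Cₘ) is the maximum |corr| over member
trait pairs — an upper bound on how strongly the two clusters can be
coupled. Its diagonal is 1 by convention and never enters score products.

### 3. LSEA

Clumping is the standard greedy procedure: take the unassigned variant with
the smallest p-value as index (ties broken by chromosome, position, id for
determinism), assign every unassigned variant within the window and with
r² at or above the threshold, repeat. Defaults r² ≥ 0.5 and a 250 kb
window are the conventional clumping settings; only genome-wide significant
variants are clumped. LD arrives as a sparse pairs table (or a small
genotype dosage matrix); pairs absent from the table count as r² = 0, with
one summary warning per operation since sparse tables routinely omit
below-threshold pairs.

Clump spans become locus intervals, merged to a fixed point when two
intervals overlap by strictly more than 70% of the **shorter** interval
(the denominator is not dictated by the rule's usual statement; the shorter
interval is the choice that makes merging insensitive to one very wide
locus) or when both overlap the same gene body by ≥ 1 bp ("different parts
of the same gene"). Intervals overlapping the MHC
(chr6:28,866,528–33,775,446) or HIST1 (chr6:25,000,528–28,000,446) regions
(hg19, 1-based inclusive; stored half-open) by ≥ 1 bp are dropped — these
regions have extreme LD and gene density and are tested separately by the
region overrepresentation test.

The locus universe merges all traits' loci by **any** overlap, a stricter
rule than the 70% criterion, because the universe must be disjoint for the
hypergeometric model to be well defined. A gene set maps onto the universe
as the subset of universe intervals overlapping at least one member gene,
each interval counted once however many member genes it spans — this is the
step that stops clusters of functionally related, genetically linked genes
from being counted repeatedly. Enrichment of a query locus list is then
F = number of set intervals among the n distinct universe intervals the
query hits, with p = P(X ≥ F), X hypergeometric with population
N = |universe| and K set members. Note that with K fixed this tail is
non-increasing in N: a larger universe makes a given overlap more
surprising.

Multiple-testing adjustment is Holm's step-down procedure, which controls
family-wise error with no independence assumptions; Benjamini–Hochberg is
available behind a flag for users who prefer FDR control. The per-cluster
"union of gene sets" report retains sets whose adjusted p is below α in two
or more member traits of a cluster.

### 4. Pleiotropy score

PS = −log₁₀ of the product of pairwise cluster correlations over all
unordered pairs of a variant's associated clusters. The product is an
upper-bound proxy for the probability that the joint association arises
from trait correlation alone, so small products (large PS) indicate
horizontal pleiotropy. Scoring applies only to variants with degree ≥ 2;
degree-1 variants are excluded from pleiotropy tables entirely. Variants
with PS ≤ 2 are removed (strict retention: PS > 2). Numerical choices: a
pair correlation of exactly 0 yields an infinite score, kept as a sentinel
that always passes the filter and serializes as `"inf"`; otherwise the
product is floored at 10⁻³⁰⁰ before the log so high-degree variants cannot
underflow. PS is permutation-invariant and non-decreasing as clusters are
added (every factor is ≤ 1).

Retained variants are stratified at degree cutoffs 2 … 10; each stratum's
loci are re-derived by the same clump-and-merge procedure and the summed
locus length reports genome coverage. Strata are nested, so coverage is
non-increasing in the cutoff.

### 5. Overrepresentation

Annotation-class tests treat the foreground (e.g. pleiotropic variants) as
draws without replacement from the background (e.g. all associated
variants), giving the one-sided hypergeometric upper tail; a two-sided
Fisher exact test on the foreground-versus-rest table is available behind a
flag because published figures for such comparisons are often Fisher
p-values. The published cis-eQTL counts (586/2,106 vs 5,640/59,449) give
−log₁₀ p ≈ 133 in both configurations here; the implementation records all
four counts so any configuration can be recomputed, and the acceptance
check asserts only strong enrichment (p < 10⁻¹⁰) in the published
direction, not the exact printed figure. Flag columns may be boolean,
categorical (queried as `column=value`), or p-values (binarized at the
cis-eQTL threshold 5×10⁻⁸). Variants missing from the annotation count as
unflagged and are logged.

## The synthetic phenome

The generator works at the summary-statistic level — it draws z-scores, not
genotypes — because every downstream method consumes summary statistics;
this keeps a full phenome under a second to generate. Null z-scores are
drawn i.i.d. across variants from a multivariate normal whose correlation
matrix has within-cluster entries 0.8 and cross-cluster entries 0.02
(traits assigned to clusters in contiguous near-equal groups). Planted
causal variants add a mean shift of effect_z (default 8, comfortably past
the 5×10⁻⁹ threshold) to their target traits; the other members of the
causal variant's LD block receive the attenuated shift √r² · effect_z, as
expected for markers in LD with a causal allele, so clumps and loci have
realistic extent. p-values are two-sided normal tails; beta = z·se with
se = 1/√(2·maf·(1−maf)·n_samples) and maf uniform on (0.01, 0.5).

Default conditions: 40 traits in 8 clusters, 5,000 variants on two
chromosomes (3,000 null, 2,000 in 200 ten-variant LD blocks with r² = 0.8
within and 0 between), 50 horizontal + 50 vertical + 100 trait-specific
causal variants each at the focal position of its own block, 400 genes
tiling 50 Mb, 30 gene sets of which 2 are planted on the genes hosting the
horizontal variants.

Horizontal variants target one trait in each of 3 distinct clusters by
default. The span of 3 follows from the score's own arithmetic: at
threshold 2, a degree-2 variant is retained only when its realized cluster
pair correlation is below 0.01, which neither the generating cross-cluster
correlation (0.02) nor the noise floor of a max-|r| estimate over ~25
member-trait pairs at feasible null counts can deliver — degree-2
"horizontal" plants would be indistinguishable from the filter's intended
rejections. With three near-orthogonal clusters the score is ≈ 3 × 1.2–1.7
and retention is robust. Vertical variants target two traits inside one
cluster; after correct clustering they touch a single cluster, never enter
the pleiotropy tables, and so are rejected — and if clustering happens to
split their cluster, the split halves are highly correlated and the PS
filter removes them anyway. Genes tile the genome and each LD block is
anchored inside its own gene tile, so every planted locus maps to exactly
one gene and planted gene-set membership is unambiguous.

What the generator does **not** emulate: realistic MAF and LD spectra
(r² is uniform within a block, zero between), LD in the *noise* (null
z-scores are independent across variants; LD shapes planted effects only),
population structure, binary-trait liability scaling, overlapping-sample
artifacts beyond the shared-correlation structure, and non-heritable decoy
traits (all simulated traits pass the heritability filter by default).
Passing recovery tests on this phenome therefore demonstrates correctness
of the statistical machinery under the stated model, not robustness to the
full messiness of biobank data.

## Problem sizes used in validation

The test suite exercises most modules on a scaled-down phenome (12 traits
in 4 clusters, 1,100 variants, 30 LD blocks) chosen so the whole suite runs
in a couple of minutes; end-to-end acceptance uses the default 40-trait
phenome over ten seeds. Oracle tests enumerate all hypergeometric
configurations up to population 15, compare clumping against a naive greedy
reference on 200 random 20-variant instances, compare Holm against the
step-down definition on 1,000 random vectors plus a 1,000-replicate global
null, and verify the pleiotropy score against the explicit pair product at
10⁻¹² relative tolerance.

## Known limitations

* The correlation proxy is valid only under (near-)fully overlapping
  samples; for partially overlapping cohorts an external reconstruction
  should be supplied as the input matrix.
* Clumping parameters (r² 0.5, 250 kb) and the enrichment significance
  level inside the shared-set report (0.05) are conventional defaults, not
  derived quantities; sensitivity to them should be checked on real data.
* The universe's any-overlap merge is stricter than the 70% locus merge;
  universes built by other tools with laxer merging are not interchangeable.
* Interval arithmetic assumes a single genome build throughout; no liftover
  is provided.
* The pipeline recomputes loci per degree stratum by re-clumping the
  surviving variants, so stratum loci need not be a subset relation of each
  other's intervals even though the variant sets are nested.
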