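# Methods

This note documents the models and procedures the package implements, the
defaults that matter, what the synthetic-data generator does and does not
emulate, and the numerical choices made where the design was genuinely
open. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Consensus somatic variants and TMB

Calls from four SNV callers and two indel callers are merged on the
variant key (contig, 1-based position, ref, alt). The retention rule is
≥ 2 supporting SNV callers for an SNV and both indel callers for an indel.
Because callers report different read counts for the same variant, the
consensus record takes the counts of the supporting record with the
highest tumor depth (ties broken by caller name) — the downstream filters
need one well-defined VAF per variant, and the deepest record is the most
informative single choice.

Filters (all must hold): tumor depth ≥ 10 and normal depth ≥ 10; tumor
VAF ≥ 0.05 **and** tumor alt reads ≥ 4 (the strict reading of "> 3
reads"); normal VAF ≤ 0.01 **or** normal alt reads ≤ 1 ("just one read"
is read as ≤ 1 so the zero-read case passes); not known-germline unless
also a known somatic hotspot (database membership is supplied as flags or
sets, never queried live); not on the optional artifact-position
blacklist. Zero-depth records are rejected with a dedicated reason rather
than raising. Rejected records carry *every* failed criterion, which is
why merging precedes filtering: the final set is the same either way
(all criteria are per-record), but the bookkeeping is complete.

TMB divides the retained count by the coverage space in megabases. The
package counts whatever variant set it is handed; silent/non-silent
annotation needs transcript models and is out of scope.

## 96-category catalogs and signature extraction

Category labels follow the pyrimidine-strand convention `X[R>A]Y` with the
fixed ordering: classes C>A, C>G, C>T, T>A, T>C, T>G; within a class the
16 flanking contexts in alphabetical order (5′ base major). Purine-strand
substitutions are reverse-complemented before labeling, so the 192
strand-specific substitutions map two-to-one onto the 96 labels. Variants
with non-ACGT context, boundary positions, reference mismatches, or indel
alleles are excluded from catalogs and counted per sample.

Extraction is NMF under the generalized Kullback–Leibler divergence with
the standard multiplicative updates, which never increase the objective;
the per-iteration divergence path is retained and asserted monotone in the
tests. The best of `n_restarts` random initialisations (default 10) wins
by final divergence. Profile columns are normalized to probability
vectors, with exposures rescaled so the product is unchanged.

**Rank selection.** Three clauses, all required, scanning k = 2..k_max and
keeping the largest k that passes (k = 1 otherwise):

1. *Restart stability*: mean cosine of greedily matched profiles across
   restarts ≥ 0.85.
2. *Error improvement*: relative **Frobenius** reconstruction-error
   improvement over k−1 greater than 2%. The KL objective is unsuitable
   here: count catalogs carry an irreducible multinomial noise floor in
   likelihood units, and each extra rank chips away at that floor by more
   than 2% essentially forever.
3. *Bootstrap stability*: refits on catalogs whose sample columns are
   multinomially resampled must reproduce, for every component, both the
   profile (cosine) and the exposure pattern across samples (correlation),
   at a mean score ≥ 0.85. This clause is what rejects stable-looking
   noise splits: when a spiky signature's two peak categories are split
   into two components, the split profiles are canonical (hence restart-
   and even bootstrap-stable) but their exposure ratios are pure sampling
   noise and decorrelate under resampling. On rank-1 synthetic catalogs
   this rule selects k = 1 and on two-signature catalogs k = 2, across
   seeds (see the test suite).

Matching to a reference catalog is plain cosine similarity (argmax per
extracted signature, ties to the earlier reference column), and the
combined profiles are clustered with Ward linkage on 1 − cosine. scipy's
`ward` on a precomputed dissimilarity applies the Lance–Williams update to
squared dissimilarities — the ward.D2 variant. The packaged reference
catalog is synthetic but structured like the real landscape (an
APOBEC-like TCW-concentrated C>T/C>G pair, a CpG-deamination C>T profile,
an MMR-like and a NER-like broad profile, and a flat background); real
96 × k catalogs load from TSV.

## MSI scoring

A site is evaluated only if both histograms have ≥ 20 reads (default).
The site test is a chi-square homogeneity test of tumor vs normal
repeat-length distributions; adjacent length bins are pooled until every
expected cell count is ≥ 5 (merging into the smaller neighbour for
determinism), degrees of freedom follow the pooled table, and degenerate
single-bin tables score p = 1 (stable). The sample score is
100 · unstable / **evaluated** sites — the denominator of the scoring tool
the 3.5 cut-off was calibrated on — with a flag to divide by stable sites
only for the alternative reading. A boundary score of exactly 3.5 is
classified MSS (the cut-off is defined by strict inequalities).

Two calibration facts shape the defaults. At per-site α = 0.05 the null
call rate is ≈ 5%, so the *score* of a perfectly stable sample sits near
5 — above the 3.5 threshold. The score therefore tracks
(planted fraction + type-I rate) × 100, which is how the tracking property
is tested. The pipeline default is α = 0.01: a stricter per-site level
standing in for the multiple-testing control the original tool applies to
its somatic-status calls, and the level at which a cohort with ~1%
genuinely unstable sites scores below 3.5 — the microsatellite-stable
phenotype sporadic upper-tract cohorts show.

## Expression harmonization and testing

Quantile normalization maps every sample onto the across-sample mean
quantile vector at its own ranks; tied values receive the mean of the tied
quantiles (average ranks, interpolating between the two flanking reference
values), so column value-multisets are identical afterwards and
within-sample order is preserved. The log transform is log2(x+1).

Housekeeping QC z-scores each housekeeping gene across all samples,
summarizes per cohort, and tests cohorts with Kruskal–Wallis + BH; a
flagged gene after harmonization indicates a residual gene-specific cohort
effect (which quantile normalization, by design, cannot remove — it only
equalizes per-sample distributions).

The differential-expression stage is deliberately simple: Welch's t on the
normalized-log scale, BH adjustment, and the |log2FC| > 1 with adjusted
p ≤ 0.05 significance convention. The scientific content reproduced here
is the thresholding convention, not a count-model GLM; a negative-binomial
stage could be slotted in behind the same interface.

Outlier z-scores are computed on raw FPKM by default (the abundance gate
"> 50 FPKM" lives on the raw scale, and the scale of the z-score is
otherwise unspecified); a `log_scale` switch standardises log2(x+1)
instead while keeping the gate raw. Zero-spread genes never yield
outliers. Tukey fences per sample (Q1 − 1.5·IQR, Q3 + 1.5·IQR) are
reported as a secondary annotation only.

## Subtype label transfer and NMF deconvolution

Signature genes are z-scored per gene before the sample–sample Pearson
correlation — without this, correlations are dominated by overall
abundance rather than subtype profile. Reference and query samples are
clustered jointly (average linkage on 1 − r), the cophenetic matrix is
read off the tree, and each query takes the label of the reference at
minimum cophenetic distance; ties break by smaller raw correlation
distance, then reference order. Joint clustering over all cohorts is the
default; clustering per query cohort is available by subsetting the input.

Deconvolution retains the top 25% of genes by variance of log2(x+1)
("expression variability" made concrete: the log stabilizes heavy-tailed
FPKM), then runs Frobenius multiplicative-update NMF at rank 3, best of 30
initialisations over 100 iterations by default. Component assignment is
the argmax of column-normalized coefficients; PCA of the transposed
coefficient matrix gives 2-D visualization coordinates. Component naming
(luminal/CIS-low, basal/squamous, ECM/EMT) is post-hoc annotation by
marker-gene membership of each component's top-loading genes — reported,
never inferred.

## Immune contexture

Variable genes are ranked by median absolute deviation (boundary ties by
gene symbol); the selected genes are median-centered and the *genes* are
clustered by Euclidean Ward (ward.D2), the tree cut into k = 20 clusters,
and the CD8A-containing cluster returned (anchor first, rest sorted).
Agglomeration is scipy's deterministic nearest-neighbor chain; there is no
randomness to seed.

Consensus clustering runs 100 k-means (k = 2) fits on random 80% sample
subsets of the per-gene z-scored classifier matrix; the consensus entry
for a sample pair is its co-assignment frequency among runs containing
both. The final bipartition cuts an average-linkage tree of 1 − consensus
at two clusters, and the cluster with higher mean classifier-gene
expression is "inflamed". The procedure is defined for the two-state
contexture only; other k are rejected.

The Fisher test enumerates the hypergeometric distribution directly
(two-sided: sum of point probabilities ≤ the observed, with a 1e-7
relative tolerance for floating ties) — the tests cross-check it against
an independent implementation to 1e-12. The odds ratio is the sample
ad/bc with a 0.5 continuity correction applied when any cell is zero.
Mann–Whitney is exact for combined n ≤ 25, tie-corrected normal otherwise.

## IHC H-scores

H = 1·(%1+) + 2·(%2+) + 3·(%3+); inputs must be non-negative and sum to
100 (±1e-6). Group comparison uses Welch's t-test by default ("t-test" in
the source convention is underspecified; unequal variances is the robust
default, and the cohorts are unpaired — 16 vs 14 samples cannot be
paired), with a pooled-variance option.

## The synthetic-data generator

The generator's defaults are the study conditions: a 32-sample UTUC cohort
against a 128-sample UCB cohort; immune contexture planted exactly as
28 depleted / 4 inflamed vs 71 / 57; subtype composition predominantly
luminal in UTUC (85/10/5%) versus mixed in UCB (46/34/20%); four SNV
callers (sensitivities 0.85–0.95, false positives 2–4 per Mb) and two
indel callers; mean tumor/normal depths 80×/60×; tumor VAF ~ Beta(8,12)
truncated at 0.02 (mean 0.4, producing both passing and failing variants
for the 5%/1% filters); normal contamination Binomial(depth, 0.002);
a 1% microsatellite-unstable site fraction (the stable, sub-3.5-score
regime); IHC cohorts of 16 vs 14 samples with low- vs high-intensity
Dirichlet profiles. One linear contig (default 100–200 kb at desk scale)
hosts mutations; multi-contig references are supported downstream.

Expression is FPKM = 2^(centroid + ε) with per-gene noise scales: tightly
co-regulated immune module (scale 0.6) and housekeeping set (0.5) against
heterogeneous background genes (0.6–1.8), around a base σ of 0.5 log2
units. Two features were added to the minimal
exp(centroid + noise) model after integration testing showed the minimal
model contradicts the pipeline it is supposed to exercise:

* **Batch effects are monotone.** Each cohort applies a global scale and a
  power bend to its values. This is exactly the class of distortion
  quantile normalization removes; a gene-wise multiplicative batch effect
  would survive normalization and flag most housekeeping genes, which is
  not the phenomenon the QC stage models.
* **Immune infiltration is continuous.** Inflamed samples get the binary
  `immune_hot_shift` (2.0 log2 units) *plus* every sample draws a shared
  continuous immune-activity component (sd 0.6). A purely binary shift
  affecting a ~38% minority of samples is nearly invisible to the median
  absolute deviation, so CD8A would never rank among the top variable
  genes and the discovery procedure could not find its own anchor.
  Continuous activity is also what real infiltration looks like.

What the generator does **not** emulate: read-level data (no alignments,
no sequencing-error profiles — caller behaviour is programmed directly),
gene-length or GC biases in expression, correlated background gene
modules, subclonal copy-number structure, or homopolymer slippage error
models for microsatellites. Passing tests demonstrate that the
implementations recover *planted* structure under these idealized
conditions; they do not certify performance on real tumor data.

All generators are bit-reproducible: each draws from
`default_rng([seed, stream])` with a fixed stream id per generator, so one
config seed drives every stage without coupling their draws. Ground truth
is always returned alongside the data and written under `truth/` in demo
bundles; no analysis stage reads it.

## Pipeline, determinism, problem sizes

`run_pipeline` executes variants → signatures, expression → subtype +
immune, with msi and ihc independent; a stage failure aborts its
dependents, the rest continue, and the run exits non-zero after writing
the manifest. The YAML config is validated strictly (unknown keys are
errors) against a complete defaults schema; the manifest records
parameters, the seed, and a SHA-256 per output. Re-running the same
config on the same inputs is byte-identical, which the test suite asserts.

Demo problem sizes are chosen for a laptop-class run: a 100 kb contig,
6 tumor–normal pairs × 200 mutations, the full 160-sample expression
design over 2 000 genes, 200 microsatellite sites, 30 IHC samples; the
demo's signature stage uses a fixed rank 3 with 5 restarts (rank-"auto"
with its bootstrap clause is available but costs several times more fits).
Recovery simulations in the tests use the sizes stated alongside each
property (e.g. 50 samples × 500 mutations for signature recovery; 5 000
genes with a planted 150-gene module for classifier discovery).

## Known limitations

* The consensus read-count reconciliation (deepest record) is one of
  several defensible rules; VAFs can differ slightly from any single
  caller's report.
* The MSI site test approximates the cited tool's behaviour; it is not a
  reimplementation of its internals, and the α = 0.01 pipeline default is
  a stand-in for its multiple-testing control.
* The DE stage is a location test on normalized values, not a count
  model; dispersion shrinkage and count offsets are out of scope.
* Rank-"auto" signature selection is calibrated on the synthetic designs
  in the tests; heavily correlated real signatures (cosine ≫ 0.6) may
  still merge.
* Component naming in the NMF deconvolution and the inflamed/depleted
  naming are annotations driven by marker lists and mean expression; they
  carry no statistical guarantee.
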