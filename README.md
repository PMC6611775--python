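# uromics

An integrated-genomics toolkit for contrasting urothelial carcinoma cohorts
— upper-tract tumors (UTUC) against bladder tumors (UCB) — covering the
full computational arc of such a study: consensus somatic variant calling
and tumor mutational burden, trinucleotide mutational-signature extraction,
microsatellite-instability scoring, multi-cohort expression harmonization,
molecular-subtype label transfer, NMF expression deconvolution, immune-
contexture discovery, and immunohistochemistry H-scoring.

Real cohorts of this kind are controlled-access, so the package ships a
first-class synthetic-data generator (`uromics.simulate`) that emulates
every input with known ground truth: mutation catalogs drawn from known
signature mixtures, multi-caller call sets with programmed sensitivity and
false-positive behaviour, expression cohorts with planted subtype centroids
and immune-hot/cold structure, stable/unstable microsatellite sites, and
IHC intensity tables. Every analysis stage is therefore testable end to
end without any download.

## The methods at the core

**Consensus somatic variants.** Tumor–normal calls from four SNV callers
(MuTect2/Strelka/VarScan/SomaticSniper-style tables) are merged on
(contig, pos, ref, alt); an SNV is kept iff ≥ 2 callers agree, an indel iff
both indel callers agree. Retained calls are filtered by: tumor and normal
depth ≥ 10; tumor VAF ≥ 5% with > 3 alt reads; normal VAF ≤ 1% or ≤ 1 alt
read; known-germline calls dropped unless they are known somatic hotspots.
TMB = n / (coverage bases / 10⁶) mutations per megabase.

**Mutational signatures.** Each SNV is classified into one of 96 categories
`X[R>A]Y` (pyrimidine strand, 5′→3′: 6 substitution classes × 16 flanking
contexts). Per-sample category counts V (96 × S) are factorised as
V ≈ WH by NMF under the generalized Kullback–Leibler divergence with
multiplicative updates, best of n restarts; profile columns of W are
normalized to probability vectors. Rank selection ("auto") requires
restart stability of matched profiles, a > 2% relative Frobenius error
improvement over rank k−1, and bootstrap stability of both profiles and
exposures under multinomial resampling of the catalog. Extracted
signatures are matched to a 96 × k reference catalog by cosine similarity
and placed on a Ward (ward.D2) dendrogram of 1 − cosine.

**MSI.** Each microsatellite site carries tumor and normal repeat-length
read histograms; adequately covered sites are tested by chi-square
homogeneity (low-expectation bins pooled). The MSI score is
100 · unstable / evaluated sites; a sample is MSI-high iff score > 3.5.

**Expression.** Cohort FPKM matrices are combined on the shared gene
universe and quantile normalized (each sample mapped onto the mean
quantile vector, ties averaged), then log2(x+1)-transformed. Housekeeping
genes are checked for residual cohort effects (Kruskal–Wallis + BH).
Differential expression is a per-gene Welch t-test on the log scale with
BH adjustment; significance requires |log2FC| > 1 and adjusted p ≤ 0.05.
Outlier calls on a gene panel require z > 1 (across the cohort) and
abundance > 50 FPKM.

**Subtypes.** Query samples inherit the molecular subtype of the reference
sample at minimum cophenetic distance, from average-linkage clustering of
1 − Pearson correlation over z-scored signature genes (BASE47/MDACC/TCGA
gene lists are interchangeable inputs). Independently, the FPKM matrix
(top quartile of genes by log-scale variance) is deconvolved by rank-3
Frobenius NMF, with PCA of the coefficient matrix for visualization.

**Immune contexture.** The top-variable genes (median absolute deviation)
are median-centered and clustered (Ward/ward.D2, Euclidean, k = 20); the
cluster containing CD8A is the immune classifier. Samples are then
partitioned by k-means consensus clustering (100 runs on 80% subsamples,
k = 2) of the classifier genes; the cluster with higher classifier-gene
expression is "T-cell inflamed", the other "T-cell depleted". Association
with cohort membership uses an exact two-sided Fisher test (hypergeometric
enumeration); single-gene contrasts use the two-sided Mann–Whitney test.

**IHC.** H = 1·(%1+) + 2·(%2+) + 3·(%3+) ∈ [0, 300] per sample/protein,
with Welch's t-test for group comparisons.

## Worked example

Generate a self-contained synthetic study and run every stage:

```sh
uromics demo --seed 42 --out demo
uromics run demo/config.yaml
```

The run completes in a few seconds and writes per-stage TSV/JSON outputs
plus a `manifest.json` of parameters and checksums. On this bundle,
`demo/outputs/msi.json` reports

```json
{"classification": "MSS", "n_evaluated": 200, "n_unstable": 0, "score": 0.0}
```

(no microsatellite site deviates between tumor and normal — the cohort is
microsatellite-stable, score below the 3.5 MSI-high cut-off), and
`demo/outputs/immune_association.json` reports a Fisher p ≈ 9.4 × 10⁻⁴ for
the contexture × cohort table — the planted design places 28/32 UTUC
samples (87.5%) in the depleted state against 71/128 UCB samples.

The `examples/` directory holds one narrative script per capability; e.g.

```sh
python examples/02_mutational_signatures.py
```

prints

```
chosen rank: 2
  S1 -> APOBEC_CT (cosine 1.000)
  S2 -> CPG_CT (cosine 0.999)
  exposure correlation with true APOBEC_CT: 1.000
  exposure correlation with true CPG_CT: 1.000
```

meaning the rank chosen from the data matches the two planted signatures,
and both the 96-channel profiles and the per-sample exposures are
quantitatively recovered.

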