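"""Immune contexture discovery: a CD8A-anchored classifier gene set,
consensus clustering of samples into T-cell inflamed vs depleted states,
and association tests.

The classifier is discovered by taking the most variable genes (median
absolute deviation), median-centering them, clustering the genes with Ward
(ward.D2) linkage on Euclidean distance, cutting at k clusters, and keeping
the cluster containing the anchor gene.  Samples are then partitioned by
k-means consensus clustering over random subsamples; the cluster with the
higher mean classifier-gene expression is the T-cell inflamed state.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform
from sklearn.cluster import KMeans


@dataclass
class ContextureLabeling:
    classifier_genes: list[str]
    labels: dict[str, str]  # sample -> "inflamed" | "depleted"
    consensus_matrix: pd.DataFrame
    anchor_gene: str


@dataclass(frozen=True)
class AssociationResult:
    table: tuple[tuple[int, int], tuple[int, int]]
    odds_ratio: float
    p_value: float


def select_variable_genes(matrix, n: int = 5000) -> list[str]:
    """Top-n genes by median absolute deviation across all samples.

    Ties at the selection boundary break by gene-symbol lexicographic order.
    """
    if n > len(matrix.genes):
        raise ValueError(f"n={n} exceeds gene count {len(matrix.genes)}")
    mad = stats.median_abs_deviation(matrix.values.to_numpy(dtype=float), axis=1)
    ranked = sorted(zip(matrix.genes, mad), key=lambda t: (-t[1], t[0]))
    return [g for g, _ in ranked[:n]]


def discover_classifier(
    matrix, anchor_gene: str = "CD8A", n_variable: int = 5000, k: int = 20
) -> list[str]:
    """Return the gene cluster containing the anchor gene.

    The top ``n_variable`` MAD-ranked genes are median-centered per gene and
    clustered (genes as items) by Euclidean distance with Ward (ward.D2)
    linkage; the tree is cut into ``k`` clusters and the anchor's cluster is
    returned, sorted with the anchor first.  Agglomeration follows scipy's
    deterministic nearest-neighbor chain, so the result has no randomness.
    """
    n_variable = min(n_variable, len(matrix.genes))
    genes = select_variable_genes(matrix, n_variable)
    if anchor_gene not in genes:
        raise ValueError(
            f"anchor gene {anchor_gene!r} is not among the top {n_variable} variable "
            "genes; increase n_variable"
        )
    X = matrix.values.loc[genes].to_numpy(dtype=float)
    X = X - np.median(X, axis=1, keepdims=True)
    if k == 1:
        cluster_genes = list(genes)
    else:
        Z = hierarchy.linkage(pdist(X, metric="euclidean"), method="ward")
        assignments = hierarchy.fcluster(Z, t=k, criterion="maxclust")
        anchor_cluster = assignments[genes.index(anchor_gene)]
        cluster_genes = [g for g, a in zip(genes, assignments) if a == anchor_cluster]
    cluster_genes.sort()
    cluster_genes.remove(anchor_gene)
    return [anchor_gene] + cluster_genes


def consensus_cluster_samples(
    matrix,
    classifier_genes: Sequence[str],
    k: int = 2,
    n_runs: int = 100,
    subsample: float = 0.8,
    seed: int = 0,
    anchor_gene: str = "CD8A",
) -> ContextureLabeling:
    """Bipartition samples by k-means consensus clustering on classifier genes.

    ``n_runs`` k-means runs (k = 2) on random ``subsample`` fractions of the
    samples, on the per-gene z-scored, gene-restricted matrix.  The
    consensus matrix holds the co-assignment frequency over runs containing
    both samples; the final bipartition is average-linkage clustering of
    1 - consensus cut at 2 clusters.  The cluster with the higher mean
    classifier-gene expression is labeled "inflamed".
    """
    if k != 2:
        raise ValueError("this procedure is defined for the two-state contexture (k=2)")
    genes = [g for g in classifier_genes if g in matrix.values.index]
    if len(genes) < 2:
        raise ValueError("need >= 2 classifier genes present in the matrix")
    samples = matrix.samples
    n = len(samples)
    if n < 4:
        raise ValueError(f"need >= 4 samples, found {n}")

    X = matrix.values.loc[genes].to_numpy(dtype=float)
    mean = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, ddof=0, keepdims=True)
    sd[sd == 0] = 1.0
    Xz = ((X - mean) / sd).T  # samples x genes

    rng = np.random.default_rng(seed)
    n_sub = max(2, int(round(subsample * n)))
    together = np.zeros((n, n))
    both = np.zeros((n, n))
    for _ in range(n_runs):
        idx = rng.choice(n, size=n_sub, replace=False)
        km = KMeans(n_clusters=2, n_init=1, random_state=int(rng.integers(2**31)))
        assign = km.fit_predict(Xz[idx])
        same = assign[:, None] == assign[None, :]
        both[np.ix_(idx, idx)] += 1
        together[np.ix_(idx, idx)] += same
    with np.errstate(invalid="ignore"):
        consensus = np.where(both > 0, together / np.maximum(both, 1), 0.0)
    np.fill_diagonal(consensus, 1.0)
    consensus = (consensus + consensus.T) / 2.0

    dist = np.clip(1.0 - consensus, 0.0, None)
    np.fill_diagonal(dist, 0.0)
    Z = hierarchy.linkage(squareform(dist, checks=False), method="average")
    parts = hierarchy.fcluster(Z, t=2, criterion="maxclust")

    mean_expr = {c: Xz[parts == c].mean() for c in np.unique(parts)}
    inflamed_cluster = max(mean_expr, key=lambda c: mean_expr[c])
    labels = {
        s: ("inflamed" if parts[i] == inflamed_cluster else "depleted")
        for i, s in enumerate(samples)
    }
    return ContextureLabeling(
        classifier_genes=list(genes),
        labels=labels,
        consensus_matrix=pd.DataFrame(consensus, index=samples, columns=samples),
        anchor_gene=anchor_gene,
    )


def fisher_exact_2x2(table: Sequence[Sequence[int]]) -> tuple[float, float]:
    """Two-sided Fisher exact test by hypergeometric enumeration.

    Returns (odds_ratio, p).  The p-value sums the point probabilities of
    every table with the observed margins whose probability does not exceed
    the observed table's (with a small relative tolerance for float ties).
    The odds ratio is the sample ad/bc, with a 0.5 continuity correction
    applied to every cell when any cell is zero.
    """
    (a, b), (c, d) = table
    if min(a, b, c, d) < 0:
        raise ValueError("negative cell count")
    row1, col1, total = a + b, a + c, a + b + c + d
    if row1 == 0 or row1 == total or col1 == 0 or col1 == total:
        raise ValueError("degenerate margins: a row or column is empty")

    def pmf(x: int) -> float:
        return comb(col1, x) * comb(total - col1, row1 - x) / comb(total, row1)

    lo = max(0, row1 + col1 - total)
    hi = min(row1, col1)
    p_obs = pmf(a)
    p = sum(px for x in range(lo, hi + 1) if (px := pmf(x)) <= p_obs * (1 + 1e-7))

    if min(a, b, c, d) == 0:
        a_, b_, c_, d_ = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    else:
        a_, b_, c_, d_ = a, b, c, d
    return (a_ * d_) / (b_ * c_), min(p, 1.0)


def fisher_association(
    labels: Mapping[str, str], group: Mapping[str, str]
) -> AssociationResult:
    """Test association between contexture labels and cohort membership.

    Builds the 2x2 table (rows: cohorts in sorted order; columns: depleted,
    inflamed) over samples present in both mappings and applies the exact
    two-sided Fisher test.
    """
    samples = [s for s in labels if s in group]
    cohorts = sorted({group[s] for s in samples})
    states = sorted({labels[s] for s in samples})
    if len(cohorts) != 2 or len(states) != 2:
        raise ValueError(
            f"need exactly two cohorts and two labels, got {cohorts} / {states}"
        )
    table = tuple(
        tuple(
            sum(1 for s in samples if group[s] == g and labels[s] == st)
            for st in states
        )
        for g in cohorts
    )
    odds, p = fisher_exact_2x2(table)
    return AssociationResult(table=table, odds_ratio=odds, p_value=p)


def compare_gene_by_label(
    matrix, gene: str, labels: Mapping[str, str]
) -> pd.DataFrame:
    """Two-group summary + two-sided Mann-Whitney p for one gene.

    Exact enumeration when the combined n <= 25 (and there are no ties);
    tie-corrected normal approximation otherwise.  Returns a one-row frame
    with per-label mean/median and the p-value.
    """
    if gene not in matrix.values.index:
        raise ValueError(f"gene {gene!r} not in matrix")
    states = sorted(set(labels.values()))
    if len(states) != 2:
        raise ValueError(f"need exactly two labels, got {states}")
    x = matrix.values.loc[gene]
    g1 = x[[s for s in matrix.samples if labels.get(s) == states[0]]].to_numpy(float)
    g2 = x[[s for s in matrix.samples if labels.get(s) == states[1]]].to_numpy(float)
    if len(g1) == 0 or len(g2) == 0:
        raise ValueError("both labels must be populated")
    method = "exact" if len(g1) + len(g2) <= 25 else "asymptotic"
    res = stats.mannwhitneyu(g1, g2, alternative="two-sided", method=method)
    return pd.DataFrame(
        {
            "label": states,
            "n": [len(g1), len(g2)],
            "mean": [g1.mean(), g2.mean()],
            "median": [float(np.median(g1)), float(np.median(g2))],
            "mannwhitney_p": [float(res.pvalue)] * 2,
        }
    ).set_index("label")
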