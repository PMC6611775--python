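"""Molecular subtype label transfer and three-component NMF deconvolution.

Label transfer clusters reference + query samples jointly on a signature
gene set (per-gene z-scored, 1 - Pearson distance, average linkage) and
assigns each query the subtype of the reference sample at minimum
cophenetic distance — the dendrogram height at which the two samples first
join.  NMF deconvolution factorises the FPKM matrix (top quartile of genes
by log-scale variance) at rank 3 and projects the coefficient matrix onto
two principal components for visualization.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from sklearn.decomposition import PCA


@dataclass(frozen=True)
class SubtypeAssignment:
    sample: str
    scheme: str
    label: str
    nearest_reference: str
    cophenetic_distance: float


@dataclass
class ComponentModel:
    """Rank-3 NMF of an expression matrix plus 2-D PCA of the coefficients."""

    basis: pd.DataFrame  # genes x rank
    coefficients: pd.DataFrame  # rank x samples
    component_assignment: dict[str, int]
    pca_coordinates: pd.DataFrame  # samples x 2
    reconstruction_error: float
    error_history: np.ndarray


def _zscore_rows(X: np.ndarray) -> np.ndarray:
    mean = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, ddof=0, keepdims=True)
    sd[sd == 0] = 1.0
    return (X - mean) / sd


def transfer_labels(
    matrix,  # ExpressionMatrix, normalized-log
    signature_genes: Sequence[str],
    reference_labels: Mapping[str, str],
    scheme: str = "custom",
) -> list[SubtypeAssignment]:
    """Assign subtypes to query samples by cophenetic nearest reference.

    The matrix is restricted to the signature genes (intersection with the
    matrix's gene universe), z-scored per gene, and all samples — labeled
    references and unlabeled queries together — are clustered with average
    linkage on 1 - Pearson correlation.  Each query inherits the label of
    the reference at minimum cophenetic distance; ties break by smaller raw
    correlation distance, then by reference order.
    """
    refs = [s for s in matrix.samples if s in reference_labels]
    queries = [s for s in matrix.samples if s not in reference_labels]
    if len(refs) < 2:
        raise ValueError(f"need >= 2 labeled reference samples, found {len(refs)}")
    genes = [g for g in signature_genes if g in matrix.values.index]
    if not genes:
        raise ValueError("signature genes do not intersect the expression matrix")

    X = _zscore_rows(matrix.values.loc[genes].to_numpy(dtype=float))
    samples = matrix.samples
    corr = np.corrcoef(X.T)
    corr = np.nan_to_num(corr, nan=0.0)
    dist = np.clip(1.0 - corr, 0.0, None)
    np.fill_diagonal(dist, 0.0)
    Z = hierarchy.linkage(squareform(dist, checks=False), method="average")
    coph = squareform(hierarchy.cophenet(Z))

    idx = {s: i for i, s in enumerate(samples)}
    ref_order = {s: i for i, s in enumerate(refs)}
    out = []
    for q in queries:
        qi = idx[q]
        best = min(
            refs,
            key=lambda r: (coph[qi, idx[r]], dist[qi, idx[r]], ref_order[r]),
        )
        out.append(
            SubtypeAssignment(
                sample=q,
                scheme=scheme,
                label=reference_labels[best],
                nearest_reference=best,
                cophenetic_distance=float(coph[qi, idx[best]]),
            )
        )
    return out


def _nmf_frobenius(
    V: np.ndarray, k: int, n_iter: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Multiplicative-update NMF under the Frobenius objective."""
    m, n = V.shape
    scale = np.sqrt(V.mean() / k) if V.mean() > 0 else 1.0
    W = rng.uniform(0.5, 1.5, size=(m, k)) * scale
    H = rng.uniform(0.5, 1.5, size=(k, n)) * scale
    eps = 1e-12
    errors = [float(np.linalg.norm(V - W @ H))]
    for _ in range(n_iter):
        H *= (W.T @ V) / np.maximum(W.T @ W @ H, eps)
        W *= (V @ H.T) / np.maximum(W @ H @ H.T, eps)
        errors.append(float(np.linalg.norm(V - W @ H)))
    return W, H, np.asarray(errors)


def nmf_components(
    matrix,  # ExpressionMatrix in FPKM/RPKM units
    variability_fraction: float = 0.25,
    rank: int = 3,
    n_init: int = 30,
    n_iter: int = 100,
    seed: int = 0,
) -> ComponentModel:
    """Deconvolve an FPKM matrix into ``rank`` expression components.

    Genes are ranked by variance of log2(x+1) and the top
    ``variability_fraction`` retained; the best of ``n_init`` random NMF
    initialisations (Frobenius error after ``n_iter`` multiplicative
    updates) is kept.  Component assignment is the argmax of the
    column-normalized coefficients; PCA of the transposed coefficient
    matrix supplies 2-D visualization coordinates.
    """
    if rank > len(matrix.samples):
        raise ValueError(f"rank {rank} exceeds sample count {len(matrix.samples)}")
    values = matrix.values.to_numpy(dtype=float)
    variances = np.log2(values + 1.0).var(axis=1, ddof=0)
    n_keep = max(rank, int(round(len(variances) * variability_fraction)))
    order = np.argsort(-variances, kind="stable")[:n_keep]
    genes = [matrix.genes[i] for i in sorted(order)]
    V = matrix.values.loc[genes].to_numpy(dtype=float)

    rng = np.random.default_rng(seed)
    best: tuple[np.ndarray, np.ndarray, np.ndarray] | None = None
    for _ in range(n_init):
        W, H, errors = _nmf_frobenius(V, rank, n_iter, rng)
        if best is None or errors[-1] < best[2][-1]:
            best = (W, H, errors)
    W, H, errors = best

    comp_names = [f"C{i + 1}" for i in range(rank)]
    col_sums = H.sum(axis=0)
    col_sums[col_sums == 0] = 1.0
    assignment = {
        s: int(np.argmax(H[:, j] / col_sums[j])) for j, s in enumerate(matrix.samples)
    }
    pca = PCA(n_components=2, random_state=0)
    coords = pca.fit_transform(H.T)
    return ComponentModel(
        basis=pd.DataFrame(W, index=genes, columns=comp_names),
        coefficients=pd.DataFrame(H, index=comp_names, columns=matrix.samples),
        component_assignment=assignment,
        pca_coordinates=pd.DataFrame(
            coords, index=matrix.samples, columns=["PC1", "PC2"]
        ),
        reconstruction_error=float(errors[-1]),
        error_history=errors,
    )


def annotate_components(
    model: ComponentModel, marker_sets: Mapping[str, Sequence[str]], top_n: int = 25
) -> pd.DataFrame:
    """Score each component's top-loading genes against named marker lists.

    Component naming (luminal/CIS-low, basal/squamous, ECM/EMT) is post hoc
    annotation: for every component, counts how many of each marker set's
    genes fall in its ``top_n`` highest-loading basis genes.
    """
    rows = []
    for comp in model.basis.columns:
        top = set(model.basis[comp].nlargest(top_n).index)
        row = {"component": comp}
        for name, markers in marker_sets.items():
            row[name] = len(top & set(markers))
        rows.append(row)
    return pd.DataFrame(rows).set_index("component")
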