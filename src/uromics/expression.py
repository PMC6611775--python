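"""Multi-cohort expression harmonization, QC, differential expression, and
outlier detection.

Cohort FPKM/RPKM matrices are combined on their shared gene universe and
quantile normalized (every sample is forced onto the across-sample mean
quantile vector), then log2(x+1)-transformed.  Housekeeping-gene QC checks
that harmonization removed cohort-level location shifts.  The differential-
expression stage is a Welch t-test on the normalized-log scale with
Benjamini-Hochberg adjustment and the |log2FC| > 1, adjusted p <= 0.05
significance convention.  Outlier calls flag (gene, sample) pairs with
z-score > 1 and abundance > 50 FPKM.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass
class ExpressionMatrix:
    """Gene x sample abundance matrix with per-sample cohort labels.

    ``values`` rows are gene symbols (unique), columns are samples; every
    sample must have a cohort label.  ``unit`` is FPKM, RPKM, or
    normalized-log (the only unit allowed to carry the result of a log
    transform; raw units must be non-negative).
    """

    values: pd.DataFrame
    unit: str = "FPKM"
    cohort: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            dupes = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene symbols: {dupes[:5]}")
        if self.unit not in ("FPKM", "RPKM", "normalized-log"):
            raise ValueError(f"unknown unit {self.unit!r}")
        if self.unit != "normalized-log" and (self.values.to_numpy() < 0).any():
            raise ValueError("raw abundance values must be non-negative")
        missing = [s for s in self.values.columns if s not in self.cohort]
        if missing:
            raise ValueError(f"samples without a cohort label: {missing[:5]}")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)


@dataclass(frozen=True)
class DifferentialExpressionRecord:
    gene: str
    log2_fold_change: float
    p_value: float
    adjusted_p: float
    significant: bool


@dataclass(frozen=True)
class OutlierCall:
    gene: str
    sample: str
    z_score: float
    abundance: float
    is_outlier: bool


def quantile_normalize(matrices: Sequence[ExpressionMatrix]) -> ExpressionMatrix:
    """Combine cohort matrices and force a common value distribution.

    Genes are restricted to the intersection across inputs.  Each sample's
    values are replaced by the across-sample mean quantile vector at its own
    ranks; tied values receive the mean of the tied quantiles, so every
    column's sorted values are identical afterwards and within-sample rank
    order is preserved.
    """
    if not matrices:
        raise ValueError("no matrices supplied")
    shared = matrices[0].values.index
    for m in matrices[1:]:
        shared = shared.intersection(m.values.index)
    if len(shared) == 0:
        raise ValueError("empty gene intersection across cohorts")
    shared = sorted(shared)
    combined = pd.concat([m.values.loc[shared] for m in matrices], axis=1)
    cohort: dict[str, str] = {}
    for m in matrices:
        cohort.update(m.cohort)

    X = combined.to_numpy(dtype=float)
    n_genes = X.shape[0]
    reference = np.sort(X, axis=0).mean(axis=1)  # mean quantile vector
    out = np.empty_like(X)
    for j in range(X.shape[1]):
        ranks = stats.rankdata(X[:, j], method="average") - 1  # 0-based, ties averaged
        lo = np.floor(ranks).astype(int)
        hi = np.ceil(ranks).astype(int)
        out[:, j] = (reference[lo] + reference[hi]) / 2.0
    frame = pd.DataFrame(out, index=shared, columns=combined.columns)
    unit = matrices[0].unit
    return ExpressionMatrix(values=frame, unit=unit, cohort=cohort)


def log_transform(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """log2(x + 1); the unit becomes normalized-log."""
    if (matrix.values.to_numpy() < 0).any():
        raise ValueError("cannot log-transform negative values")
    return replace(matrix, values=np.log2(matrix.values + 1.0), unit="normalized-log")


def housekeeping_qc(
    matrix: ExpressionMatrix, housekeeping_genes: Sequence[str]
) -> pd.DataFrame:
    """Per-housekeeping-gene batch-effect check across cohorts.

    For each housekeeping gene found in the matrix: z-scores across all
    samples, per-cohort mean and SD of those z-scores, a Kruskal-Wallis
    p-value comparing cohorts, and a Benjamini-Hochberg adjusted p with a
    flag at adjusted p < 0.05.  Genes flagged after successful harmonization
    indicate residual cohort effects.
    """
    present = [g for g in housekeeping_genes if g in matrix.values.index]
    if not present:
        raise ValueError(
            f"no housekeeping genes found in matrix; missing: {list(housekeeping_genes)}"
        )
    cohorts = pd.Series(matrix.cohort)[matrix.samples]
    groups = sorted(cohorts.unique())
    rows = []
    for gene in present:
        x = matrix.values.loc[gene].to_numpy(dtype=float)
        sd = x.std(ddof=0)
        z = (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)
        row: dict[str, object] = {"gene": gene}
        samples_z = pd.Series(z, index=matrix.samples)
        per_group = [samples_z[cohorts == g].to_numpy() for g in groups]
        for g, vals in zip(groups, per_group):
            row[f"mean_{g}"] = float(vals.mean())
            row[f"sd_{g}"] = float(vals.std(ddof=0))
        if all(np.ptp(v) == 0 for v in per_group) and len({v.mean() for v in per_group}) == 1:
            row["p_value"] = 1.0
        else:
            row["p_value"] = float(stats.kruskal(*per_group).pvalue)
        rows.append(row)
    table = pd.DataFrame(rows).set_index("gene")
    table["adjusted_p"] = multipletests(table["p_value"], method="fdr_bh")[1]
    table["flagged"] = table["adjusted_p"] < 0.05
    return table


def differential_expression(
    matrix: ExpressionMatrix,
    group_a: Sequence[str],
    group_b: Sequence[str],
    logfc_threshold: float = 1.0,
    alpha: float = 0.05,
) -> list[DifferentialExpressionRecord]:
    """Per-gene Welch t-test between two sample groups on the log scale.

    log2 fold change is mean(A) - mean(B) of normalized-log values; p-values
    are Benjamini-Hochberg adjusted; a gene is significant iff
    |log2FC| > ``logfc_threshold`` and adjusted p <= ``alpha``.
    """
    set_a, set_b = set(group_a), set(group_b)
    if set_a & set_b:
        raise ValueError(f"groups overlap: {sorted(set_a & set_b)[:5]}")
    if len(set_a) < 2 or len(set_b) < 2:
        raise ValueError("each group needs at least 2 samples")
    if matrix.unit != "normalized-log":
        raise ValueError("differential expression expects a normalized-log matrix")
    A = matrix.values[list(group_a)].to_numpy(dtype=float)
    B = matrix.values[list(group_b)].to_numpy(dtype=float)
    logfc = A.mean(axis=1) - B.mean(axis=1)
    t = stats.ttest_ind(A, B, axis=1, equal_var=False)
    p = np.where(np.isnan(t.pvalue), 1.0, t.pvalue)  # zero-variance identical groups
    adj = multipletests(p, method="fdr_bh")[1]
    records = []
    for i, gene in enumerate(matrix.genes):
        records.append(
            DifferentialExpressionRecord(
                gene=gene,
                log2_fold_change=float(logfc[i]),
                p_value=float(p[i]),
                adjusted_p=float(adj[i]),
                significant=bool(abs(logfc[i]) > logfc_threshold and adj[i] <= alpha),
            )
        )
    return records


def detect_outliers(
    matrix: ExpressionMatrix,
    gene_panel: Sequence[str],
    z_threshold: float = 1.0,
    abundance_threshold: float = 50.0,
    log_scale: bool = False,
) -> tuple[list[OutlierCall], pd.DataFrame]:
    """Flag high-expression outliers on a gene panel.

    Per (gene, sample): z = (x - gene mean) / gene SD across the cohort,
    computed on raw FPKM by default (``log_scale=True`` standardises
    log2(x+1) instead, while the abundance gate stays on the raw scale).
    A call is an outlier iff z > ``z_threshold`` and raw abundance >
    ``abundance_threshold``.  Also returns per-sample Tukey fence bounds
    (Q1 - 1.5 IQR, Q3 + 1.5 IQR) over the panel as a secondary annotation.
    Genes with zero spread never produce outliers.
    """
    if matrix.unit not in ("FPKM", "RPKM"):
        raise ValueError("outlier detection expects a raw FPKM/RPKM matrix")
    present = [g for g in gene_panel if g in matrix.values.index]
    missing = [g for g in gene_panel if g not in matrix.values.index]
    if not present:
        raise ValueError(f"no panel genes found in matrix; missing: {missing}")
    if missing:
        warnings.warn(f"panel genes absent from matrix: {missing}", stacklevel=2)
    raw = matrix.values.loc[present].to_numpy(dtype=float)
    scored = np.log2(raw + 1.0) if log_scale else raw
    mean = scored.mean(axis=1, keepdims=True)
    sd = scored.std(axis=1, ddof=0, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(sd > 0, (scored - mean) / sd, np.nan)
    calls = []
    for i, gene in enumerate(present):
        for j, sample in enumerate(matrix.samples):
            zij = z[i, j]
            calls.append(
                OutlierCall(
                    gene=gene,
                    sample=sample,
                    z_score=float(zij) if np.isfinite(zij) else float("nan"),
                    abundance=float(raw[i, j]),
                    is_outlier=bool(
                        np.isfinite(zij)
                        and zij > z_threshold
                        and raw[i, j] > abundance_threshold
                    ),
                )
            )
    q1 = np.percentile(raw, 25, axis=0)
    q3 = np.percentile(raw, 75, axis=0)
    iqr = q3 - q1
    bounds = pd.DataFrame(
        {"lower": q1 - 1.5 * iqr, "upper": q3 + 1.5 * iqr}, index=matrix.samples
    )
    return calls, bounds
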