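"""Harmonize two simulated cohorts (quantile normalization + log transform),
check housekeeping genes for residual batch effects, run the differential-
expression stage, and call FPKM outliers.

Prints the housekeeping QC summary, the top differential genes, and outlier
calls on the luminal marker panel.
"""

from uromics import (
    ExpressionMatrix,
    SimulationConfig,
    detect_outliers,
    differential_expression,
    gen_expression_cohort,
    housekeeping_qc,
    log_transform,
    quantile_normalize,
)
from uromics.simulate import HOUSEKEEPING_GENES, LUMINAL_MARKERS

config = SimulationConfig(seed=7)
matrix, truth = gen_expression_cohort(config)

# split by cohort, then harmonize (exercising the batch distortion removal)
parts = []
for group in config.n_samples_per_group:
    cols = [s for s in matrix.samples if matrix.cohort[s] == group]
    parts.append(ExpressionMatrix(values=matrix.values[cols], unit="FPKM",
                                  cohort={s: group for s in cols}))
combined = quantile_normalize(parts)
normalized = log_transform(combined)

qc = housekeeping_qc(normalized, list(HOUSEKEEPING_GENES))
print(f"housekeeping genes flagged for cohort effects: {int(qc['flagged'].sum())}/{len(qc)}")

utuc = [s for s in normalized.samples if normalized.cohort[s] == "UTUC"]
ucb = [s for s in normalized.samples if normalized.cohort[s] == "UCB"]
records = differential_expression(normalized, utuc, ucb)
significant = [r for r in records if r.significant]
print(f"significant genes (|log2FC| > 1, BH p <= 0.05): {len(significant)}")
for r in sorted(significant, key=lambda r: r.adjusted_p)[:5]:
    print(f"  {r.gene:>8}: log2FC {r.log2_fold_change:+.2f}, adj p {r.adjusted_p:.2e}")

utuc_matrix = ExpressionMatrix(values=combined.values[utuc], unit="FPKM",
                               cohort={s: "UTUC" for s in utuc})
calls, _ = detect_outliers(utuc_matrix, list(LUMINAL_MARKERS))
outliers = [c for c in calls if c.is_outlier]
print(f"\noutlier calls on the luminal panel (z > 1 and FPKM > 50): {len(outliers)}")
for c in outliers[:5]:
    print(f"  {c.gene} in {c.sample}: z {c.z_score:.2f}, {c.abundance:.0f} FPKM")
print("(after quantile normalization every sample shares one value")
print(" distribution, so housekeeping genes should show no cohort shift)")
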