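"""Immunohistochemistry H-scores from per-intensity cell percentages.

The H-score weights the percentage of tumor cells staining at each
intensity level: H = 1*(% at 1+) + 2*(% at 2+) + 3*(% at 3+), ranging from
0 (all cells negative) to 300 (all cells at 3+).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class HScoreRecord:
    sample: str
    protein: str
    pct_0: float
    pct_1: float
    pct_2: float
    pct_3: float
    h_score: float


def compute_hscore(
    pcts: Sequence[float], sample: str = "", protein: str = ""
) -> HScoreRecord:
    """H-score from the four intensity percentages (0, 1+, 2+, 3+).

    Percentages must be non-negative and sum to 100 (within 1e-6).
    """
    if len(pcts) != 4:
        raise ValueError(f"need 4 intensity percentages, got {len(pcts)}")
    p0, p1, p2, p3 = (float(p) for p in pcts)
    if min(p0, p1, p2, p3) < 0:
        raise ValueError(f"negative percentage in {pcts}")
    total = p0 + p1 + p2 + p3
    if abs(total - 100.0) > 1e-6:
        raise ValueError(f"intensity percentages must sum to 100, got {total}")
    return HScoreRecord(
        sample=sample,
        protein=protein,
        pct_0=p0,
        pct_1=p1,
        pct_2=p2,
        pct_3=p3,
        h_score=1.0 * p1 + 2.0 * p2 + 3.0 * p3,
    )


def compare_hscores(
    group_a: Sequence[HScoreRecord],
    group_b: Sequence[HScoreRecord],
    equal_var: bool = False,
) -> dict[str, float]:
    """Group means/SDs and a two-sided t-test p-value for one protein.

    Welch's (unequal-variance) t-test by default; ``equal_var=True`` gives
    the pooled-variance variant.  Both groups must contain records for the
    same single protein.
    """
    proteins = {r.protein for r in group_a} | {r.protein for r in group_b}
    if len(proteins) > 1:
        raise ValueError(f"mixed proteins in one comparison: {sorted(proteins)}")
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("each group needs >= 2 records")
    a = np.array([r.h_score for r in group_a], dtype=float)
    b = np.array([r.h_score for r in group_b], dtype=float)
    t = stats.ttest_ind(a, b, equal_var=equal_var)
    p = 1.0 if np.isnan(t.pvalue) else float(t.pvalue)
    return {
        "mean_a": float(a.mean()),
        "sd_a": float(a.std(ddof=1)),
        "mean_b": float(b.mean()),
        "sd_b": float(b.std(ddof=1)),
        "t_statistic": 0.0 if np.isnan(t.statistic) else float(t.statistic),
        "p_value": p,
    }
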