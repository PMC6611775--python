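"""Microsatellite instability scoring from paired tumor-normal repeat-length
histograms.

Each microsatellite site carries a tumor and a normal read-length histogram.
A site with adequate coverage is tested for somatic instability with a
chi-square homogeneity test (low-expectation length bins pooled); the
cohort-level MSI score is the percentage of evaluated sites called unstable,
classified MSI-high above the 3.5 cut-off.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats


@dataclass
class MicrosatelliteSite:
    site_id: str
    tumor_hist: dict[int, int]
    normal_hist: dict[int, int]
    evaluated: bool = False
    unstable: bool = False
    p_value: float | None = None

    def __post_init__(self) -> None:
        for hist in (self.tumor_hist, self.normal_hist):
            if any(c < 0 for c in hist.values()):
                raise ValueError(f"negative read count in site {self.site_id}")


@dataclass(frozen=True)
class MsiResult:
    """MSI score = 100 * unstable / evaluated sites; MSI-H iff score > 3.5."""

    n_unstable: int
    n_evaluated: int
    score: float
    classification: str


MSI_H_CUTOFF = 3.5


def _pooled_table(tumor: Mapping[int, int], normal: Mapping[int, int]) -> np.ndarray:
    """2 x L contingency table over repeat lengths, adjacent bins merged until
    every expected count is >= 5 (or only two bins remain)."""
    lengths = sorted(set(tumor) | set(normal))
    table = np.array(
        [[tumor.get(l, 0) for l in lengths], [normal.get(l, 0) for l in lengths]],
        dtype=float,
    )
    # drop empty columns
    table = table[:, table.sum(axis=0) > 0]
    while table.shape[1] > 2:
        expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / table.sum()
        bad = np.where(expected.min(axis=0) < 5)[0]
        if bad.size == 0:
            break
        j = int(bad[0])
        # merge into the smaller neighbour for determinism
        if j == 0:
            k = 1
        elif j == table.shape[1] - 1:
            k = j - 1
        else:
            k = j - 1 if table[:, j - 1].sum() <= table[:, j + 1].sum() else j + 1
        table[:, k] += table[:, j]
        table = np.delete(table, j, axis=1)
    return table


def test_site(
    site: MicrosatelliteSite, min_depth: int = 20, alpha: float = 0.05
) -> MicrosatelliteSite:
    """Chi-square homogeneity test of tumor vs normal length distributions.

    The site is evaluated only if both histograms total at least
    ``min_depth`` reads; it is called unstable when the test rejects at
    ``alpha``.  Degenerate tables (a single length bin, or an empty margin)
    yield p = 1 and a stable call.
    """
    if not site.tumor_hist or not site.normal_hist:
        raise ValueError(f"site {site.site_id} has an empty histogram")
    t_total = sum(site.tumor_hist.values())
    n_total = sum(site.normal_hist.values())
    if t_total < min_depth or n_total < min_depth:
        site.evaluated = False
        site.unstable = False
        site.p_value = None
        return site
    site.evaluated = True
    table = _pooled_table(site.tumor_hist, site.normal_hist)
    if table.shape[1] < 2 or (table.sum(axis=1) == 0).any():
        site.p_value = 1.0
        site.unstable = False
        return site
    _, p, _, _ = stats.chi2_contingency(table, correction=False)
    site.p_value = float(p)
    site.unstable = bool(site.p_value < alpha)
    return site


def msi_score(
    sites: Sequence[MicrosatelliteSite], denominator: str = "evaluated"
) -> MsiResult:
    """Score a sample from its tested sites.

    By default the denominator is every evaluated site (stable + unstable),
    matching how the scoring tool the cut-off was calibrated for defines its
    score; ``denominator="stable"`` divides by the stable sites only, for the
    alternative reading of the score.  A boundary score of exactly 3.5 is
    classified MSS (the threshold is a strict inequality for MSI-H).
    """
    if denominator not in ("evaluated", "stable"):
        raise ValueError(f"denominator must be 'evaluated' or 'stable', got {denominator!r}")
    evaluated = [s for s in sites if s.evaluated]
    if not evaluated:
        raise ValueError("no evaluated sites; cannot compute an MSI score")
    n_unstable = sum(s.unstable for s in evaluated)
    denom = len(evaluated) if denominator == "evaluated" else len(evaluated) - n_unstable
    if denom == 0:
        raise ValueError("zero stable sites; cannot use the 'stable' denominator")
    score = 100.0 * n_unstable / denom
    return MsiResult(
        n_unstable=n_unstable,
        n_evaluated=len(evaluated),
        score=score,
        classification="MSI-H" if score > MSI_H_CUTOFF else "MSS",
    )
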