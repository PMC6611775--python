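"""Consensus somatic variant merging, filtering, and tumor mutational burden.

Multi-caller tumor-normal call sets are merged on the (contig, pos, ref, alt)
key.  Single-nucleotide variants are retained when at least two of the four
SNV callers agree; indels require both indel callers.  The retained set is
then passed through depth/VAF filters, and TMB is the number of surviving
mutations per megabase of coverage space.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

SNV_CALLERS: tuple[str, ...] = ("mutect2", "strelka", "varscan", "somaticsniper")
INDEL_CALLERS: tuple[str, ...] = ("strelka", "varscan")

#: (contig, pos, ref, alt) — the identity of a variant across callers.
VariantKey = tuple[str, int, str, str]


@dataclass
class VariantRecord:
    """One somatic candidate with per-caller provenance and read counts."""

    contig: str
    pos: int  # 1-based
    ref_allele: str
    alt_allele: str
    callers: frozenset[str] = field(default_factory=frozenset)
    tumor_depth: int = 0
    tumor_alt: int = 0
    normal_depth: int = 0
    normal_alt: int = 0
    known_germline: bool = False
    known_somatic_hotspot: bool = False

    def __post_init__(self) -> None:
        if not (0 <= self.tumor_alt <= self.tumor_depth):
            raise ValueError(
                f"tumor_alt={self.tumor_alt} outside [0, tumor_depth={self.tumor_depth}]"
            )
        if not (0 <= self.normal_alt <= self.normal_depth):
            raise ValueError(
                f"normal_alt={self.normal_alt} outside [0, normal_depth={self.normal_depth}]"
            )
        self.callers = frozenset(self.callers)

    @property
    def key(self) -> VariantKey:
        return (self.contig, self.pos, self.ref_allele, self.alt_allele)

    @property
    def variant_class(self) -> str:
        """"SNV" iff both alleles are single bases, else "indel"."""
        if len(self.ref_allele) == 1 and len(self.alt_allele) == 1:
            return "SNV"
        return "indel"

    @property
    def tumor_vaf(self) -> float:
        return self.tumor_alt / self.tumor_depth if self.tumor_depth else 0.0

    @property
    def normal_vaf(self) -> float:
        return self.normal_alt / self.normal_depth if self.normal_depth else 0.0


@dataclass(frozen=True)
class TmbResult:
    """Tumor mutational burden: mutations per megabase of coverage space."""

    n_mutations: int
    coverage_bases: int
    tmb: float


def merge_caller_calls(
    call_tables: Mapping[str, Sequence[VariantRecord]],
    snv_callers: Sequence[str] = SNV_CALLERS,
    indel_callers: Sequence[str] = INDEL_CALLERS,
) -> list[VariantRecord]:
    """Merge per-caller call tables into the consensus variant set.

    An SNV is retained iff called by >= 2 SNV callers; an indel iff called by
    every indel caller (both of the two).  Retained records carry the union of
    supporting callers; read counts come from the supporting record with the
    highest tumor depth (ties broken by caller-name order), so downstream VAF
    filters act on one well-defined set of counts.

    Parameters
    ----------
    call_tables
        Mapping caller name -> list of :class:`VariantRecord`.

    Raises
    ------
    ValueError
        If a caller name is not in the configured SNV or indel caller sets.
    """
    known = set(snv_callers) | set(indel_callers)
    for caller in call_tables:
        if caller not in known:
            raise ValueError(f"unknown caller: {caller!r} (known: {sorted(known)})")

    by_key: dict[VariantKey, dict[str, VariantRecord]] = {}
    for caller, table in call_tables.items():
        for rec in table:
            by_key.setdefault(rec.key, {})[caller] = rec

    snv_set = set(snv_callers)
    indel_set = set(indel_callers)
    consensus: list[VariantRecord] = []
    for key in sorted(by_key):
        support = by_key[key]
        any_rec = next(iter(support.values()))
        if any_rec.variant_class == "SNV":
            if len(set(support) & snv_set) < 2:
                continue
        else:
            if not indel_set <= set(support):
                continue
        # counts from the deepest tumor record; deterministic tie-break
        order = sorted(support, key=lambda c: (-support[c].tumor_depth, c))
        best = support[order[0]]
        consensus.append(replace(best, callers=frozenset(support)))
    return consensus


# Filter reason codes, in evaluation order.
REASON_ZERO_DEPTH = "zero-depth"
REASON_DEPTH = "min-depth"
REASON_TUMOR_VAF = "tumor-vaf"
REASON_NORMAL_VAF = "normal-vaf"
REASON_GERMLINE = "germline-db"
REASON_BLACKLIST = "blacklist"


def apply_somatic_filters(
    variants: Iterable[VariantRecord],
    min_depth: int = 10,
    min_tumor_vaf: float = 0.05,
    min_tumor_alt: int = 4,
    max_normal_vaf: float = 0.01,
    max_normal_alt: int = 1,
    blacklist: set[tuple[str, int]] | None = None,
) -> tuple[list[VariantRecord], dict[VariantKey, list[str]]]:
    """Apply the post-consensus somatic filters.

    A record is retained iff all of the following hold:

    * tumor and normal depth both >= ``min_depth`` (10 reads);
    * tumor VAF >= 5% AND more than 3 alt reads (>= 4);
    * normal VAF <= 1% OR at most one alt read in the normal;
    * not a known germline variant, unless it is also a known somatic
      hotspot (the dbSNP-unless-COSMIC rule, via membership flags);
    * position not on the optional artifact blacklist.

    Returns the retained list and, for every rejected record, the list of
    every criterion it failed.  Zero-depth records are rejected with the
    dedicated ``"zero-depth"`` reason rather than raising.
    """
    retained: list[VariantRecord] = []
    reasons: dict[VariantKey, list[str]] = {}
    blacklist = blacklist or set()
    for rec in variants:
        failed: list[str] = []
        if rec.tumor_depth == 0 or rec.normal_depth == 0:
            failed.append(REASON_ZERO_DEPTH)
        if rec.tumor_depth < min_depth or rec.normal_depth < min_depth:
            failed.append(REASON_DEPTH)
        if not (rec.tumor_vaf >= min_tumor_vaf and rec.tumor_alt >= min_tumor_alt):
            failed.append(REASON_TUMOR_VAF)
        if not (rec.normal_vaf <= max_normal_vaf or rec.normal_alt <= max_normal_alt):
            failed.append(REASON_NORMAL_VAF)
        if rec.known_germline and not rec.known_somatic_hotspot:
            failed.append(REASON_GERMLINE)
        if (rec.contig, rec.pos) in blacklist:
            failed.append(REASON_BLACKLIST)
        if failed:
            reasons[rec.key] = failed
        else:
            retained.append(rec)
    return retained, reasons


def compute_tmb(variants: Sequence[VariantRecord], coverage_bases: int) -> TmbResult:
    """Mutations per megabase: ``n / (coverage_bases / 1e6)``."""
    if coverage_bases <= 0:
        raise ValueError(f"coverage_bases must be positive, got {coverage_bases}")
    n = len(variants)
    return TmbResult(n_mutations=n, coverage_bases=coverage_bases, tmb=n / (coverage_bases / 1e6))
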