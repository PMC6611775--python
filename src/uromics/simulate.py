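"""Synthetic data generation with known ground truth for every pipeline stage.

The study's real cohorts are controlled-access; this module emulates their
inputs — a reference contig, mutation catalogs drawn from known signature
mixtures, multi-caller call sets with programmed sensitivity and
false-positive behaviour, expression cohorts with planted subtype centroids
and immune-hot/cold structure, stable and unstable microsatellite sites, and
IHC intensity tables.  Every generator is bit-reproducible for a fixed seed
and returns the ground truth alongside the data; no analysis stage ever
reads the truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .expression import ExpressionMatrix
from .msi import MicrosatelliteSite
from .signatures import CATEGORIES_96, reverse_complement
from .variants import VariantRecord

# Independent, fixed sub-streams per generator so the same config seed can
# drive every stage without coupling their draws.
_STREAM_REFERENCE = 1
_STREAM_MUTATIONS = 2
_STREAM_CALLERS = 3
_STREAM_EXPRESSION = 4
_STREAM_MSI = 5
_STREAM_IHC = 6


class GenerationError(RuntimeError):
    """Raised when a generator cannot satisfy its configuration."""


@dataclass(frozen=True)
class CallerProfile:
    """Programmed behaviour of one variant caller."""

    sensitivity: float
    fp_per_mb: float
    calls_snv: bool = True
    calls_indel: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.sensitivity <= 1.0):
            raise ValueError(f"sensitivity {self.sensitivity} outside [0, 1]")
        if self.fp_per_mb < 0:
            raise ValueError(f"fp_per_mb {self.fp_per_mb} negative")


def default_caller_profiles() -> dict[str, CallerProfile]:
    """Four SNV callers and two indel callers (strelka/varscan call both)."""
    return {
        "mutect2": CallerProfile(0.95, 2.0, calls_snv=True),
        "strelka": CallerProfile(0.95, 2.0, calls_snv=True, calls_indel=True),
        "varscan": CallerProfile(0.90, 3.0, calls_snv=True, calls_indel=True),
        "somaticsniper": CallerProfile(0.85, 4.0, calls_snv=True),
    }


# Marker and utility gene sets planted into the synthetic expression cohorts.
LUMINAL_MARKERS = (
    "FGFR3", "KRT20", "SNX31", "UPK1A", "UPK2", "CRTAC1", "CTSE", "SHH", "PPARG",
)
BASAL_MARKERS = (
    "KRT5", "KRT14", "KRT6A", "DSC3", "GSDMC", "PI3", "TGM1", "CXCL11", "SAA1",
)
ECM_MARKERS = ("C7", "COMP", "DES", "PGM5", "SFRP4", "CLDN3", "TWIST1")

_NAMED_IMMUNE = (
    "CD8A", "CCL2", "CCL3", "CCL4", "CXCL9", "CXCL10", "IFNG", "GZMA", "GZMB",
    "PRF1", "CD3E", "CD3D", "CD2", "LAG3", "IDO1", "TIGIT", "PDCD1", "CTLA4",
    "HAVCR2", "STAT1",
)
#: 170 co-regulated immune genes, CD8A-anchored, planted as one cluster.
IMMUNE_GENES: tuple[str, ...] = _NAMED_IMMUNE + tuple(
    f"IMM{i:03d}" for i in range(1, 151)
)

_NAMED_HOUSEKEEPING = (
    "ACTB", "GAPDH", "B2M", "TBP", "RPL13A", "HPRT1", "PGK1", "PPIA", "GUSB", "SDHA",
)
#: 40 housekeeping genes expected to be cohort-invariant after normalization.
HOUSEKEEPING_GENES: tuple[str, ...] = _NAMED_HOUSEKEEPING + tuple(
    f"HK{i:03d}" for i in range(1, 31)
)


@dataclass
class SimulationConfig:
    """Study-condition parameters for every synthetic generator.

    Defaults mirror the study's design: a 32-sample upper-tract (UTUC)
    cohort against a 128-sample bladder (UCB) cohort, planted immune
    contexture 28 depleted / 4 inflamed vs 71 / 57, subtype composition
    predominantly luminal in UTUC, four SNV callers + two indel callers,
    and a sub-threshold microsatellite-unstable site fraction.
    """

    seed: int = 0
    contig_length: int = 200_000
    gc_fraction: float = 0.41
    signature_mix: dict[str, float] = field(
        default_factory=lambda: {"APOBEC_CT": 0.5, "APOBEC_CG": 0.3, "CPG_CT": 0.2}
    )
    n_mutations_per_sample: int = 200
    n_samples_per_group: dict[str, int] = field(
        default_factory=lambda: {"UTUC": 32, "UCB": 128}
    )
    subtype_centroids: dict[str, pd.Series] | None = None
    immune_hot_shift: float = 2.0
    caller_profiles: dict[str, CallerProfile] = field(
        default_factory=default_caller_profiles
    )
    mean_tumor_depth: float = 80.0
    mean_normal_depth: float = 60.0
    msi_unstable_fraction: float = 0.01
    # expression model
    n_genes: int = 2000
    expr_sigma: float = 0.5
    immune_activity_sd: float = 0.6
    batch_sigma: float = 0.3
    subtype_proportions: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            "UTUC": {"luminal": 0.85, "basal": 0.10, "ecm": 0.05},
            "UCB": {"luminal": 0.46, "basal": 0.34, "ecm": 0.20},
        }
    )
    immune_split: dict[str, tuple[int, int]] = field(
        default_factory=lambda: {"UTUC": (28, 4), "UCB": (71, 57)}
    )  # (n_depleted, n_inflamed) per group
    # read-count model
    vaf_alpha: float = 8.0
    vaf_beta: float = 12.0
    vaf_floor: float = 0.02
    normal_contamination: float = 0.002
    fp_vaf_alpha: float = 2.0
    fp_vaf_beta: float = 30.0
    # microsatellites
    msi_n_sites: int = 200
    msi_shift: int = 3
    msi_shift_mass: float = 0.7

    def __post_init__(self) -> None:
        if self.contig_length < 3:
            raise ValueError(f"contig_length must be >= 3, got {self.contig_length}")
        if not (0.0 <= self.gc_fraction <= 1.0):
            raise ValueError(f"gc_fraction {self.gc_fraction} outside [0, 1]")
        total = sum(self.signature_mix.values())
        if any(w < 0 for w in self.signature_mix.values()) or abs(total - 1.0) > 1e-9:
            raise ValueError(
                f"signature_mix weights must be non-negative and sum to 1, got {total}"
            )
        if self.n_mutations_per_sample < 0:
            raise ValueError("n_mutations_per_sample must be >= 0")
        for g, n in self.n_samples_per_group.items():
            if n < 1:
                raise ValueError(f"group {g!r} must have >= 1 sample, got {n}")
        for name in ("msi_unstable_fraction", "normal_contamination"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")
        if not (0.0 <= self.immune_hot_shift or True):
            pass

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, stream])


def gen_reference(config: SimulationConfig) -> tuple[str, str]:
    """A random contig with the configured GC content.

    Returns ``(name, sequence)``; deterministic for a fixed seed.
    """
    rng = config.rng(_STREAM_REFERENCE)
    gc = config.gc_fraction
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    bases = rng.choice(np.array(list("ACGT")), size=config.contig_length, p=probs)
    return "chrS", "".join(bases)


def _category_parts(label: str) -> tuple[str, str, str]:
    """Split "X[R>A]Y" into (forward triplet XRY, ref, alt)."""
    five, rest = label[0], label[2:]
    ref, alt, three = rest[0], rest[2], rest[4]
    return five + ref + three, ref, alt


def gen_mutations(
    config: SimulationConfig,
    reference: tuple[str, str],
    true_signatures: pd.DataFrame,
    n_samples: int = 1,
    sample_prefix: str = "S",
    per_sample_mix: Sequence[Mapping[str, float]] | None = None,
) -> tuple[dict[str, list[VariantRecord]], pd.DataFrame]:
    """Draw per-sample SNVs whose trinucleotide categories follow a signature
    mixture.

    Each mutation first draws its signature from ``config.signature_mix``
    (restricted to columns of ``true_signatures``), then its 96-category from
    that signature, then a uniformly random eligible site: a position whose
    reference triplet matches the category on either strand (the alt allele
    is reverse-complemented on the purine strand).  Positions are distinct
    within a sample.  ``per_sample_mix`` overrides the config mixture with
    one weight mapping per sample, so cohorts can carry heterogeneous
    exposures (required for signature deconvolution to be identifiable).
    Returns the variants and the realized per-sample exposure counts
    (samples x signatures).
    """
    contig, seq = reference
    if per_sample_mix is not None and len(per_sample_mix) != n_samples:
        raise ValueError("per_sample_mix must supply one mixture per sample")
    mixes = list(per_sample_mix) if per_sample_mix is not None else [
        config.signature_mix
    ] * n_samples
    names_union: list[str] = []
    for mix in mixes:
        total = sum(mix.values())
        if any(w < 0 for w in mix.values()) or abs(total - 1.0) > 1e-9:
            raise ValueError(f"mixture weights must be non-negative and sum to 1, got {total}")
        for s in mix:
            if s not in names_union:
                names_union.append(s)
    sig_names = [s for s in true_signatures.columns if s in names_union]
    missing = set(names_union) - set(sig_names)
    if missing:
        raise ValueError(f"signature_mix names absent from profiles: {sorted(missing)}")
    profiles = true_signatures[sig_names].to_numpy(dtype=float)
    if not np.allclose(profiles.sum(axis=0), 1.0, atol=1e-6):
        raise ValueError("each signature profile must sum to 1 over the 96 categories")

    # index eligible center positions (1-based) per trinucleotide
    tri_pos: dict[str, list[int]] = {}
    for i in range(1, len(seq) - 1):
        tri_pos.setdefault(seq[i - 1 : i + 2], []).append(i + 1)

    cat_sites: list[np.ndarray] = []
    cat_strand: list[np.ndarray] = []
    for label in CATEGORIES_96:
        tri, _, _ = _category_parts(label)
        fwd = tri_pos.get(tri, [])
        rev = tri_pos.get(reverse_complement(tri), [])
        cat_sites.append(np.array(fwd + rev, dtype=int))
        cat_strand.append(np.array([True] * len(fwd) + [False] * len(rev)))

    rng = config.rng(_STREAM_MUTATIONS)
    variants: dict[str, list[VariantRecord]] = {}
    exposures = np.zeros((n_samples, len(sig_names)), dtype=int)
    for si in range(n_samples):
        sample = f"{sample_prefix}{si + 1:03d}"
        weights = np.array([mixes[si].get(s, 0.0) for s in sig_names])
        used: set[int] = set()
        recs: list[VariantRecord] = []
        for _ in range(config.n_mutations_per_sample):
            s = int(rng.choice(len(sig_names), p=weights))
            c = int(rng.choice(96, p=profiles[:, s]))
            sites = cat_sites[c]
            if sites.size == 0:
                raise GenerationError(
                    f"no eligible context site for category {CATEGORIES_96[c]!r}"
                )
            free = [k for k in range(sites.size) if sites[k] not in used]
            if not free:
                raise GenerationError(
                    f"eligible sites exhausted for category {CATEGORIES_96[c]!r}"
                )
            k = int(rng.choice(len(free)))
            pick = free[k]
            pos = int(sites[pick])
            used.add(pos)
            _, ref, alt = _category_parts(CATEGORIES_96[c])
            if not cat_strand[c][pick]:  # purine strand: emit the complement
                ref = reverse_complement(ref)
                alt = reverse_complement(alt)
            recs.append(VariantRecord(contig=contig, pos=pos, ref_allele=ref, alt_allele=alt))
            exposures[si, s] += 1
        variants[sample] = recs
    frame = pd.DataFrame(
        exposures,
        index=[f"{sample_prefix}{i + 1:03d}" for i in range(n_samples)],
        columns=sig_names,
    )
    return variants, frame


def _truncated_beta(rng: np.random.Generator, a: float, b: float, floor: float) -> float:
    for _ in range(1000):
        v = float(rng.beta(a, b))
        if v >= floor:
            return v
    return floor


def gen_caller_tables(
    true_variants: Sequence[VariantRecord],
    config: SimulationConfig,
    reference: tuple[str, str],
    rng: np.random.Generator | None = None,
) -> tuple[dict[str, list[VariantRecord]], set[tuple[str, int, str, str]]]:
    """Simulate per-caller call tables for one tumor-normal pair.

    Each true variant enters caller c's table with probability c's
    sensitivity (SNVs for SNV callers, indels for indel callers).  Tumor VAF
    is drawn once per variant from a truncated Beta; per-caller read counts
    are Poisson depths with binomial alt counts, and the normal carries
    binomial contamination reads.  False positives are injected per caller,
    independently, at the configured per-megabase rate at random non-variant
    positions.  Returns the tables and the set of true variant keys.
    """
    contig, seq = reference
    if rng is None:
        rng = config.rng(_STREAM_CALLERS)
    truth_keys = {v.key for v in true_variants}
    truth_positions = {v.pos for v in true_variants}

    vafs = {
        v.key: _truncated_beta(rng, config.vaf_alpha, config.vaf_beta, config.vaf_floor)
        for v in true_variants
    }

    def read_counts(vaf: float) -> tuple[int, int, int, int]:
        td = max(1, int(rng.poisson(config.mean_tumor_depth)))
        ta = int(rng.binomial(td, vaf))
        nd = max(1, int(rng.poisson(config.mean_normal_depth)))
        na = int(rng.binomial(nd, config.normal_contamination))
        return td, ta, nd, na

    tables: dict[str, list[VariantRecord]] = {}
    for caller, profile in config.caller_profiles.items():
        table: list[VariantRecord] = []
        for v in true_variants:
            handles = profile.calls_snv if v.variant_class == "SNV" else profile.calls_indel
            if not handles or rng.random() >= profile.sensitivity:
                continue
            td, ta, nd, na = read_counts(vafs[v.key])
            table.append(
                VariantRecord(
                    contig=contig,
                    pos=v.pos,
                    ref_allele=v.ref_allele,
                    alt_allele=v.alt_allele,
                    callers=frozenset({caller}),
                    tumor_depth=td,
                    tumor_alt=ta,
                    normal_depth=nd,
                    normal_alt=na,
                )
            )
        n_fp = int(rng.poisson(profile.fp_per_mb * len(seq) / 1e6))
        for _ in range(n_fp):
            for _attempt in range(100):
                pos = int(rng.integers(2, len(seq)))  # 1-based, inside the contig
                if pos not in truth_positions:
                    break
            ref = seq[pos - 1]
            if profile.calls_snv:
                alt = str(rng.choice([b for b in "ACGT" if b != ref]))
            else:
                alt = ref + str(rng.choice(list("ACGT")))
            fp_vaf = float(rng.beta(config.fp_vaf_alpha, config.fp_vaf_beta))
            td, ta, nd, na = read_counts(fp_vaf)
            table.append(
                VariantRecord(
                    contig=contig,
                    pos=pos,
                    ref_allele=ref,
                    alt_allele=alt,
                    callers=frozenset({caller}),
                    tumor_depth=td,
                    tumor_alt=ta,
                    normal_depth=nd,
                    normal_alt=na,
                )
            )
        tables[caller] = table
    return tables, truth_keys


def default_subtype_centroids(
    config: SimulationConfig, genes: Sequence[str], rng: np.random.Generator
) -> dict[str, pd.Series]:
    """Three centroids (luminal, basal, ecm) on the log2 scale: a shared
    baseline with subtype markers elevated by 3 log2 units in their own
    subtype."""
    base = pd.Series(rng.normal(3.0, 1.5, size=len(genes)), index=list(genes))
    marker_map = {
        "luminal": LUMINAL_MARKERS,
        "basal": BASAL_MARKERS,
        "ecm": ECM_MARKERS,
    }
    centroids = {}
    for subtype, markers in marker_map.items():
        c = base.copy()
        present = [m for m in markers if m in c.index]
        c[present] += 3.0
        centroids[subtype] = c
    return centroids


def default_gene_universe(config: SimulationConfig) -> list[str]:
    """Marker + immune + housekeeping genes padded with background genes."""
    named = list(
        dict.fromkeys(
            list(LUMINAL_MARKERS)
            + list(BASAL_MARKERS)
            + list(ECM_MARKERS)
            + list(IMMUNE_GENES)
            + list(HOUSEKEEPING_GENES)
        )
    )
    n_bg = max(0, config.n_genes - len(named))
    return named + [f"G{i:04d}" for i in range(1, n_bg + 1)]


def gen_expression_cohort(
    config: SimulationConfig,
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Simulate a multi-cohort FPKM matrix with planted structure.

    Per sample: FPKM = 2**(centroid + N(0, (sigma*scale_g)^2)), with immune
    genes shifted up by ``immune_hot_shift`` log2 units in "inflamed"
    samples.  Per-gene noise scales are heterogeneous (background genes vary
    more than the tightly co-regulated immune module or the housekeeping
    set).  Each cohort applies a monotone distortion — a global scale and a
    power bend — which is exactly the class of batch effect quantile
    normalization removes.  Returns the matrix and a truth table (sample,
    cohort, subtype, immune_state).
    """
    if len(config.n_samples_per_group) < 2:
        raise ValueError("need >= 2 sample groups")
    rng = config.rng(_STREAM_EXPRESSION)
    genes = default_gene_universe(config)
    centroids = config.subtype_centroids or default_subtype_centroids(config, genes, rng)
    if len(centroids) < 2:
        raise ValueError("need >= 2 subtype centroids")
    subtype_names = list(centroids)
    immune_present = [g for g in IMMUNE_GENES if g in genes]

    # gene-level noise heterogeneity: a fixed property of each gene
    noise_scale = rng.uniform(0.6, 1.8, size=len(genes))
    tight = {g for g in IMMUNE_GENES}
    hk = {g for g in HOUSEKEEPING_GENES}
    for i, g in enumerate(genes):
        if g in tight:
            noise_scale[i] = 0.6  # co-regulated module: small residual spread
        elif g in hk:
            noise_scale[i] = 0.5  # housekeeping genes are stably expressed

    columns: dict[str, np.ndarray] = {}
    cohort: dict[str, str] = {}
    truth_rows = []
    for group, n in config.n_samples_per_group.items():
        n_depleted, n_inflamed = config.immune_split.get(group, (n, 0))
        if n_depleted + n_inflamed != n:
            # fall back to a proportional split preserving the configured ratio
            frac = n_inflamed / max(n_depleted + n_inflamed, 1)
            n_inflamed = int(round(frac * n))
            n_depleted = n - n_inflamed
        states = ["depleted"] * n_depleted + ["inflamed"] * n_inflamed
        props = config.subtype_proportions.get(
            group, {s: 1 / len(subtype_names) for s in subtype_names}
        )
        p = np.array([props.get(s, 0.0) for s in subtype_names], dtype=float)
        p = p / p.sum()
        # monotone per-cohort distortion: global scale + power bend
        batch_scale = 2.0 ** rng.normal(0.0, config.batch_sigma)
        batch_gamma = rng.uniform(0.9, 1.1) if config.batch_sigma > 0 else 1.0
        for i in range(n):
            sample = f"{group}_{i + 1:03d}"
            subtype = subtype_names[int(rng.choice(len(subtype_names), p=p))]
            logv = centroids[subtype].loc[genes].to_numpy(dtype=float).copy()
            if config.expr_sigma > 0:
                logv = logv + rng.normal(0.0, 1.0, size=len(genes)) * (
                    config.expr_sigma * noise_scale
                )
            if immune_present:
                # shared infiltration program: binary state shift plus a
                # continuous per-sample activity component
                activity = (
                    config.immune_hot_shift if states[i] == "inflamed" else 0.0
                )
                if config.immune_activity_sd > 0:
                    activity += rng.normal(0.0, config.immune_activity_sd)
                gi = [genes.index(g) for g in immune_present]
                logv[gi] += activity
            columns[sample] = batch_scale * (2.0**logv) ** batch_gamma
            cohort[sample] = group
            truth_rows.append(
                {
                    "sample": sample,
                    "cohort": group,
                    "subtype": subtype,
                    "immune_state": states[i],
                }
            )
    values = pd.DataFrame(columns, index=genes)
    truth = pd.DataFrame(truth_rows).set_index("sample")
    return ExpressionMatrix(values=values, unit="FPKM", cohort=cohort), truth


def gen_msi_sites(
    config: SimulationConfig,
) -> tuple[list[MicrosatelliteSite], dict[str, bool]]:
    """Simulate paired tumor/normal repeat-length histograms.

    Stable sites draw both histograms from the same stutter distribution
    around the site's modal repeat length; unstable sites move
    ``msi_shift_mass`` of the tumor's mass to a distribution shifted by
    ``msi_shift`` repeat units.  Read totals are Poisson at the configured
    depths.  Returns the sites and the truth stability flags.
    """
    rng = config.rng(_STREAM_MSI)
    stutter = np.array([0.05, 0.15, 0.60, 0.15, 0.05])
    offsets = np.arange(-2, 3)
    sites: list[MicrosatelliteSite] = []
    truth: dict[str, bool] = {}
    for i in range(config.msi_n_sites):
        site_id = f"MS{i + 1:04d}"
        unstable = bool(rng.random() < config.msi_unstable_fraction)
        modal = int(rng.integers(10, 31))
        lengths = modal + offsets

        def draw_hist(probs: np.ndarray, mean_depth: float) -> dict[int, int]:
            n = max(1, int(rng.poisson(mean_depth)))
            counts = rng.multinomial(n, probs / probs.sum())
            return {int(l): int(c) for l, c in zip(lengths, counts) if c > 0}

        normal_hist = draw_hist(stutter, config.mean_normal_depth)
        if unstable:
            shifted = np.concatenate(
                [stutter * (1 - config.msi_shift_mass), stutter * config.msi_shift_mass]
            )
            support = np.concatenate([lengths, lengths + config.msi_shift])
            n = max(1, int(rng.poisson(config.mean_tumor_depth)))
            counts = rng.multinomial(n, shifted / shifted.sum())
            tumor_hist = {int(l): int(c) for l, c in zip(support, counts) if c > 0}
        else:
            tumor_hist = draw_hist(stutter, config.mean_tumor_depth)
        sites.append(
            MicrosatelliteSite(site_id=site_id, tumor_hist=tumor_hist, normal_hist=normal_hist)
        )
        truth[site_id] = unstable
    return sites, truth


def gen_ihc_table(
    config: SimulationConfig,
    alphas: Mapping[str, Sequence[float]] | None = None,
    n_per_group: Mapping[str, int] | None = None,
    protein: str = "MLH1",
) -> pd.DataFrame:
    """Simulate per-sample intensity-percentage tables for one protein.

    Percentages of cells at intensities 0/1+/2+/3+ are Dirichlet draws per
    group (defaults plant a low-intensity UTUC group against a
    high-intensity UCB group, 16 vs 14 samples, matching the IHC cohort
    sizes).  Rows sum to 100 exactly.
    """
    rng = config.rng(_STREAM_IHC)
    if alphas is None:
        alphas = {"UTUC": (5.0, 3.0, 1.5, 0.5), "UCB": (0.5, 1.5, 3.0, 5.0)}
    if n_per_group is None:
        n_per_group = {"UTUC": 16, "UCB": 14}
    rows = []
    for group, alpha in alphas.items():
        n = n_per_group.get(group, 10)
        draws = rng.dirichlet(np.asarray(alpha, dtype=float), size=n) * 100.0
        for i in range(n):
            p = draws[i]
            p = p * (100.0 / p.sum())  # exact row sum
            rows.append(
                {
                    "sample": f"{group}_IHC{i + 1:02d}",
                    "group": group,
                    "protein": protein,
                    "pct_0": p[0],
                    "pct_1": p[1],
                    "pct_2": p[2],
                    "pct_3": p[3],
                }
            )
    return pd.DataFrame(rows).set_index("sample")
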