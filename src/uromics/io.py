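"""Readers and writers for the pipeline's plain-text interchange formats.

FASTA goes through Biopython; variant tables are exchanged either as a
columnar TSV or as a minimal VCF 4.2 dialect carrying tumor/normal depths
and alt counts in the INFO keys TDP/TAD/NDP/NAD (plus the supporting caller
set in CALLERS); expression matrices, gene lists, signature catalogs, MSI
histograms and IHC tables are TSV.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .msi import MicrosatelliteSite
from .signatures import CATEGORIES_96
from .expression import ExpressionMatrix
from .variants import VariantRecord


# ---------------------------------------------------------------- FASTA

def write_fasta(path: str | Path, contigs: Mapping[str, str]) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in contigs.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


# ------------------------------------------------------------- variants

_VARIANT_COLUMNS = [
    "contig", "pos", "ref", "alt", "callers",
    "tumor_depth", "tumor_alt", "normal_depth", "normal_alt",
]


def write_variants_tsv(path: str | Path, records: Iterable[VariantRecord]) -> None:
    rows = [
        {
            "contig": r.contig,
            "pos": r.pos,
            "ref": r.ref_allele,
            "alt": r.alt_allele,
            "callers": ",".join(sorted(r.callers)),
            "tumor_depth": r.tumor_depth,
            "tumor_alt": r.tumor_alt,
            "normal_depth": r.normal_depth,
            "normal_alt": r.normal_alt,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=_VARIANT_COLUMNS).to_csv(path, sep="\t", index=False)


def read_variants_tsv(path: str | Path) -> list[VariantRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"contig": str, "ref": str, "alt": str})
    out = []
    for row in df.itertuples(index=False):
        callers = frozenset(str(row.callers).split(",")) if pd.notna(row.callers) and row.callers else frozenset()
        out.append(
            VariantRecord(
                contig=row.contig,
                pos=int(row.pos),
                ref_allele=row.ref,
                alt_allele=row.alt,
                callers=callers,
                tumor_depth=int(row.tumor_depth),
                tumor_alt=int(row.tumor_alt),
                normal_depth=int(row.normal_depth),
                normal_alt=int(row.normal_alt),
            )
        )
    return out


def write_vcf(
    path: str | Path, records: Sequence[VariantRecord], contig_lengths: Mapping[str, int]
) -> None:
    """Minimal VCF 4.2 with INFO keys TDP/TAD/NDP/NAD and CALLERS."""
    lines = ["##fileformat=VCFv4.2"]
    for name, length in contig_lengths.items():
        lines.append(f"##contig=<ID={name},length={length}>")
    for key, desc in (
        ("TDP", "Tumor read depth"),
        ("TAD", "Tumor alt read count"),
        ("NDP", "Normal read depth"),
        ("NAD", "Normal alt read count"),
    ):
        lines.append(
            f'##INFO=<ID={key},Number=1,Type=Integer,Description="{desc}">'
        )
    lines.append(
        '##INFO=<ID=CALLERS,Number=.,Type=String,Description="Supporting callers">'
    )
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")
    for r in sorted(records, key=lambda x: x.key):
        info = (
            f"TDP={r.tumor_depth};TAD={r.tumor_alt};"
            f"NDP={r.normal_depth};NAD={r.normal_alt}"
        )
        if r.callers:
            info += f";CALLERS={','.join(sorted(r.callers))}"
        lines.append(
            f"{r.contig}\t{r.pos}\t.\t{r.ref_allele}\t{r.alt_allele}\t.\t.\t{info}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_vcf(path: str | Path) -> list[VariantRecord]:
    """Read the minimal VCF dialect written by :func:`write_vcf`."""
    out = []
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        chrom, pos, _, ref, alt, _, _, info = line.split("\t")[:8]
        fields: dict[str, str] = {}
        for item in info.split(";"):
            if "=" in item:
                k, v = item.split("=", 1)
                fields[k] = v
        out.append(
            VariantRecord(
                contig=chrom,
                pos=int(pos),
                ref_allele=ref,
                alt_allele=alt,
                callers=frozenset(fields.get("CALLERS", "").split(","))
                if fields.get("CALLERS")
                else frozenset(),
                tumor_depth=int(fields.get("TDP", 0)),
                tumor_alt=int(fields.get("TAD", 0)),
                normal_depth=int(fields.get("NDP", 0)),
                normal_alt=int(fields.get("NAD", 0)),
            )
        )
    return out


# ----------------------------------------------------------- expression

def write_expression_tsv(path: str | Path, matrix: ExpressionMatrix) -> None:
    """Rows = genes (first column ``gene``), columns = samples; cohorts go in
    a sidecar written by :func:`write_cohort_tsv`."""
    out = matrix.values.copy()
    out.index.name = "gene"
    out.to_csv(path, sep="\t")


def read_expression_tsv(
    path: str | Path, cohort: Mapping[str, str], unit: str = "FPKM"
) -> ExpressionMatrix:
    values = pd.read_csv(path, sep="\t", index_col=0)
    values.index.name = None
    return ExpressionMatrix(values=values, unit=unit, cohort=dict(cohort))


def write_cohort_tsv(path: str | Path, cohort: Mapping[str, str]) -> None:
    pd.Series(dict(cohort), name="cohort").rename_axis("sample").to_csv(path, sep="\t")


def read_cohort_tsv(path: str | Path) -> dict[str, str]:
    return pd.read_csv(path, sep="\t", index_col=0)["cohort"].to_dict()


def write_gene_list(path: str | Path, genes: Sequence[str]) -> None:
    Path(path).write_text("\n".join(genes) + "\n")


def read_gene_list(path: str | Path) -> list[str]:
    return [
        line.strip()
        for line in Path(path).read_text().splitlines()
        if line.strip() and not line.startswith("#")
    ]


def write_labels_tsv(path: str | Path, labels: Mapping[str, str], column: str = "label") -> None:
    pd.Series(dict(labels), name=column).rename_axis("sample").to_csv(path, sep="\t")


def read_labels_tsv(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.iloc[:, 0].to_dict()


# ------------------------------------------------------------ catalogs

def write_signature_catalog(path: str | Path, catalog: pd.DataFrame) -> None:
    """96 rows labeled "A[C>A]A"-style x signature columns."""
    out = catalog.copy()
    out.index.name = "category"
    out.to_csv(path, sep="\t")


def read_signature_catalog(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = None
    if list(df.index) != list(CATEGORIES_96):
        raise ValueError(
            "signature catalog rows must be the 96 categories in canonical order"
        )
    return df


def write_mutation_catalog(path: str | Path, counts: pd.DataFrame) -> None:
    """Transposes to the conventional 96-rows x sample-columns layout."""
    out = counts.T.copy()
    out.index.name = "category"
    out.to_csv(path, sep="\t")


def read_mutation_catalog(path: str | Path) -> pd.DataFrame:
    """Returns samples x 96 counts (the in-memory orientation)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = None
    if list(df.index) != list(CATEGORIES_96):
        raise ValueError("catalog rows must be the 96 categories in canonical order")
    out = df.T.astype(int)
    out.columns.name = None
    return out


# ------------------------------------------------------------------ MSI

def write_msi_tsv(path: str | Path, sites: Sequence[MicrosatelliteSite]) -> None:
    rows = []
    for site in sites:
        for sample, hist in (("tumor", site.tumor_hist), ("normal", site.normal_hist)):
            for length, count in sorted(hist.items()):
                rows.append(
                    {
                        "site_id": site.site_id,
                        "sample": sample,
                        "allele_length": length,
                        "read_count": count,
                    }
                )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_msi_tsv(path: str | Path) -> list[MicrosatelliteSite]:
    df = pd.read_csv(path, sep="\t")
    sites = []
    for site_id, group in df.groupby("site_id", sort=True):
        hists: dict[str, dict[int, int]] = {"tumor": {}, "normal": {}}
        for row in group.itertuples(index=False):
            hists[row.sample][int(row.allele_length)] = int(row.read_count)
        sites.append(
            MicrosatelliteSite(
                site_id=str(site_id), tumor_hist=hists["tumor"], normal_hist=hists["normal"]
            )
        )
    return sites


# ------------------------------------------------------------------ IHC

def write_ihc_tsv(path: str | Path, table: pd.DataFrame) -> None:
    table.to_csv(path, sep="\t")


def read_ihc_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)
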