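"""End-to-end orchestration: demo-bundle generation and pipeline runs driven
by a validated YAML configuration.

``make_demo`` writes a self-contained synthetic dataset (reference FASTA,
per-caller VCFs, expression TSVs, signature reference catalog, MSI
histograms, IHC table, gene lists, reference labels) plus a matching
config; ``run_pipeline`` executes the stages in dependency order and writes
a manifest recording every parameter, seed, and output checksum.  Re-running
the same config over the same inputs reproduces byte-identical outputs.
Ground-truth files live under ``truth/`` and are never read by any stage.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

from . import expression as expr
from . import ihc as ihc_mod
from . import immune as immune_mod
from . import io as uio
from . import msi as msi_mod
from . import signatures as sig_mod
from . import simulate as sim
from . import subtypes as sub_mod
from . import variants as var_mod

log = logging.getLogger("uromics")

#: Full config schema with defaults; unknown keys are rejected.
DEFAULT_CONFIG: dict[str, Any] = {
    "seed": 0,
    "log_level": "INFO",
    "input_dir": "inputs",
    "output_dir": "outputs",
    "stages": {
        "variants": {
            "enabled": True,
            "samples": [],
            "coverage_bases": 200_000,
        },
        "signatures": {
            "enabled": True,
            "rank": 3,
            "n_restarts": 5,
            "max_iter": 300,
        },
        "msi": {"enabled": True, "min_depth": 20, "alpha": 0.01},
        "expression": {
            "enabled": True,
            "cohorts": [],
            "housekeeping": "housekeeping.txt",
            "group_a": "UTUC",
            "group_b": "UCB",
            "outlier_panel": "outlier_panel.txt",
        },
        "subtype": {
            "enabled": True,
            "signature_genes": "subtype_signature.txt",
            "reference_labels": "reference_labels.tsv",
            "nmf_rank": 3,
            "nmf_n_init": 10,
            "nmf_n_iter": 100,
        },
        "immune": {
            "enabled": True,
            "anchor": "CD8A",
            "n_variable": 2000,
            "k": 20,
            "runs": 100,
            "subsample": 0.8,
        },
        "ihc": {"enabled": True, "protein": "MLH1", "group_a": "UTUC", "group_b": "UCB"},
    },
}


def _validate(config: Mapping[str, Any], schema: Mapping[str, Any], path: str = "") -> dict:
    out = {}
    for key in config:
        if key not in schema:
            raise ValueError(f"unknown config key: {path}{key}")
    for key, default in schema.items():
        value = config.get(key, default)
        if isinstance(default, dict) and isinstance(value, Mapping):
            out[key] = _validate(value, default, path=f"{path}{key}.")
        else:
            out[key] = value
    return out


def load_config(path: str | Path) -> dict:
    """Load and strictly validate a pipeline YAML config."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    return _validate(raw, DEFAULT_CONFIG)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _json_default(obj: Any):
    """Coerce numpy scalars so manifests and result files stay plain JSON."""
    if hasattr(obj, "item"):
        return obj.item()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def make_demo(seed: int, outdir: str | Path) -> Path:
    """Write a self-contained synthetic dataset and its pipeline config.

    Problem sizes are desk-scale: a 100 kb contig, 6 tumor-normal pairs for
    the variant/signature stages, the full 32 + 128 expression design, 200
    microsatellite sites, and 16 + 14 IHC samples.
    """
    outdir = Path(outdir)
    inputs = outdir / "inputs"
    truth_dir = outdir / "truth"
    inputs.mkdir(parents=True, exist_ok=True)
    truth_dir.mkdir(parents=True, exist_ok=True)

    config = sim.SimulationConfig(seed=seed, contig_length=100_000)
    contig, seq = sim.gen_reference(config)
    uio.write_fasta(inputs / "reference.fasta", {contig: seq})

    reference_catalog = sig_mod.synthetic_reference_catalog()
    uio.write_signature_catalog(inputs / "signature_reference.tsv", reference_catalog)

    n_variant_samples = 6
    variants_by_sample, exposures = sim.gen_mutations(
        config, (contig, seq), reference_catalog, n_samples=n_variant_samples
    )
    exposures.rename_axis("sample").to_csv(truth_dir / "exposures.tsv", sep="\t")
    samples = sorted(variants_by_sample)
    truth_rows = []
    caller_rng = config.rng(sim._STREAM_CALLERS)  # one stream shared across samples
    for sample in samples:
        tables, truth_keys = sim.gen_caller_tables(
            variants_by_sample[sample], config, (contig, seq), rng=caller_rng
        )
        for caller, table in tables.items():
            uio.write_vcf(
                inputs / f"calls_{sample}_{caller}.vcf", table, {contig: len(seq)}
            )
        for key in sorted(truth_keys):
            truth_rows.append({"sample": sample, "contig": key[0], "pos": key[1],
                               "ref": key[2], "alt": key[3]})
    pd.DataFrame(truth_rows).to_csv(truth_dir / "true_variants.tsv", sep="\t", index=False)

    matrix, expr_truth = sim.gen_expression_cohort(config)
    for group in config.n_samples_per_group:
        cols = [s for s in matrix.samples if matrix.cohort[s] == group]
        part = expr.ExpressionMatrix(
            values=matrix.values[cols],
            unit="FPKM",
            cohort={s: group for s in cols},
        )
        uio.write_expression_tsv(inputs / f"expression_{group}.tsv", part)
    uio.write_cohort_tsv(inputs / "cohorts.tsv", matrix.cohort)
    expr_truth.to_csv(truth_dir / "expression_truth.tsv", sep="\t")

    uio.write_gene_list(inputs / "housekeeping.txt", list(sim.HOUSEKEEPING_GENES))
    uio.write_gene_list(
        inputs / "outlier_panel.txt", list(sim.LUMINAL_MARKERS + sim.BASAL_MARKERS)
    )
    uio.write_gene_list(
        inputs / "subtype_signature.txt",
        list(sim.LUMINAL_MARKERS + sim.BASAL_MARKERS + sim.ECM_MARKERS),
    )
    # labeled reference cohort for label transfer: the UCB samples
    ucb = expr_truth[expr_truth["cohort"] == "UCB"]
    uio.write_labels_tsv(
        inputs / "reference_labels.tsv", ucb["subtype"].to_dict(), column="subtype"
    )

    sites, msi_truth = sim.gen_msi_sites(config)
    uio.write_msi_tsv(inputs / "msi_sites.tsv", sites)
    uio.write_labels_tsv(truth_dir / "msi_truth.tsv",
                         {k: str(v) for k, v in msi_truth.items()}, column="unstable")

    ihc_table = sim.gen_ihc_table(config)
    uio.write_ihc_tsv(inputs / "ihc.tsv", ihc_table)

    cfg = json.loads(json.dumps(DEFAULT_CONFIG, default=_json_default))  # deep copy
    cfg["seed"] = seed
    cfg["input_dir"] = "inputs"
    cfg["output_dir"] = "outputs"
    cfg["stages"]["variants"]["samples"] = samples
    cfg["stages"]["expression"]["cohorts"] = sorted(config.n_samples_per_group)
    config_path = outdir / "config.yaml"
    config_path.write_text(yaml.safe_dump(cfg, sort_keys=True))
    return config_path


def _load_expression(indir: Path, stage_cfg: Mapping[str, Any]) -> list[expr.ExpressionMatrix]:
    cohort = uio.read_cohort_tsv(indir / "cohorts.tsv")
    matrices = []
    for group in stage_cfg["cohorts"]:
        path = indir / f"expression_{group}.tsv"
        part_cohort = {s: g for s, g in cohort.items() if g == group}
        matrices.append(uio.read_expression_tsv(path, part_cohort, unit="FPKM"))
    return matrices


def run_pipeline(config_path: str | Path) -> dict:
    """Execute the configured stages and write a run manifest.

    Stage order: variants -> signatures (needs the consensus sets);
    expression -> subtype + immune; msi and ihc are independent.  A failed
    stage aborts its dependents but independent stages still run; any
    failure is re-raised at the end after the manifest is written.
    """
    config_path = Path(config_path)
    cfg = load_config(config_path)
    logging.basicConfig(level=getattr(logging, str(cfg["log_level"]).upper(), logging.INFO))
    base = config_path.parent
    indir = base / cfg["input_dir"]
    outdir = base / cfg["output_dir"]
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    stages = cfg["stages"]
    manifest: dict[str, Any] = {"config": cfg, "stages": {}}
    failures: list[tuple[str, Exception]] = []

    def record(stage: str, outputs: list[Path], params: Mapping[str, Any]) -> None:
        manifest["stages"][stage] = {
            "params": dict(params),
            "seed": seed,
            "outputs": {p.name: _sha256(p) for p in sorted(outputs)},
        }

    consensus_by_sample: dict[str, list[var_mod.VariantRecord]] = {}
    scfg = stages["variants"]
    if scfg["enabled"]:
        try:
            outputs = []
            tmb_rows = []
            for sample in scfg["samples"]:
                tables = {}
                for caller in sorted(sim.default_caller_profiles()):
                    path = indir / f"calls_{sample}_{caller}.vcf"
                    if path.exists():
                        tables[caller] = uio.read_vcf(path)
                merged = var_mod.merge_caller_calls(tables)
                retained, reasons = var_mod.apply_somatic_filters(merged)
                consensus_by_sample[sample] = retained
                out = outdir / f"consensus_{sample}.tsv"
                uio.write_variants_tsv(out, retained)
                outputs.append(out)
                rej = outdir / f"rejected_{sample}.tsv"
                pd.DataFrame(
                    [
                        {"contig": k[0], "pos": k[1], "ref": k[2], "alt": k[3],
                         "reject_reason": ";".join(v)}
                        for k, v in sorted(reasons.items())
                    ]
                ).to_csv(rej, sep="\t", index=False)
                outputs.append(rej)
                tmb = var_mod.compute_tmb(retained, int(scfg["coverage_bases"]))
                tmb_rows.append(
                    {"sample": sample, "n_mutations": tmb.n_mutations,
                     "coverage_bases": tmb.coverage_bases, "tmb": tmb.tmb}
                )
            tmb_path = outdir / "tmb.tsv"
            pd.DataFrame(tmb_rows).to_csv(tmb_path, sep="\t", index=False)
            outputs.append(tmb_path)
            record("variants", outputs, scfg)
        except Exception as e:  # noqa: BLE001 - stage isolation by design
            log.error("variants stage failed: %s", e)
            failures.append(("variants", e))

    scfg = stages["signatures"]
    if scfg["enabled"] and not any(s == "variants" for s, _ in failures):
        try:
            reference = uio.read_fasta(indir / "reference.fasta")
            catalog = sig_mod.build_catalog(consensus_by_sample, reference)
            model = sig_mod.extract_signatures(
                catalog,
                k=int(scfg["rank"]),
                n_restarts=int(scfg["n_restarts"]),
                max_iter=int(scfg["max_iter"]),
                seed=seed,
            )
            ref_catalog = uio.read_signature_catalog(indir / "signature_reference.tsv")
            model, linkage, labels = sig_mod.match_to_reference(model, ref_catalog)
            outputs = []
            cat_path = outdir / "catalog.tsv"
            uio.write_mutation_catalog(cat_path, catalog.counts)
            prof_path = outdir / "signature_profiles.tsv"
            uio.write_signature_catalog(prof_path, model.profiles)
            exp_path = outdir / "signature_exposures.tsv"
            model.exposures.rename_axis("signature").to_csv(exp_path, sep="\t")
            match_path = outdir / "signature_matches.tsv"
            pd.DataFrame(
                [
                    {"signature": s, "best_reference": m[0], "cosine": m[1]}
                    for s, m in model.best_match.items()
                ]
            ).to_csv(match_path, sep="\t", index=False)
            tree_path = outdir / "signature_tree.nwk"
            tree_path.write_text(sig_mod.linkage_to_newick(linkage, labels) + "\n")
            outputs += [cat_path, prof_path, exp_path, match_path, tree_path]
            record("signatures", outputs, scfg)
        except Exception as e:  # noqa: BLE001
            log.error("signatures stage failed: %s", e)
            failures.append(("signatures", e))

    scfg = stages["msi"]
    if scfg["enabled"]:
        try:
            sites = uio.read_msi_tsv(indir / "msi_sites.tsv")
            for site in sites:
                msi_mod.test_site(site, min_depth=int(scfg["min_depth"]), alpha=float(scfg["alpha"]))
            result = msi_mod.msi_score(sites)
            path = outdir / "msi.json"
            path.write_text(
                json.dumps(
                    {
                        "n_unstable": result.n_unstable,
                        "n_evaluated": result.n_evaluated,
                        "score": result.score,
                        "classification": result.classification,
                    },
                    indent=2,
                    sort_keys=True,
                    default=_json_default,
                )
                + "\n"
            )
            record("msi", [path], scfg)
        except Exception as e:  # noqa: BLE001
            log.error("msi stage failed: %s", e)
            failures.append(("msi", e))

    normalized = None
    scfg = stages["expression"]
    if scfg["enabled"]:
        try:
            matrices = _load_expression(indir, scfg)
            combined = expr.quantile_normalize(matrices)
            normalized = expr.log_transform(combined)
            outputs = []
            norm_path = outdir / "expression_normalized.tsv"
            uio.write_expression_tsv(norm_path, normalized)
            outputs.append(norm_path)
            hk = uio.read_gene_list(indir / scfg["housekeeping"])
            qc = expr.housekeeping_qc(normalized, hk)
            qc_path = outdir / "housekeeping_qc.tsv"
            qc.to_csv(qc_path, sep="\t")
            outputs.append(qc_path)
            group_a = [s for s in normalized.samples if normalized.cohort[s] == scfg["group_a"]]
            group_b = [s for s in normalized.samples if normalized.cohort[s] == scfg["group_b"]]
            de = expr.differential_expression(normalized, group_a, group_b)
            de_path = outdir / "differential_expression.tsv"
            pd.DataFrame([r.__dict__ for r in de]).to_csv(de_path, sep="\t", index=False)
            outputs.append(de_path)
            panel = uio.read_gene_list(indir / scfg["outlier_panel"])
            utuc_cols = [s for s in combined.samples if combined.cohort[s] == scfg["group_a"]]
            utuc_matrix = expr.ExpressionMatrix(
                values=combined.values[utuc_cols],
                unit=combined.unit,
                cohort={s: combined.cohort[s] for s in utuc_cols},
            )
            calls, _bounds = expr.detect_outliers(utuc_matrix, panel)
            out_path = outdir / "outliers.tsv"
            pd.DataFrame([c.__dict__ for c in calls if c.is_outlier]).to_csv(
                out_path, sep="\t", index=False
            )
            outputs.append(out_path)
            record("expression", outputs, scfg)
        except Exception as e:  # noqa: BLE001
            log.error("expression stage failed: %s", e)
            failures.append(("expression", e))

    scfg = stages["subtype"]
    if scfg["enabled"] and normalized is not None:
        try:
            genes = uio.read_gene_list(indir / scfg["signature_genes"])
            ref_labels = uio.read_labels_tsv(indir / scfg["reference_labels"])
            assignments = sub_mod.transfer_labels(normalized, genes, ref_labels)
            outputs = []
            path = outdir / "subtype_assignments.tsv"
            pd.DataFrame([a.__dict__ for a in assignments]).to_csv(path, sep="\t", index=False)
            outputs.append(path)
            matrices = _load_expression(indir, stages["expression"])
            combined = expr.quantile_normalize(matrices)
            model = sub_mod.nmf_components(
                combined,
                rank=int(scfg["nmf_rank"]),
                n_init=int(scfg["nmf_n_init"]),
                n_iter=int(scfg["nmf_n_iter"]),
                seed=seed,
            )
            for name, frame in (
                ("nmf_basis.tsv", model.basis.rename_axis("gene")),
                ("nmf_coefficients.tsv", model.coefficients.rename_axis("component")),
                ("nmf_pca.tsv", model.pca_coordinates.rename_axis("sample")),
            ):
                p = outdir / name
                frame.to_csv(p, sep="\t")
                outputs.append(p)
            record("subtype", outputs, scfg)
        except Exception as e:  # noqa: BLE001
            log.error("subtype stage failed: %s", e)
            failures.append(("subtype", e))

    scfg = stages["immune"]
    if scfg["enabled"] and normalized is not None:
        try:
            classifier = immune_mod.discover_classifier(
                normalized,
                anchor_gene=scfg["anchor"],
                n_variable=int(scfg["n_variable"]),
                k=int(scfg["k"]),
            )
            labeling = immune_mod.consensus_cluster_samples(
                normalized,
                classifier,
                n_runs=int(scfg["runs"]),
                subsample=float(scfg["subsample"]),
                seed=seed,
                anchor_gene=scfg["anchor"],
            )
            assoc = immune_mod.fisher_association(labeling.labels, normalized.cohort)
            outputs = []
            genes_path = outdir / "immune_classifier.txt"
            uio.write_gene_list(genes_path, classifier)
            labels_path = outdir / "immune_labels.tsv"
            uio.write_labels_tsv(labels_path, labeling.labels)
            assoc_path = outdir / "immune_association.json"
            assoc_path.write_text(
                json.dumps(
                    {
                        "table": assoc.table,
                        "odds_ratio": assoc.odds_ratio,
                        "p_value": assoc.p_value,
                    },
                    indent=2,
                    sort_keys=True,
                    default=_json_default,
                )
                + "\n"
            )
            outputs += [genes_path, labels_path, assoc_path]
            record("immune", outputs, scfg)
        except Exception as e:  # noqa: BLE001
            log.error("immune stage failed: %s", e)
            failures.append(("immune", e))

    scfg = stages["ihc"]
    if scfg["enabled"]:
        try:
            table = uio.read_ihc_tsv(indir / "ihc.tsv")
            records = [
                ihc_mod.compute_hscore(
                    (row.pct_0, row.pct_1, row.pct_2, row.pct_3),
                    sample=str(idx),
                    protein=str(row.protein),
                )
                for idx, row in table.iterrows()
            ]
            scores = pd.DataFrame([r.__dict__ for r in records]).set_index("sample")
            scores["group"] = table["group"]
            path = outdir / "hscores.tsv"
            scores.to_csv(path, sep="\t")
            ga = [r for r in records if table.loc[r.sample, "group"] == scfg["group_a"]]
            gb = [r for r in records if table.loc[r.sample, "group"] == scfg["group_b"]]
            comp = ihc_mod.compare_hscores(ga, gb)
            comp_path = outdir / "hscore_comparison.json"
            comp_path.write_text(json.dumps(comp, indent=2, sort_keys=True, default=_json_default) + "\n")
            record("ihc", [path, comp_path], scfg)
        except Exception as e:  # noqa: BLE001
            log.error("ihc stage failed: %s", e)
            failures.append(("ihc", e))

    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True, default=_json_default) + "\n")
    if failures:
        stage, err = failures[0]
        raise RuntimeError(f"stage {stage!r} failed: {err}") from err
    return manifest
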