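"""End-to-end orchestration: simulate -> quantify -> annotate -> profile ->
specificity -> differential expression -> targets/network -> assays ->
report.

Each stage consumes only the serialized interfaces of the previous one, so
stages can also be run individually from the command line. The mRNA
direction table used by the network stage is derived from the synthetic
ground truth (targets of truly stage-responsive miRNAs move opposite to
their miRNA), standing in for a matched mRNA profiling experiment.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from . import annotate, assays as assay_stats, de, profiles, quantify, targets
from . import io as _io
from . import report as reporting
from .containers import CountMatrix, TruthTables
from .simulate import (
    SyntheticConfig,
    SyntheticReference,
    generate_reference,
    make_manifest,
    simulate_assays,
    simulate_counts,
    synthesize_reads,
)
from .specificity import score_specificity

logger = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    report: dict
    manifest: pd.DataFrame
    reference: SyntheticReference
    counts_true: CountMatrix
    counts: CountMatrix
    counts_filtered: CountMatrix
    rpm: pd.DataFrame
    specificity: pd.DataFrame
    de_table: pd.DataFrame
    network_edges: list = field(default_factory=list)
    enrichment: pd.DataFrame | None = None


def derive_gene_directions(
    truth: TruthTables, tissues: list[str]
) -> pd.DataFrame:
    """Synthetic mRNA direction table implied by the planted regulation."""
    rows = []
    for (mid, tissue), lfc in truth.true_de.items():
        if tissue not in tissues:
            continue
        gdir = "down" if lfc > 0 else "up"
        for gid in truth.true_targets.get(mid, ()):
            rows.append((gid, tissue, gdir))
    return pd.DataFrame(rows, columns=["gene_id", "tissue", "direction"]) \
        .drop_duplicates(["gene_id", "tissue"])


def _truth_recovery(de_table: pd.DataFrame, spec_table: pd.DataFrame,
                    truth: TruthTables) -> dict:
    called = {
        (r.mirna_id, r.tissue) for r in de_table[de_table["is_de"]].itertuples()
    }
    true_pairs = set(truth.true_de)
    scored = {
        (m, t) for (m, t) in true_pairs if m in set(de_table["mirna_id"])
    }
    tp = len(called & true_pairs)
    recall = tp / len(scored) if scored else float("nan")
    precision = tp / len(called) if called else float("nan")

    spec_called = spec_table[spec_table["category"] == "tissue_specific"]
    truly = {m: t for m, t in truth.true_specific.items()
             if t != "none" and m in spec_table.index}
    correct = sum(
        1 for m, t in truly.items()
        if m in spec_called.index and spec_called.loc[m, "assigned_tissue"] == t
    )
    spec_acc = correct / len(truly) if truly else float("nan")
    return {
        "de_recall": recall,
        "de_precision": precision,
        "specificity_recovery": spec_acc,
    }


def run_pipeline(
    config: SyntheticConfig,
    outdir: str | os.PathLike | None = None,
    three_prime_tolerance: int = 0,
    write_fastq: bool = False,
) -> PipelineResult:
    """Run the whole analysis on a synthetic study and assemble the report."""
    logger.info("generating reference (seed=%d, %d miRNAs)",
                config.seed, config.n_mirnas)
    ref = generate_reference(config)
    manifest = make_manifest(config)
    mirna_ids = [m.id for m in ref.matures]

    counts_true = simulate_counts(config, ref.truth, manifest, mirna_ids)
    fastq_dir = os.path.join(str(outdir), "fastq") if (outdir and write_fastq) else None
    readsets = synthesize_reads(counts_true, ref.mature_seqs, config,
                                outdir=fastq_dir)

    logger.info("quantifying %d samples", len(readsets))
    cm, quant_stats = quantify.quantify_samples(
        {s: rs.records for s, rs in readsets.items()},
        ref.mature_seqs,
        config.adapter,
        three_prime_tolerance=three_prime_tolerance,
        hairpins=ref.hairpin_seqs,
        mature_positions=ref.mature_positions,
    )
    filtered = quantify.detection_filter(cm)
    logger.info("detection filter kept %d of %d miRNAs",
                len(filtered.mirnas), len(cm.mirnas))
    rpm = quantify.rpm_normalize(filtered)

    # annotation
    classes = annotate.classify_all(ref.matures, ref.same_species_ref,
                                    ref.other_species_ref)
    census = annotate.arm_census(ref.precursors, ref.matures, classes)
    _calls, ctx_counts = annotate.context_census(ref.precursors, ref.genes)

    # expression structure
    log_expr = profiles.log_transform(rpm)
    corr = profiles.pearson_matrix(log_expr)
    z = profiles.zscore_rows(log_expr)
    _coords, pca_fracs = profiles.pca(z)

    # specificity and differential expression
    spec_table = score_specificity(rpm, manifest)
    de_table = de.de_per_tissue(filtered, manifest)

    de_sets = {
        t: set(sub.loc[sub["is_de"], "mirna_id"])
        for t, sub in de_table.groupby("tissue")
    }
    overlap = targets.overlap_distribution(de_sets)
    conserved, _heat = targets.direction_conservation(de_table)

    universe_mirnas = pd.Index(filtered.mirnas)
    de_flags = pd.Series(
        [any(m in s for s in de_sets.values()) for m in universe_mirnas],
        index=universe_mirnas,
    )
    spec_flags = spec_table.loc[universe_mirnas, "category"] == "tissue_specific"
    chi_table, chi_stat, chi_p = targets.specificity_enrichment(de_flags,
                                                                spec_flags)

    # targets, network, gene-set enrichment
    de_mirna_ids = sorted({m for s in de_sets.values() for m in s})
    predictions = targets.predict_all_targets(
        {m: ref.mature_seqs[m] for m in de_mirna_ids}, ref.utrs
    )
    gene_dirs = derive_gene_directions(ref.truth, list(config.tissues))
    edges = targets.build_network(de_table, gene_dirs, predictions)
    universe_genes = {g.id for g in ref.genes}
    network_genes = {e.gene_id for e in edges} & universe_genes
    enrichment = (
        targets.geneset_enrichment(network_genes, ref.gene_sets, universe_genes)
        if network_genes
        else None
    )

    # assays
    assay_data = simulate_assays(ref.truth, config)
    rel = assay_stats.ddct(assay_data.ct, calibrator="prenatal")
    qpcr = {}
    for gene, sub in rel.groupby("target_gene"):
        post = sub[sub["group"] == "postnatal"]["relative_expression"]
        comparison = assay_stats.group_compare(
            sub["relative_expression"], sub["group"]
        )
        qpcr[gene] = {"fold_change": float(post.mean()), **comparison}
    luc = assay_stats.luciferase_relative_activity(assay_data.luciferase)
    luc_summary = {
        construct: float(sub.loc[sub["treatment"] == "mimic",
                                 "relative_activity"].mean())
        for construct, sub in luc.groupby("construct")
    }
    glucose_wells, glucose_summary = assay_stats.glucose_output(assay_data.glucose)
    glucose_test = assay_stats.group_compare(
        glucose_wells["glucose_normalized"], glucose_wells["group"]
    )
    nadir_hour = assay_data.blood_glucose.mean(axis=1).idxmin()

    # report assembly ------------------------------------------------------
    matures_by_class = dict(pd.Series(classes).value_counts())
    precursors_by_class = dict(census["precursors"])
    per_tissue_de = {t: len(s) for t, s in de_sets.items()}
    cat_counts = dict(spec_table["category"].value_counts())
    for c in ("tissue_specific", "nonspecific", "housekeeping"):
        cat_counts.setdefault(c, 0)

    report = {
        "provenance": {
            "package_version": __version__,
            "seed": config.seed,
            "config_hash": reporting.config_hash(config),
            "n_samples": len(manifest),
        },
        "quantification": {
            "n_samples": len(manifest),
            "total_raw_reads": int(quant_stats["n_raw"].sum()),
            "total_clean_reads": int(quant_stats["n_clean"].sum()),
            "total_assigned_reads": int(quant_stats["assigned"].sum()),
            "n_detected_mirnas": len(filtered.mirnas),
        },
        "annotation": {
            "n_matures": len(ref.matures),
            "n_precursors": len(ref.precursors),
            "matures_by_class": {k: int(v) for k, v in matures_by_class.items()},
            "precursors_by_class": {k: int(v) for k, v in precursors_by_class.items()},
        },
        "genomic_context": {
            "counts": {k: int(v) for k, v in ctx_counts.items()},
            "total": int(sum(ctx_counts.values())),
            "pct": {
                k: reporting.percent(v, sum(ctx_counts.values()))
                for k, v in ctx_counts.items()
            },
        },
        "expression": {
            "pc_variance_pct": [round(100 * float(f), 2) for f in pca_fracs[:3]],
            "median_intra_tissue_correlation": float(np.nanmedian(corr.to_numpy())),
        },
        "specificity": {
            "n_scored": int(len(spec_table)),
            "counts": {k: int(v) for k, v in cat_counts.items()},
            "pct": {
                k: reporting.percent(v, len(spec_table))
                for k, v in cat_counts.items()
            },
        },
        "differential_expression": {
            "per_tissue": {k: int(v) for k, v in per_tissue_de.items()},
            "total_events": int(sum(per_tissue_de.values())),
            "unique_mirnas": int(overlap.total_unique),
            "n_conserved_direction": int(conserved.sum()) if len(conserved) else 0,
        },
        "overlap": {
            "counts": {int(k): int(v) for k, v in overlap.counts.items()},
            "total_unique": int(overlap.total_unique),
            "pct": {
                int(k): reporting.percent(v, overlap.total_unique)
                for k, v in overlap.counts.items()
            } if overlap.total_unique else {},
        },
        "enrichment": {
            "chi_square": {
                "table": chi_table.astype(int).tolist(),
                "statistic": float(chi_stat),
                "pvalue": float(chi_p),
            },
            "top_gene_sets": (
                enrichment.head(5).to_dict("records") if enrichment is not None else []
            ),
        },
        "network": {
            "n_edges": len(edges),
            "n_mirnas": len({e.mirna_id for e in edges}),
            "n_genes": len({e.gene_id for e in edges}),
        },
        "assays": {
            "qpcr": qpcr,
            "luciferase_relative_activity": luc_summary,
            "glucose": {
                "summary": glucose_summary.to_dict("records"),
                **glucose_test,
            },
            "blood_glucose_nadir_hours": float(nadir_hour),
        },
        "truth_recovery": _truth_recovery(de_table, spec_table, ref.truth),
    }
    reporting.validate_report(report)

    result = PipelineResult(
        report=report,
        manifest=manifest,
        reference=ref,
        counts_true=counts_true,
        counts=cm,
        counts_filtered=filtered,
        rpm=rpm,
        specificity=spec_table,
        de_table=de_table,
        network_edges=edges,
        enrichment=enrichment,
    )
    if outdir is not None:
        _write_artifacts(result, config, outdir)
    return result


def _write_artifacts(result: PipelineResult, config: SyntheticConfig, outdir):
    os.makedirs(outdir, exist_ok=True)
    ref_dir = os.path.join(str(outdir), "reference")
    result.reference.write(ref_dir)
    _io.write_manifest(os.path.join(str(outdir), "manifest.tsv"), result.manifest)
    _io.write_count_matrix(os.path.join(str(outdir), "counts.tsv"),
                           result.counts)
    _io.write_count_matrix(os.path.join(str(outdir), "counts_filtered.tsv"),
                           result.counts_filtered)
    result.rpm.rename_axis("mirna_id").to_csv(
        os.path.join(str(outdir), "rpm.tsv"), sep="\t"
    )
    result.specificity.rename_axis("mirna_id").to_csv(
        os.path.join(str(outdir), "specificity.tsv"), sep="\t"
    )
    result.de_table.to_csv(os.path.join(str(outdir), "de.tsv"), sep="\t",
                           index=False)
    pd.DataFrame(
        [(e.tissue, e.mirna_id, e.gene_id, e.mirna_direction, e.gene_direction)
         for e in result.network_edges],
        columns=["tissue", "mirna_id", "gene_id", "mirna_direction",
                 "gene_direction"],
    ).to_csv(os.path.join(str(outdir), "network.tsv"), sep="\t", index=False)
    if result.enrichment is not None:
        result.enrichment.to_csv(os.path.join(str(outdir), "enrichment.tsv"),
                                 sep="\t", index=False)
    config.to_yaml(os.path.join(str(outdir), "config.yaml"))
    reporting.report_to_json(result.report, os.path.join(str(outdir),
                                                         "report.json"))
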