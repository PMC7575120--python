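"""End-to-end orchestration of the co-expression analysis.

Stage order mirrors the analysis it packages: (optional) depth-normalise by
downsampling each library and taking the median TPM over replicate draws;
per-library Zipf QC and gene dispersion; detection filtering; sample-to-sample
correlation network (with threshold scan and maximum full-inclusion
threshold); gene-to-gene correlation network at the configured threshold;
Markov clustering; cluster profiles, enrichment and the group-ratio marker
screen.  Every intermediate is persisted in documented text formats and a
JSON manifest records parameters, input hashes and per-stage summaries.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os

from sklearn.metrics import adjusted_rand_score

from . import correlation, filtering, graph, mcl, profiles, qc, synthetic
from .config import PipelineConfig
from .matrix import (ExpressionMatrix, SampleAnnotation, aggregate_replicates,
                     counts_to_tpm, read_annotation, read_tpm_table,
                     write_annotation, write_tpm_table)

logger = logging.getLogger(__name__)

try:  # installed-package version for the manifest
    from importlib.metadata import version as _pkg_version
    _VERSION = _pkg_version("coexnet")
except Exception:  # pragma: no cover - not installed
    _VERSION = "unknown"


def _sha256_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def recovery_ari(cluster_set: mcl.ClusterSet,
                 truth: synthetic.SyntheticTruth) -> float:
    """Adjusted Rand index between MCL clusters and planted module labels.

    Scored over planted-module genes only (signal, IEG and contaminant
    modules); genes the clustering left outside any cluster each count as
    their own singleton, so missing a module is penalised rather than
    ignored.
    """
    truth_labels = truth.module_gene_labels()
    predicted = cluster_set.labels()
    y_true, y_pred = [], []
    singleton = -1
    for gene, label in truth_labels.items():
        y_true.append(label)
        if gene in predicted:
            y_pred.append(predicted[gene])
        else:
            y_pred.append(singleton)
            singleton -= 1
    return float(adjusted_rand_score(y_true, y_pred))


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all configured stages and return the run manifest."""
    config.validate()
    outdir = config.outdir
    os.makedirs(outdir, exist_ok=True)
    manifest: dict = {
        "coexnet_version": _VERSION,
        "parameters": config.to_dict(),
        "inputs": {},
        "stages": {},
    }

    # -- stage: input (load files or simulate) --------------------------------
    truth = None
    annotation = None
    counts = None
    lengths = None
    if config.synthetic is not None or (
            config.tpm_path is None and config.counts_path is None):
        spec = synthetic.spec_from_dict(
            {**(config.synthetic or {}), "seed": config.seed})
        tpm, counts, annotation, truth = synthetic.generate_expression(spec)
        lengths = truth.gene_lengths
        truth.write(os.path.join(outdir, "truth.tsv"),
                    os.path.join(outdir, "truth_summary.json"))
        manifest["inputs"]["synthetic_spec"] = synthetic.spec_to_dict(spec)
    else:
        if config.tpm_path is not None:
            tpm = read_tpm_table(config.tpm_path)
            manifest["inputs"]["tpm_sha256"] = _sha256_file(config.tpm_path)
        else:
            tpm = None
        if config.counts_path is not None:
            counts = read_tpm_table(config.counts_path, unit="counts")
            manifest["inputs"]["counts_sha256"] = _sha256_file(config.counts_path)
        if config.lengths_path is not None:
            import pandas as pd
            lengths = pd.read_csv(config.lengths_path, sep="\t",
                                  index_col=0).iloc[:, 0]
        if config.annotation_path is not None:
            annotation = read_annotation(config.annotation_path)

    # -- stage: depth normalisation ------------------------------------------
    if config.downsample and counts is not None and lengths is not None:
        draws = synthetic.generate_replicate_draws(
            counts, depth=config.downsample_depth,
            k=config.n_replicate_draws, seed=config.seed)
        tpm_draws = [counts_to_tpm(d, lengths) for d in draws]
        tpm = aggregate_replicates(tpm_draws, method="median")
        manifest["stages"]["downsample"] = {
            "depth": config.downsample_depth,
            "n_draws": config.n_replicate_draws,
        }
    if tpm is None:
        raise ValueError("no TPM matrix available after input stage")
    write_tpm_table(tpm, os.path.join(outdir, "tpm.tsv"))
    if annotation is not None:
        write_annotation(annotation, os.path.join(outdir, "annotation.tsv"))
    manifest["stages"]["input"] = {
        "n_genes": tpm.n_genes, "n_samples": tpm.n_samples}

    # -- stage: QC ------------------------------------------------------------
    zipf = qc.zipf_report(tpm)
    zipf.to_csv(os.path.join(outdir, "qc_zipf.tsv"), sep="\t", index=False)
    disp = qc.dispersion_stats(tpm)
    disp.to_csv(os.path.join(outdir, "dispersion.tsv"), sep="\t")
    manifest["stages"]["qc"] = {
        "n_compliant_libraries": int(zipf["compliant"].sum()),
        "n_libraries": len(zipf),
        "median_zipf_slope": float(zipf["slope"].median()),
        "n_low_cov_genes": int((disp["cov"] < 0.5).sum()),
    }

    # -- stage: detection filter ---------------------------------------------
    filtered = filtering.filter_detected(tpm, min_tpm=config.min_tpm,
                                         min_samples=config.min_samples)
    summary = filtering.detection_summary(
        filtered, min_tpm=config.min_tpm,
        fractions=(config.detection_fraction,))
    write_tpm_table(filtered, os.path.join(outdir, "filtered.tsv"))
    manifest["stages"]["filter"] = {
        "n_input": tpm.n_genes,
        "n_retained": filtered.n_genes,
        "n_detected_ge_fraction": {
            str(k): v for k, v in summary["n_detected_ge_fraction"].items()},
        "n_median_above": summary["n_median_above"],
    }

    # -- stage: sample network ------------------------------------------------
    sample_corr = correlation.correlation_matrix(
        filtered, axis="samples", method=config.method,
        block_size=config.block_size, log2p1=config.log2p1)
    scan = graph.threshold_scan(sample_corr)
    scan.to_csv(os.path.join(outdir, "sample_scan.tsv"), sep="\t", index=False)
    t_full = graph.max_full_inclusion_threshold(sample_corr,
                                                step=config.scan_step)
    sample_graph = graph.build_threshold_graph(sample_corr, t_full)
    graph.write_edge_list(sample_graph,
                          os.path.join(outdir, "sample_network_edges.tsv"))
    manifest["stages"]["sample_network"] = {
        "max_full_inclusion_threshold": t_full,
        "n_nodes": sample_graph.n_nodes,
        "n_edges": sample_graph.n_edges,
    }

    # -- stage: gene network + MCL -------------------------------------------
    gene_corr = correlation.correlation_matrix(
        filtered, axis="genes", method=config.method,
        block_size=config.block_size, log2p1=config.log2p1)
    gene_scan = graph.threshold_scan(gene_corr)
    gene_scan.to_csv(os.path.join(outdir, "gene_scan.tsv"),
                     sep="\t", index=False)
    gene_graph = graph.build_threshold_graph(gene_corr,
                                             config.gene_r_threshold)
    graph.write_edge_list(gene_graph,
                          os.path.join(outdir, "gene_network_edges.tsv"))
    clusters = mcl.run_mcl(gene_graph, config.mcl)
    kept = mcl.filter_clusters(clusters, config.min_cluster_size)
    mcl.write_clusters(kept, os.path.join(outdir, "clusters.tsv"))
    manifest["stages"]["gene_network"] = {
        "r_threshold": config.gene_r_threshold,
        "n_nodes": gene_graph.n_nodes,
        "n_edges": gene_graph.n_edges,
        "n_clusters_ge_min_size": kept.n_clusters,
        "n_clusters_total": clusters.n_clusters,
        "mcl_converged": clusters.converged,
        "mcl_iterations": clusters.n_iterations,
    }

    # -- stage: profiles / screen / enrichment --------------------------------
    profs = profiles.cluster_profiles(kept, filtered)
    profiles.profiles_table(profs).to_csv(
        os.path.join(outdir, "cluster_profiles.tsv"), sep="\t")
    if annotation is not None:
        try:
            screen = profiles.group_ratio_screen(
                filtered, annotation, group_a=config.screen_group_a,
                group_b=config.screen_group_b, epsilon=config.screen_epsilon)
            screen.to_csv(os.path.join(outdir, "group_ratio_screen.tsv"),
                          sep="\t")
            manifest["stages"]["screen"] = {
                "group_a": config.screen_group_a,
                "group_b": config.screen_group_b,
                "n_ratio_ge_2": int((screen["ratio"] >= 2).sum()),
            }
        except profiles.ProfileError as exc:
            logger.warning("marker screen skipped: %s", exc)
    if config.gene_sets_path is not None:
        sets = profiles.read_gmt(config.gene_sets_path)
        enr = profiles.gene_set_enrichment(kept, sets, filtered.gene_ids)
        enr.to_csv(os.path.join(outdir, "enrichment.tsv"),
                   sep="\t", index=False)
        manifest["stages"]["enrichment"] = {
            "n_sets": len(sets),
            "n_significant_q05": int((enr["q_value"] < 0.05).sum())
            if len(enr) else 0,
        }

    # -- stage: truth evaluation (synthetic runs only) ------------------------
    if truth is not None:
        ari = recovery_ari(clusters, truth)
        manifest["stages"]["recovery"] = {"planted_module_ari": ari}
        logger.info("planted-module recovery ARI = %.3f", ari)

    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    return manifest
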