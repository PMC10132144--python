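"""End-to-end orchestration: simulate -> QC -> normalize/integrate ->
cluster -> markers -> activity -> regulons -> trajectory, with a
machine-readable run manifest."""

from __future__ import annotations

import json
import hashlib
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import qc as qc_mod
from .aucell import score_gene_sets_aucell
from .cluster import build_snn_graph, louvain_cluster, partition_major_states, reduce_pca
from .config import PipelineConfig
from .datatypes import CountMatrix
from .enrich import differential_set_activity, enrich_hypergeometric
from .gam import (cluster_smoothed_curves, smooth_on_grid,
                  test_gene_association, test_regulon_association)
from .grn import (find_dual_targeting_tfs, infer_grn_edges, prune_to_regulons,
                  score_regulons)
from .io import write_tsv
from .markers import find_markers_lr
from .normalize import integrate_donors, normalize_residuals, select_variable_genes
from .simulate import (DISSOC_PREFIX, MITO_PREFIX, SimConfig, simulate_counts,
                       write_truth)
from .trajectory import LineageSpec, fit_lineage_curve

log = logging.getLogger("tonsilflow")

__all__ = ["run_pipeline", "derive_lineage"]


def derive_lineage(clusters, partition: dict, asc_score: pd.Series,
                   labels: pd.Series) -> LineageSpec:
    """Build the predefined GC->ASC path from anonymous cluster IDs.

    Clusters called GC or ASC by the partition rule are ordered by their
    mean antibody-secreting-program activity; the lowest-scoring GC cluster
    is the root (the GC-1 analogue) and the highest-scoring cluster the
    terminus.
    """
    lineage_clusters = [c for c in clusters if partition.get(c) in ("GC", "ASC")]
    if len(lineage_clusters) < 2:
        raise ValueError("need >=2 GC/ASC clusters to define a lineage")
    means = {c: float(asc_score[(labels == c).to_numpy()].mean())
             for c in lineage_clusters}
    ordered = sorted(lineage_clusters, key=lambda c: (means[c], c))
    return LineageSpec(tuple(ordered))


def run_pipeline(config: PipelineConfig, out_dir,
                 sim_config: SimConfig | None = None,
                 counts: CountMatrix | None = None,
                 gene_sets: dict | None = None,
                 prior: pd.DataFrame | None = None,
                 tf_list=None,
                 dissociation_genes=None,
                 run_trajectory: bool = True) -> dict:
    """Execute the full pipeline and return the manifest dictionary.

    Either ``counts`` (with its gene-set/prior/TF inputs) or a
    ``sim_config`` must be given; with a ``sim_config`` the generator
    supplies the counts, its designated gene blocks, the true-regulon prior
    and TF list, so the pipeline runs fully self-contained.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config_hash": config.hash(), "seed": config.seed,
                      "stages": [], "counts": {}}
    truth = None

    # --- stage: simulate / load ------------------------------------------
    if counts is None:
        if sim_config is None:
            raise ValueError("need counts or a sim_config")
        sim_config.seed = config.stage_seed("simulate")
        counts, truth = simulate_counts(sim_config)
        write_truth(truth, out / "truth")
        if tf_list is None:
            tf_list = sim_config.tf_names
        if prior is None:
            prior = pd.DataFrame(
                [(tf, g) for tf, ts in truth.regulons_true.regulons.items()
                 for g in ts], columns=["tf", "target"],
            )
        if gene_sets is None:
            rising = [g for g, d in truth.gene_dynamics.items() if d == "rising"]
            falling = [g for g, d in truth.gene_dynamics.items() if d == "falling"]
            gene_sets = {"ASC_program": rising, "GC_program": falling}
        if dissociation_genes is None:
            dissociation_genes = [g for g in counts.gene_ids
                                  if str(g).startswith(DISSOC_PREFIX)]
        manifest["stages"].append("simulate")
    if tf_list is None:
        raise ValueError("tf_list required when counts are supplied directly")
    manifest["counts"]["input_cells"] = counts.n_cells
    manifest["counts"]["input_genes"] = counts.n_genes

    # --- stage: qc ---------------------------------------------------------
    th = qc_mod.QCThresholds(
        min_genes_per_cell=config.min_genes_per_cell,
        min_cells_per_gene=config.min_cells_per_gene,
        max_mito_fraction=config.max_mito_fraction,
        max_dissociation_fraction=config.max_dissociation_fraction,
        max_features=config.max_features,
        tcell_min_detected=config.tcell_min_detected,
    )
    metrics = qc_mod.compute_qc_metrics(
        counts, config.mito_prefix, dissociation_genes or [])
    filtered, report = qc_mod.filter_matrix(counts, metrics, th)
    write_tsv(report, out / "qc_report.tsv", comment=config.hash(), index=False)
    manifest["stages"].append("qc")
    manifest["counts"]["cells_retained"] = filtered.n_cells
    manifest["counts"]["genes_retained"] = filtered.n_genes
    log.info("QC retained %d/%d cells", filtered.n_cells, counts.n_cells)

    # --- stage: normalize / integrate / reduce / cluster -------------------
    norm = normalize_residuals(filtered)
    hvg = select_variable_genes(norm, n=config.n_variable_genes)
    norm = integrate_donors(norm, hvg)
    coords, _, _ = reduce_pca(norm, n_components=config.n_pcs,
                              exclude_prefixes=config.ig_exclude_prefixes)
    graph = build_snn_graph(coords, k=config.knn_k,
                            jaccard_min=config.snn_jaccard_min)
    labels = louvain_cluster(graph, resolution=config.louvain_resolution,
                             seed=config.stage_seed("cluster"))
    labels.index = filtered.barcodes
    partition = partition_major_states(filtered, labels)
    cl_df = pd.DataFrame({"cluster": labels,
                          "partition": [partition[c] for c in labels]})
    write_tsv(cl_df, out / "clusters.tsv", comment=config.hash())
    manifest["stages"].append("cluster")
    manifest["counts"]["n_clusters"] = int(labels.nunique())

    # --- stage: markers -----------------------------------------------------
    markers = find_markers_lr(filtered, labels, lfc_min=config.marker_lfc_min,
                              alpha=config.marker_alpha)
    write_tsv(markers, out / "markers.tsv", comment=config.hash(), index=False)
    manifest["stages"].append("markers")
    manifest["counts"]["n_marker_rows"] = len(markers)

    # --- stage: gene-set activity ------------------------------------------
    activity = score_gene_sets_aucell(filtered, gene_sets or {},
                                      top_fraction=config.aucell_top_fraction)
    diff = differential_set_activity(activity, labels,
                                     auc_min=config.diff_activity_auc_min,
                                     alpha=config.diff_activity_alpha)
    write_tsv(activity.scores, out / "set_activity.tsv", comment=config.hash())
    write_tsv(diff, out / "set_enrichment.tsv", comment=config.hash(), index=False)
    manifest["stages"].append("score-sets")

    # --- stage: regulons ----------------------------------------------------
    edges = infer_grn_edges(filtered, tf_list, seed=config.stage_seed("grn"),
                            n_estimators=config.grn_n_estimators,
                            max_genes=config.grn_max_genes,
                            targets=list(prior["target"]) if prior is not None else None)
    regulons = prune_to_regulons(edges, prior=prior, top_k=config.grn_top_k,
                                 universe=filtered.gene_ids)
    reg_activity = score_regulons(filtered, regulons,
                                  top_fraction=config.aucell_top_fraction)
    reg_diff = differential_set_activity(reg_activity, labels,
                                         auc_min=config.diff_activity_auc_min,
                                         alpha=config.diff_activity_alpha)
    any_tfs, dual_tfs = find_dual_targeting_tfs(regulons)
    write_tsv(edges, out / "grn_edges.tsv", comment=config.hash(), index=False)
    write_tsv(reg_diff, out / "regulon_enrichment.tsv", comment=config.hash(),
              index=False)
    manifest["stages"].append("regulons")
    manifest["counts"]["n_regulons"] = len(regulons)
    manifest["chemokine_targeting_tfs"] = {"any": any_tfs, "both": dual_tfs}

    # --- stage: trajectory --------------------------------------------------
    if run_trajectory:
        asc_key = "ASC_program" if gene_sets and "ASC_program" in gene_sets else None
        if asc_key is None:
            manifest["stages"].append("trajectory-skipped")
        else:
            asc_score = activity.scores.loc[asc_key]
            try:
                lineage = derive_lineage(sorted(labels.unique()), partition,
                                         asc_score, labels)
            except ValueError as err:
                raise RuntimeError(f"trajectory stage failed: {err}") from err
            pt = fit_lineage_curve(coords[:, :2], labels, lineage,
                                   min_cells=config.trajectory_min_cells,
                                   barcodes=filtered.barcodes)
            on_cells = pt.t.index
            cell_idx = {b: i for i, b in enumerate(filtered.barcodes)}
            cols = [cell_idx[b] for b in on_cells]
            sub_counts = pd.DataFrame(
                filtered.counts[:, cols].toarray(), index=filtered.gene_ids,
                columns=on_cells)
            gene_assoc = test_gene_association(
                sub_counts, pt.t.to_numpy(), knots=config.knots,
                alpha=config.gene_assoc_alpha)
            reg_assoc = test_regulon_association(
                reg_activity.scores[on_cells], pt.t.to_numpy(),
                knots=config.knots, alpha_adj=config.regulon_assoc_alpha_adj)
            curves = smooth_on_grid(reg_assoc, g=config.curve_grid_size)
            if len(curves.zscored) >= config.curve_n_clusters:
                cluster_smoothed_curves(curves, k=config.curve_n_clusters)
            write_tsv(pt.t.to_frame(), out / "pseudotime.tsv", comment=config.hash())
            write_tsv(gene_assoc.table, out / "gene_association.tsv",
                      comment=config.hash(), index=False)
            write_tsv(reg_assoc.table, out / "regulon_association.tsv",
                      comment=config.hash(), index=False)
            manifest["stages"].append("trajectory")
            manifest["counts"]["lineage_cells"] = int(len(pt.t))
            manifest["counts"]["genes_tested_pseudotime"] = int(
                gene_assoc.table["p"].notna().sum())
            manifest["counts"]["genes_associated"] = int(
                gene_assoc.table["associated"].fillna(False).sum())
            manifest["counts"]["regulons_significant"] = int(
                reg_assoc.table["significant"].fillna(False).sum())

    manifest["output_hash"] = _hash_outputs(out)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def _hash_outputs(out: Path) -> str:
    h = hashlib.sha256()
    for p in sorted(out.rglob("*.tsv")):
        h.update(p.name.encode())
        h.update(p.read_bytes())
    return h.hexdigest()[:16]
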