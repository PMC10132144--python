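"""Cell and gene quality-control filters.

Defaults follow the study design this pipeline reproduces: keep cells with
at least 200 unique genes, drop cells with >5% mitochondrial read fraction,
>4% dissociation-signature fraction or >40,000 unique RNA features, exclude
T-cell contaminants detecting >=2 of {CD3D, IL32, CD2}, then keep genes
expressed in at least 3 surviving cells.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import CountMatrix, QCMetrics

__all__ = ["QCThresholds", "compute_qc_metrics", "flag_tcell_contaminants",
           "filter_matrix"]

DEFAULT_TCELL_MARKERS = ("CD3D", "IL32", "CD2")


@dataclass
class QCThresholds:
    min_genes_per_cell: int = 200        # inclusive ("at least 200")
    min_cells_per_gene: int = 3          # inclusive
    max_mito_fraction: float = 0.05      # exclusive (">5%" removed)
    max_dissociation_fraction: float = 0.04
    max_features: int = 40_000           # exclusive (">40,000" removed)
    tcell_min_detected: int = 2


def _fractions(cm: CountMatrix, gene_set) -> np.ndarray:
    present = [g for g in gene_set if g in set(cm.gene_ids)]
    missing = set(gene_set) - set(present)
    if missing:
        warnings.warn(f"genes absent from universe ignored: {sorted(missing)}")
    totals = np.asarray(cm.counts.sum(axis=0)).ravel()
    if not present:
        return np.zeros(cm.n_cells)
    rows = cm.gene_index(present)
    block = np.asarray(cm.counts[rows].sum(axis=0)).ravel()
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(totals > 0, block / np.maximum(totals, 1), 0.0)
    if np.any(totals == 0):
        warnings.warn("cells with zero total counts: fractions set to 0")
    return frac


def compute_qc_metrics(cm: CountMatrix, mito_genes, dissociation_genes,
                       tcell_markers=DEFAULT_TCELL_MARKERS) -> QCMetrics:
    """Per-cell detected genes, mito/dissociation fractions and T-marker hits.

    ``mito_genes`` may be an explicit list or a prefix string (e.g. "MT-").
    """
    if isinstance(mito_genes, str):
        mito_genes = [g for g in cm.gene_ids if str(g).startswith(mito_genes)]
    detected = np.asarray((cm.counts > 0).sum(axis=0)).ravel()
    tmark = [g for g in tcell_markers if g in set(cm.gene_ids)]
    if tmark:
        t_det = np.asarray((cm.counts[cm.gene_index(tmark)] > 0).sum(axis=0)).ravel()
    else:
        t_det = np.zeros(cm.n_cells, dtype=int)
    table = pd.DataFrame(
        {
            "n_detected_genes": detected,
            "mito_fraction": _fractions(cm, mito_genes),
            "dissociation_fraction": _fractions(cm, dissociation_genes),
            "n_features": detected,  # unique RNA features = detected genes
            "tcell_markers_detected": t_det,
        },
        index=cm.barcodes,
    )
    return QCMetrics(table)


def flag_tcell_contaminants(cm: CountMatrix, markers=DEFAULT_TCELL_MARKERS,
                            min_detected: int = 2) -> np.ndarray:
    """Boolean mask of cells detecting >= ``min_detected`` T-cell markers."""
    present = [g for g in markers if g in set(cm.gene_ids)]
    if not present:
        raise ValueError("no T-cell marker genes present in the universe")
    det = np.asarray((cm.counts[cm.gene_index(present)] > 0).sum(axis=0)).ravel()
    return det >= min_detected


def filter_matrix(cm: CountMatrix, metrics: QCMetrics,
                  thresholds: QCThresholds | None = None,
                  exclude_tcells: bool = True):
    """Apply cell filters, then the gene filter on surviving cells.

    Returns ``(filtered CountMatrix, removal report DataFrame)``; the report
    counts cells removed per criterion (a cell failing several criteria is
    counted under each) plus genes removed.
    """
    th = thresholds or QCThresholds()
    t = metrics.table.loc[cm.barcodes]
    fail_genes = t["n_detected_genes"].to_numpy() < th.min_genes_per_cell
    fail_mito = t["mito_fraction"].to_numpy() > th.max_mito_fraction
    fail_diss = t["dissociation_fraction"].to_numpy() > th.max_dissociation_fraction
    fail_feat = t["n_features"].to_numpy() > th.max_features
    fail_t = (
        t["tcell_markers_detected"].to_numpy() >= th.tcell_min_detected
        if exclude_tcells
        else np.zeros(cm.n_cells, dtype=bool)
    )
    keep_cells = ~(fail_genes | fail_mito | fail_diss | fail_feat | fail_t)
    if not keep_cells.any():
        raise ValueError("all cells removed by QC filters")
    sub = cm.subset(cell_mask=keep_cells)
    cells_per_gene = np.asarray((sub.counts > 0).sum(axis=1)).ravel()
    keep_genes = cells_per_gene >= th.min_cells_per_gene
    out = sub.subset(gene_mask=keep_genes)
    report = pd.DataFrame(
        {
            "criterion": [
                "low_gene_count", "high_mito", "high_dissociation",
                "high_features", "tcell_contaminant", "cells_removed_total",
                "genes_removed", "cells_retained", "genes_retained",
            ],
            "count": [
                int(fail_genes.sum()), int(fail_mito.sum()), int(fail_diss.sum()),
                int(fail_feat.sum()), int(fail_t.sum()),
                int((~keep_cells).sum()), int((~keep_genes).sum()),
                out.n_cells, out.n_genes,
            ],
        }
    )
    return out, report
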