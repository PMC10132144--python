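"""Core in-memory containers shared across pipeline stages.

The pipeline passes around a small number of typed containers: raw counts
(:class:`CountMatrix`), per-cell QC metrics (:class:`QCMetrics`), Pearson-type
residuals (:class:`NormalizedMatrix`), TF regulons (:class:`RegulonSet`) and
per-cell gene-set activities (:class:`ActivityMatrix`).  All matrices are
genes x cells; cells are identified by barcode, genes by symbol.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = [
    "CountMatrix",
    "QCMetrics",
    "NormalizedMatrix",
    "RegulonSet",
    "ActivityMatrix",
    "ClusterAssignment",
]


@dataclass
class CountMatrix:
    """Sparse genes x cells UMI count matrix with donor labels.

    Parameters
    ----------
    counts
        Non-negative integer matrix, genes in rows, cells in columns.
    gene_ids
        Unique gene symbols, one per row.
    barcodes
        Unique cell barcodes, one per column.
    donor
        Donor label per cell.
    """

    counts: sp.csr_matrix
    gene_ids: np.ndarray
    barcodes: np.ndarray
    donor: np.ndarray

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.barcodes = np.asarray(self.barcodes, dtype=object)
        self.donor = np.asarray(self.donor, dtype=object)
        n_genes, n_cells = self.counts.shape
        if len(self.gene_ids) != n_genes:
            raise ValueError("gene_ids length does not match count rows")
        if len(self.barcodes) != n_cells:
            raise ValueError("barcodes length does not match count columns")
        if len(self.donor) != n_cells:
            raise ValueError("donor label required for every cell")
        if len(set(self.gene_ids)) != n_genes:
            raise ValueError("gene IDs must be unique")
        if len(set(self.barcodes)) != n_cells:
            raise ValueError("barcodes must be unique")
        if self.counts.nnz and self.counts.data.min() < 0:
            raise ValueError("negative counts")

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    def gene_index(self, genes) -> np.ndarray:
        """Row indices of ``genes`` (missing names raise KeyError)."""
        lookup = {g: i for i, g in enumerate(self.gene_ids)}
        return np.array([lookup[g] for g in genes], dtype=int)

    def subset(self, gene_mask=None, cell_mask=None) -> "CountMatrix":
        """Return a copy restricted to boolean/index masks over genes/cells."""
        mat = self.counts
        gi = np.arange(self.n_genes) if gene_mask is None else np.arange(self.n_genes)[gene_mask]
        ci = np.arange(self.n_cells) if cell_mask is None else np.arange(self.n_cells)[cell_mask]
        mat = mat[gi][:, ci]
        return CountMatrix(mat, self.gene_ids[gi], self.barcodes[ci], self.donor[ci])

    def to_frame(self) -> pd.DataFrame:
        """Dense DataFrame (genes x cells); for small matrices / debugging."""
        return pd.DataFrame(
            self.counts.toarray(), index=self.gene_ids, columns=self.barcodes
        )


@dataclass
class QCMetrics:
    """Per-cell QC metrics (indexed by barcode)."""

    table: pd.DataFrame  # columns: n_detected_genes, mito_fraction,
    #          dissociation_fraction, n_features, tcell_markers_detected

    REQUIRED = (
        "n_detected_genes",
        "mito_fraction",
        "dissociation_fraction",
        "n_features",
        "tcell_markers_detected",
    )

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValueError(f"QC table missing columns: {missing}")
        for col in ("mito_fraction", "dissociation_fraction"):
            v = self.table[col].to_numpy(float)
            if np.any((v < 0) | (v > 1)):
                raise ValueError(f"{col} outside [0, 1]")


@dataclass
class NormalizedMatrix:
    """Clipped Pearson-type residuals with the variable-gene selection.

    ``values`` is dense genes x cells; ``|values| <= clip_bound`` holds by
    construction.  ``variable_genes`` is the union-over-donors selection used
    downstream for PCA.
    """

    values: np.ndarray
    gene_ids: np.ndarray
    barcodes: np.ndarray
    donor: np.ndarray
    clip_bound: float
    variable_genes: np.ndarray = field(default_factory=lambda: np.array([], dtype=object))

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.barcodes = np.asarray(self.barcodes, dtype=object)
        self.donor = np.asarray(self.donor, dtype=object)
        self.variable_genes = np.asarray(self.variable_genes, dtype=object)
        if self.values.shape != (len(self.gene_ids), len(self.barcodes)):
            raise ValueError("values shape inconsistent with gene/cell labels")
        if np.any(np.abs(self.values) > self.clip_bound + 1e-9):
            raise ValueError("residuals exceed clip bound")
        if not set(self.variable_genes) <= set(self.gene_ids):
            raise ValueError("variable_genes not a subset of gene_ids")

    def variable_submatrix(self, exclude_prefixes=()) -> tuple[np.ndarray, np.ndarray]:
        """(values, gene_ids) restricted to variable genes, minus prefixes."""
        keep = [
            g
            for g in self.variable_genes
            if not any(str(g).startswith(p) for p in exclude_prefixes)
        ]
        idx = {g: i for i, g in enumerate(self.gene_ids)}
        rows = np.array([idx[g] for g in keep], dtype=int)
        return self.values[rows], np.asarray(keep, dtype=object)


@dataclass
class RegulonSet:
    """Transcription factors with weighted target-gene sets.

    ``regulons`` maps TF name -> {target gene -> non-negative weight}.  A TF is
    never its own target.
    """

    regulons: dict
    provenance: str = "inferred"  # {"inferred", "pruned", "ground-truth"}

    def __post_init__(self) -> None:
        for tf, targets in self.regulons.items():
            if tf in targets:
                raise ValueError(f"TF {tf} appears in its own target set")
            for g, w in targets.items():
                if w < 0:
                    raise ValueError(f"negative weight for {tf}->{g}")

    @property
    def tfs(self) -> list:
        return sorted(self.regulons)

    def target_sets(self) -> dict:
        return {tf: set(t) for tf, t in self.regulons.items()}

    def __len__(self) -> int:
        return len(self.regulons)


@dataclass
class ActivityMatrix:
    """Gene-set / regulon activity scores per cell (ranked-recovery AUC).

    ``scores`` is a DataFrame, rows = set names, columns = cell barcodes,
    every value in [0, 1].  ``top_fraction`` is the fraction of the per-cell
    gene ranking used as the recovery threshold.
    """

    scores: pd.DataFrame
    top_fraction: float

    def __post_init__(self) -> None:
        v = self.scores.to_numpy(float)
        if v.size and (v.min() < -1e-12 or v.max() > 1 + 1e-12):
            raise ValueError("activity scores outside [0, 1]")
        if not 0 < self.top_fraction <= 1:
            raise ValueError("top_fraction must be in (0, 1]")


@dataclass
class ClusterAssignment:
    """Per-cell cluster labels with the cluster-level partition call."""

    labels: pd.Series  # index = barcodes, values = cluster IDs (str)
    resolution: float
    partition: dict = field(default_factory=dict)  # cluster -> non-GC/GC/ASC

    def __post_init__(self) -> None:
        if self.partition:
            missing = set(self.labels.unique()) - set(self.partition)
            if missing:
                raise ValueError(f"partition missing clusters: {sorted(missing)}")

    @property
    def clusters(self) -> list:
        return sorted(self.labels.unique())
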