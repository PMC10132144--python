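"""Pipeline configuration with every stage default, YAML round-trip and
per-stage seed derivation."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
import yaml

__all__ = ["PipelineConfig"]

# fixed fan-out order: a stage's seed is SeedSequence([seed, index]) so each
# stage is independently reproducible from the single global seed
STAGE_ORDER = ("simulate", "cluster", "grn", "trajectory")


@dataclass
class PipelineConfig:
    """Every tunable the pipeline exposes, with its study-derived default.

    QC: >=200 genes/cell, >=3 cells/gene, mito <=5%, dissociation <=4%,
    <=40,000 features, T-contaminant rule >=2 of {CD3D, IL32, CD2}.
    Clustering: 3000 variable genes/donor, 35 PCs (Ig light chains
    excluded), kNN k=30 euclidean, SNN Jaccard minimum 1/15, Louvain
    resolution 1.3.  Markers: LR test with donor latent variable,
    p_adj < 0.01, log2FC > 0.3.  Activity: AUCell top fraction 0.05,
    Wilcoxon enrichment AUC > 0.85.  Enrichment: hypergeometric, BH
    alpha 0.05.  Trajectory: knots = 3, gene p < 0.01, regulon BH-adjusted
    p < 1e-5, Manhattan/complete clustering cut at 6.
    """

    # QC
    min_genes_per_cell: int = 200
    min_cells_per_gene: int = 3
    max_mito_fraction: float = 0.05
    max_dissociation_fraction: float = 0.04
    max_features: int = 40_000
    tcell_min_detected: int = 2
    mito_prefix: str = "MT-"
    # normalization / integration / reduction
    n_variable_genes: int = 3000
    n_pcs: int = 35
    ig_exclude_prefixes: tuple = ("IGKC", "IGLC")
    # graph clustering
    knn_k: int = 30
    snn_jaccard_min: float = 1 / 15
    louvain_resolution: float = 1.3
    # markers
    marker_lfc_min: float = 0.3
    marker_alpha: float = 0.01
    # activity scoring / differential activity
    aucell_top_fraction: float = 0.05
    diff_activity_auc_min: float = 0.85
    diff_activity_alpha: float = 0.05
    # enrichment
    enrichment_alpha: float = 0.05
    # GRN
    grn_top_k: int = 50
    grn_n_estimators: int = 50
    grn_max_genes: int = 500
    # trajectory
    knots: int = 3
    gene_assoc_alpha: float = 0.01
    regulon_assoc_alpha_adj: float = 1e-5
    curve_grid_size: int = 100
    curve_n_clusters: int = 6
    trajectory_min_cells: int = 50
    # global
    seed: int = 0

    def __post_init__(self) -> None:
        checks = [
            self.min_genes_per_cell >= 0,
            self.min_cells_per_gene >= 0,
            0 <= self.max_mito_fraction <= 1,
            0 <= self.max_dissociation_fraction <= 1,
            0 < self.aucell_top_fraction <= 1,
            0 < self.marker_alpha < 1,
            0 < self.enrichment_alpha < 1,
            0.5 <= self.diff_activity_auc_min <= 1,
            self.knots >= 1,
            self.curve_n_clusters >= 1,
            self.louvain_resolution > 0,
            0 <= self.snn_jaccard_min <= 1,
        ]
        if not all(checks):
            raise ValueError("PipelineConfig value outside its documented range")
        self.ig_exclude_prefixes = tuple(self.ig_exclude_prefixes)

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage seed below 2^31 derived from the global seed."""
        if stage not in STAGE_ORDER:
            raise KeyError(f"unknown stage {stage!r}")
        ss = np.random.SeedSequence([self.seed, STAGE_ORDER.index(stage)])
        return int(ss.generate_state(1)[0] % (2**31 - 1))

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["ig_exclude_prefixes"] = list(self.ig_exclude_prefixes)
        return d

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))

    def hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]
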