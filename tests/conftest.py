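"""Shared fixtures: small synthetic datasets reused across test modules."""

import warnings

import numpy as np
import pytest
import scipy.sparse as sp

from tonsilflow.datatypes import CountMatrix
from tonsilflow.simulate import SimConfig, simulate_counts

warnings.filterwarnings("ignore", category=UserWarning)


def make_count_matrix(X, gene_ids=None, donors=None) -> CountMatrix:
    """Wrap a dense array as a CountMatrix with generated labels."""
    X = np.asarray(X)
    G, n = X.shape
    genes = (np.array(gene_ids, dtype=object) if gene_ids is not None
             else np.array([f"g{i:04d}" for i in range(G)], dtype=object))
    barcodes = np.array([f"cell{i:05d}" for i in range(n)], dtype=object)
    donor = (np.array(donors, dtype=object) if donors is not None
             else np.array(["d1"] * n, dtype=object))
    return CountMatrix(sp.csr_matrix(X), genes, barcodes, donor)


@pytest.fixture(scope="session")
def discrete_sim():
    """Discrete-state benchmark: 6 well-separated states, no continuum."""
    # disjoint regulons: each planted TF program is driven in one state only
    cfg = SimConfig(seed=11, n_states=6, n_donors=2, cells_per_donor=300,
                    n_genes=900, n_tfs=6, targets_per_tf=15,
                    regulon_overlap_fraction=0.0,
                    continuum_states=(), artifact_fractions={})
    cm, truth = simulate_counts(cfg)
    return cfg, cm, truth


@pytest.fixture(scope="session")
def continuum_sim():
    """Full default simulation without artifacts (continuum intact)."""
    cfg = SimConfig(seed=12, artifact_fractions={})
    cm, truth = simulate_counts(cfg)
    return cfg, cm, truth


@pytest.fixture(scope="session")
def artifact_sim():
    """Smaller simulation with every artifact class planted."""
    cfg = SimConfig(seed=13, cells_per_donor=400, n_states=10,
                    continuum_states=("GC1", "GC2", "ASC1"))
    cm, truth = simulate_counts(cfg)
    return cfg, cm, truth


@pytest.fixture(scope="session")
def continuum_embedding(continuum_sim):
    """PCA embedding and labels restricted to the continuum branch."""
    from tonsilflow.cluster import reduce_pca
    from tonsilflow.normalize import (integrate_donors, normalize_residuals,
                                      select_variable_genes)

    cfg, cm, truth = continuum_sim
    on = truth.cells["state"].isin(cfg.continuum_states).to_numpy()
    sub = cm.subset(cell_mask=on)
    norm = normalize_residuals(sub)
    norm = integrate_donors(norm, select_variable_genes(norm, 1000))
    coords, _, _ = reduce_pca(norm, n_components=10)
    labels = truth.cells["state"][on]
    latent = truth.cells["latent_t"][on]
    return cfg, sub, coords, labels, latent


@pytest.fixture(scope="session")
def pipeline_runs(tmp_path_factory):
    """The full pipeline run twice with identical config and seed."""
    from tonsilflow.config import PipelineConfig
    from tonsilflow.pipeline import run_pipeline

    root = tmp_path_factory.mktemp("pipe")
    cfg = PipelineConfig(seed=5, n_variable_genes=500, n_pcs=20,
                         grn_n_estimators=20, trajectory_min_cells=40)
    sim = dict(n_states=8, n_donors=2, cells_per_donor=250, n_genes=900,
               n_tfs=8, targets_per_tf=15)
    m1 = run_pipeline(cfg, root / "run1", sim_config=SimConfig(**sim))
    m2 = run_pipeline(cfg, root / "run2", sim_config=SimConfig(**sim))
    return m1, m2, root


@pytest.fixture(scope="session")
def fitted_pseudotime(continuum_embedding):
    from tonsilflow.trajectory import LineageSpec, fit_lineage_curve

    cfg, sub, coords, labels, latent = continuum_embedding
    pt = fit_lineage_curve(coords[:, :2], labels.values,
                           LineageSpec(cfg.continuum_states),
                           barcodes=sub.barcodes)
    return pt, latent
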