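"""PCA reduction, SNN graph vs brute-force Jaccard, Louvain behavior and
the CCR7/CD38/PRDM1 partition rule."""

import igraph
import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score, silhouette_score

from tonsilflow.cluster import (build_snn_graph, louvain_cluster,
                                partition_major_states, reduce_pca)
from tonsilflow.datatypes import NormalizedMatrix

from conftest import make_count_matrix


def _norm_from_values(vals, gene_ids=None):
    G, n = vals.shape
    genes = gene_ids or [f"g{i:03d}" for i in range(G)]
    return NormalizedMatrix(vals, genes, [f"c{i}" for i in range(n)],
                            ["d1"] * n, clip_bound=float(np.abs(vals).max()),
                            variable_genes=genes)


class TestReducePCA:
    def test_rank_two_data_has_two_informative_components(self):
        rng = np.random.default_rng(51)
        u = rng.normal(0, 1, (40, 2))
        v = rng.normal(0, 1, (2, 300))
        vals = u @ v  # exact rank 2
        coords, _, _ = reduce_pca(_norm_from_values(vals), n_components=6)
        var = coords.var(axis=0)
        assert var[2:].max() < 1e-15 * var[0]

    def test_excluded_prefix_genes_absent_from_loadings(self):
        rng = np.random.default_rng(52)
        vals = rng.normal(0, 1, (30, 100))
        genes = [f"g{i:03d}" for i in range(28)] + ["IGKC", "IGLC1"]
        _, loadings, used = reduce_pca(_norm_from_values(vals, genes),
                                       n_components=5)
        assert "IGKC" not in used and "IGLC1" not in used
        assert loadings.shape[0] == 28

    def test_planted_states_separate_on_top_pcs(self, discrete_sim):
        from tonsilflow.normalize import normalize_residuals, select_variable_genes

        cfg, cm, truth = discrete_sim
        norm = normalize_residuals(cm)
        norm.variable_genes = select_variable_genes(norm, 500)
        coords, _, _ = reduce_pca(norm, n_components=10)
        assert silhouette_score(coords[:, :5], truth.cells["state"].values) > 0

    def test_sign_convention_deterministic(self):
        rng = np.random.default_rng(53)
        vals = rng.normal(0, 1, (30, 120))
        c1, l1, _ = reduce_pca(_norm_from_values(vals), n_components=4)
        c2, l2, _ = reduce_pca(_norm_from_values(vals.copy()), n_components=4)
        assert np.allclose(c1, c2) and np.allclose(l1, l2)


class TestSNNGraph:
    def test_small_instance_matches_brute_force(self):
        rng = np.random.default_rng(54)
        pts = rng.normal(0, 1, (12, 3))
        k = 4
        g = build_snn_graph(pts, k=k, jaccard_min=0.0)
        # brute-force neighbor sets (self + k nearest by euclidean)
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        sets = [set(np.argsort(d[i])[:k + 1]) for i in range(12)]
        w = {tuple(sorted((e.source, e.target))): e["weight"] for e in g.es}
        for i in range(12):
            for j in range(i + 1, 12):
                inter = len(sets[i] & sets[j])
                jac = inter / len(sets[i] | sets[j])
                assert w.get((i, j), 0.0) == pytest.approx(jac)

    def test_identical_neighbor_sets_give_weight_one(self):
        # two tight, far-apart groups of 5: within a group every point has
        # the same neighbor set
        rng = np.random.default_rng(55)
        a = rng.normal(0, 0.01, (5, 2))
        b = rng.normal(100, 0.01, (5, 2))
        g = build_snn_graph(np.vstack([a, b]), k=4, jaccard_min=0.0)
        w = {tuple(sorted((e.source, e.target))): e["weight"] for e in g.es}
        for i in range(5):
            for j in range(i + 1, 5):
                assert w[(i, j)] == pytest.approx(1.0)
        # disjoint neighbor sets across groups -> no edge
        assert all((i, j) not in w for i in range(5) for j in range(5, 10))

    def test_k_too_large_raises(self):
        with pytest.raises(ValueError):
            build_snn_graph(np.zeros((5, 2)), k=5)


class TestLouvain:
    @staticmethod
    def _two_cliques():
        g = igraph.Graph.Full(5) + igraph.Graph.Full(5)
        g.es["weight"] = [1.0] * g.ecount()
        return g

    def test_two_disjoint_cliques_two_clusters(self):
        labels = louvain_cluster(self._two_cliques(), resolution=1.3, seed=1)
        assert labels.nunique() == 2
        assert labels[:5].nunique() == 1 and labels[5:].nunique() == 1

    def test_single_clique_one_cluster(self):
        # at resolution gamma the RB null keeps a clique whole only for
        # n < gamma/(gamma-1) ~ 4.3, so a 4-clique is the clean case
        g = igraph.Graph.Full(4)
        g.es["weight"] = [1.0] * g.ecount()
        assert louvain_cluster(g, resolution=1.3, seed=1).nunique() == 1

    def test_empty_graph_raises(self):
        with pytest.raises(ValueError):
            louvain_cluster(igraph.Graph(n=0), seed=1)

    def test_seeded_determinism(self):
        g = self._two_cliques()
        a = louvain_cluster(g, seed=3)
        b = louvain_cluster(g, seed=3)
        assert a.equals(b)

    def test_node_permutation_invariance_up_to_relabeling(self):
        rng = np.random.default_rng(56)
        g = self._two_cliques()
        perm = list(rng.permutation(10))
        gp = g.permute_vertices(perm)
        la = louvain_cluster(g, seed=4)
        lp = louvain_cluster(gp, seed=4)
        back = [lp[perm[i]] for i in range(10)]
        assert adjusted_rand_score(la, back) == 1.0

    def test_planted_states_recovered(self, discrete_sim):
        from tonsilflow.normalize import (integrate_donors,
                                          normalize_residuals,
                                          select_variable_genes)
        from tonsilflow.cluster import reduce_pca

        cfg, cm, truth = discrete_sim
        norm = normalize_residuals(cm)
        norm = integrate_donors(norm, select_variable_genes(norm, 500))
        coords, _, _ = reduce_pca(norm, n_components=10)
        g = build_snn_graph(coords, k=30)
        labels = louvain_cluster(g, resolution=1.3, seed=5)
        assert adjusted_rand_score(truth.cells["state"], labels) >= 0.8


class TestPartitionMajorStates:
    @staticmethod
    def _toy(ccr7, cd38, prdm1):
        """4 clusters of 10 cells with prescribed marker levels each."""
        n_per = 10
        rows = {"CCR7": ccr7, "CD38": cd38, "PRDM1": prdm1}
        genes = ["BG", "CCR7", "CD38", "PRDM1"]
        # large constant background keeps per-cluster depths comparable
        mat = np.ones((4, 40)) * 2
        mat[0] = 500
        for r, (g, levels) in enumerate(rows.items(), start=1):
            for c, lvl in enumerate(levels):
                mat[r, c * n_per:(c + 1) * n_per] = lvl
        cm = make_count_matrix(mat.astype(int), gene_ids=genes)
        labels = pd.Series(np.repeat([f"cl{i}" for i in range(4)], n_per),
                           index=cm.barcodes)
        return cm, labels

    def test_truth_table(self):
        # cl0 naive-like (CCR7+), cl1 GC (CD38+), cl2 ASC (CD38+PRDM1+),
        # cl3 another CCR7+ cluster
        cm, labels = self._toy(ccr7=[30, 0, 0, 30], cd38=[0, 30, 30, 0],
                               prdm1=[0, 0, 30, 0])
        part = partition_major_states(cm, labels)
        assert part == {"cl0": "non-GC", "cl1": "GC", "cl2": "ASC",
                        "cl3": "non-GC"}

    def test_ccr7_precedence_flags_ambiguous(self):
        cm, labels = self._toy(ccr7=[30, 0, 0, 30], cd38=[40, 30, 35, 0],
                               prdm1=[30, 0, 30, 0])
        with pytest.warns(UserWarning, match="ambiguous"):
            part = partition_major_states(cm, labels)
        assert part["cl0"] == "non-GC"

    def test_missing_marker_raises(self):
        cm = make_count_matrix([[1, 1]], gene_ids=["CCR7"])
        with pytest.raises(ValueError, match="absent"):
            partition_major_states(cm, pd.Series(["a", "b"], index=cm.barcodes))

    def test_planted_continuum_partition(self, continuum_sim):
        cfg, cm, truth = continuum_sim
        labels = pd.Series(truth.cells["state"].values, index=cm.barcodes)
        part = partition_major_states(cm, labels)
        assert part["ASC1"] == "ASC"
        assert part["GC1"] == "GC" and part["GC2"] == "GC"
        assert part["NGC01"] == "non-GC"
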