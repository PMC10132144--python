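"""Dimensionality reduction, SNN graph construction, Louvain clustering and
the CCR7/CD38/PRDM1 major-state partition."""

from __future__ import annotations

import random
import warnings

import igraph
import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

from .datatypes import ClusterAssignment, CountMatrix, NormalizedMatrix

__all__ = ["reduce_pca", "build_snn_graph", "louvain_cluster",
           "partition_major_states"]

IG_EXCLUDE_PREFIXES = ("IGKC", "IGLC")


def reduce_pca(norm: NormalizedMatrix, n_components: int = 35,
               exclude_prefixes=IG_EXCLUDE_PREFIXES):
    """Centered PCA on the variable genes, excluding Ig light-chain prefixes.

    Component signs are fixed so the gene with the largest |loading| on each
    component loads positively, making the embedding deterministic.  Returns
    ``(coords cells x k, loadings genes x k, gene_ids)``.
    """
    values, genes = norm.variable_submatrix(exclude_prefixes)
    if len(genes) == 0:
        values, genes = norm.values, norm.gene_ids
        keep = [not any(str(g).startswith(p) for p in exclude_prefixes) for g in genes]
        values, genes = values[keep], genes[np.asarray(keep)]
    if len(genes) < n_components:
        raise ValueError("fewer variable genes than requested components")
    X = values.T  # cells x genes
    n_components = min(n_components, min(X.shape) - 1)
    pca = PCA(n_components=n_components, svd_solver="full")
    coords = pca.fit_transform(X)
    loadings = pca.components_.T  # genes x k
    for j in range(n_components):
        top = np.argmax(np.abs(loadings[:, j]))
        if loadings[top, j] < 0:
            loadings[:, j] *= -1
            coords[:, j] *= -1
    return coords, loadings, np.asarray(genes, dtype=object)


def build_snn_graph(coords: np.ndarray, k: int = 30,
                    jaccard_min: float = 1 / 15) -> igraph.Graph:
    """Shared-nearest-neighbor graph from a kNN (euclidean) neighborhood.

    Each cell's neighbor set is itself plus its ``k`` nearest neighbors.
    Edge weight = Jaccard overlap of the two neighbor sets; edges below
    ``jaccard_min`` are trimmed.
    """
    n = coords.shape[0]
    if k >= n:
        raise ValueError("k must be smaller than the number of cells")
    nn = NearestNeighbors(n_neighbors=k + 1).fit(coords)
    _, idx = nn.kneighbors(coords)  # includes self at position 0
    import scipy.sparse as sp

    rows = np.repeat(np.arange(n), k + 1)
    A = sp.csr_matrix((np.ones(n * (k + 1)), (rows, idx.ravel())), shape=(n, n))
    A.data[:] = 1.0
    inter = (A @ A.T).tocoo()
    size = k + 1
    jac = inter.data / (2 * size - inter.data)
    mask = (inter.row < inter.col) & (jac >= jaccard_min)
    edges = np.column_stack([inter.row[mask], inter.col[mask]])
    g = igraph.Graph(n=n, edges=[tuple(e) for e in edges])
    g.es["weight"] = [float(w) for w in jac[mask]]
    return g


def louvain_cluster(graph: igraph.Graph, resolution: float = 1.3,
                    seed: int = 0) -> pd.Series:
    """Louvain (multilevel modularity) communities at the given resolution.

    The igraph RNG is seeded per call and labels are canonicalized by first
    occurrence, so identical inputs give identical labels.  Singleton
    components become singleton clusters.
    """
    if graph.vcount() == 0:
        raise ValueError("empty graph")
    igraph.set_random_number_generator(random.Random(seed))
    part = graph.community_multilevel(
        weights=graph.es["weight"] if graph.ecount() else None,
        resolution=resolution,
    )
    raw = np.array(part.membership)
    remap: dict = {}
    labels = []
    for m in raw:
        if m not in remap:
            remap[m] = f"c{len(remap):02d}"
        labels.append(remap[m])
    return pd.Series(labels, name="cluster")


def _log_normalize(cm: CountMatrix, scale: float = 1e4) -> np.ndarray:
    totals = np.asarray(cm.counts.sum(axis=0)).ravel()
    totals[totals == 0] = 1
    return np.log1p(np.asarray(cm.counts.todense()) / totals[None, :] * scale)


def partition_major_states(cm: CountMatrix, labels: pd.Series,
                           markers=("CCR7", "CD38", "PRDM1")) -> dict:
    """Call each cluster non-GC / GC / ASC from CCR7, CD38 and PRDM1.

    Each marker is binarized per cluster: "high" when the cluster's mean
    log-normalized expression exceeds the median of cluster means.  Then
    CCR7-high => non-GC (taking precedence, flagged ambiguous if CD38 is
    also high); CCR7-low & CD38-high & PRDM1-low => GC; CCR7-low &
    CD38-high & PRDM1-high => ASC; any other combination => non-GC with a
    warning.
    """
    universe = set(cm.gene_ids)
    missing = [m for m in markers if m not in universe]
    if missing:
        raise ValueError(f"partition markers absent from universe: {missing}")
    ccr7, cd38, prdm1 = markers
    ln = _log_normalize(cm)
    rows = cm.gene_index(markers)
    clusters = sorted(labels.unique())
    means = pd.DataFrame(
        {cl: ln[rows][:, (labels == cl).to_numpy()].mean(axis=1) for cl in clusters},
        index=list(markers),
    )
    high = means.gt(means.median(axis=1), axis=0)
    partition = {}
    for cl in clusters:
        h = high[cl]
        if h[ccr7]:
            partition[cl] = "non-GC"
            if h[cd38]:
                warnings.warn(f"cluster {cl}: CCR7+CD38+ is ambiguous; non-GC takes precedence")
        elif h[cd38] and h[prdm1]:
            partition[cl] = "ASC"
        elif h[cd38]:
            partition[cl] = "GC"
        else:
            warnings.warn(f"cluster {cl}: marker combination matches no rule; labeled non-GC")
            partition[cl] = "non-GC"
    return partition
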