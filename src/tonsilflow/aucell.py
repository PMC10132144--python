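"""Ranked-recovery AUC ("AUCell") gene-set activity scoring.

For each cell, genes are ranked by decreasing count (ties broken
deterministically by gene ID).  The recovery curve counts how many members
of a gene set appear within the top ``r`` ranks, for ``r`` up to the
threshold ``B = ceil(top_fraction * n_genes)``.  The score is the area under
this step curve divided by the maximal achievable area (the set occupying
the very top of the ranking), which bounds it to [0, 1].  The score depends
only on ranks, so it is invariant to monotone transforms of the counts.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .datatypes import ActivityMatrix, CountMatrix
from .io import GeneSetCollection

__all__ = ["score_gene_sets_aucell", "rank_genes_per_cell"]


def rank_genes_per_cell(cm: CountMatrix) -> np.ndarray:
    """Per-cell rank (0 = top) of every gene; ties break by gene ID order.

    Returns a genes x cells integer array of ranks.
    """
    X = np.asarray(cm.counts.todense())
    gene_order = np.argsort(np.asarray(cm.gene_ids, dtype=str), kind="stable")
    ranks = np.empty_like(X, dtype=np.int32)
    # sort gene-ID-ordered rows by decreasing count (stable => ID tie-break)
    for c in range(X.shape[1]):
        col = X[gene_order, c]
        order = np.argsort(-col, kind="stable")
        rr = np.empty(len(col), dtype=np.int32)
        rr[order] = np.arange(len(col), dtype=np.int32)
        ranks[gene_order, c] = rr
    return ranks


def score_gene_sets_aucell(cm: CountMatrix, sets: GeneSetCollection | dict,
                           top_fraction: float = 0.05) -> ActivityMatrix:
    """Score every gene set in every cell by ranked-recovery AUC.

    Sets with no genes in the universe are dropped with a warning.
    """
    if isinstance(sets, dict):
        sets = GeneSetCollection(sets)
    universe = set(cm.gene_ids)
    n_genes = cm.n_genes
    B = int(np.ceil(top_fraction * n_genes))
    ranks = rank_genes_per_cell(cm)
    idx = {g: i for i, g in enumerate(cm.gene_ids)}
    rows = {}
    for name in sets.names():
        members = [g for g in sets[name] if g in universe]
        if not members:
            warnings.warn(f"gene set {name!r} has no genes in the universe; dropped")
            continue
        rows[name] = _score_set(ranks, [idx[g] for g in members], B)
    scores = pd.DataFrame(rows, index=cm.barcodes).T
    scores = scores.loc[sorted(scores.index)]
    return ActivityMatrix(scores, top_fraction)


def _score_set(ranks: np.ndarray, member_rows, B: int) -> np.ndarray:
    m = len(member_rows)
    r = ranks[member_rows]  # members x cells
    inside = r < B
    # area under the recovery step curve = sum over hit ranks of (B - rank)
    area = np.where(inside, B - r, 0).sum(axis=0).astype(float)
    kmax = min(m, B)
    max_area = kmax * B - (kmax * (kmax - 1)) // 2  # set occupying top ranks
    return area / max_area
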