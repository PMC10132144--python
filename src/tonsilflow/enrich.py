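"""Differential gene-set activity (Wilcoxon rank-AUC) and hypergeometric
over-representation testing with Benjamini-Hochberg control."""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datatypes import ActivityMatrix
from .io import GeneSetCollection

__all__ = ["differential_set_activity", "enrich_hypergeometric", "bh_adjust"]


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p, float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def differential_set_activity(activity: ActivityMatrix, labels: pd.Series,
                              auc_min: float = 0.85,
                              alpha: float = 0.05) -> pd.DataFrame:
    """One-vs-rest Wilcoxon rank-sum test of each set's activity per cluster.

    The discrimination AUC is ``U / (n1 * n2)``; a (set, cluster) pair is
    flagged enriched iff ``AUC > auc_min`` and the BH-adjusted rank-sum p
    (across all set x cluster tests) is below ``alpha``.  Constant scores
    give AUC 0.5 and p 1.
    """
    labels = pd.Series(np.asarray(labels), index=activity.scores.columns)
    clusters = sorted(labels.unique())
    rows = []
    for cl in clusters:
        mask = (labels == cl).to_numpy()
        if mask.sum() < 2 or (~mask).sum() < 2:
            raise ValueError(f"cluster {cl} needs >=2 cells on both sides")
        for name, vals in activity.scores.iterrows():
            a = vals.to_numpy(float)[mask]
            b = vals.to_numpy(float)[~mask]
            if np.all(a == a[0]) and np.all(b == a[0]):
                auc, p = 0.5, 1.0
            else:
                res = stats.mannwhitneyu(a, b, alternative="two-sided")
                auc = float(res.statistic) / (len(a) * len(b))
                p = float(res.pvalue)
            rows.append(dict(set=name, cluster=cl, auc=auc, p=p))
    df = pd.DataFrame(rows)
    df["p_adj"] = bh_adjust(df["p"].to_numpy())
    df["enriched"] = (df["auc"] > auc_min) & (df["p_adj"] < alpha)
    return df.sort_values(["set", "cluster"]).reset_index(drop=True)


def enrich_hypergeometric(query_sets: dict, collection: GeneSetCollection,
                          universe, alpha: float = 0.05) -> pd.DataFrame:
    """Upper-tail hypergeometric over-representation of collection sets in
    each query set.

    ``p = P(X >= k)`` for overlap ``k`` between a query of size ``n`` and a
    collection set of size ``K`` in a universe of ``N`` genes; sets are
    intersected with the universe first (with a warning if genes fall out).
    BH adjustment is applied within each query set across collection sets.
    """
    universe = set(universe)
    N = len(universe)
    rows = []
    for qname, qgenes in query_sets.items():
        q = set(qgenes) & universe
        if len(q) < len(set(qgenes)):
            warnings.warn(f"query {qname!r}: genes outside universe dropped")
        if not q:
            continue
        for cname in collection.names():
            cset = set(collection[cname]) & universe
            k = len(q & cset)  # K = 0 gives the degenerate p = 1 row
            # P(X >= k) with X ~ Hypergeom(N, K=len(cset), n=len(q))
            p = float(stats.hypergeom.sf(k - 1, N, len(cset), len(q)))
            rows.append(dict(query=qname, collection_set=cname, overlap=k,
                             query_n=len(q), set_K=len(cset), universe_N=N, p=p))
    df = pd.DataFrame(rows, columns=["query", "collection_set", "overlap",
                                     "query_n", "set_K", "universe_N", "p"])
    if len(df):
        df["p_adj"] = np.concatenate(
            [bh_adjust(g["p"].to_numpy()) for _, g in df.groupby("query", sort=False)]
        )
        df["significant"] = df["p_adj"] < alpha
    else:
        df["p_adj"] = []
        df["significant"] = []
    return df.reset_index(drop=True)
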