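"""Gene regulatory network inference, regulon pruning and target-set
analysis.

Edges are inferred per target gene by tree-ensemble regression of the
gene's expression on all TF expressions (random-forest feature importance,
GRNBoost-style).  Pruning either intersects inferred edges with a
TF->target prior table (the stand-in for motif-based pruning) or keeps the
top-k targets per TF by weight.  Regulon activity scoring and differential
activity delegate to the AUCell and Wilcoxon implementations.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.ensemble import ExtraTreesRegressor

from .aucell import score_gene_sets_aucell
from .datatypes import ActivityMatrix, CountMatrix, RegulonSet
from .enrich import differential_set_activity, enrich_hypergeometric  # noqa: F401
from .markers import log_normalize

__all__ = ["infer_grn_edges", "prune_to_regulons", "score_regulons",
           "differential_regulon_activity", "find_dual_targeting_tfs",
           "partition_targets"]


def infer_grn_edges(cm: CountMatrix, tf_list, seed: int = 0,
                    n_estimators: int = 30, max_depth: int = 5,
                    max_genes: int | None = None, targets=None,
                    importance_min: float = 0.01) -> pd.DataFrame:
    """Weighted TF->gene edges from per-target tree-ensemble regressions.

    For every non-TF gene, an extra-trees regressor predicts its
    log-normalized expression from all TF expressions; normalized feature
    importances above ``importance_min`` become edge weights.  Constant
    target genes yield no edges.  ``targets`` restricts inference to a
    candidate gene list (e.g. the genes of a motif prior); otherwise
    ``max_genes`` caps inference at the highest-variance targets
    (inference cost is linear in targets).
    """
    universe = set(cm.gene_ids)
    tfs = [t for t in tf_list if t in universe]
    if not tfs:
        raise ValueError("no TFs from tf_list present in the universe")
    ln = log_normalize(cm)
    idx = {g: i for i, g in enumerate(cm.gene_ids)}
    X = ln[[idx[t] for t in tfs]].T  # cells x TFs
    if targets is None:
        targets = [g for g in cm.gene_ids if g not in set(tfs)]
    else:
        targets = [g for g in targets if g in universe and g not in set(tfs)]
    if max_genes is not None and len(targets) > max_genes:
        var = ln.var(axis=1)
        targets = sorted(targets, key=lambda g: (-var[idx[g]], g))[:max_genes]
    rows = []
    rng = np.random.default_rng(seed)
    for g in targets:
        y = ln[idx[g]]
        if np.all(y == y[0]):
            continue
        model = ExtraTreesRegressor(
            n_estimators=n_estimators, max_depth=max_depth,
            random_state=int(rng.integers(2**31 - 1)), n_jobs=1,
        )
        model.fit(X, y)
        imp = model.feature_importances_
        s = imp.sum()
        if s <= 0:
            continue
        imp = imp / s
        for ti, tf in enumerate(tfs):
            if imp[ti] >= importance_min and tf != g:
                rows.append(dict(tf=tf, target=g, weight=float(imp[ti])))
    return pd.DataFrame(rows, columns=["tf", "target", "weight"])


def prune_to_regulons(edges: pd.DataFrame, prior: pd.DataFrame | None = None,
                      top_k: int = 50, universe=None) -> RegulonSet:
    """Prune inferred edges into regulons.

    With a ``prior`` table (columns tf, target) only edges present in the
    prior survive — the motif-pruning contract with the motif database
    replaced by an explicit pair list.  Without a prior, the top ``top_k``
    targets per TF by weight are kept.  Empty regulons are dropped.
    """
    if edges.empty:
        warnings.warn("no edges to prune; empty regulon set")
        return RegulonSet({}, provenance="pruned")
    if prior is not None:
        pairs = set(zip(prior["tf"], prior["target"]))
        if universe is not None:
            uni = set(universe)
            outside = {t for _, t in pairs if t not in uni}
            if outside:
                warnings.warn(f"{len(outside)} prior targets outside universe ignored")
            pairs = {(a, b) for a, b in pairs if b in uni}
        kept = edges[[(a, b) in pairs for a, b in zip(edges["tf"], edges["target"])]]
    else:
        kept = (edges.sort_values(["tf", "weight", "target"],
                                  ascending=[True, False, True])
                .groupby("tf", sort=True).head(top_k))
    regs: dict = {}
    for _, r in kept.iterrows():
        regs.setdefault(r["tf"], {})[r["target"]] = float(r["weight"])
    if not regs:
        warnings.warn("pruning removed every edge; empty regulon set")
    return RegulonSet(regs, provenance="pruned")


def score_regulons(cm: CountMatrix, regulons: RegulonSet,
                   top_fraction: float = 0.05) -> ActivityMatrix:
    """AUCell activity of each regulon's target set in each cell."""
    sets = {tf: list(t) for tf, t in regulons.target_sets().items()}
    return score_gene_sets_aucell(cm, sets, top_fraction=top_fraction)


def differential_regulon_activity(activity: ActivityMatrix, labels,
                                  auc_min: float = 0.85,
                                  alpha: float = 0.05) -> pd.DataFrame:
    """Per-cluster Wilcoxon differential regulon activity (AUC > 0.85 rule)."""
    return differential_set_activity(activity, labels, auc_min=auc_min, alpha=alpha)


def find_dual_targeting_tfs(regulons: RegulonSet,
                            query_genes=("CCL4", "CCL3")) -> tuple[list, list]:
    """TFs targeting at least one, and all, of the query genes (sorted)."""
    query = list(query_genes)
    if not query:
        raise ValueError("query_genes must be non-empty")
    any_hit, all_hit = [], []
    for tf, targets in regulons.target_sets().items():
        n = sum(g in targets for g in query)
        if n >= 1:
            any_hit.append(tf)
        if n == len(query):
            all_hit.append(tf)
    return sorted(any_hit), sorted(all_hit)


def partition_targets(regulons: RegulonSet, tf_triple) -> dict:
    """Venn partition of three regulons' targets into 7 disjoint sets.

    Keys: "A-only", "B-only", "C-only", "AB", "AC", "BC", "ABC" where
    (A, B, C) is the given ordered TF triple.
    """
    a, b, c = tf_triple
    sets = regulons.target_sets()
    missing = [t for t in (a, b, c) if t not in sets]
    if missing:
        raise ValueError(f"TFs missing from regulon set: {missing}")
    A, B, C = sets[a], sets[b], sets[c]
    return {
        "A-only": A - B - C,
        "B-only": B - A - C,
        "C-only": C - A - B,
        "AB": (A & B) - C,
        "AC": (A & C) - B,
        "BC": (B & C) - A,
        "ABC": A & B & C,
    }
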