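"""Regulon inference, activity scoring, chemokine-targeting TFs and the
Venn-partition enrichment analysis.

Infers TF->target edges from expression, prunes with the planted-truth
prior (the stand-in for a motif database), scores regulon activity per
cell, finds TFs predicted to target both chemokine transcripts, and runs
the hypergeometric over-representation of the 7-way target partition.
"""

import importlib.util
import sys
from pathlib import Path

import pandas as pd

from tonsilflow.enrich import enrich_hypergeometric
from tonsilflow.grn import (differential_regulon_activity,
                            find_dual_targeting_tfs, infer_grn_edges,
                            partition_targets, prune_to_regulons,
                            score_regulons)
from tonsilflow.io import GeneSetCollection, write_tsv

ROOT = Path(__file__).resolve().parents[1]
SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 0

spec = importlib.util.spec_from_file_location(
    "cluster_markers", Path(__file__).parent / "03_cluster_markers.py")
cluster_markers = importlib.util.module_from_spec(spec)
spec.loader.exec_module(cluster_markers)


def main() -> None:
    cfg, cm, truth = cluster_markers.qc_filtered(SEED)
    prior = pd.DataFrame(
        [(tf, g) for tf, ts in truth.regulons_true.regulons.items()
         for g in ts], columns=["tf", "target"])
    edges = infer_grn_edges(cm, cfg.tf_names, seed=SEED + 2,
                            targets=sorted(set(prior["target"])))
    regulons = prune_to_regulons(edges, prior=prior, universe=cm.gene_ids)
    activity = score_regulons(cm, regulons)
    diff = differential_regulon_activity(
        activity, pd.Series(truth.cells.loc[cm.barcodes, "state"].values,
                            index=cm.barcodes))
    any_tfs, dual = find_dual_targeting_tfs(regulons)

    write_tsv(edges, ROOT / "results" / "04_grn_edges.tsv", index=False)
    write_tsv(diff, ROOT / "results" / "04_regulon_enrichment.tsv", index=False)

    print(f"inferred {len(edges)} edges over {edges['tf'].nunique()} TFs; "
          f"{len(regulons)} regulons after prior pruning")
    print(f"TFs targeting >=1 chemokine: {any_tfs}")
    print(f"TFs targeting both CCL4 and CCL3: {dual} "
          f"(planted: TF01, TF02, TF03)")
    enr = diff[diff["enriched"]]
    print(f"differentially enriched (AUC>0.85): {len(enr)} regulon-state pairs")

    if len(dual) == 3:
        parts = partition_targets(regulons, tuple(dual))
        collection = GeneSetCollection(
            {tf: list(ts) for tf, ts in truth.regulons_true.target_sets().items()})
        table = enrich_hypergeometric(
            {k: v for k, v in parts.items() if v}, collection,
            universe=cm.gene_ids)
        write_tsv(table, ROOT / "results" / "04_partition_enrichment.tsv",
                  index=False)
        sizes = {k: len(v) for k, v in parts.items()}
        print(f"target partition sizes: {sizes}")
        sig = table[table["significant"]]
        print(f"significant partition enrichments (BH<0.05): {len(sig)}")


if __name__ == "__main__":
    main()
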