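"""GC-to-ASC principal-curve pseudotime with spline modeling of gene
expression and regulon activity.

Restricts to the continuum branch, fits the predefined-path principal
curve rooted at the first GC state, tests genes (NB splines, library
offset) and regulon activities (Gaussian splines) for pseudotime
association, smooths the significant fits on a grid and clusters the
curve shapes at the 6-cluster cut.
"""

import importlib.util
import sys
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from tonsilflow.cluster import reduce_pca
from tonsilflow.gam import (cluster_smoothed_curves, smooth_on_grid,
                            test_gene_association, test_regulon_association)
from tonsilflow.grn import score_regulons
from tonsilflow.io import write_tsv
from tonsilflow.normalize import (integrate_donors, normalize_residuals,
                                  select_variable_genes)
from tonsilflow.trajectory import LineageSpec, fit_lineage_curve

ROOT = Path(__file__).resolve().parents[1]
SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 0

spec = importlib.util.spec_from_file_location(
    "cluster_markers", Path(__file__).parent / "03_cluster_markers.py")
cluster_markers = importlib.util.module_from_spec(spec)
spec.loader.exec_module(cluster_markers)


def main() -> None:
    cfg, cm, truth = cluster_markers.qc_filtered(SEED)
    cells = truth.cells.loc[cm.barcodes]
    on = cells["state"].isin(cfg.continuum_states).to_numpy()
    sub = cm.subset(cell_mask=on)
    norm = normalize_residuals(sub)
    norm = integrate_donors(norm, select_variable_genes(norm, 1000))
    coords, _, _ = reduce_pca(norm, n_components=10)

    pt = fit_lineage_curve(coords[:, :2], cells["state"][on].values,
                           LineageSpec(cfg.continuum_states),
                           barcodes=sub.barcodes)
    latent = cells["latent_t"][on].loc[pt.t.index]
    rho = spearmanr(pt.t.to_numpy(), latent.to_numpy()).statistic
    print(f"principal curve: {len(pt.t)} cells, converged={pt.converged} "
          f"in {pt.iterations} iterations; Spearman vs planted latent time "
          f"= {rho:.3f}")

    idx = {b: i for i, b in enumerate(sub.barcodes)}
    cols = [idx[b] for b in pt.t.index]
    counts = pd.DataFrame(sub.counts[:, cols].toarray(),
                          index=sub.gene_ids, columns=pt.t.index)
    gene_res = test_gene_association(counts, pt.t.to_numpy())
    n_tested = int(gene_res.table["p"].notna().sum())
    n_assoc = int(gene_res.table["associated"].fillna(False).sum())
    print(f"gene splines: {n_tested} genes tested, {n_assoc} associated "
          f"at p<0.01")

    act = score_regulons(sub, truth.regulons_true)
    reg_res = test_regulon_association(act.scores[pt.t.index], pt.t.to_numpy())
    n_sig = int(reg_res.table["significant"].fillna(False).sum())
    print(f"regulon splines: {len(reg_res.table)} regulons, {n_sig} "
          f"significant at BH-adjusted p<1e-5")

    curves = smooth_on_grid(reg_res)
    labels = cluster_smoothed_curves(curves, k=6)
    direction = {}
    for tf, d in truth.tf_dynamics.items():
        if d in ("rising", "falling") and tf in curves.values.index:
            v = curves.values.loc[tf]
            direction[tf] = (d, "rising" if v.iloc[-1] > v.iloc[0] else "falling")
    n_ok = sum(a == b for a, b in direction.values())
    print(f"planted dynamic regulons direction-correct: {n_ok}/{len(direction)}")

    write_tsv(pt.t.to_frame(), ROOT / "results" / "05_pseudotime.tsv")
    write_tsv(gene_res.table, ROOT / "results" / "05_gene_association.tsv",
              index=False)
    out = reg_res.table.set_index("feature")
    out["curve_cluster"] = labels.reindex(out.index)
    write_tsv(out.reset_index(), ROOT / "results" / "05_regulon_association.tsv",
              index=False)
    write_tsv(curves.zscored, ROOT / "results" / "05_smoothed_curves.tsv")


if __name__ == "__main__":
    main()
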