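"""One-vs-all marker detection by logistic likelihood-ratio test with a
donor latent variable.

For each cluster, cell membership is regressed on each gene's
log-normalized expression with donor indicator covariates; the LR statistic
against the donor-only null is referred to chi^2(1).  P values are BH
adjusted across genes within each cluster, and markers require
``p_adj < alpha`` and ``log2FC > lfc_min``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datatypes import CountMatrix

__all__ = ["find_markers_lr", "log_normalize"]

_MAX_BETA = 30.0


def log_normalize(cm: CountMatrix, scale: float = 1e4) -> np.ndarray:
    """log1p of depth-normalized counts (genes x cells, dense)."""
    totals = np.asarray(cm.counts.sum(axis=0)).ravel()
    totals[totals == 0] = 1
    return np.log1p(np.asarray(cm.counts.todense()) / totals[None, :] * scale)


def _logit_irls(X: np.ndarray, y: np.ndarray, max_iter: int = 50,
                ridge: float = 1e-8) -> tuple[np.ndarray, float]:
    """Ridge-stabilized IRLS for logistic regression; returns (beta, loglik).

    Coefficients are capped at +-30 so perfectly separating predictors
    converge to a finite (saturated) fit; the log-likelihood, which is what
    the LR test consumes, is unaffected by the cap at that magnitude.
    """
    n, p = X.shape
    beta = np.zeros(p)
    for _ in range(max_iter):
        eta = np.clip(X @ beta, -_MAX_BETA, _MAX_BETA)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = np.maximum(mu * (1 - mu), 1e-10)
        z = eta + (y - mu) / w
        XtW = X.T * w
        H = XtW @ X + ridge * np.eye(p)
        new = np.linalg.solve(H, XtW @ z)
        new = np.clip(new, -_MAX_BETA, _MAX_BETA)
        if np.max(np.abs(new - beta)) < 1e-8:
            beta = new
            break
        beta = new
    eta = np.clip(X @ beta, -_MAX_BETA, _MAX_BETA)
    mu = 1.0 / (1.0 + np.exp(-eta))
    mu = np.clip(mu, 1e-12, 1 - 1e-12)
    ll = float(np.sum(y * np.log(mu) + (1 - y) * np.log(1 - mu)))
    return beta, ll


def find_markers_lr(cm: CountMatrix, labels: pd.Series, donor=None,
                    lfc_min: float = 0.3, alpha: float = 0.01,
                    min_cells: int = 10, min_detect_fraction: float = 0.05,
                    use_donor_covariate: bool = True,
                    return_all: bool = False) -> pd.DataFrame:
    """One-vs-all LR marker test per cluster.

    Genes detected in fewer than ``min_detect_fraction`` of the cluster's
    cells are not tested for that cluster.  Returns rows
    (cluster, gene, log2FC, p, p_adj) satisfying both thresholds (or every
    tested row when ``return_all``).
    """
    labels = pd.Series(np.asarray(labels), index=cm.barcodes)
    donor = np.asarray(donor if donor is not None else cm.donor)
    clusters = sorted(labels.unique())
    if len(clusters) < 2:
        raise ValueError("need at least 2 clusters for one-vs-all testing")
    ln = log_normalize(cm)
    expm1 = np.expm1(ln)
    donor_levels = sorted(set(donor))
    D = np.column_stack(
        [np.ones(cm.n_cells)]
        + ([np.asarray(donor == d, float) for d in donor_levels[1:]]
           if use_donor_covariate else [])
    )
    out = []
    for cl in clusters:
        y = (labels == cl).to_numpy().astype(float)
        n_in = int(y.sum())
        if n_in < min_cells:
            continue
        _, ll0 = _logit_irls(D, y)
        detect = np.asarray((cm.counts[:, y.astype(bool)] > 0).mean(axis=1)).ravel()
        test_genes = np.where(detect >= min_detect_fraction)[0]
        mean_in = expm1[:, y.astype(bool)].mean(axis=1)
        mean_out = expm1[:, ~y.astype(bool)].mean(axis=1)
        lfc = np.log2((mean_in + 1) / (mean_out + 1))
        pvals = np.ones(len(test_genes))
        for j, gi in enumerate(test_genes):
            Xg = np.column_stack([D, ln[gi]])
            _, ll1 = _logit_irls(Xg, y)
            lr = max(0.0, 2 * (ll1 - ll0))
            pvals[j] = stats.chi2.sf(lr, df=1)
        padj = multipletests(pvals, method="fdr_bh")[1] if len(pvals) else pvals
        for j, gi in enumerate(test_genes):
            row = dict(cluster=cl, gene=cm.gene_ids[gi], log2FC=float(lfc[gi]),
                       p=float(pvals[j]), p_adj=float(padj[j]))
            if return_all or (padj[j] < alpha and lfc[gi] > lfc_min):
                out.append(row)
    cols = ["cluster", "gene", "log2FC", "p", "p_adj"]
    df = pd.DataFrame(out, columns=cols)
    return df.sort_values(["cluster", "p_adj", "gene"]).reset_index(drop=True)
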