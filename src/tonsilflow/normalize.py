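"""Regularized negative-binomial (Pearson residual) normalization.

Each gene is modeled as NB with mean ``mu_gc = depth_c * pi_g`` (a log-link
regression of counts on log total counts with unit slope, fitted in closed
form), and a per-gene dispersion ``theta_g`` estimated by moments and then
regularized by kernel smoothing across genes of similar log mean (Silverman
bandwidth).  Residuals ``(x - mu) / sqrt(mu + mu^2/theta)`` are clipped to
``+- sqrt(n_cells)``.
"""

from __future__ import annotations

import warnings

import numpy as np

from .datatypes import CountMatrix, NormalizedMatrix

__all__ = ["normalize_residuals", "select_variable_genes", "integrate_donors"]


def _silverman_bandwidth(x: np.ndarray) -> float:
    n = len(x)
    sd = np.std(x)
    iqr = np.subtract(*np.percentile(x, [75, 25]))
    scale = min(sd, iqr / 1.349) if iqr > 0 else sd
    return max(0.9 * scale * n ** (-1 / 5), 1e-3)


def _smooth_dispersion(log_mean: np.ndarray, theta_raw: np.ndarray) -> np.ndarray:
    """Nadaraya-Watson smoothing of log(theta) over log gene mean."""
    h = _silverman_bandwidth(log_mean)
    lt = np.log(theta_raw)
    # evaluate at each gene; O(G^2) but G is a few thousand
    d = log_mean[:, None] - log_mean[None, :]
    w = np.exp(-0.5 * (d / h) ** 2)
    sm = (w @ lt) / w.sum(axis=1)
    return np.exp(sm)


def normalize_residuals(cm: CountMatrix, theta_max: float = 1e6) -> NormalizedMatrix:
    """Clipped Pearson residuals under the regularized NB model.

    Genes with zero total counts are excluded with a warning.  The clip
    bound is ``sqrt(n_cells)``.
    """
    X = np.asarray(cm.counts.todense(), dtype=float)
    totals = X.sum(axis=0)
    gene_tot = X.sum(axis=1)
    nonzero = gene_tot > 0
    if not nonzero.all():
        warnings.warn(f"{int((~nonzero).sum())} zero-count genes excluded")
    X = X[nonzero]
    gene_ids = cm.gene_ids[nonzero]
    gene_tot = gene_tot[nonzero]

    pi = gene_tot / totals.sum()  # closed-form MLE of the unit-slope log-link fit
    mu = pi[:, None] * totals[None, :]

    # moment estimate of theta: Var = mu + mu^2/theta
    excess = ((X - mu) ** 2 - mu).sum(axis=1)
    denom = (mu ** 2).sum(axis=1)
    with np.errstate(divide="ignore"):
        theta_raw = np.where(excess > 0, denom / np.maximum(excess, 1e-12), theta_max)
    theta_raw = np.clip(theta_raw, 1e-3, theta_max)
    theta = _smooth_dispersion(np.log(pi * totals.mean()), theta_raw)

    sd = np.sqrt(mu + mu ** 2 / theta[:, None])
    clip = float(np.sqrt(cm.n_cells))
    resid = np.clip((X - mu) / sd, -clip, clip)
    return NormalizedMatrix(resid, gene_ids, cm.barcodes, cm.donor, clip)


def select_variable_genes(norm: NormalizedMatrix, n: int = 3000) -> np.ndarray:
    """Top-``n`` genes per donor by residual variance; union over donors.

    Ties break deterministically by gene ID.  If fewer than ``n`` genes are
    available all are returned with a warning.
    """
    donors = sorted(set(norm.donor))
    if n > len(norm.gene_ids):
        warnings.warn("requested more variable genes than available; returning all")
        return np.array(sorted(norm.gene_ids), dtype=object)
    chosen: set = set()
    for d in donors:
        cols = norm.donor == d
        var = norm.values[:, cols].var(axis=1)
        order = sorted(range(len(var)), key=lambda i: (-var[i], str(norm.gene_ids[i])))
        chosen.update(norm.gene_ids[i] for i in order[:n])
    return np.array(sorted(chosen), dtype=object)


def integrate_donors(norm: NormalizedMatrix, variable_genes=None) -> NormalizedMatrix:
    """Simplified batch correction: per-donor center/rescale of residuals.

    For every gene (restricted to ``variable_genes`` when given, otherwise
    all genes) each donor's residuals are centered to mean 0 and rescaled to
    the pooled across-donor SD.  A single donor is an identity transform.
    """
    donors = sorted(set(norm.donor))
    values = norm.values.copy()
    if variable_genes is None:
        rows = np.arange(len(norm.gene_ids))
    else:
        idx = {g: i for i, g in enumerate(norm.gene_ids)}
        rows = np.array([idx[g] for g in variable_genes if g in idx], dtype=int)
    if len(donors) >= 2:
        for d in donors:
            if (norm.donor == d).sum() < 2:
                raise ValueError(f"donor {d} has fewer than 2 cells")
        pooled_sd = values[rows].std(axis=1, ddof=0)
        for d in donors:
            cols = norm.donor == d
            block = values[np.ix_(rows, np.where(cols)[0])]
            m = block.mean(axis=1, keepdims=True)
            s = block.std(axis=1, ddof=0, keepdims=True)
            s[s == 0] = 1.0
            scaled = (block - m) / s * pooled_sd[:, None]
            values[np.ix_(rows, np.where(cols)[0])] = scaled
    clip = max(norm.clip_bound, float(np.abs(values).max()) if values.size else 0.0)
    return NormalizedMatrix(values, norm.gene_ids, norm.barcodes, norm.donor,
                            clip, norm.variable_genes if variable_genes is None
                            else np.asarray(variable_genes, dtype=object))
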