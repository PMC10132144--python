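"""Predefined-path principal-curve pseudotime.

A single lineage is specified as an ordered cluster path with a named root.
The curve is fitted by Hastie-Stuetzle alternation: initialize with the
polyline through the path clusters' centroids, then repeat {project cells
onto the curve, smooth each embedding coordinate against arc-length,
reparameterize by arc length} until the mean squared projection distance
stabilizes.  Pseudotime is the arc-length position of each cell's
projection, oriented so the root cluster has the lower mean.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import make_smoothing_spline

__all__ = ["LineageSpec", "PseudotimeAssignment", "fit_lineage_curve"]


@dataclass
class LineageSpec:
    """Ordered cluster path defining one lineage; the root is the first element."""

    path: tuple
    root_cluster: str | None = None

    def __post_init__(self) -> None:
        self.path = tuple(self.path)
        if len(self.path) < 2:
            raise ValueError("lineage path needs at least 2 clusters")
        if self.root_cluster is None:
            self.root_cluster = self.path[0]
        if self.root_cluster != self.path[0]:
            raise ValueError("root cluster must be the first path element")


@dataclass
class PseudotimeAssignment:
    """Arc-length pseudotime for on-lineage cells plus the fitted curve."""

    t: pd.Series  # index = on-lineage barcodes, arc-length position >= 0
    curve: np.ndarray  # ordered polyline points in embedding space
    converged: bool
    iterations: int
    lineage: LineageSpec = field(default=None)


def _project_to_polyline(points: np.ndarray, poly: np.ndarray):
    """Project points onto a polyline; return (arc_length, sq_distance)."""
    seg_vec = np.diff(poly, axis=0)  # S x d
    seg_len = np.linalg.norm(seg_vec, axis=1)
    seg_len = np.maximum(seg_len, 1e-12)
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    # points x segments projection parameter, clipped to the segment
    diff = points[:, None, :] - poly[None, :-1, :]  # P x S x d
    tau = np.einsum("psd,sd->ps", diff, seg_vec) / (seg_len ** 2)[None, :]
    tau = np.clip(tau, 0.0, 1.0)
    proj = poly[None, :-1, :] + tau[:, :, None] * seg_vec[None, :, :]
    d2 = ((points[:, None, :] - proj) ** 2).sum(axis=2)
    best = np.argmin(d2, axis=1)
    rows = np.arange(len(points))
    arc = cum[best] + tau[rows, best] * seg_len[best]
    return arc, d2[rows, best]


def _smooth_coordinates(t: np.ndarray, points: np.ndarray, grid_size: int = 120):
    """Smooth each coordinate against t and return the new polyline."""
    order = np.argsort(t, kind="stable")
    ts, ps = t[order], points[order]
    # collapse duplicate t (smoothing spline needs strictly increasing x)
    uniq, inv = np.unique(np.round(ts, 10), return_inverse=True)
    if len(uniq) < 4:
        raise ValueError("degenerate input: too few distinct projections")
    avg = np.zeros((len(uniq), points.shape[1]))
    for j in range(points.shape[1]):
        avg[:, j] = np.bincount(inv, weights=ps[:, j]) / np.bincount(inv)
    grid = np.linspace(uniq[0], uniq[-1], grid_size)
    new = np.empty((grid_size, points.shape[1]))
    for j in range(points.shape[1]):
        try:
            spl = make_smoothing_spline(uniq, avg[:, j])
        except Exception:  # tiny lineages: fall back to local-linear fit
            coef = np.polyfit(uniq, avg[:, j], 1)
            new[:, j] = np.polyval(coef, grid)
            continue
        new[:, j] = spl(grid)
    return new


def fit_lineage_curve(embedding: np.ndarray, labels: pd.Series,
                      lineage: LineageSpec, tol: float = 1e-4,
                      max_iter: int = 50, min_cells: int = 50,
                      barcodes=None) -> PseudotimeAssignment:
    """Fit the principal curve for one predefined lineage.

    ``embedding`` is cells x 2 (any low-dimensional embedding); only cells
    whose cluster is on the lineage path are used.  Pseudotime is oriented
    so the root cluster's mean precedes the terminal cluster's mean.
    """
    labels = pd.Series(np.asarray(labels),
                       index=barcodes if barcodes is not None else range(len(labels)))
    missing = [c for c in lineage.path if c not in set(labels)]
    if missing:
        raise ValueError(f"lineage clusters not present in labels: {missing}")
    on = labels.isin(lineage.path).to_numpy()
    pts = np.asarray(embedding, float)[on]
    cell_ids = labels.index[on]
    lab_on = labels[on].to_numpy()
    if len(pts) < min_cells:
        raise ValueError(f"only {len(pts)} cells on lineage (< {min_cells})")
    if np.allclose(pts, pts[0]):
        raise ValueError("degenerate embedding: all on-lineage points identical")

    centroids = np.array([pts[lab_on == c].mean(axis=0) for c in lineage.path])
    poly = _densify(centroids, 20)
    arc, d2 = _project_to_polyline(pts, poly)
    prev = d2.mean()
    # scale-free convergence: change in mean sq projection distance relative
    # to the total embedding variance (the GCV smoother re-tunes its penalty
    # every pass, so the raw distance carries a small jitter floor)
    scale = max(float(pts.var(axis=0).sum()), 1e-12)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        poly = _smooth_coordinates(arc, pts)
        poly = _reparam_arclength(poly)
        arc, d2 = _project_to_polyline(pts, poly)
        cur = d2.mean()
        if abs(prev - cur) < tol * scale:
            converged = True
            break
        prev = cur
    if not converged:
        warnings.warn(f"principal curve did not converge in {max_iter} iterations")

    root_mean = arc[lab_on == lineage.path[0]].mean()
    term_mean = arc[lab_on == lineage.path[-1]].mean()
    if root_mean > term_mean:
        total = _polyline_length(poly)
        arc = total - arc
        poly = poly[::-1]
    t = pd.Series(arc, index=cell_ids, name="pseudotime")
    return PseudotimeAssignment(t, poly, converged, it, lineage)


def _densify(poly: np.ndarray, per_segment: int) -> np.ndarray:
    out = []
    for a, b in zip(poly[:-1], poly[1:]):
        for s in np.linspace(0, 1, per_segment, endpoint=False):
            out.append(a + s * (b - a))
    out.append(poly[-1])
    return np.asarray(out)


def _polyline_length(poly: np.ndarray) -> float:
    return float(np.linalg.norm(np.diff(poly, axis=0), axis=1).sum())


def _reparam_arclength(poly: np.ndarray, n: int = 120) -> np.ndarray:
    seg = np.linalg.norm(np.diff(poly, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    if cum[-1] <= 0:
        return poly
    grid = np.linspace(0, cum[-1], n)
    out = np.empty((n, poly.shape[1]))
    for j in range(poly.shape[1]):
        out[:, j] = np.interp(grid, cum, poly[:, j])
    return out
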