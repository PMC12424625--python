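"""Statistical testing of ridges, overlap removal and final thresholding.

Each ridge point contributes a local enrichment ratio — the mean pixel value
of a width-wide box centered on the point divided by the mean of its two
lateral flanking boxes — sampled once from the observed strip and once from
the null strip (the column-correlation image, which preserves banding but no
jet-specific center-over-flank enrichment).  A one-sided two-sample
Kolmogorov-Smirnov test asks whether the observed ratios are stochastically
larger than the null ratios; the statistic is sup_t F_null(t) - F_obs(t) and
the p-value uses the asymptotic one-sided form exp(-2 d^2 n m / (n + m)).

Overlapping ridges (detected at multiple scales) are deduplicated greedily by
p-value minimization: ridges whose 7-pixel-buffered footprints overlap with
IoU above 0.05 form a group, of which only the lowest-p member survives.
Benjamini-Hochberg correction and the saliency-percentile gate come last.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from shapely.geometry import MultiPoint
from statsmodels.stats.multitest import multipletests


@dataclass
class BoxTriplet:
    center: np.ndarray
    left: np.ndarray
    right: np.ndarray


def extract_boxes(strip_pixels: np.ndarray, point, width: float, angle_deg: float) -> BoxTriplet:
    """Sample center / left / right boxes at a ridge point.

    The center box is ``width`` pixels long, 1 pixel high, centered on the
    point and aligned with the ridge *normal* (so a vertical ridge at 90
    degrees gets a horizontal row of pixels); the flanks are the center box
    translated by one box width along the normal on each side.  Pixels are
    gathered by nearest-pixel rasterization; out-of-strip portions are
    dropped.
    """
    img = np.asarray(strip_pixels, dtype=float)
    m, n = img.shape
    y0, x0 = float(point[0]), float(point[1])
    w = max(1, int(round(width)))
    theta = math.radians(angle_deg)
    # normal = tangent rotated by 90 degrees
    nx_, ny_ = -math.sin(theta), math.cos(theta)
    offsets = np.arange(w, dtype=float) - (w - 1) / 2.0

    def gather(shift):
        ys = np.round(y0 + (offsets + shift) * ny_).astype(int)
        xs = np.round(x0 + (offsets + shift) * nx_).astype(int)
        ok = (ys >= 0) & (ys < m) & (xs >= 0) & (xs < n)
        return img[ys[ok], xs[ok]]

    return BoxTriplet(center=gather(0.0), left=gather(-float(w)), right=gather(float(w)))


def enrichment_ratio(triplet: BoxTriplet) -> Optional[float]:
    """mean(center) / mean(left u right); None when undefined (empty boxes or
    zero flank mean), in which case the point is skipped."""
    flank = np.concatenate([triplet.left, triplet.right])
    if triplet.center.size == 0 or flank.size == 0:
        return None
    fm = float(flank.mean())
    if fm == 0.0:
        return None
    return float(triplet.center.mean()) / fm


def ridge_ratios(ridge, obs_pixels: np.ndarray, null_pixels: np.ndarray):
    """Observed and null enrichment-ratio vectors for one ridge (identical box
    geometry on both strips; points with undefined ratios are skipped)."""
    t_obs, t_null = [], []
    for i in range(ridge.n_points):
        pt = ridge.points[i]
        w = ridge.widths[i]
        ang = ridge.angles[i]
        ro = enrichment_ratio(extract_boxes(obs_pixels, pt, w, ang))
        rn = enrichment_ratio(extract_boxes(null_pixels, pt, w, ang))
        if ro is None or rn is None:
            continue
        t_obs.append(ro)
        t_null.append(rn)
    return np.asarray(t_obs), np.asarray(t_null)


def ks_pvalue(t_obs: np.ndarray, t_null: np.ndarray):
    """One-sided two-sample KS test that the observed ratios are
    stochastically larger.

    Returns (KS, p) with KS = sup_t F_null(t) - F_obs(t) and the asymptotic
    p = exp(-2 KS^2 n m / (n + m)), clipped to [0, 1]; degenerate inputs
    (fewer than 2 values) give p = 1 with a warning.
    """
    t_obs = np.asarray(t_obs, dtype=float)
    t_null = np.asarray(t_null, dtype=float)
    n, m_ = t_obs.size, t_null.size
    if n < 2 or m_ < 2:
        warnings.warn("too few enrichment ratios for a KS test; p set to 1")
        return 0.0, 1.0
    grid = np.concatenate([t_obs, t_null])
    f_obs = np.searchsorted(np.sort(t_obs), grid, side="right") / n
    f_null = np.searchsorted(np.sort(t_null), grid, side="right") / m_
    ks = float(np.max(f_null - f_obs))
    if ks <= 0:
        return max(ks, 0.0), 1.0
    p = math.exp(-2.0 * ks * ks * n * m_ / (n + m_))
    return ks, min(p, 1.0)


def _buffered(points: np.ndarray, radius: float):
    return MultiPoint([tuple(p[::-1]) for p in np.atleast_2d(points)]).buffer(radius)


def buffered_iou(points_a: np.ndarray, points_b: np.ndarray, radius: float = 7.0) -> float:
    """Area IoU of the two point sets buffered by Euclidean disks of the given
    radius."""
    A = _buffered(points_a, radius)
    B = _buffered(points_b, radius)
    union = A.union(B).area
    if union == 0:
        return 0.0
    return A.intersection(B).area / union


def remove_overlaps(ridges: Sequence, pvalues: Sequence[float],
                    saliencies: Optional[Sequence[float]] = None,
                    radius: float = 7.0, iou_threshold: float = 0.05) -> list:
    """Greedy overlap removal by p-value minimization.

    Iterating over ridges in input order, each unremoved ridge gathers the
    ridges having any point within ``radius`` of its own points; pairs whose
    ``radius``-buffered footprints overlap with IoU above ``iou_threshold``
    join its group, and only the group's lowest-p ridge is kept (ties broken
    by higher saliency, then lower index).  Returns the kept index list.
    """
    J = len(ridges)
    pvals = np.asarray(pvalues, dtype=float)
    sal = np.asarray(saliencies, dtype=float) if saliencies is not None else np.zeros(J)
    pts = [np.atleast_2d(r.points if hasattr(r, "points") else r) for r in ridges]
    buffered = [None] * J  # built lazily; polygon ops dominate the cost
    # bounding boxes, inflated by the radius, prune far-apart pairs cheaply
    lo = np.array([p.min(axis=0) for p in pts]) - radius
    hi = np.array([p.max(axis=0) for p in pts]) + radius

    def poly(j):
        if buffered[j] is None:
            buffered[j] = _buffered(pts[j], radius)
        return buffered[j]

    removed = set()
    kept = []
    for j in range(J):
        if j in removed:
            continue
        group = [j]
        near = np.flatnonzero(np.all((lo[j] <= hi) & (lo <= hi[j]), axis=1))
        for t in near:
            t = int(t)
            if t == j or t in removed:
                continue
            # candidate: any point of Z_t within radius of any point of Z_j
            d2 = ((pts[j][:, None, :] - pts[t][None, :, :]) ** 2).sum(axis=2)
            if d2.min() > radius * radius:
                continue
            union = poly(j).union(poly(t)).area
            iou = poly(j).intersection(poly(t)).area / union if union else 0.0
            if iou > iou_threshold:
                group.append(t)
        best = min(group, key=lambda t: (pvals[t], -sal[t], t))
        if best not in kept:
            kept.append(best)
        removed.update(set(group) - {best})
    return kept


def bh_correct(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def final_threshold(p_corrected, saliencies, alpha: float,
                    saliency_thresh_percentile: float) -> np.ndarray:
    """Indices of jets passing both gates: corrected p <= alpha and saliency
    at or above the given percentile of the candidate saliency distribution."""
    p = np.asarray(p_corrected, dtype=float)
    s = np.asarray(saliencies, dtype=float)
    if p.size == 0:
        return np.array([], dtype=int)
    cut = np.percentile(s, saliency_thresh_percentile)
    return np.flatnonzero((p <= alpha) & (s >= cut))
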