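"""Ridge quantification: normalized entropy, normalized RMSE of the expected
scale, jet saliency, summary metrics, and the quantification filters.

Entropy flags conflicting structures in scale space (a stripe at small scale
under a TAD at large scale makes the per-position mean ridge strength
multimodal); the RMSE flags abrupt scale changes along the ridge, which a
genuine jet — diffusing slowly as it leaves the diagonal — does not show.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .ridge_tracing import Ridge


@dataclass
class EntropyBinning:
    points_min: float = 0.0
    points_max: Optional[float] = None   # None: max mean strength over the ridge set
    num_bins: int = 32
    bin_size: Optional[float] = None


def mean_strength(ridge: Ridge) -> np.ndarray:
    """Per-position ridge strength averaged over all scales (lambda-bar)."""
    lam = ridge.samples.get("Lambda")
    if lam is None:
        raise ValueError("ridge lacks per-scale strength samples")
    return lam.mean(axis=1)


def normalized_entropy(ridge: Ridge, binning: EntropyBinning) -> float:
    """Normalized Shannon entropy of the histogram of mean ridge strength.

    H_norm = -(1/log2 q) * sum_k P(k) log2 P(k), with 0*log 0 := 0; 0 for a
    point mass, 1 for a uniform occupancy of the q bins.
    """
    lam_bar = mean_strength(ridge)
    lo = binning.points_min
    hi = binning.points_max if binning.points_max is not None else float(lam_bar.max())
    if hi <= lo:
        hi = lo + 1.0
    if binning.bin_size is not None:
        q = max(1, int(math.ceil((hi - lo) / binning.bin_size)))
    else:
        q = int(binning.num_bins)
    if q < 2:
        raise ValueError("entropy binning needs at least 2 bins")
    counts, _ = np.histogram(lam_bar, bins=q, range=(lo, hi))
    total = counts.sum()
    if total == 0:
        return 0.0
    P = counts / total
    nz = P[P > 0]
    return float(-(nz * np.log2(nz)).sum() / math.log2(q))


def expected_scales(ridge: Ridge, scales: np.ndarray) -> np.ndarray:
    """Expected scale per position: s-bar_i = sum_s s * Q_i(s), where Q_i is
    the strength PMF across scales (uniform where all strengths are zero)."""
    lam = ridge.samples.get("Lambda")
    if lam is None:
        raise ValueError("ridge lacks per-scale strength samples")
    scales = np.asarray(scales, dtype=float)
    tot = lam.sum(axis=1, keepdims=True)
    k = lam.shape[1]
    Q = np.where(tot > 0, lam / np.where(tot > 0, tot, 1.0), 1.0 / k)
    if np.any(tot == 0):
        ridge.flags["uniform_scale_pmf"] = True
    return Q @ scales


def normalized_rmse(ridge: Ridge, scales: np.ndarray) -> float:
    """RMSE of a least-squares cubic fit to the expected scales, divided by
    the ridge length N (cubic degree reduced for N <= 4, so short ridges fit
    exactly and score 0)."""
    s_bar = expected_scales(ridge, scales)
    n = len(s_bar)
    deg = min(3, n - 1)
    idx = np.arange(n, dtype=float)
    coeffs = np.polyfit(idx, s_bar, deg)
    s_hat = np.polyval(coeffs, idx)
    rmse = math.sqrt(float(np.mean((s_bar - s_hat) ** 2)))
    return rmse / n


def _parse_sum_cond(sum_cond: str) -> set:
    parts = [p for p in sum_cond.split("-") if p]
    if not parts or any(p not in ("a", "r", "c") for p in parts) or len(set(parts)) != len(parts):
        raise ValueError(f"malformed sum_cond {sum_cond!r}: expected subset of a,r,c joined by '-'")
    return set(parts)


def saliency_weights(ridge: Ridge, angle_range=(60.0, 120.0), ang_frac: bool = True,
                     sum_cond: str = "a-r-c") -> np.ndarray:
    """Per-point weights alpha_i in [0, 1].

    alpha^R = 1{ridge condition holds at s*}; alpha^C = 1{no corner at s*};
    alpha^theta = 1{angle at s* in range} times the fraction of scales whose
    angle is in range (dropped when ang_frac is off).  ``sum_cond`` selects
    which factors multiply in (a=angle, r=ridge, c=corner).
    """
    selected = _parse_sum_cond(sum_cond)
    n = ridge.n_points
    lb, ub = angle_range
    alpha = np.ones(n)
    if "r" in selected:
        r = ridge.samples["R"][:, ridge.scale_index].astype(float)
        alpha = alpha * r
    if "c" in selected:
        c = ridge.samples["C"][:, ridge.scale_index].astype(float)
        alpha = alpha * (1.0 - c)
    if "a" in selected:
        theta_all = ridge.samples["Theta"]
        th = theta_all[:, ridge.scale_index]
        a = ((th >= lb) & (th <= ub)).astype(float)
        if ang_frac:
            frac = ((theta_all >= lb) & (theta_all <= ub)).mean(axis=1)
            a = a * frac
        alpha = alpha * a
    return alpha


def jet_saliency(ridge: Ridge, angle_range=(60.0, 120.0), ang_frac: bool = True,
                 sum_cond: str = "a-r-c", agg: str = "sum") -> float:
    """Weighted aggregate of the ridge strength at the detected scale."""
    alpha = saliency_weights(ridge, angle_range, ang_frac, sum_cond)
    lam = ridge.samples["Lambda"][:, ridge.scale_index]
    weighted = alpha * lam
    if agg == "sum":
        return float(weighted.sum())
    if agg == "mean":
        return float(weighted.mean())
    raise ValueError(f"unknown agg {agg!r}; expected 'sum' or 'mean'")


def summary_metrics(ridge: Ridge, image: np.ndarray) -> dict:
    """Genomic span and per-ridge means.

    ``end_bp`` reproduces the (max x') * resolution convention of the summary
    table; ``end_bp_halfopen`` adds one bin for BED-style half-open intervals.
    """
    if ridge.shifted_x is None:
        raise ValueError("ridge has no shifted coordinates")
    res = ridge.resolution
    xs = np.round(ridge.shifted_x).astype(int)
    yi = np.clip(np.round(ridge.points[:, 0]).astype(int), 0, image.shape[0] - 1)
    xi = np.clip(np.round(ridge.points[:, 1]).astype(int), 0, image.shape[1] - 1)
    theta = (ridge.samples["Theta"][:, ridge.scale_index]
             if "Theta" in ridge.samples else ridge.angles)
    return {
        "start_bp": int(xs.min()) * res,
        "end_bp": int(xs.max()) * res,
        "end_bp_halfopen": (int(xs.max()) + 1) * res,
        "length_bp": ridge.n_points * res,
        "input_mean": float(np.mean(image[yi, xi])),
        "angle_mean": float(np.mean(theta)),
        "width_mean": float(np.mean(ridge.widths)),
    }


def filter_quant(ridges, entropies, rmses, entropy_thresh: float, rmse_thresh: float):
    """Drop ridges with entropy or RMSE strictly above their thresholds.

    Returns the indices of the survivors.
    """
    keep = [i for i in range(len(ridges))
            if not (entropies[i] > entropy_thresh or rmses[i] > rmse_thresh)]
    return keep
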