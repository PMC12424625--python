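"""Ridge post-processing: ordering, diagonal filters, coordinate shifting and
the four trimming criteria (corner, angle, smallest-eigenvalue, whitespace).

Ridge points are indexed from the main diagonal outwards: position 0 is the
point closest to the diagonal.  Every trim identifies the first offending
position i* and keeps the prefix before it; a trim may be blocked by a policy
floor (a minimum ridge length in bins when the parameter exceeds 1, or a
protected leading fraction when it lies in [0, 1]).  Whitespace trimming is
the one exception that may keep the suffix instead, since the offending side
is the one that crossed a large unmappable gap.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .ridge_tracing import Ridge


@dataclass
class TrimPolicy:
    """Trimming parameters.

    ``corner_trim`` / ``angle_trim`` / ``eig2_trim``: None disables the trim;
    a value > 1 is a minimum ridge length in bins; a value in [0, 1] protects
    that leading fraction of the ridge from trimming.
    """

    corner_trim: Optional[float] = 2.0
    angle_trim: Optional[float] = 2.0
    eig2_trim: Optional[float] = 2.0
    angle_range: tuple = (60.0, 120.0)
    rem_k_strata: int = 2
    root_within: Optional[float] = None
    whitespace_shift_bins: float = 5.0
    # "psi turns negative" uses a relative tolerance: on sampled images psi
    # fluctuates numerically around zero along a coherent ridge, so a cut
    # requires psi below -psi_tol_frac times the ridge's peak strength.
    psi_tol_frac: float = 0.05

    def __post_init__(self):
        lb, ub = self.angle_range
        if not lb < ub:
            raise ValueError("angle_range must satisfy lb < ub")

    def floor_index(self, param: Optional[float], n: int) -> int:
        """Smallest trim index allowed for a ridge of n points: the trim index
        i* must satisfy i* >= floor_index, else the trim is blocked."""
        if param is None:
            return 0
        if param > 1:
            return int(param)
        return int(math.ceil(param * n))


def _apply_prefix_trim(ridge: Ridge, i_star: Optional[int], param: Optional[float],
                       policy: TrimPolicy) -> Optional[Ridge]:
    """Keep positions [0, i_star); block the trim if it would cut into the
    policy floor; drop the ridge if fewer than 2 points survive."""
    n = ridge.n_points
    if i_star is None or i_star >= n:
        return ridge
    if i_star < policy.floor_index(param, n):
        return ridge  # blocked by floor
    if i_star < 2:
        return None
    return ridge.take(np.arange(i_star))


def normalize_and_order(ridge: Ridge) -> Ridge:
    """Wrap angles to [0, 180) and order points by ascending genomic distance
    from the diagonal (descending strip row); ties by descending column.

    Traced paths are contiguous, so ordering reduces to possibly reversing the
    path; a full re-sort is applied otherwise.  Ridges whose column sequence
    is not monotone non-increasing after ordering are flagged as curved.
    """
    ridge.angles = np.mod(ridge.angles, 180.0)
    y = ridge.points[:, 0]
    x = ridge.points[:, 1]
    n = ridge.n_points
    if n >= 2:
        if y[0] < y[-1]:          # tip-first: reverse
            ridge = ridge.take(np.arange(n)[::-1])
        elif not np.all(np.diff(ridge.points[:, 0]) <= 0):
            order = np.lexsort((-ridge.points[:, 1], -ridge.points[:, 0]))
            ridge = ridge.take(order)
    if not np.all(np.diff(ridge.points[:, 1]) <= 1e-9):
        ridge.curved = True
    return ridge


def filter_points(ridge: Ridge, policy: TrimPolicy, strip_shape: tuple) -> Optional[Ridge]:
    """Drop points outside the map or within ``rem_k_strata`` pixels of the
    diagonal; discard the ridge if <= 1 point remains or (with ``root_within``
    set) its nearest point is farther than ``root_within`` pixels from the
    diagonal."""
    m, n = strip_shape
    y = ridge.points[:, 0]
    x = ridge.points[:, 1]
    dist = (m - 1) - y                       # genomic distance in pixels
    keep = (x >= 0) & (x <= n - 1) & (y >= 0) & (y <= m - 1) & (dist >= policy.rem_k_strata)
    if keep.sum() <= 1:
        return None
    ridge = ridge.take(np.flatnonzero(keep))
    if policy.root_within is not None:
        min_dist = np.min((m - 1) - ridge.points[:, 0])
        if min_dist > policy.root_within:
            return None
    return ridge


def shift_to_genomic(ridge: Ridge, retained_bins, strip_shape: tuple) -> Ridge:
    """Attach bin-shifted x coordinates.

    Each point (y, x) corresponds to the reduced bin pair (x - d/2, x + d/2)
    with d = (m-1) - y; both bins are mapped through ``retained_bins`` and the
    shifted x is their original-coordinate midpoint.
    """
    rb = np.asarray(retained_bins, dtype=int)
    m, _ = strip_shape
    y = ridge.points[:, 0]
    x = ridge.points[:, 1]
    d = (m - 1) - y
    i = np.clip(np.round(x - d / 2.0).astype(int), 0, len(rb) - 1)
    j = np.clip(np.round(x + d / 2.0).astype(int), 0, len(rb) - 1)
    ridge.shifted_x = (rb[i] + rb[j]) / 2.0
    return ridge


def relative_shifts(ridge: Ridge) -> np.ndarray:
    """d-bar: per-point shift deltas relative to the first point (invariant to
    any global shift)."""
    if ridge.shifted_x is None:
        raise ValueError("ridge has no shifted coordinates; call shift_to_genomic first")
    d = ridge.points[:, 1] - ridge.shifted_x
    return d - d[0]


def trim_corner(ridge: Ridge, policy: TrimPolicy) -> Optional[Ridge]:
    """Trim at the first position where a corner is detected at *every* scale.

    The saddle definition fires often at single scales, so a genuine corner
    must persist across the whole grid.
    """
    if policy.corner_trim is None:
        return ridge
    c = ridge.samples.get("C")
    if c is None:
        raise ValueError("ridge lacks per-scale corner samples")
    all_scales = np.all(c, axis=1)
    hits = np.flatnonzero(all_scales)
    i_star = int(hits[0]) if hits.size else None
    return _apply_prefix_trim(ridge, i_star, policy.corner_trim, policy)


def trim_angle(ridge: Ridge, policy: TrimPolicy) -> Optional[Ridge]:
    """Trim at the first position whose tangent angle at the detected scale
    leaves ``angle_range``."""
    if policy.angle_trim is None:
        return ridge
    theta = ridge.samples.get("Theta")
    if theta is None:
        raise ValueError("ridge lacks per-scale angle samples")
    th = theta[:, ridge.scale_index]
    lb, ub = policy.angle_range
    bad = np.flatnonzero((th < lb) | (th > ub))
    i_star = int(bad[0]) if bad.size else None
    return _apply_prefix_trim(ridge, i_star, policy.angle_trim, policy)


def first_nonneg_peak(psi: np.ndarray) -> int:
    """Index of the first non-negative strict interior local maximum of psi;
    the global argmax if there is no interior maximum; 0 if all interior
    maxima are negative."""
    n = len(psi)
    interior = [i for i in range(1, n - 1) if psi[i] > psi[i - 1] and psi[i] > psi[i + 1]]
    nonneg = [i for i in interior if psi[i] >= 0]
    if nonneg:
        return nonneg[0]
    if not interior:
        return int(np.argmax(psi))
    return 0


def trim_eigenvalue(ridge: Ridge, policy: TrimPolicy) -> Optional[Ridge]:
    """Trim where the smallest eigenvalue turns negative after its first
    non-negative peak — the point where a coherent ridge gives way to another
    structure."""
    if policy.eig2_trim is None:
        return ridge
    psi_all = ridge.samples.get("Psi")
    if psi_all is None:
        raise ValueError("ridge lacks per-scale eigenvalue samples")
    psi = psi_all[:, ridge.scale_index]
    lam = ridge.samples.get("Lambda")
    peak_strength = float(np.max(np.abs(lam[:, ridge.scale_index]))) if lam is not None else 0.0
    eps = policy.psi_tol_frac * peak_strength
    i_peak = first_nonneg_peak(psi)
    neg = np.flatnonzero(psi[i_peak:] < -eps)
    i_star = int(i_peak + neg[0]) if neg.size else None
    return _apply_prefix_trim(ridge, i_star, policy.eig2_trim, policy)


def trim_whitespace(ridge: Ridge, image: np.ndarray, policy: TrimPolicy) -> Optional[Ridge]:
    """Trim the side of the ridge that jumped across a large unmappable gap.

    The first position whose relative shift reaches ``whitespace_shift_bins``
    splits the ridge into a head (before) and tip (from there on); the side
    whose pixel intensities all lie below the image's 25th-percentile positive
    value — the estimated background — is removed (a single-point side is
    removed regardless).  If neither side qualifies the ridge is left alone.
    """
    dbar = np.abs(relative_shifts(ridge))
    hits = np.flatnonzero(dbar >= policy.whitespace_shift_bins)
    if hits.size == 0:
        return ridge
    i0 = int(hits[0])
    if i0 == 0:
        return ridge
    img = np.asarray(image, dtype=float)
    pos = img[img > 0]
    v25 = np.percentile(pos, 25) if pos.size else 0.0
    yi = np.clip(np.round(ridge.points[:, 0]).astype(int), 0, img.shape[0] - 1)
    xi = np.clip(np.round(ridge.points[:, 1]).astype(int), 0, img.shape[1] - 1)
    inten = img[yi, xi]
    head = np.arange(i0)
    tip = np.arange(i0, ridge.n_points)
    if np.all(inten[head] < v25) or head.size == 1:
        kept = tip
    elif np.all(inten[tip] < v25) or tip.size == 1:
        kept = head
    else:
        return ridge
    if kept.size <= 1:
        return None
    return ridge.take(kept)
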