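"""Scale grid and gamma-normalized Hessian feature maps.

The scale space of a strip image is the family of Gaussian blurs I(s).
Derivatives are normalized by s^(gamma * order) so that the response of a
structure peaks at the scale matching its size: for a bright Gaussian bar of
cross-section sigma0, the crest ridge strength is maximized at
s^2 = 2*gamma*sigma0^2 / (3 - 2*gamma), i.e. exactly s = sigma0 for the
default gamma = 0.75.

Sign convention: bright ridges have negative curvature across the crest, so
all eigen maps are computed on the *negated* Hessian -H.  The principal
eigenvalue of -H (clipped at 0) is the ridge strength Lambda; its eigenvector
is the ridge normal, and adding 90 degrees gives the tangent angle Theta in
[0, 180).  Psi is the second eigenvalue of -H, positive along a coherent
fading ridge and negative where the profile curls the other way.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage

LOG_BASE = 1.5
DELTA = 0.25           # log-grid resolution
MIN_SCALES = 3
MAX_SCALES = 30
DEFAULT_START = 1.0    # default grid: LOG_BASE**1 .. LOG_BASE**7, 24 points
DEFAULT_STOP = 7.0
DEFAULT_NUM = 24


def width_to_scale(b: float) -> float:
    """Convert an expected line width in pixels to a blurring scale (sigma).

    Uses the ridge-detection convention s = b / (2*sqrt(3)) + 0.5, the sigma
    at which a bar of width b produces the strongest second-derivative
    response.
    """
    if b < 0:
        raise ValueError("width must be non-negative")
    return b / (2.0 * math.sqrt(3.0)) + 0.5


def scale_to_width(s: float) -> float:
    """Inverse of :func:`width_to_scale` (clipped at zero width)."""
    return max(0.0, 2.0 * math.sqrt(3.0) * (s - 0.5))


@dataclass
class ScaleGrid:
    scales: np.ndarray
    gamma: float = 0.75
    source: str = "default"

    def __post_init__(self):
        self.scales = np.asarray(self.scales, dtype=float)
        if len(self.scales) == 0:
            raise ValueError("empty scale grid")
        if np.any(np.diff(self.scales) < 0):
            raise ValueError("scales must be non-decreasing")

    def __len__(self):
        return len(self.scales)

    def __iter__(self):
        return iter(self.scales)


def make_scale_grid(jet_widths: Optional[tuple] = None,
                    scale_range: Optional[Sequence[float]] = None,
                    image_shape: Optional[tuple] = None,
                    gamma: float = 0.75) -> ScaleGrid:
    """Build the set of blurring scales S.

    Priority: explicit ``scale_range`` > ``jet_widths`` (converted to a
    geometric grid in log base 1.5 with resolution 0.25, between 3 and 30
    points) > the default grid 1.5^1 .. 1.5^7 with 24 points.  Scales larger
    than min(m, n)/4 of the image are dropped when ``image_shape`` is given.
    """
    if scale_range is not None:
        scales = np.sort(np.asarray(list(scale_range), dtype=float))
        source = "explicit"
    elif jet_widths is not None:
        b_lb, b_ub = jet_widths
        if not (0 < b_lb <= b_ub):
            raise ValueError("jet_widths must satisfy 0 < lower <= upper")
        s_lb, s_ub = width_to_scale(b_lb), width_to_scale(b_ub)
        l0 = math.log(s_lb) / math.log(LOG_BASE)
        l1 = math.log(s_ub) / math.log(LOG_BASE)
        n_scales = int(min(max(round((l1 - l0) / DELTA), MIN_SCALES), MAX_SCALES))
        scales = np.logspace(l0, l1, num=n_scales, base=LOG_BASE)
        source = "jet_widths"
    else:
        scales = np.logspace(DEFAULT_START, DEFAULT_STOP, num=DEFAULT_NUM, base=LOG_BASE)
        source = "default"
    if image_shape is not None:
        s_max = min(image_shape) / 4.0
        scales = scales[scales <= s_max]
        if len(scales) == 0:
            raise ValueError(f"no scale fits the image (s_max = {s_max:.2f})")
    return ScaleGrid(scales, gamma=gamma, source=source)


def gamma_derivative(image: np.ndarray, order: tuple, gamma: float, s: float,
                     mode: str = "reflect", blurred: bool = True) -> np.ndarray:
    """Gamma-normalized Gaussian derivative of given (x-order, y-order).

    ``order=(a, b)`` takes the a-th x-derivative (columns) and b-th
    y-derivative (rows) at scale s, multiplied by s^(gamma*(a+b)).  If
    ``blurred`` is False the Gaussian smoothing is folded into the same
    separable convolution; otherwise the input is assumed pre-blurred and only
    small finite-difference kernels are applied.
    """
    a, b = order
    if a + b not in (1, 2) or a < 0 or b < 0:
        raise ValueError(f"unsupported derivative order {order}")
    if blurred:
        first = [-0.5, 0.0, 0.5]
        second = [1.0, -2.0, 1.0]
        out = image
        if a == 2:
            out = ndimage.correlate1d(out, second, axis=1, mode=mode)
        elif a == 1:
            out = ndimage.correlate1d(out, first, axis=1, mode=mode)
        if b == 2:
            out = ndimage.correlate1d(out, second, axis=0, mode=mode)
        elif b == 1:
            out = ndimage.correlate1d(out, first, axis=0, mode=mode)
    else:
        out = ndimage.gaussian_filter(image, s, order=(b, a), mode=mode)
    return out * s ** (gamma * (a + b))


def _derivatives(image: np.ndarray, s: float, mode: str):
    """All first/second Gaussian derivatives of ``image`` at scale s
    (separable Gaussian-derivative filtering; unnormalized).

    The mean is subtracted first: truncated derivative kernels do not sum
    exactly to zero, so a constant offset would otherwise bias the output.
    """
    img = image - image.mean()
    g = lambda ob, oa: ndimage.gaussian_filter(img, s, order=(ob, oa), mode=mode)
    return dict(Ix=g(0, 1), Iy=g(1, 0), Ixx=g(0, 2), Iyy=g(2, 0), Ixy=g(1, 1))


def _eig2_sym(a, b, c):
    """Eigen-decomposition of the symmetric 2x2 field [[a, b], [b, c]].

    Returns (lam_hi, lam_lo, vhi_x, vhi_y) with lam_hi >= lam_lo and the unit
    eigenvector of lam_hi.  Degenerate (isotropic) pixels get eigenvector
    (1, 0).
    """
    t = 0.5 * (a + c)
    r = np.sqrt(np.maximum(0.25 * (a - c) ** 2 + b ** 2, 0.0))
    lam_hi, lam_lo = t + r, t - r
    vx = np.where(np.abs(b) > 1e-300, b, np.where(a >= c, 1.0, 0.0))
    vy = np.where(np.abs(b) > 1e-300, lam_hi - a, np.where(a >= c, 0.0, 1.0))
    norm = np.hypot(vx, vy)
    norm = np.where(norm == 0, 1.0, norm)
    return lam_hi, lam_lo, vx / norm, vy / norm


@dataclass
class FeatureVolume:
    """Per-scale feature maps over a strip image.

    Arrays are stacked scale-first (k x m x n): ``Lambda`` ridge strength
    (>= 0), ``Theta`` tangent angle in degrees [0, 180), ``Psi`` second
    eigenvalue of -H, ``R`` boolean ridge condition, ``C`` boolean corner
    (saddle) condition computed on the corner image.
    """

    grid: ScaleGrid
    Lambda: np.ndarray
    Theta: np.ndarray
    Psi: np.ndarray
    R: np.ndarray
    C: np.ndarray

    @property
    def shape(self):
        return self.Lambda.shape[1:]

    def sample(self, name: str, ys, xs):
        """Sample a feature map at rounded point locations for all scales.

        Returns an array (n_points, n_scales)."""
        arr = getattr(self, name)
        yi = np.clip(np.round(ys).astype(int), 0, arr.shape[1] - 1)
        xi = np.clip(np.round(xs).astype(int), 0, arr.shape[2] - 1)
        return arr[:, yi, xi].T


def _ridge_condition(d: dict, eps_rel: float = 1e-3) -> np.ndarray:
    """Lindeberg-style ridge condition on the (p, q) principal-curvature frame.

    I_pp/I_qq are the Hessian eigenvalues (I_pp the smaller), I_p/I_q the
    gradient components along the eigendirections.  Zero tests use a relative
    tolerance: exact zeros are vacuous on sampled images.
    """
    lam_hi, lam_lo, vhx, vhy = _eig2_sym(d["Ixx"], d["Ixy"], d["Iyy"])
    # eigenvector of the smaller eigenvalue is perpendicular to (vhx, vhy)
    vlx, vly = -vhy, vhx
    Ipp, Iqq = lam_lo, lam_hi
    Ip = d["Ix"] * vlx + d["Iy"] * vly
    Iq = d["Ix"] * vhx + d["Iy"] * vhy
    Iv = np.hypot(d["Ix"], d["Iy"])
    eps_v = eps_rel * max(Iv.max(), 1e-300)
    eps_p = eps_rel * max(np.abs(Ip).max(), np.abs(Iq).max(), 1e-300)
    eps_h = eps_rel * max(np.abs(Ipp).max(), np.abs(Iqq).max(), 1e-300)
    grad_pos = Iv > eps_v
    grad_zero = ~grad_pos
    cond = (grad_pos & (np.abs(Ip) <= eps_p) & (Ipp < 0)) \
        | (grad_pos & (np.abs(Iq) <= eps_p) & (Iqq < 0)) \
        | (grad_zero & (Ipp < 0) & (np.abs(Iqq) <= eps_h)) \
        | (grad_zero & (Iqq < 0) & (np.abs(Ipp) <= eps_h))
    return cond


def _corner_condition(d: dict, eps_rel: float = 1e-3) -> np.ndarray:
    """Saddle condition on the corner image: vanishing gradient with opposite-
    sign principal curvatures."""
    lam_hi, lam_lo, _, _ = _eig2_sym(d["Ixx"], d["Ixy"], d["Iyy"])
    Iv = np.hypot(d["Ix"], d["Iy"])
    eps_v = eps_rel * max(Iv.max(), 1e-300)
    return (Iv <= eps_v) & (lam_hi * lam_lo < 0)


def compute_feature_maps(strip, corner_strip, grid: ScaleGrid,
                         mode: str = "reflect") -> FeatureVolume:
    """Compute Lambda, Theta, Psi, R (from the main strip) and C (from the
    corner strip) at every scale of the grid."""
    I = np.asarray(strip.pixels if hasattr(strip, "pixels") else strip, dtype=float)
    Icorner = np.asarray(
        corner_strip.pixels if hasattr(corner_strip, "pixels") else corner_strip, dtype=float)
    if Icorner.shape != I.shape:
        raise ValueError("main and corner strips must share shape")
    k = len(grid)
    m, n = I.shape
    gamma = grid.gamma
    Lam = np.empty((k, m, n), dtype=np.float32)
    The = np.empty((k, m, n), dtype=np.float32)
    Psi = np.empty((k, m, n), dtype=np.float32)
    Rc = np.empty((k, m, n), dtype=bool)
    Cc = np.empty((k, m, n), dtype=bool)
    for idx, s in enumerate(grid.scales):
        d = _derivatives(I, s, mode)
        norm2 = s ** (2.0 * gamma)
        a, b, c = d["Ixx"] * norm2, d["Ixy"] * norm2, d["Iyy"] * norm2
        # eigen maps of -H: bright ridges -> large positive principal eigenvalue
        lam_hi, lam_lo, vx, vy = _eig2_sym(-a, -b, -c)
        Lam[idx] = np.maximum(lam_hi, 0.0)
        The[idx] = np.mod(np.degrees(np.arctan2(vy, vx)) + 90.0, 180.0)
        Psi[idx] = lam_lo
        Rc[idx] = _ridge_condition(d)
        dc = _derivatives(Icorner, s, mode)
        Cc[idx] = _corner_condition(dc)
    return FeatureVolume(grid, Lam, The, Psi, Rc, Cc)
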