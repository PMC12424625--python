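"""Sub-pixel curvilinear structure detection (Steger-style line tracer).

At each scale s the strip image is convolved with Gaussian derivatives; every
pixel whose second directional derivative across the line (the most negative
Hessian eigenvalue, for bright lines) is strong, and whose sub-pixel crest
position falls inside the pixel, is a *line point*.  Line points are linked
into curves by orientation continuity, with hysteresis thresholding: a curve
is reported only if it contains a point whose response exceeds the upper
threshold, and is extended through points above the lower threshold.  Widths
come from the flanking extrema of the directional derivative along the line
normal (the line's edges), searched up to 2.5*s per side.

Junctions are not split, and only bright lines are detected.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import ndimage

WIDTH_SEARCH_FACTOR = 2.5   # max flank search distance, in units of the scale
LINK_MAX_ANGLE = 45.0       # max tangent angle difference between linked pixels


@dataclass
class Ridge:
    """An ordered traced curve in strip coordinates.

    ``points`` are sub-pixel (y, x) positions; ``angles`` are tangent angles in
    degrees; ``widths`` are per-point line widths in pixels.  After refinement
    the ridge additionally carries per-point feature samples across all scales
    and bin-shifted x coordinates.
    """

    points: np.ndarray                       # N x 2, (y, x)
    widths: np.ndarray                       # N
    angles: np.ndarray                       # N, degrees
    responses: np.ndarray                    # N, tracer response
    scale: float                             # detection scale s*
    scale_index: int = 0                     # index of s* in the grid
    width_flags: np.ndarray = None           # True where flank search failed
    chromosome: str = ""
    resolution: int = 1
    # filled by ridge_refine / quantify:
    shifted_x: Optional[np.ndarray] = None
    samples: dict = field(default_factory=dict)   # name -> (N, n_scales) array
    curved: bool = False
    flags: dict = field(default_factory=dict)

    def __post_init__(self):
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        self.widths = np.asarray(self.widths, dtype=float)
        self.angles = np.asarray(self.angles, dtype=float)
        self.responses = np.asarray(self.responses, dtype=float)
        if self.width_flags is None:
            self.width_flags = np.zeros(len(self.points), dtype=bool)

    def __len__(self):
        return len(self.points)

    @property
    def n_points(self) -> int:
        return len(self.points)

    def take(self, index) -> "Ridge":
        """Return a copy restricted to the given point indices (order kept)."""
        idx = np.asarray(index)
        r = Ridge(self.points[idx], self.widths[idx], self.angles[idx],
                  self.responses[idx], self.scale, self.scale_index,
                  self.width_flags[idx], self.chromosome, self.resolution)
        r.curved = self.curved
        r.flags = dict(self.flags)
        if self.shifted_x is not None:
            r.shifted_x = self.shifted_x[idx]
        r.samples = {k: v[idx] for k, v in self.samples.items()}
        return r


def bar_response_threshold(contrast: float, s: float) -> float:
    """Second-derivative response of a bar of the width implied by scale s.

    A dark-flanked bright bar of width w and height (contrast) c, blurred at
    sigma = s, produces a crest response whose magnitude is
        |c * (w/2) / (sqrt(2*pi) * s^3) * 2 * exp(-(w/2)^2 / (2 s^2))|,
    the sum of the two edge contributions g'_s(+-w/2); w = 2*sqrt(3)*(s - 0.5)
    inverts the width->scale convention.  Linear in contrast.
    """
    w = max(2.0 * math.sqrt(3.0) * (s - 0.5), 1e-3)
    half = w / 2.0
    return abs(contrast * half / (math.sqrt(2.0 * math.pi) * s ** 3)
               * 2.0 * math.exp(-(half ** 2) / (2.0 * s ** 2)))


def estimate_thresholds(image: np.ndarray, s: float) -> tuple:
    """Hysteresis thresholds from the 25th/90th percentile non-zero contrast.

    The percentile contrasts are mapped through the bar-response formula at
    scale s; the 25th percentile gives the lower threshold and the 90th the
    upper.
    """
    img = np.asarray(image, dtype=float)
    nz = img[img > 0]
    if nz.size == 0:
        warnings.warn("all-zero image; thresholds set to 0")
        return 0.0, 0.0
    c_low, c_high = np.percentile(nz, 25), np.percentile(nz, 90)
    lower = bar_response_threshold(c_low, s)
    upper = bar_response_threshold(c_high, s)
    if lower > upper:
        lower, upper = upper, lower
    return lower, upper


def _line_points(image: np.ndarray, s: float, mode: str = "reflect"):
    """Per-pixel line-point geometry at scale s.

    Returns (response, nx, ny, ty, tx_off, ty_off, valid): the bright-line
    response (-lambda_min of the Hessian, clipped at 0), the unit normal, the
    sub-pixel offsets and whether the crest falls inside the pixel.
    """
    # mean-subtract: truncated derivative kernels do not sum exactly to zero
    img0 = image - image.mean()
    g = lambda ob, oa: ndimage.gaussian_filter(img0, s, order=(ob, oa), mode=mode)
    Ix, Iy = g(0, 1), g(1, 0)
    Ixx, Iyy, Ixy = g(0, 2), g(2, 0), g(1, 1)
    t = 0.5 * (Ixx + Iyy)
    r = np.sqrt(np.maximum(0.25 * (Ixx - Iyy) ** 2 + Ixy ** 2, 0.0))
    lam_min = t - r
    # eigenvector of lam_min: normal to the (bright) line
    nx = np.where(np.abs(Ixy) > 1e-300, Ixy, np.where(Ixx <= Iyy, 1.0, 0.0))
    ny = np.where(np.abs(Ixy) > 1e-300, lam_min - Ixx, np.where(Ixx <= Iyy, 0.0, 1.0))
    nrm = np.hypot(nx, ny)
    nrm = np.where(nrm == 0, 1.0, nrm)
    nx, ny = nx / nrm, ny / nrm
    response = np.maximum(-lam_min, 0.0)
    second = Ixx * nx ** 2 + 2.0 * Ixy * nx * ny + Iyy * ny ** 2
    with np.errstate(divide="ignore", invalid="ignore"):
        tpar = -(Ix * nx + Iy * ny) / second
        tpar = np.where(np.isfinite(tpar), tpar, np.inf)
        off_x, off_y = tpar * nx, tpar * ny
        off_x = np.where(np.isfinite(off_x), off_x, np.inf)
        off_y = np.where(np.isfinite(off_y), off_y, np.inf)
    valid = (np.abs(off_x) <= 0.5) & (np.abs(off_y) <= 0.5) & (response > 0)
    return response, nx, ny, off_x, off_y, valid, (Ix, Iy)


def _interp_bilinear(arr: np.ndarray, ys: np.ndarray, xs: np.ndarray) -> np.ndarray:
    """Vectorized bilinear interpolation with edge clamping."""
    m, n = arr.shape
    ys = np.clip(ys, 0.0, m - 1.0)
    xs = np.clip(xs, 0.0, n - 1.0)
    y0 = ys.astype(int)
    x0 = xs.astype(int)
    y1 = np.minimum(y0 + 1, m - 1)
    x1 = np.minimum(x0 + 1, n - 1)
    fy, fx = ys - y0, xs - x0
    return ((1 - fy) * (1 - fx) * arr[y0, x0] + (1 - fy) * fx * arr[y0, x1]
            + fy * (1 - fx) * arr[y1, x0] + fy * fx * arr[y1, x1])


def _measure_width(Ix, Iy, py, px, nx, ny, s):
    """Line width from the flanking extrema of the first directional
    derivative along the normal (the line's edges); each side searched up to
    2.5*s.  The directional projection cancels background gradients running
    along the ridge.  A side with no interior extremum contributes 2.5*s and
    the point is flagged."""
    max_d = WIDTH_SEARCH_FACTOR * s
    step = 0.25
    dists = np.arange(step, max_d + step, step)
    width = 0.0
    failed = False
    for sign in (1.0, -1.0):
        ys = py + sign * dists * ny
        xs = px + sign * dists * nx
        prof = np.abs(_interp_bilinear(Ix, ys, xs) * nx
                      + _interp_bilinear(Iy, ys, xs) * ny)
        k = int(np.argmax(prof))
        if 0 < k < len(prof) - 1:
            width += dists[k]
        else:
            width += max_d
            failed = True
    return width, failed


def trace_ridges(image: np.ndarray, scale: float, thresholds: tuple,
                 mode: str = "reflect") -> list:
    """Trace all bright ridges in ``image`` at one scale.

    ``thresholds = (lower, upper)`` act on the second-derivative line response:
    curves are seeded at points above ``upper`` (strongest first) and extended
    through points above ``lower``.
    """
    img = np.asarray(image, dtype=float)
    lower, upper = thresholds
    response, nx, ny, off_x, off_y, valid, (Ix, Iy) = _line_points(img, scale, mode)
    m, n = img.shape
    candidate = valid & (response >= lower) & (response > 0)
    if not candidate.any():
        return []
    visited = np.zeros((m, n), dtype=bool)
    # tangent = normal rotated by 90 degrees
    tx, ty = -ny, nx
    seeds = np.argwhere(candidate & (response >= upper))
    order = np.argsort(-response[seeds[:, 0], seeds[:, 1]])
    seeds = seeds[order]
    ridges = []
    for sy, sx in seeds:
        if visited[sy, sx]:
            continue
        chain = _link_from(sy, sx, candidate, visited, response, tx, ty)
        if len(chain) < 2:
            visited[sy, sx] = True
            continue
        pts, widths, angs, resp, wflags = [], [], [], [], []
        for (cy, cx) in chain:
            py, px = cy + off_y[cy, cx], cx + off_x[cy, cx]
            w, failed = _measure_width(Ix, Iy, py, px, nx[cy, cx], ny[cy, cx], scale)
            pts.append((py, px))
            widths.append(w)
            angs.append(math.degrees(math.atan2(ty[cy, cx], tx[cy, cx])) % 180.0)
            resp.append(response[cy, cx])
            wflags.append(failed)
        ridges.append(Ridge(np.array(pts), np.array(widths), np.array(angs),
                            np.array(resp), float(scale),
                            width_flags=np.array(wflags)))
    return ridges


def _link_from(sy, sx, candidate, visited, response, tx, ty):
    """Grow a chain of pixels from a seed in both tangent directions.

    The successor is chosen among the 3 neighbors nearest the tangent
    direction, requiring an orientation difference below 45 degrees; ties are
    broken by the smaller response difference.
    """
    m, n = candidate.shape
    visited[sy, sx] = True
    chain = [(sy, sx)]
    for direction in (1.0, -1.0):
        cy, cx = sy, sx
        dir_x, dir_y = direction * tx[sy, sx], direction * ty[sy, sx]
        while True:
            nxt = _best_neighbor(cy, cx, dir_x, dir_y, candidate, visited,
                                 response, tx, ty)
            if nxt is None:
                break
            (cy, cx), (dir_x, dir_y) = nxt
            visited[cy, cx] = True
            if direction > 0:
                chain.append((cy, cx))
            else:
                chain.insert(0, (cy, cx))
    return chain


def _best_neighbor(cy, cx, dir_x, dir_y, candidate, visited, response, tx, ty):
    m, n = candidate.shape
    base = math.atan2(dir_y, dir_x)
    # the 3 neighbor offsets closest to the travel direction
    octant = int(round(base / (math.pi / 4.0))) % 8
    steps = {0: [(0, 1), (-1, 1), (1, 1)], 1: [(1, 1), (0, 1), (1, 0)],
             2: [(1, 0), (1, 1), (1, -1)], 3: [(1, -1), (1, 0), (0, -1)],
             4: [(0, -1), (1, -1), (-1, -1)], 5: [(-1, -1), (0, -1), (-1, 0)],
             6: [(-1, 0), (-1, -1), (-1, 1)], 7: [(-1, 1), (-1, 0), (0, 1)]}[octant]
    best = None
    for dy, dx in steps:
        yy, xx = cy + dy, cx + dx
        if not (0 <= yy < m and 0 <= xx < n):
            continue
        if visited[yy, xx] or not candidate[yy, xx]:
            continue
        # orientation continuity (tangents are axial: compare mod 180)
        cand_ang = math.atan2(ty[yy, xx], tx[yy, xx])
        diff = abs((math.degrees(cand_ang - base) + 90.0) % 180.0 - 90.0)
        if diff >= LINK_MAX_ANGLE:
            continue
        score = (diff, abs(response[yy, xx] - response[cy, cx]))
        if best is None or score < best[0]:
            # orient the stored tangent along the travel direction
            sign = 1.0 if (math.cos(cand_ang) * dir_x + math.sin(cand_ang) * dir_y) >= 0 else -1.0
            best = (score, (yy, xx), (sign * tx[yy, xx], sign * ty[yy, xx]))
    if best is None:
        return None
    return best[1], best[2]


def combine_across_scales(per_scale: dict, grid=None) -> list:
    """Concatenate per-scale ridge lists, tagging each ridge with its
    detection scale; no deduplication (overlap removal happens after
    significance).  When a scale grid is given, each ridge also records the
    index of its scale in the grid.
    """
    out = []
    for s, ridges in sorted(per_scale.items()):
        for r in ridges:
            r.scale = float(s)
            if grid is not None:
                r.scale_index = int(np.argmin(np.abs(np.asarray(grid.scales) - s)))
            out.append(r)
    return out
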