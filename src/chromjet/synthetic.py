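"""Synthetic contact maps with planted jets, confounders and ground truth.

The generator emulates the gross statistics of a single-chromosome Hi-C map:
a power-law distance decay P(contact) ~ (|i-j|+1)^-alpha with multiplicative
confounders (TAD blocks, loop dots, architectural stripes), counting noise,
and unmappable zero rows.  Jets are planted *multiplicatively on the expected
matrix before noise*, as a line in strip coordinates rising from the diagonal
at a controlled origin, angle, curvature and linearly interpolated Gaussian
cross-section, so that both observed and O/E derived images see them.

Truth is recorded in strip space (crest pixel coordinates plus a fuzzy mask)
to keep scoring independent of the matrix<->strip transform under test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .contact_image import ContactMatrix


@dataclass
class JetSpec:
    """A planted jet, parameterized in strip space (angle 90 = perpendicular
    to the diagonal)."""

    origin_bin: int
    length_bins: int
    angle_deg: float = 90.0
    width_start: float = 2.0       # Gaussian sigma (bins) at the diagonal
    width_end: float = 4.0         # sigma at the tip (diffuseness)
    curvature: float = 0.0         # lateral drift, bins per bin of extrusion^2
    contrast: float = 5.0          # multiplicative enrichment over background
    decay_along: float = 0.0       # intensity decay rate per bin toward the tip

    def __post_init__(self):
        if self.contrast < 1:
            raise ValueError("contrast must be at least 1 (1 = no enrichment)")
        if self.width_start <= 0 or self.width_end <= 0:
            raise ValueError("widths must be positive")

    def crest_x(self, d):
        """Crest column (strip space) at genomic distance d bins."""
        d = np.asarray(d, dtype=float)
        slope = 1.0 / math.tan(math.radians(self.angle_deg)) if self.angle_deg != 90.0 else 0.0
        return self.origin_bin + slope * d + 0.5 * self.curvature * d ** 2

    def sigma(self, d):
        d = np.asarray(d, dtype=float)
        f = np.clip(d / max(self.length_bins, 1), 0.0, 1.0)
        return self.width_start + (self.width_end - self.width_start) * f


@dataclass
class BackgroundSpec:
    """Jet-free expected contact map plus noise model."""

    p: int = 500
    decay_exponent: float = 1.0
    # Diagonal-bin depth of a deeply sequenced map at 25 kb: thousands of
    # counts per bin, so the Poisson coefficient of variation at mid-window
    # distances is ~0.1, as in published in situ Hi-C.
    base_intensity: float = 5000.0
    noise: str = "poisson"               # "poisson" | "gaussian" | "none"
    noise_level: float = 0.1             # gaussian sd as fraction of the mean
    tads: Sequence = field(default_factory=list)      # (start, end, enrichment)
    loops: Sequence = field(default_factory=list)     # (i, j, enrichment, sigma)
    stripes: Sequence = field(default_factory=list)   # (anchor, length, enrichment)
    unmappable: Sequence = field(default_factory=list)
    seed: int = 0


def expected_background(spec: BackgroundSpec) -> np.ndarray:
    """Noise-free expected matrix mu with confounders applied."""
    p = spec.p
    i, j = np.indices((p, p))
    d = np.abs(i - j)
    mu = spec.base_intensity * (d + 1.0) ** (-spec.decay_exponent)
    for (s, e, enr) in spec.tads:
        block = (i >= s) & (i < e) & (j >= s) & (j < e)
        mu = np.where(block, mu * enr, mu)
    for (li, lj, enr, sig) in spec.loops:
        bump = np.exp(-((i - li) ** 2 + (j - lj) ** 2) / (2.0 * sig ** 2)) \
            + np.exp(-((i - lj) ** 2 + (j - li) ** 2) / (2.0 * sig ** 2))
        mu = mu * (1.0 + (enr - 1.0) * np.clip(bump, 0.0, 1.0))
    for (a, ln, enr) in spec.stripes:
        band = ((i == a) & (j >= a) & (j < a + ln)) | ((j == a) & (i >= a) & (i < a + ln))
        mu = np.where(band, mu * enr, mu)
    return mu


def plant_jet(mu: np.ndarray, spec: JetSpec, window_bins: int):
    """Multiply the expected matrix along the jet locus.

    Returns (modified mu, truth) where truth is a dict with the strip-space
    crest coordinates (rows of (y, x) for the strip of height window_bins)
    and a boolean strip mask covering +-2 sigma around the crest.
    """
    p = mu.shape[0]
    h = int(window_bins)
    out = mu.copy()
    m, n = h, p
    mask = np.zeros((m, n), dtype=bool)
    crest = []
    truncated = False
    for d in range(0, min(spec.length_bins, h)):
        xc = float(spec.crest_x(d))
        sig = float(spec.sigma(d))
        gain = (spec.contrast - 1.0) * math.exp(-spec.decay_along * d)
        # matrix entries at distance d have midpoint (i + j)/2 = i + d/2
        ii = np.arange(0, p - d)
        mid = ii + d / 2.0
        prof = np.exp(-((mid - xc) ** 2) / (2.0 * sig ** 2))
        factor = 1.0 + gain * prof
        out[ii, ii + d] *= factor
        if d > 0:
            out[ii + d, ii] *= factor
        y = m - 1 - d
        xr = int(round(xc))
        if 0 <= xr < n:
            crest.append((y, xr))
        else:
            truncated = True
        lo = max(0, int(math.floor(xc - 2 * sig)))
        hi = min(n, int(math.ceil(xc + 2 * sig)) + 1)
        mask[y, lo:hi] = True
    if spec.origin_bin + spec.length_bins > p:
        truncated = True
    if truncated:
        import warnings
        warnings.warn("jet exits the matrix; truncated")
    return out, {"crest": np.array(crest, dtype=int), "mask": mask, "spec": spec}


def make_background(spec: BackgroundSpec) -> ContactMatrix:
    """Sample a jet-free contact matrix (see :func:`simulate`)."""
    return simulate(spec, jets=[], window_bins=2)[0]


def simulate(background: BackgroundSpec, jets: Sequence[JetSpec],
             window_bins: int, chromosome: str = "chrS", resolution: int = 25_000):
    """Full simulation: expected background, planted jets, noise, zero rows.

    Returns (ContactMatrix of raw counts, list of truth dicts).  The
    ContactMatrix keeps all bins (retained_bins = identity); zero-row removal
    happens in the loading step of the pipeline, as for real data.
    """
    rng = np.random.default_rng(background.seed)
    mu = expected_background(background)
    truths = []
    for jet in jets:
        mu, truth = plant_jet(mu, jet, window_bins)
        truths.append(truth)
    if background.noise == "poisson":
        upper = np.triu(rng.poisson(np.triu(mu)).astype(float))
        A = upper + np.triu(upper, 1).T
    elif background.noise == "gaussian":
        noise = rng.normal(0.0, background.noise_level * mu)
        noise = np.triu(noise) + np.triu(noise, 1).T
        A = np.maximum(mu + noise, 0.0)
    elif background.noise == "none":
        A = mu.copy()
    else:
        raise ValueError(f"unknown noise model {background.noise!r}")
    for b in background.unmappable:
        A[b, :] = 0.0
        A[:, b] = 0.0
    cm = ContactMatrix(A, chromosome, resolution, data_type="observed")
    return cm, truths


# ---------------------------------------------------------------------------
# Ground-truth scoring
# ---------------------------------------------------------------------------

def _call_points(call) -> np.ndarray:
    """Strip-space (y, x) points of a call: a Ridge (using shifted coordinates
    when present, so scoring is in original-bin space) or a bare array."""
    if hasattr(call, "points"):
        y = call.points[:, 0]
        x = call.shifted_x if call.shifted_x is not None else call.points[:, 1]
        return np.column_stack([y, x])
    return np.atleast_2d(np.asarray(call, dtype=float))


def _coverage(crest: np.ndarray, pts: np.ndarray, lateral_tol: float = 2.0) -> float:
    """Fraction of crest pixels having a call point on the same row within the
    lateral tolerance."""
    if len(crest) == 0 or len(pts) == 0:
        return 0.0
    hit = 0
    for (cy, cx) in crest:
        rows = np.abs(pts[:, 0] - cy) <= 0.5
        if rows.any() and np.min(np.abs(pts[rows, 1] - cx)) <= lateral_tol:
            hit += 1
    return hit / len(crest)


def score_calls(truths: Sequence[dict], calls: Sequence, lateral_tol: float = 2.0):
    """Precision / recall / positional error of called jets vs planted truth.

    A truth jet is recovered when one call covers at least half of its crest
    pixels within the lateral tolerance; a call is a true positive when at
    least half of its points lie within the tolerance of some truth crest.
    With no calls, precision is reported as 1 with a zero-support flag.
    """
    call_pts = [_call_points(c) for c in calls]
    recovered = np.zeros(len(truths), dtype=bool)
    tp_call = np.zeros(len(calls), dtype=bool)
    errors = []
    for ti, truth in enumerate(truths):
        crest = truth["crest"]
        for ci, pts in enumerate(call_pts):
            cov = _coverage(crest, pts, lateral_tol)
            if cov >= 0.5:
                recovered[ti] = True
            # call-side coverage: fraction of call points near this crest
            if len(pts) and len(crest):
                crest_by_row = {int(cy): cx for cy, cx in crest}
                near = 0
                errs = []
                for (py, px) in pts:
                    cx = crest_by_row.get(int(round(py)))
                    if cx is not None and abs(px - cx) <= lateral_tol:
                        near += 1
                        errs.append(abs(px - cx))
                if near / len(pts) >= 0.5:
                    tp_call[ci] = True
                    errors.extend(errs)
    recall = float(recovered.mean()) if len(truths) else 1.0
    if len(calls) == 0:
        return {"precision": 1.0, "recall": recall, "lateral_error": float("nan"),
                "zero_support": True}
    return {"precision": float(tp_call.mean()), "recall": recall,
            "lateral_error": float(np.mean(errors)) if errors else float("nan"),
            "zero_support": False}


# ---------------------------------------------------------------------------
# Fixture writers (plain-text and minimal .cool)
# ---------------------------------------------------------------------------

def write_dense_text(path, matrix: ContactMatrix) -> None:
    """Write the dense-text dialect: '# chrom=<id> resolution=<bp>' + rows."""
    header = f"# chrom={matrix.chromosome} resolution={matrix.resolution}"
    np.savetxt(path, matrix.values, fmt="%.6g", header=header, comments="")


def write_cool(path, matrix: ContactMatrix) -> None:
    """Write a minimal single-resolution .cool file (cooler HDF5 schema:
    chroms / bins / pixels with upper-triangle nonzero counts)."""
    import h5py

    A = matrix.values
    p = A.shape[0]
    res = matrix.resolution
    iu, ju = np.nonzero(np.triu(A))
    with h5py.File(path, "w") as f:
        f.attrs["format"] = "HDF5::Cooler"
        f.attrs["bin-size"] = res
        f.attrs["nbins"] = p
        chroms = f.create_group("chroms")
        chroms.create_dataset("name", data=np.array([matrix.chromosome], dtype="S32"))
        chroms.create_dataset("length", data=np.array([p * res], dtype=np.int64))
        bins = f.create_group("bins")
        bins.create_dataset("chrom", data=np.zeros(p, dtype=np.int32))
        bins.create_dataset("start", data=np.arange(p, dtype=np.int64) * res)
        bins.create_dataset("end", data=(np.arange(p, dtype=np.int64) + 1) * res)
        pixels = f.create_group("pixels")
        pixels.create_dataset("bin1_id", data=iu.astype(np.int64))
        pixels.create_dataset("bin2_id", data=ju.astype(np.int64))
        pixels.create_dataset("count", data=A[iu, ju])
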