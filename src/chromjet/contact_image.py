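"""Contact-map input and strip-image generation.

A chromosome's contact matrix ``A`` (p x p, symmetric) is turned into up to
four "strip" images — the 45-degree rotated band along the main diagonal in
which jets perpendicular to the diagonal appear as near-vertical lines:

* ``I``      the main ridge-characterization image,
* ``I_obs``  the observed image for the statistical test,
* ``I_null`` the null image: the strip of the column-correlation matrix
  (1/p) A'^T A' of the z-standardized observed map,
* ``I_corr`` ("corner image") the strip of the correlation matrix of the
  windowed O/E map, used only for the saddle/corner condition.

Strip geometry: the strip has ``m = h`` rows (h = window in bins) and
``n = p`` columns, so one column equals one genomic bin and one row equals one
bin of genomic distance.  The row index *increases toward the diagonal*: a
pixel (y, x) sits at genomic distance ``d = m - 1 - y`` bins and maps to the
bin pair ``(x - d/2, x + d/2)``.  This direct construction is the invertible
resampling of the classic 45-degree rotation; the round-trip error of the
pixel<->bin mapping is at most one bin everywhere.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np


class MatrixFormatError(ValueError):
    """Unknown or unreadable contact-matrix format."""


class MatrixLookupError(KeyError):
    """Requested chromosome / resolution not present in the file."""


class EmptyMatrixError(ValueError):
    """Contact matrix is empty (all rows sum to zero)."""


@dataclass
class ContactMatrix:
    """Dense symmetric contact map with removed-bin bookkeeping.

    ``retained_bins[k]`` is the original bin index of reduced row/column ``k``
    after zero-sum row/column removal.
    """

    values: np.ndarray
    chromosome: str
    resolution: int
    data_type: str = "observed"
    normalization: str = "NONE"
    retained_bins: np.ndarray = field(default=None)
    n_bins_original: int = 0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError("contact matrix must be square")
        if self.retained_bins is None:
            self.retained_bins = np.arange(self.values.shape[0])
        self.retained_bins = np.asarray(self.retained_bins, dtype=int)
        if len(self.retained_bins) != self.values.shape[0]:
            raise ValueError("retained_bins length must match matrix size")
        if np.any(np.diff(self.retained_bins) <= 0):
            raise ValueError("retained_bins must be strictly increasing")
        if not self.n_bins_original:
            self.n_bins_original = int(self.retained_bins[-1]) + 1 if len(self.retained_bins) else 0

    @property
    def p(self) -> int:
        return self.values.shape[0]


@dataclass
class StripImage:
    """Rotated diagonal strip with an invertible pixel<->bin mapping."""

    pixels: np.ndarray          # m x n, values in [0, 1]
    window_bins: int            # h
    role: str = "main"          # main | observed | null | corner
    clip_bounds: tuple = (None, None)

    @property
    def shape(self):
        return self.pixels.shape

    # -- geometry ------------------------------------------------------------
    def pixel_to_bins(self, y, x):
        """Map strip pixel (row y, col x) to fractional bin pair (i, j), j >= i."""
        y = np.asarray(y, dtype=float)
        x = np.asarray(x, dtype=float)
        d = (self.pixels.shape[0] - 1) - y
        return x - d / 2.0, x + d / 2.0

    def bins_to_pixel(self, i, j):
        """Map a bin pair (i, j) to fractional strip pixel (y, x)."""
        i = np.asarray(i, dtype=float)
        j = np.asarray(j, dtype=float)
        y = (self.pixels.shape[0] - 1) - (j - i)
        x = (i + j) / 2.0
        return y, x

    def distance_bins(self, y):
        """Genomic distance from the diagonal, in bins, of strip row ``y``."""
        return (self.pixels.shape[0] - 1) - np.asarray(y, dtype=float)


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

def _read_dense_text(path: Path, chromosome: str, resolution: int):
    """Read the dense-text dialect: '# chrom=<id> resolution=<bp>' header, then rows."""
    with open(path) as fh:
        header = fh.readline().strip()
        if not header.startswith("#"):
            raise MatrixFormatError(f"{path}: dense-text file must start with a '#' header line")
        meta = {}
        for tok in header.lstrip("#").split():
            if "=" in tok:
                k, v = tok.split("=", 1)
                meta[k] = v
        body = np.loadtxt(fh, dtype=float, ndmin=2)
    if "chrom" in meta and chromosome is not None and meta["chrom"] != str(chromosome):
        raise MatrixLookupError(f"{path}: chromosome {chromosome!r} not found (file has {meta['chrom']!r})")
    if "resolution" in meta and resolution is not None and int(meta["resolution"]) != int(resolution):
        raise MatrixLookupError(
            f"{path}: resolution {resolution} not available (file has {meta['resolution']})")
    return body


def _read_cool(path: Path, chromosome: str, resolution: int, normalization: str):
    """Read a single-resolution .cool (or .mcool) HDF5 file into a dense array.

    Follows the public cooler schema (chroms/bins/pixels tables, upper-triangle
    pixels).  Balancing weights are applied when ``normalization`` names a bin
    column (e.g. "weight"); NaN weights are treated as zero.
    """
    import h5py

    with h5py.File(path, "r") as f:
        grp = f
        if "resolutions" in f:  # .mcool layout
            key = str(int(resolution))
            if key not in f["resolutions"]:
                raise MatrixLookupError(f"{path}: resolution {resolution} not in file")
            grp = f["resolutions"][key]
        if "bins" not in grp or "pixels" not in grp:
            raise MatrixFormatError(f"{path}: not a cooler file (missing bins/pixels)")
        binsize = int(grp.attrs.get("bin-size", grp.attrs.get("binsize", resolution)))
        if resolution is not None and binsize != int(resolution):
            raise MatrixLookupError(f"{path}: resolution {resolution} not available (file has {binsize})")
        chrom_names = [c.decode() if isinstance(c, bytes) else str(c)
                       for c in grp["chroms"]["name"][:]]
        if str(chromosome) not in chrom_names:
            raise MatrixLookupError(f"{path}: chromosome {chromosome!r} not in {chrom_names}")
        bin_chrom = grp["bins"]["chrom"][:]
        cid = chrom_names.index(str(chromosome))
        sel = np.flatnonzero(bin_chrom == cid)
        lo, hi = int(sel[0]), int(sel[-1]) + 1
        p = hi - lo
        b1 = grp["pixels"]["bin1_id"][:]
        b2 = grp["pixels"]["bin2_id"][:]
        cnt = grp["pixels"]["count"][:].astype(float)
        mask = (b1 >= lo) & (b1 < hi) & (b2 >= lo) & (b2 < hi)
        A = np.zeros((p, p))
        A[b1[mask] - lo, b2[mask] - lo] = cnt[mask]
        A = np.maximum(A, A.T)
        if normalization not in (None, "NONE") and normalization in grp["bins"]:
            w = np.asarray(grp["bins"][normalization][lo:hi], dtype=float)
            w = np.nan_to_num(w, nan=0.0)
            A = A * w[:, None] * w[None, :]
    return A


def _read_hic(path: Path, chromosome: str, resolution: int, data_type: str, normalization: str):
    try:
        import hicstraw  # noqa: F401
    except ImportError as exc:
        raise MatrixFormatError(
            ".hic input requires the optional 'hicstraw' package; "
            "convert to .cool or dense text instead") from exc
    dtype = "observed" if data_type == "observed" else "oe"
    result = hicstraw.straw(dtype, normalization or "NONE", str(path),
                            str(chromosome), str(chromosome), "BP", int(resolution))
    rows = np.array([r.binX for r in result]) // resolution
    cols = np.array([r.binY for r in result]) // resolution
    vals = np.array([r.counts for r in result], dtype=float)
    p = int(max(rows.max(), cols.max())) + 1 if len(rows) else 0
    A = np.zeros((p, p))
    A[rows, cols] = vals
    return np.maximum(A, A.T)


def expected_by_distance(values: np.ndarray) -> np.ndarray:
    """Mean contact frequency per genomic distance (diagonal) of a dense map."""
    p = values.shape[0]
    return np.array([np.mean(np.diagonal(values, offset=d)) for d in range(p)])


def observed_over_expected(values: np.ndarray) -> np.ndarray:
    """Divide each entry by the mean of its diagonal (distance-decay removal)."""
    p = values.shape[0]
    exp = expected_by_distance(values)
    out = np.zeros_like(values, dtype=float)
    for d in range(p):
        if exp[d] > 0:
            diag = np.diagonal(values, offset=d) / exp[d]
            idx = np.arange(p - d)
            out[idx, idx + d] = diag
            out[idx + d, idx] = diag
    return out


def load_contact_matrix(source, chromosome=None, resolution=None,
                        data_type: str = "observed",
                        normalization: str = "NONE") -> ContactMatrix:
    """Load one chromosome's contact matrix and remove zero-sum rows/columns.

    ``source`` may be a dense-text file ('# chrom=.. resolution=..' header),
    a ``.cool``/``.mcool`` file, a ``.hic`` file (if hicstraw is installed), or
    an in-memory square array.  For formats storing raw counts, ``data_type``
    "oe" divides by the per-distance expected value after zero-row removal.
    """
    if isinstance(source, np.ndarray):
        A = np.array(source, dtype=float)
    else:
        path = Path(source)
        if not path.exists():
            raise MatrixFormatError(f"input file not found: {path}")
        suffix = path.suffix.lower()
        if suffix in (".cool", ".mcool"):
            A = _read_cool(path, chromosome, resolution, normalization)
        elif suffix == ".hic":
            A = _read_hic(path, chromosome, resolution, data_type, normalization)
            A = np.nan_to_num(A, nan=0.0)
            keep = np.flatnonzero(A.sum(axis=0) > 0)
            if keep.size == 0:
                raise EmptyMatrixError(f"{path}: all rows sum to zero")
            return ContactMatrix(A[np.ix_(keep, keep)], str(chromosome), int(resolution),
                                 data_type, normalization, keep, A.shape[0])
        else:
            A = _read_dense_text(path, chromosome, resolution)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise MatrixFormatError("contact matrix must be square")
    A = np.nan_to_num(np.asarray(A, dtype=float), nan=0.0)
    n_orig = A.shape[0]
    keep = np.flatnonzero(A.sum(axis=0) > 0)
    if keep.size == 0:
        raise EmptyMatrixError("all rows/columns sum to zero")
    A = A[np.ix_(keep, keep)]
    if data_type == "oe":
        A = observed_over_expected(A)
    return ContactMatrix(A, str(chromosome), int(resolution) if resolution else 1,
                         data_type, normalization, keep, n_orig)


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------

def _clip_minmax(values: np.ndarray, im_vmin: float, im_vmax: float):
    """Percentile clip (skipped when the two percentile values coincide), then
    min-max normalize to [0, 1].  Returns (array, (lo, hi) clip bounds)."""
    lo = np.percentile(values, im_vmin)
    hi = np.percentile(values, im_vmax)
    out = values if lo == hi else np.clip(values, lo, hi)
    vmin, vmax = out.min(), out.max()
    if vmax == vmin:
        warnings.warn("constant matrix after transform; returning zeros")
        return np.zeros_like(out, dtype=float), (lo, hi)
    return (out - vmin) / (vmax - vmin), (lo, hi)


def preprocess(values: np.ndarray, data_type: str = "observed",
               im_vmin: float = 1.0, im_vmax: float = 99.0) -> np.ndarray:
    """log1p (observed data only) -> percentile clip -> min-max to [0, 1]."""
    if not (0 <= im_vmin <= im_vmax <= 100):
        raise ValueError("need 0 <= im_vmin <= im_vmax <= 100")
    v = np.asarray(values, dtype=float)
    if data_type == "observed":
        v = np.log1p(v)
    out, _ = _clip_minmax(v, im_vmin, im_vmax)
    return out


def rotate_and_extract(values: np.ndarray, window_bins: int,
                       padding_mode: str = "constant") -> StripImage:
    """Extract the diagonal strip (the 45-degree rotation, resampled so one
    column = one bin and one row = one bin of distance).

    Only constant-zero padding is meaningful here: out-of-matrix pixels are 0.
    """
    A = np.asarray(values, dtype=float)
    p = A.shape[0]
    h = int(window_bins)
    if h < 2:
        raise ValueError("window_bins must be >= 2")
    if h > p:
        raise ValueError(f"window_bins ({h}) exceeds matrix size ({p})")
    m, n = h, p
    strip = np.zeros((m, n))
    for y in range(m):
        d = m - 1 - y
        diag = np.diagonal(A, offset=d)
        if d % 2 == 0:
            strip[y, d // 2: d // 2 + diag.size] = diag
        else:
            if diag.size >= 2:
                mid = 0.5 * (diag[:-1] + diag[1:])
                strip[y, (d + 1) // 2: (d + 1) // 2 + mid.size] = mid
    return StripImage(strip, h, role="main")


def correlation_matrix(values: np.ndarray) -> np.ndarray:
    """(1/p) A'^T A' where A' is the column-z-standardized input.

    Columns with zero variance are set to zero (with a warning), as are the
    corresponding correlation rows/columns.
    """
    A = np.asarray(values, dtype=float)
    p = A.shape[0]
    mu = A.mean(axis=0)
    sd = A.std(axis=0, ddof=1)  # sample-sd z-scores; with the 1/p prefactor the
    # result is the Pearson matrix scaled by (p-1)/p (immaterial after min-max)
    zero_var = sd == 0
    if zero_var.any():
        warnings.warn(f"{int(zero_var.sum())} constant column(s); correlations set to 0")
    sd_safe = np.where(zero_var, 1.0, sd)
    Z = (A - mu) / sd_safe
    Z[:, zero_var] = 0.0
    return (Z.T @ Z) / p


def _strip_of_correlation(corr: np.ndarray, window_bins: int,
                          im_vmin: float, im_vmax: float, role: str) -> StripImage:
    norm, bounds = _clip_minmax(corr, im_vmin, im_vmax)
    strip = rotate_and_extract(norm, window_bins)
    strip.role = role
    strip.clip_bounds = bounds
    return strip


def build_pvalue_images(source, chromosome=None, resolution=None,
                        window_bins: int = None, im_vmin: float = 1.0,
                        im_vmax: float = 99.0, normalization: str = "NONE"):
    """Build (I_obs, I_null) for the statistical test.

    The data type is forced to "observed".  I_obs is the strip of the
    preprocessed observed map; I_null is the strip of the correlation matrix
    (1/p) A'^T A' of the column-z-standardized preprocessed map.
    """
    if isinstance(source, ContactMatrix):
        if source.data_type != "observed":
            raise ValueError("build_pvalue_images requires an observed-count matrix")
        cm = source
    else:
        cm = load_contact_matrix(source, chromosome, resolution,
                                 data_type="observed", normalization=normalization)
    proc = preprocess(cm.values, "observed", im_vmin, im_vmax)
    obs = rotate_and_extract(proc, window_bins)
    obs.role = "observed"
    corr = correlation_matrix(proc)
    null = _strip_of_correlation(corr, window_bins, im_vmin, im_vmax, "null")
    return obs, null


def build_corner_image(source, chromosome=None, resolution=None,
                       window_bins: int = None, im_vmin: float = 1.0,
                       im_vmax: float = 99.0, normalization: str = "NONE") -> StripImage:
    """Build the corner image: strip of the correlation matrix of the windowed,
    log/clip/normalized O/E map.  Data type is forced to "oe"; rows removed in
    the MAIN matrix are removed here too (same retained-bin set)."""
    if isinstance(source, ContactMatrix):
        cm = source
        oe = cm.values if cm.data_type == "oe" else observed_over_expected(cm.values)
    else:
        cm = load_contact_matrix(source, chromosome, resolution,
                                 data_type="oe", normalization=normalization)
        oe = cm.values
    p = oe.shape[0]
    h = int(window_bins)
    i, j = np.indices((p, p))
    windowed = np.where(np.abs(i - j) > h, 0.0, oe)
    proc = preprocess(windowed, "observed", im_vmin, im_vmax)  # log1p + clip + minmax, as specified
    corr = correlation_matrix(proc)
    return _strip_of_correlation(corr, window_bins, im_vmin, im_vmax, "corner")


def shift_map(retained_bins) -> Callable:
    """Return a function mapping a reduced column index to its original bin."""
    rb = np.asarray(retained_bins, dtype=int)

    def _shift(col):
        idx = np.asarray(col, dtype=int)
        if np.any(idx < 0) or np.any(idx >= len(rb)):
            raise IndexError(f"column index out of range [0, {len(rb)})")
        return rb[idx] if idx.ndim else int(rb[idx])

    return _shift
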