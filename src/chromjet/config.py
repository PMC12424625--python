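"""Pipeline configuration and experiment-type presets.

All tunable parameters of the jet-calling pipeline live in a single
:class:`JetConfig` dataclass so that every output folder can carry a complete,
machine-readable provenance dump (see :mod:`chromjet.jet_io`).  Experiment-type
presets ("hic" / "replihic") only change default values, never the code path.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from typing import Optional, Sequence


@dataclass
class JetConfig:
    """Full parameter set for one chromosome run.

    Units: genomic quantities are in base pairs unless the name says bins;
    image-space quantities (widths, radii, scales) are in strip pixels, where
    one pixel column equals one genomic bin.
    """

    # --- input ---
    resolution: int = 25_000          # bp per bin
    window: int = 5_000_000           # max genomic distance considered, bp
    exp: str = "hic"                  # experiment type: "hic" | "replihic"
    data_type: str = "observed"       # "observed" | "oe"
    norm: str = "NONE"                # normalization label (passed to readers)

    # --- image generation ---
    im_vmin: float = 1.0              # lower clip percentile
    im_vmax: float = 99.0             # upper clip percentile
    rotation_padding: str = "constant"
    convolution_padding: str = "reflect"

    # --- scale grid ---
    gamma: float = 0.75
    jet_widths: Optional[tuple[float, float]] = None   # (b_lb, b_ub) in pixels
    scale_range: Optional[Sequence[float]] = None      # explicit scales

    # --- ridge detection ---
    # Fixed hysteresis thresholds on the second-derivative line response,
    # independent of image statistics: the classic ridge-detection defaults
    # (0.5, 1.36) for 8-bit images, rescaled to [0, 1] intensities.
    thresholds: Optional[tuple[float, float]] = (0.5 / 255.0, 1.36 / 255.0)
    auto_thresholds: bool = False     # estimate per scale from image percentiles instead

    # --- ridge processing / trimming ---
    angle_range: tuple[float, float] = (60.0, 120.0)   # degrees, strip space
    rem_k_strata: int = 2             # pixels adjacent to the diagonal to drop
    # A jet emanates from the main diagonal, so its nearest traced point must
    # lie within this many pixels of it; 15 px accommodates the root
    # displacement that Gaussian blurring causes at detection scales up to ~6.
    root_within: Optional[float] = 15.0
    corner_trim: Optional[float] = 2.0                 # None=off; >1 min bins; [0,1] min fraction
    angle_trim: Optional[float] = 2.0
    eig2_trim: Optional[float] = 2.0
    whitespace_shift_bins: float = 5.0
    psi_tol_frac: float = 0.05        # relative zero-tolerance for the eigenvalue trim

    # --- quantification ---
    points_min: float = 0.0
    points_max: Optional[float] = None  # None = max mean strength over the ridge set
    num_bins: int = 32
    bin_size: Optional[float] = None    # overrides num_bins when given
    entropy_thresh: float = 0.9
    rmse: float = 0.5
    ang_frac: bool = True
    sum_cond: str = "a-r-c"           # subset of {a,r,c} joined by "-"
    agg: str = "sum"                  # "sum" | "mean"

    # --- significance ---
    alpha: tuple[float, ...] = (0.1,)
    # Percentile-of-candidates saliency gate; 0 reports every significant jet.
    # A relative gate only makes sense for large candidate sets (whole real
    # chromosomes), so it is off by default and opt-in for ranking analyses.
    saliency_thresh: float = 0.0
    overlap_radius: float = 7.0       # px buffer for Algorithm-style overlap removal
    iou_threshold: float = 0.05

    seed: int = 0
    debug_dir: Optional[str] = None   # per-scale ridge overlays + tables

    @property
    def window_bins(self) -> int:
        return max(2, int(round(self.window / self.resolution)))

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, default=list)

    @classmethod
    def from_dict(cls, d: dict) -> "JetConfig":
        kwargs = dict(d)
        for key in ("jet_widths", "thresholds", "angle_range"):
            if kwargs.get(key) is not None:
                kwargs[key] = tuple(kwargs[key])
        if kwargs.get("alpha") is not None:
            a = kwargs["alpha"]
            kwargs["alpha"] = tuple(a) if isinstance(a, (list, tuple)) else (float(a),)
        return cls(**kwargs)


# Presets only set defaults; the pipeline code path is identical for both.
_PRESETS = {
    "hic": dict(data_type="observed"),
    "replihic": dict(data_type="oe", jet_widths=(2.0, 30.0)),
}


def preset_config(exp: str, **overrides) -> JetConfig:
    """Build a config for an experiment type, applying user overrides last."""
    if exp not in _PRESETS:
        raise ValueError(f"unknown experiment type {exp!r}; expected one of {sorted(_PRESETS)}")
    kwargs = dict(_PRESETS[exp])
    kwargs["exp"] = exp
    kwargs.update({k: v for k, v in overrides.items() if v is not None})
    return JetConfig(**kwargs)
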