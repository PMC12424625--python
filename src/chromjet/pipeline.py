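"""End-to-end jet calling for one chromosome.

Stages: load -> strip images (I, I_obs, I_null, corner) -> scale grid ->
feature volume -> per-scale ridge tracing -> processing & trimming ->
quantification & filtering -> KS testing -> overlap removal -> BH correction
and final thresholds.  Per-stage ridge counts are logged so pipeline
attrition is auditable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from . import contact_image as ci
from . import quantify as qt
from . import ridge_refine as rr
from . import ridge_tracing as rt
from . import scale_space as ss
from . import significance as sig
from .config import JetConfig

logger = logging.getLogger("chromjet")


@dataclass
class JetResult:
    """Everything a run produces, before and after the final thresholds."""

    config: JetConfig
    chromosome: str
    ridges: list = field(default_factory=list)        # candidate ridges (post overlap removal)
    summary: pd.DataFrame = None                      # one row per candidate jet
    expanded: pd.DataFrame = None                     # one row per ridge position
    stage_counts: dict = field(default_factory=dict)
    strip: object = None

    def significant(self, alpha: float, saliency_thresh: float) -> pd.DataFrame:
        """Summary rows passing corrected-p and saliency-percentile gates."""
        if self.summary is None or len(self.summary) == 0:
            return self.summary
        keep = sig.final_threshold(self.summary["p_corrected"].to_numpy(),
                                   self.summary["saliency"].to_numpy(),
                                   alpha, saliency_thresh)
        return self.summary.iloc[keep].reset_index(drop=True)


def _sample_features(ridge: rt.Ridge, volume: ss.FeatureVolume) -> rt.Ridge:
    ys, xs = ridge.points[:, 0], ridge.points[:, 1]
    for name in ("Lambda", "Theta", "Psi", "R", "C"):
        ridge.samples[name] = volume.sample(name, ys, xs)
    return ridge


def call_jets(source, config: JetConfig, chromosome: Optional[str] = None) -> JetResult:
    """Run the full pipeline on one chromosome.

    ``source`` is a contact-map path (dense text, .cool/.mcool, .hic) or an
    in-memory :class:`~chromjet.contact_image.ContactMatrix` of raw observed
    counts.
    """
    counts = {}
    # --- load + images ------------------------------------------------------
    if isinstance(source, ci.ContactMatrix):
        observed = source
        chromosome = observed.chromosome
    else:
        observed = ci.load_contact_matrix(source, chromosome, config.resolution,
                                          data_type="observed", normalization=config.norm)
    h = min(config.window_bins, observed.p)
    main_values = (observed.values if config.data_type == "observed"
                   else ci.observed_over_expected(observed.values))
    proc = ci.preprocess(main_values, config.data_type, config.im_vmin, config.im_vmax)
    strip = ci.rotate_and_extract(proc, h, config.rotation_padding)
    obs_strip, null_strip = ci.build_pvalue_images(
        observed, window_bins=h, im_vmin=config.im_vmin, im_vmax=config.im_vmax)
    corner_strip = ci.build_corner_image(
        observed, window_bins=h, im_vmin=config.im_vmin, im_vmax=config.im_vmax)

    # --- scale space --------------------------------------------------------
    grid = ss.make_scale_grid(config.jet_widths, config.scale_range,
                              image_shape=strip.shape, gamma=config.gamma)
    volume = ss.compute_feature_maps(strip, corner_strip, grid,
                                     mode=config.convolution_padding)

    # --- tracing ------------------------------------------------------------
    per_scale = {}
    for s in np.unique(grid.scales):
        if config.auto_thresholds or config.thresholds is None:
            thr = rt.estimate_thresholds(strip.pixels, s)
        else:
            thr = config.thresholds
        per_scale[float(s)] = rt.trace_ridges(strip.pixels, s, thr,
                                              mode=config.convolution_padding)
        if config.debug_dir:
            from .jet_io import write_scale_debug
            write_scale_debug(strip.pixels, per_scale[float(s)], float(s),
                              config.debug_dir)
    ridges = rt.combine_across_scales(per_scale, grid)
    counts["detected"] = len(ridges)

    # --- processing + trimming ---------------------------------------------
    policy = rr.TrimPolicy(config.corner_trim, config.angle_trim, config.eig2_trim,
                           config.angle_range, config.rem_k_strata,
                           config.root_within, config.whitespace_shift_bins,
                           config.psi_tol_frac)
    processed = []
    for r in ridges:
        r.chromosome = observed.chromosome
        r.resolution = observed.resolution
        r = rr.normalize_and_order(r)
        r = rr.filter_points(r, policy, strip.shape)
        if r is None:
            continue
        r = rr.shift_to_genomic(r, observed.retained_bins, strip.shape)
        r = _sample_features(r, volume)
        processed.append(r)
    counts["processed"] = len(processed)

    trimmed = []
    for r in processed:
        for trim in (rr.trim_corner, rr.trim_angle, rr.trim_eigenvalue):
            r = trim(r, policy)
            if r is None:
                break
        if r is None:
            continue
        r = rr.trim_whitespace(r, strip.pixels, policy)
        if r is not None:
            trimmed.append(r)
    counts["trimmed"] = len(trimmed)

    # --- quantification -----------------------------------------------------
    binning = qt.EntropyBinning(config.points_min, config.points_max,
                                config.num_bins, config.bin_size)
    if binning.points_max is None and trimmed:
        binning.points_max = max(float(qt.mean_strength(r).max()) for r in trimmed)
    entropies = [qt.normalized_entropy(r, binning) for r in trimmed]
    rmses = [qt.normalized_rmse(r, grid.scales) for r in trimmed]
    keep = qt.filter_quant(trimmed, entropies, rmses, config.entropy_thresh, config.rmse)
    filtered = [trimmed[i] for i in keep]
    entropies = [entropies[i] for i in keep]
    rmses = [rmses[i] for i in keep]
    counts["filtered"] = len(filtered)

    saliencies = [qt.jet_saliency(r, config.angle_range, config.ang_frac,
                                  config.sum_cond, config.agg) for r in filtered]

    # --- significance -------------------------------------------------------
    ks_stats, pvals = [], []
    for r in filtered:
        t_obs, t_null = sig.ridge_ratios(r, obs_strip.pixels, null_strip.pixels)
        ks, p = sig.ks_pvalue(t_obs, t_null)
        ks_stats.append(ks)
        pvals.append(p)

    kept_idx = sig.remove_overlaps(filtered, pvals, saliencies,
                                   radius=config.overlap_radius,
                                   iou_threshold=config.iou_threshold)
    counts["deduplicated"] = len(kept_idx)
    candidates = [filtered[i] for i in kept_idx]
    pvals = [pvals[i] for i in kept_idx]
    ks_stats = [ks_stats[i] for i in kept_idx]
    saliencies = [saliencies[i] for i in kept_idx]
    entropies = [entropies[i] for i in kept_idx]
    rmses = [rmses[i] for i in kept_idx]
    p_corr = sig.bh_correct(pvals)

    # --- tables -------------------------------------------------------------
    rows, expanded_rows = [], []
    for k, r in enumerate(candidates):
        uid = f"{r.chromosome}_jet_{k}"
        metrics = qt.summary_metrics(r, strip.pixels)
        # bedpe anchors: nearest-diagonal point projected onto the diagonal,
        # and the far bin (x' + d/2) of the tip point
        origin_bin = int(round(r.shifted_x[0]))
        tip_d = float(strip.distance_bins(r.points[-1, 0]))
        tip_bin = int(round(r.shifted_x[-1] + tip_d / 2.0))
        rows.append({
            "unique_id": uid, "chromosome": r.chromosome,
            "start_bp": metrics["start_bp"], "end_bp": metrics["end_bp"],
            "end_bp_halfopen": metrics["end_bp_halfopen"],
            "length_bp": metrics["length_bp"], "saliency": saliencies[k],
            "entropy": entropies[k], "rmse": rmses[k],
            "ks_stat": ks_stats[k], "p": pvals[k], "p_corrected": p_corr[k],
            "input_mean": metrics["input_mean"], "angle_mean": metrics["angle_mean"],
            "width_mean": metrics["width_mean"], "detected_scale": r.scale,
            "n_points": r.n_points, "origin_bin": origin_bin, "tip_bin": tip_bin,
        })
        theta = r.samples["Theta"][:, r.scale_index]
        lam = r.samples["Lambda"][:, r.scale_index]
        for i in range(r.n_points):
            expanded_rows.append({
                "unique_id": uid, "chromosome": r.chromosome, "position": i,
                "bin": float(r.shifted_x[i]),
                "bp": float(r.shifted_x[i]) * r.resolution,
                "distance_bins": float(strip.distance_bins(r.points[i, 0])),
                "angle": float(theta[i]), "strength": float(lam[i]),
                "width": float(r.widths[i]),
            })
    summary = pd.DataFrame(rows, columns=[
        "unique_id", "chromosome", "start_bp", "end_bp", "end_bp_halfopen",
        "length_bp", "saliency", "entropy", "rmse", "ks_stat", "p", "p_corrected",
        "input_mean", "angle_mean", "width_mean", "detected_scale", "n_points",
        "origin_bin", "tip_bin"])
    expanded = pd.DataFrame(expanded_rows, columns=[
        "unique_id", "chromosome", "position", "bin", "bp", "distance_bins",
        "angle", "strength", "width"])
    for stage, n in counts.items():
        logger.info("%s: %s ridges after %s", chromosome, n, stage)
    return JetResult(config=config, chromosome=observed.chromosome, ridges=candidates,
                     summary=summary, expanded=expanded, stage_counts=counts, strip=strip)
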