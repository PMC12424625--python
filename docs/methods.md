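# Methods

## The object and the approach

Chromatin jets (also called fountains or plumes) appear in Hi-C, Repli-HiC,
Micro-C and ChIA-PET contact maps as diffused lines running perpendicular to
the main diagonal, the footprint of two-sided cohesin loop extrusion or of
coupled replication forks. In the 45°-rotated *strip* of the contact map a
perpendicular jet is a near-vertical bright ridge rising from the diagonal.
`chromjet` detects these ridges by multi-scale image analysis and scores them
with a local enrichment test.

The pipeline for one chromosome:

1. **Images.** The contact matrix `A` (p×p, zero-sum rows/columns removed) is
   log-transformed (observed counts only), percentile-clipped, min-max
   normalized, and resampled into a strip `I` of `h` rows × `p` columns where
   one column = one genomic bin and one row = one bin of genomic distance
   (row index increases toward the diagonal). Three sibling images share the
   geometry: `I_obs` (observed, for the test), `I_null` (the strip of the
   column-correlation matrix `(1/p)·A'ᵀA'` of the z-scored observed map,
   which preserves banding but not jet-specific center-over-flank
   enrichment), and the *corner image* (the correlation strip of the
   windowed O/E map, used only for the saddle condition).
2. **Scale space.** `I` is blurred at a geometric grid of scales
   (default `1.5^1 … 1.5^7`, 24 points; a `jet_widths=(b_lb, b_ub)` setting
   converts widths to scales via `s = b/(2√3) + 0.5` and samples log-space at
   resolution 0.25 with between 3 and 30 points; scales above `min(m,n)/4`
   are dropped). Derivatives are γ-normalized (`× s^(γ·order)`), so a
   structure's response peaks at the scale matching its size. Per pixel and
   scale we keep: ridge strength Λ (principal eigenvalue of the negated
   Hessian, clipped at 0), tangent angle Θ ∈ [0°,180°), the second eigenvalue
   Ψ, the boolean ridge condition R (Lindeberg's crest test in the
   principal-curvature frame), and the corner condition C (saddle test on the
   corner image).
3. **Tracing.** A Steger-style detector finds sub-pixel line points
   (second-directional-derivative response above threshold, crest offset
   inside the pixel), links them by orientation continuity with hysteresis,
   and measures per-point widths from the flanking extrema of the
   directional derivative along the normal (search limited to 2.5·s per
   side; a side without an interior extremum contributes 2.5·s and is
   flagged). Traces are pooled across all scales.
4. **Refinement.** Points are ordered from the diagonal outward; points
   outside the map or within `rem_k_strata` pixels of the diagonal are
   dropped; ridges whose nearest point is farther than `root_within` pixels
   from the diagonal are discarded; coordinates are shifted back through the
   removed-bin bookkeeping. Four trims cut a ridge at the first offending
   position: a corner detected at *every* scale; a tangent angle outside
   `angle_range`; Ψ turning negative after its first non-negative peak; and
   a relative coordinate-shift jump of ≥ 5 bins across an unmappable gap
   (the background-dim side is removed).
5. **Quantification.** Per ridge: normalized Shannon entropy of the
   histogram of scale-averaged strength (near 1 when conflicting structures
   coexist in scale space), the RMSE of a cubic fit to the per-position
   expected scale divided by the ridge length (large when the scale jumps
   abruptly), and *jet saliency* — the sum (or mean) of per-point strength
   weighted by angle/ridge/corner indicator weights, with an optional
   across-scale angle-stability factor.
6. **Testing.** At each ridge point, a width-wide, 1-px-high box oriented
   along the normal is sampled on `I_obs` and `I_null`, together with two
   flanking boxes displaced by one box width along the normal. The ratio
   mean(center)/mean(flanks) per point gives two vectors; a one-sided
   two-sample Kolmogorov–Smirnov statistic `sup_t F_null(t) − F_obs(t)` with
   the asymptotic p-value `exp(−2d²nm/(n+m))` asks whether observed ratios
   are stochastically larger. Overlapping ridges (multi-scale duplicates)
   are removed greedily, keeping the lowest p-value in each group of ridges
   whose 7-px-buffered footprints overlap with IoU > 0.05. Benjamini–
   Hochberg correction and the final gates (corrected p ≤ α, saliency at or
   above a percentile of the candidate saliencies) produce the jet table.

## Parameters that matter

| parameter | default | unit | why |
|---|---|---|---|
| `window` | 5 Mb | bp | maximal genomic distance analyzed; jets rarely exceed a few Mb |
| `im_vmin`/`im_vmax` | 1 / 99 | percentile | clip outliers before normalization |
| `gamma` | 0.75 | — | makes the strength-maximizing scale equal a Gaussian bar's cross-section exactly (s*² = 2γσ₀²/(3−2γ) = σ₀² at γ=0.75), the cleanest calibration of scale ↔ width |
| `thresholds` | (0.5/255, 1.36/255) | response | fixed hysteresis pair, independent of image statistics: the classic single-scale ridge-detection defaults for 8-bit images rescaled to [0,1] intensities. `auto_thresholds` switches to per-scale estimation from the 25th/90th percentile contrast through the bar-response formula |
| `angle_range` | (60°, 120°) | degrees | perpendicular jets are 90° in strip space |
| `rem_k_strata` | 2 | px | the first strata hug the diagonal singularity |
| `root_within` | 15 | px | a jet emanates from the diagonal; its traced root must lie near it. 15 px covers the root displacement caused by blurring at detection scales up to ~6. Without this gate, detached local enrichments (noise speckle far from the diagonal, where counts are low) enter the candidate set and — being genuine local enrichments — pass the KS test |
| trim floors | 2 | bins | a trim may never leave fewer than 2 points |
| `psi_tol_frac` | 0.05 | fraction | Ψ must fall below −5% of the ridge's peak strength to count as "negative": along a genuine straight ridge Ψ fluctuates numerically around zero (±few % of Λ) and an exact sign test truncates at the first wiggle |
| `entropy_thresh` | 0.9 | — | entropies near 1 indicate conflicting structures; genuine long jets score ~0.7 because their strength spans many histogram bins, so the filter only removes extremes |
| `rmse` | 0.5 | scale units / position | the double-normalized RMSE of real jets is ~0.003; 0.5 only rejects egregious scale-jumpers |
| `alpha` | 0.1 | — | corrected-p cutoff, the study-level setting |
| `saliency_thresh` | 0 | percentile | the percentile gate is *relative*: on a whole real chromosome with hundreds of candidates, keeping the top decile (the setting 90 used for study-level ranking) is meaningful; on small candidate sets it caps output at ~10% of candidates regardless of evidence, so the tool default reports every statistically significant jet |
| `overlap_radius` / `iou_threshold` | 7 px / 0.05 | | buffered-footprint deduplication |

Experiment presets only alter defaults (`hic`: observed counts;
`replihic`: O/E with narrower `jet_widths=(2,30)`), never the code path.

## The synthetic generator

`chromjet.synthetic` emulates a single-chromosome contact map:
expected counts `μ(i,j) = base·(|i−j|+1)^(−α)` with α = 1 (the classic
distance-decay slope in the sub-10-Mb range) and `base = 5000` counts on the
diagonal bin — the depth of a deeply sequenced in situ Hi-C library at 25 kb,
giving a Poisson coefficient of variation of ~10% at mid-window distances.
Confounders multiply μ: TAD blocks, loop dots (Gaussian bumps), architectural
stripes, and unmappable zero rows. Jets are planted *multiplicatively on μ
before noise* (so O/E-derived images see them too) along a strip-space locus
with controlled origin, angle, curvature, linearly interpolated Gaussian
cross-section (diffuseness), and tip decay; truth is stored in strip space
(crest coordinates + a ±2σ mask) so scoring does not depend on the
matrix↔strip transform under test. Noise is Poisson on the upper triangle,
mirrored.

What the generator does **not** emulate: balancing artifacts,
compartment-scale plaid patterns, translocations, copy-number steps, and the
long-range contact enrichment of real chromatin beyond the power-law decay.
Passing the recovery suite therefore demonstrates correct mechanics of
detection, trimming, testing and deduplication under realistic depth and
decay — not performance on compartment-rich real maps, where the entropy and
corner criteria carry more of the load.

Recovery scoring: a planted jet is recovered when one called ridge covers at
least half of its crest pixels within 2 px laterally; a call is a true
positive when at least half of its points lie that close to some crest. With
no calls at all, precision is reported as 1 with a zero-support flag.

## Numerical choices

- Eigen-decompositions of the 2×2 Hessian are closed-form and vectorized;
  isotropic pixels take eigenvector (1,0). All eigen maps are computed on
  −H so bright ridges carry positive strength; the printed "+90°" then turns
  the principal direction (the ridge normal) into the tangent.
- "Zero" tests on sampled images (`I_v = 0`, `I_p = 0`, Ψ sign) use relative
  tolerances (10⁻³ of the map's maximum; 5% of peak strength for Ψ).
- Derivative kernels are truncated Gaussians; the image mean is subtracted
  before filtering because a truncated order-2 kernel does not sum exactly
  to zero and would leak a constant-offset bias (~2·10⁻⁴ per unit offset)
  into every curvature estimate.
- The strip is built directly from matrix diagonals (odd-distance strata
  average the two adjacent entries), which is the invertible resampling of
  the 45° rotation; round-trip pixel↔bin error is ≤ 1 bin everywhere.
- The correlation matrix uses sample-sd z-scores with the 1/p prefactor
  (equal to Pearson × (p−1)/p); min-max normalization downstream makes the
  scalar irrelevant.
- Cubic fits for the scale-RMSE reduce their degree to N−1 for ridges of
  N ≤ 4 points, which then score exactly 0 and trivially pass the filter.
- Ridges shorter than 2 points are discarded at every stage; ties in the
  deduplication argmin are broken by higher saliency, then lower index.
- All randomness flows through explicit seeds; a run is bit-reproducible.

## Design choices where the design was open

- **Flank placement.** The flanking boxes sit one box-width away along the
  ridge *normal*: jets are enriched relative to their sides, not along
  their length.
- **Threshold default.** The hysteresis pair is fixed (not image-adaptive),
  which keeps the response scale interpretable across scales and datasets;
  the percentile estimator remains available but is conservative for
  diffuse, low-contrast ridges (its bar-response model assumes a sharp
  boxcar profile).
- **Null image.** The column-correlation strip preserves distance banding
  and compartment texture while destroying the point-wise center-over-flank
  excess of a jet, which is exactly the contrast the test needs.
- **Length vs. saliency.** Saliency aggregates per-point strength with
  `agg="sum"` by default, so long coherent jets rank far above short
  enrichments without introducing an explicit length cutoff.

## Problem sizes used in the test suite

The recovery suite runs the full default pipeline on twenty 1,000-bin
chromosomes (150-bin window, three planted jets each, contrast 5, widths
2–6 bins); the false-positive calibration runs one hundred 400-bin jet-free
chromosomes. These sizes exercise every code path at a few seconds per
chromosome; behavior at full chromosome scale (5,000–10,000 bins) is the
same algorithmically, with runtime growing linearly in strip area × scales.

## Known limitations

- No scale-linking: the same physical jet detected at several scales is
  reconciled only by the final overlap removal, not by tracking structures
  across scale space.
- The asymptotic one-sided KS p-value is conservative for very short ridges
  (n < 5 ratio pairs); an exact test is deliberately out of scope.
- The statistical test conditions on ridge detection: any traced crest is a
  genuine local enrichment, so p-values rank jet-ness rather than control a
  detection-wide error rate. The diagonal-root requirement and the
  quantification filters carry the burden of excluding non-jet enrichments.
- Curved jets are traced and scored, but the monotone-column ordering
  assumption behind the trims is only asserted for non-curved ridges;
  strongly curled jets may be trimmed early.
- `.hic` input requires the optional `hicstraw` reader; `.cool`/`.mcool`
  support is a minimal single-resolution reader/writer on the public cooler
  HDF5 schema, not a full cooler implementation (no multi-resolution
  aggregation, no balancing).
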