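# Methods

## The measurement model

A mitotic GSPC is represented by the trajectories of its two spindle poles,
`p1(t), p2(t) ∈ R³` (μm, one sample per frame, frames `frame_interval`
minutes apart). Spindle length is the Euclidean pole-to-pole distance
`L(t) = |p1 − p2|` and the spindle axis is the undirected unit vector along
`p1 − p2` (pole labels are arbitrary, so any statistic of the axis must be
invariant to its sign; inter-frame angles are folded to [0°, 90°]).
Coordinates are assumed drift-corrected upstream (XY registration of the
raw movies is out of scope); no gap interpolation is done at I/O time —
frames missing from either pole are simply absent, and each consumer
declares its own gap policy.

## Landmark scoring from spindle length

The stereotyped GSPC length trace motivates three landmarks: NEBD (onset of
the collapse), the "start" of mitosis `t_s` (first point after NEBD at the
stable minimum — used as the start of the duration measurement because it
is far less ambiguous than NEBD itself), and anaphase onset `t_AO` (after
which length rises rapidly). `duration = t_AO − t_s`.

The scorer (`timing.score_landmarks_from_length`) is deterministic:

1. smooth `L` with a centred moving median (window 3 frames);
2. estimate the plateau level `B` as the median of the smoothed frames in
   the lower quarter of the smoothed min–max range, and define the plateau
   band as frames within ±`delta`·B of B (`delta` = 0.15);
3. `t_AO` = last band frame followed by a net smoothed increase
   ≥ `rise_frac`·B (0.25) within `rise_window_min` (4.0 min);
4. `t_s` = first band frame at/after the pre-plateau maximum;
5. NEBD = last pre-start frame on a falling run whose smoothed length
   exceeds B·(1 + `delta_nebd`), `delta_nebd` = 0.30.

All thresholds are relative to B, so scoring is invariant to the length
unit; all five numbers are configurable (`LandmarkConfig`). Two estimator
choices matter at realistic noise and were fixed on simulations: anchoring
B at the smoothed *minimum* (the obvious choice) biases `t_s` late and
`t_AO` early because the band hugs the noise floor, and a short rise
look-ahead can miss anaphase entirely when noise lifts the last plateau
frames out of the band — hence the lower-quarter median and the 4-min
window. Monotone series raise "no metaphase plateau"; a plateau with no
subsequent rise raises "no anaphase elongation"; gaps longer than 2 frames
inside the plateau flag the cell rather than failing it. Flags are never
silent guesses — flagged cells are for human follow-up.

Note one deliberate asymmetry against the generative model: the generator's
`t_nebd` marks the *onset* of the collapse, while the scored NEBD is a
threshold crossing *during* it. Duration is unaffected (it starts at
`t_s`), which is exactly why `t_s` and not NEBD anchors the measurement.

## Timing from chromatin-signal variance

Where no spindle marker is available, mitotic timing is read from the
pixel-intensity variance of a histone marker within a 4.5 μm nuclear ROI
(per frame: mean-projection of 5 z-slices centred on the tracked nucleus,
variance inside the circle, then min–max normalisation per cell). Variance
is low in interphase, rises sharply as chromosomes congress, and falls
sharply at segregation. NEBD is the last time point with normalised
variance < 0.5 *before the global maximum*; anaphase onset is the last time
point > 0.7. Both thresholds are strict inequalities. The before-max
restriction resolves the ambiguity that post-anaphase frames also sit below
50%; since the maximum normalises to 1 > 0.7, anaphase onset is always
defined.

## The nine spindle features

Per cell, with `C` the mean length on `[t_s, t_AO]` (closed window):

| feature | definition | units |
|---|---|---|
| A | mean of the 3 largest `L` in `(t_NEBD − 3 min, t_NEBD]` | μm |
| B | `t_AO − t_s` | min |
| C | mean `L` on `[t_s, t_AO]` | μm |
| D | SD (ddof 1) of 7 values of `L/C` sampled without replacement from `[t_s, t_AO]` | — |
| E | mean over consecutive frame pairs of `|ΔL|/C·100/Δt` | %/min |
| F | mean inter-frame axis angle / Δt on `[t_s, t_AO]` | °/min |
| G | least-squares slope of `L` vs `t` on `[t_AO, t_AO + 2.5 min]` | μm/min |
| H | F's formula on `[t_AO, t_AO + 2.5 min]` | °/min |
| I | second-largest `L` at `t ≥ t_AO + 7 min`, ×100/C | % of C |

Two conventions are genuinely open and therefore explicit, recorded in the
output and configurable: D samples **without replacement** under a seed
stored alongside the value (reproducibility of an otherwise stochastic
feature), and E uses the **absolute** frame-to-frame change — the feature
quantifies fluctuation, and a signed mean would cancel to ≈ 0 on any
plateau. Ties for I's "second largest" keep duplicates (descending sort,
rank 2). Features whose time window is not covered (e.g. a movie starting
mid-collapse) come back as NaN with a flag; the rest of the vector is still
computed. With fewer than 8 in-mitosis frames D is computed on all frames
and flagged.

## Cohort statistics

- **Outliers**: per (feature, genotype), values outside
  `[Q1 − 1.5·IQR, Q3 + 1.5·IQR]` are set missing in a single pass over the
  unfiltered data (the rule is not idempotent under reapplication, by
  design); duration is never filtered; every removal is logged. Groups
  below 4 cells are skipped per feature. Quartiles and percentiles use
  linear interpolation between order statistics throughout the package.
- **Standardisation**: `(x − μ)/σ` with ddof-1 σ, referenced either to the
  pooled cells (correlations, PCA) or to the control group (heatmap scale).
  Columns whose σ is at float-rounding scale are dropped and reported.
- **Group comparisons**: Kruskal–Wallis omnibus per feature, then a
  Tukey–Kramer-style post hoc on mean ranks (tie-corrected rank variance,
  studentized-range reference at large df), reporting only control-vs-group
  contrasts at α = 0.05. p-values from the original study's statistical
  environment are not expected to match digit-for-digit; the layer is
  validated by calibration properties instead (see tests). For small groups
  the omnibus can be switched to a label-permutation null.
- **Heatmap**: entry(feature, genotype) =
  `(mean_g − mean_control)/SD_control` — "number of control SDs above/below
  the control mean" — computed after outlier removal, with the post hoc
  significance mask attached. Pooled-SD scaling is available as an option.
- **Duration correlations**: Pearson r of each feature (pooled across
  genotypes, standardised) against duration, p × m with m = 8 (features
  A, C–I), reported as r when adjusted p < 0.05 and as 0 otherwise.
- **PCA**: eigendecomposition of the covariance of the standardised
  features, complete cases only (listwise deletion; univariate statistics
  use pairwise deletion). Loading signs are fixed so each vector's
  largest-magnitude element is positive. Run after outlier removal by
  default; the pre-removal order is available and the choice is recorded in
  the run config.
- **Delayed cells**: duration > 90th percentile of the in-run control
  durations (≥ 10 controls required). On a continuous control population
  this labels 10% of control itself — the natural calibration check.

Tests operate per cell by default; per-gonad-arm means are computed
alongside (the screen reports both) and the statistical unit is a config
switch.

## Intensity quantification

- **N:C ratio**: nuclear mean over a 4.5 μm disk; cytoplasmic mean over the
  donut formed by enlarging the radius 1 μm, minus any neighbour-nucleus
  masks; both background-subtracted (mean per-pixel FI over rectangular
  ROIs outside the animal, or a precomputed scalar; an optional matched
  autofluorescence image can be subtracted first). The ratio is invariant
  to adding a constant everywhere and to positive rescaling. A cytoplasmic
  mean at or below background flags the cell as undefined rather than
  returning a wild ratio. Pixel convention: 0-based indices, pixel centres
  at (i + 0.5)·pixel_size, half-open ROI rectangles.
- **Pre-mitotic N:C**: mean of the 3 highest ratios at least 10 min before
  NEBD (nuclear enrichment starts changing inside that window); 1–2
  eligible frames are averaged with a flag, none is an error.
- **PZ nucleus counting**: per frame, background subtraction (constant
  offset, per-frame median by default), median 3D filter (XY radius 2 μm,
  Z radius 1 μm, converted to pixels), Gaussian blur σ = 2 px (the pixel
  interpretation is the convention of the GUI the recipe comes from;
  configurable); detection by Difference of Gaussians at blob diameter
  4.25 μm, with the DoG σ reduced per axis by the blur the preprocessing
  already applied (floored at 0.5 px) — without this compensation,
  neighbouring nuclei merge into single maxima; linking by greedy nearest
  neighbour within 3.0 μm with ≤ 2-frame gap closing (at PZ spacings the
  assignment is unambiguous, so a full linear-assignment linker would
  produce identical links); count = tracks persisting ≥ 5 frames inside
  the PZ ROI. The detection threshold is relative to the response maximum
  (intensity-rescaling invariance) with a floor at what pure pixel noise
  could produce — the raw noise σ is estimated from adjacent-voxel
  differences and propagated through the linear kernels — so an
  object-free field yields zero. Mitotic cells are a manual count supplied
  by the user (two discernible poles is a visual call); the mitotic index
  is their ratio.
- **Assay arithmetic**: per-class percentages for the three mitotic-error
  classes (no defect / prometa-metaphase misalignment / anaphase
  lagging-bridging-misalignment), percent embryonic lethality
  (unhatched/total), reporter-depletion FI (mean of three germline ROI
  means minus matched background, clamped at 0, optionally normalised to a
  reference group), and a two-sided Fisher exact test for error/no-error
  counts between two conditions.

## The synthetic generators

The generators produce the study's data *shapes* with exact ground truth;
they are deliberately not photorealistic (no PSF, no bleaching, no animal
movement — registration is upstream of this pipeline).

- **Spindle tracks**: piecewise kinematic length profile — constant
  `pre_nebd_separation`, linear collapse on `[t_nebd, t_s]`, plateau
  `metaphase_length` + N(0, `plateau_noise_sd`), linear elongation at
  `elongation_rate` capped at `telophase_peak`, then relaxation at
  `relax_rate` (floored at 80% of the peak) so the telophase feature's
  "second largest late length" is single-peaked and well defined. A small
  localisation noise (`length_noise_sd`, 0.05 μm) applies to *every*
  frame — without it pre-NEBD separation is bitwise constant across cells
  and the cohort statistics would operate on a degenerate column. The axis
  rotates each frame by N(0, `rotation_rate_sd`·Δt) about a random
  perpendicular; both poles share a random-walk centroid
  (`centroid_drift_sd`). Ground-truth landmarks are snapped to the frame
  grid. Defaults (0.5 min/frame; 5.0 → 3.5 μm collapse; 1.2 μm/min
  elongation to an 8.0 μm peak; 5°/min rotation; control duration
  4.5 ± 1 min, consistent with control GSPC mitosis averaging under
  6 min) are *illustrative* magnitudes realistic for ~4 μm germline
  nuclei, chosen once — the study does not print its kinematic magnitudes,
  so passing recovery tests demonstrates correctness of the scoring logic
  at these noise scales, not performance on any particular real dataset.
- **Chromatin traces**: baseline before `t_nebd`, smoothstep rise to the
  peak over 1.5 min, plateau, smoothstep fall over 1.0 min after `t_ao`;
  exact extrema by construction. `render_chromatin_stack` embeds the trace
  in pixels by scaling a fixed zero-mean unit-variance texture inside the
  ROI, so the pixel-variance reader can be validated end to end.
- **Nucleus renders**: flat disks — nucleus at `true_nc_ratio` ×
  cytoplasm above background inside a cytoplasmic cell disk, neighbours at
  nuclear intensity, additive background, optional Gaussian noise.
  Neighbours may not overlap the central nucleus.
- **PZ fields**: hard-minimum-spacing random sequential placement in a box,
  Gaussian blobs of FWHM = 4.25 μm, per-frame positional jitter
  (0.15 μm), Gaussian noise at amplitude/`snr`. Defaults: 5.5 μm minimum
  spacing in an 85 × 35 × 16 μm box — slightly sparser than a real
  proliferative zone, because Gaussian blobs at FWHM = diameter are
  optically wider than real chromatin and their maxima merge analytically
  below ~4.6 μm separation. Counting at true germline crowding therefore
  has to be verified on real images; an infeasible packing request fails
  with the achievable density.

## Problem sizes and numerics

The shipped analyses and tests use 20 cells per genotype (3 genotypes),
200 tracks for landmark-recovery benchmarks, 120 nuclei at SNR 5 for
counting benchmarks, 1000 null cohorts of 300 cells for the family-wise
error calibration, and 10⁴ control durations for the delayed-rule
calibration — sizes at which every Monte-Carlo margin in the tests is much
larger than simulation noise. Seeds are explicit everywhere; a fixed seed
reproduces every output byte for byte (CSV floats are written at full
round-trip precision, and spot tables are re-read with round-trip float
parsing). Degenerate inputs are contracts, not surprises: zero-σ features
drop with a log entry, all-tied comparisons are flagged degenerate,
constant traces refuse normalisation, and ratio denominators at or below
background flag rather than divide.

## Limitations

- The landmark scorer's thresholds are calibrated on the synthetic
  kinematics only; real traces with atypical shapes (double dips, long
  pre-anaphase drift) will land in the flagged population and need human
  review — by design, matching the original workflow's discard-or-rescore
  rule for ambiguous plots.
- Post hoc p-values follow the rank-based studentized-range convention;
  other environments' multiple-comparison routines will differ in the low
  decimals.
- The PZ counter is validated on Gaussian-blob fields sparser than a real
  proliferative zone (see above); the preprocessing recipe itself follows
  the published parameter set exactly.
- Mitotic-cell identification (for the mitotic index) and error-class
  scoring are human calls; only their arithmetic lives here.
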