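# Methods

This note documents the models, estimators and numerical choices behind
`rootphen`, in the spirit of a package methods appendix: what is computed,
under which assumptions, and what the synthetic validation does and does
not demonstrate.

## Coordinate conventions and calibration

Plates are imaged upright, so image rows increase in the direction of
gravity.  All geometry uses 0-based pixel centers; metric quantities come
from a single `px_mm` calibration (mm per pixel) per study.  In metric
space, positions are `(x, y)` mm with gravity along +y; angles are unsigned
degrees from the gravity vector in `[0, 180]` (a signed variant, positive
toward +x, is available behind a flag — published root angle phenotypes are
magnitudes, so unsigned is the default).

## Skeleton graph and MR/LR decomposition

Each binary mask is reduced to the 8-connected component containing (or
nearest to, within `seed_attach_radius_px` = 20 px) the per-plant seed
point; other components are ignored with a warning, which absorbs typical
segmentation debris.  The component is thinned homotopically to a
1-pixel-wide skeleton (`skimage.morphology.skeletonize`; the contract is
the 1-px-width invariant, not a particular algorithm), which is then
converted to a graph:

* pixels with ≠ 2 skeleton neighbours are node pixels; 8-connected
  clusters of junction pixels (a T crossing produces up to four adjacent
  pixels of degree ≥ 3) are contracted to one representative node, so a
  single branch point is a single node;
* edges are ordered pixel chains between nodes, with arc length equal to
  the sum of inter-pixel Euclidean steps × `px_mm`;
* endpoint chains shorter than `prune_len_mm` (default 0.3 mm) are pruned
  iteratively — they are thinning artefacts of mask boundary noise;
* the graph is rooted at the skeleton **pixel** nearest the seed point,
  splitting its chain if that pixel is mid-chain.  Rooting at the nearest
  *node* fails when the first LR emerges at the very top of the MR: spur
  pruning can dissolve the seed-end junction, leaving the nearest node far
  down the plant.

The main root is the root-to-endpoint path of maximal arc length; ties
(within 1 µm) are broken by the smallest mean absolute angular deviation of
the chain segments from gravity, i.e. the most vertical candidate.  This is
a graph-geometric reinterpretation of an MR/LR distinction that upstream
segmentation systems make with a learned multi-class model; for
single-plant masks of a dominant vertical axis the two agree.

Every maximal subtree hanging off the MR becomes one lateral-root
observation whose polyline is the longest base-to-endpoint path in the
subtree; LRs shorter than `min_lr_len_mm` (default 0.5 mm) are discarded.
Crossing roots within one plant are out of scope (a projection crossing
merges subtrees and no purely graph-based rule can split them).

### Junction-base correction

Thinning pulls the branch fork of a Y into the acute angle between LR and
MR, displacing the apparent LR base a few pixels along the MR.  For a 2-mm
traversal this displacement rotates the emergence chord by 1–3°, a
systematic overestimate.  The decomposition therefore re-anchors each LR:
the leading chain pixels within `junction_trim_px` (default 3 px) of the MR
are dropped, the LR's initial direction is estimated from the first
~0.6 mm of clean chain, and the base is re-located where that line meets
the MR polyline.  On rendered ground truth this reduces the mean emergence
angle error from ≈ +1.6° to ≈ ±0.3°.  Setting `junction_trim_px = 0`
disables the correction (used by the length-conservation check, which
requires the raw on-skeleton partition).

### Length measurement

Raw 8-connected chain lengths overestimate oblique lines by up to ~5%
(staircase effect).  Reported lengths are therefore measured on the chain
after a 3-point moving-average smoothing of the sub-pixel polyline, which
brings MR length recovery to < 1% error at 0.1 mm/px.  The residual LR
length error is an absolute junction-geometry effect of a few pixels, so
short LRs carry a proportionally larger relative error — a resolution
limit, not a tuning issue.

## Lateral-root tracking

LR observations are matched frame-to-frame by greedy nearest neighbour on
the base pixel, gated at `radius_px` (default 10 px); unmatched current
observations open new tracks.  Matching uses the *current* base position
rather than the first-seen one, tolerating the slow base drift as the plant
settles (the alternative — anchoring on the initiation pixel — is a
one-line change).  Greedy matching rather than optimal assignment mirrors
the per-pair position rule the field uses; with millimetre-scale base
spacing the two coincide.  Tracks seen in fewer than `min_track_frames`
(default 4) frames are dropped as segmentation flicker.  Stable labels are
assigned in order of first appearance (ties broken by base arc position,
apical last), so label 1 is the first-emerged LR — the input to the
first-LR decay analysis.

An LR becomes visible only once it exceeds the length filter, so detected
emergence lags true initiation by `min_lr_len_mm / lr_speed`; validation
compares detected emergence against the first moment the true LR is long
enough to be observable.

## Angle parameters

`gravity_angle` is `arccos(Δy/‖v‖)`, which generalises the right-triangle
`arctan(|Δx|/Δy)` construction to chords pointing at or above the
horizontal.  `base_tip_angle` applies it to the base→tip chord (interior
polyline points cannot affect it); `emergence_angle` to the chord ending at
arc length `distance_mm` (default 2 mm) along the skeleton, located by
linear interpolation within a segment, and is missing while the LR is
shorter than the traversal.  An MR-referenced variant (angle against the
local MR tangent instead of gravity) is available via the `reference`
argument, since the initial growth direction can also be defined against
the parent root; the gravity-referenced form is the default.  Chains are
smoothed by a 3-point moving average before evaluation (configurable off).
`mr_tip_angle` measures the chord over the last `window_mm` (default 1 mm)
of the MR, the readout used after 90° plate-rotation gravitropism assays.

`first_lr_decay_curve` selects label 1 per plant, bins its base–tip series
by hours since (detected) emergence, and aggregates the cohort as mean ±
SD per hour; `fit_gravitropic_decay` fits
`θ(t) = θ_final + (θ_e − θ_final)·exp(−κt)` by bounded least squares.

## Feature catalogue

Per frame: MR, LR (sum) and TR = MR + LR lengths (mm); LR count; LR density
`LR/MR` (mm·mm⁻¹); discrete LR density `10·n_LR/MR` (LRs·cm⁻¹); ratio
MR/TR.  With a zero-length MR the densities are undefined and reported
missing.  Frames (nominally every 15 min) are averaged to one value per
clock hour; hours without frames stay missing and are never interpolated at
this stage.

Growth speeds are central finite differences of the hourly lengths
(one-sided at the ends).  Root length cannot shrink, so negative speeds —
segmentation noise — are clipped to zero with the raw differences retained
for diagnostics.  Spectral features detrend the speed series by subtracting
a centred 24-h moving average (isolating the daily band), scale to unit
variance, linearly interpolate missing points (count logged), and report
the one-sided DFT amplitude spectrum on the grid `k/(NΔt)`; an all-constant
series yields a zero spectrum.

Convex-hull metrics are evaluated at one configurable hour per day
(default 8, nominally lights-on): hull area (shoelace, via Qhull), width
and height as bounding-box extents of the hull (equal to those of the point
set; hull-diameter variants were considered and rejected as less
comparable across plants), aspect ratio height/width, and MR/LR/TR length
per hull area.  Degenerate point sets get area 0 and missing densities.

## Cohort statistics

Every treatment line is tested against the control per feature × hour with
the two-sided Mann–Whitney U test (midrank ties): exact null enumeration
when the combined sample size is ≤ 12 with no ties, otherwise the normal
approximation with tie and continuity corrections.  Per-line significance
is flagged at α (default 0.05) and a joint flag marks feature × hour points
where *every* line is individually significant.  No multiple-testing
correction is applied by default — hourly tests of a growth trajectory are
strongly correlated and the field reports per-hour significance — but
Benjamini–Hochberg FDR (applied across hours within each feature × line)
is available behind a flag.  Hours where any group falls below `min_n`
plants (default 3) are skipped with a warning.

Superposition maps rotate each plant's segmentation about its MR start so
that the start-to-tip chord points straight down, translate the start onto
a common reference pixel, resample with nearest neighbour (keeping the mask
binary — bilinear would create fractional plant counts), and sum.  Plants
with a degenerate chord are excluded with a warning.

## Synthetic data generator

No generative model of root growth is claimed by the measurement method;
the simulator exists to provide controllable ground truth, and all its
parameters are package choices documented here, not biological claims.
Defaults emulate plausible Arabidopsis plate-assay magnitudes:

| parameter | default | meaning |
|---|---|---|
| `mr_speed` | 0.35 mm·h⁻¹ | MR elongation rate |
| `mr_wobble_sd` | 1.0°/step | MR heading random walk |
| `lr_emergence_rate` | 0.15 h⁻¹ | Poisson emergence rate on the mature zone |
| `maturation_lag_h` | 24 h | LRs emerge only on MR older than this |
| `min_base_spacing_mm` | 1.5 mm | rejection spacing between LR bases |
| `emergence_angle_mean/sd` | 65° / 10° | θ_e distribution (clipped to [0, 180]) |
| `bend_delay_h` | 10 h | emergence plateau before bending |
| `final_angle` | 25° | gravitropic set-point angle |
| `decay_rate_kappa` | 0.0385 h⁻¹ | bending rate (half-life ≈ 18 h) |
| `lr_speed` | 0.25 mm·h⁻¹ | LR elongation rate |

The LR tip position is constructed directly from the chord:
`tip(a) = base + lr_speed·a·u(θ(a))`, so the *true base–tip angle follows
the bending law exactly* and is unit-testable against the closed form;
during the plateau the proximal segment is laid down straight at θ_e, so
the 2-mm emergence chord equals θ_e by construction (with the default
`lr_speed`, the plateau covers 2.5 mm).  An earlier design that advanced
the tip along its instantaneous heading was rejected: the chord then
averages the heading history, matches neither the law nor θ_e, and leaves
no closed-form oracle.

Two realism constraints keep the decomposition well posed: a minimum base
spacing, and a clearance (`min_lr_clearance_mm` = 0.8 mm) between each LR
trajectory and both the other LRs and the wobbling MR (the opposite side is
tried first, then the emergence event is skipped).  Sparse Arabidopsis LRs
with similar set-point angles rarely cross in projection, so this stays
within realism — but it means the validation says nothing about crossing
roots, which the decomposition does not handle.

Rendering rasterises each polyline with anti-alias-free Bresenham segments
dilated to `stroke_width_px` (default 3), so masks are strictly binary;
geometry outside the image raises an error naming the frame.  Simulation is
bit-reproducible for a fixed seed (`numpy.random.default_rng`).

What the synthetic validation does **not** show: robustness to real
segmentation artefacts (holes, breaks, width variation, neighbouring
plants), root crossings, plate rotation mid-series, or learned MR/LR
labelling — the masks here are clean strokes of constant width.

## Validation problem sizes

The test suite and `scripts/acceptance.py` use rendered cohorts of 12–20
plants, 42–60 h at hourly measurement cadence, at 0.1 mm/px (0.04 mm/px for
the angle-recovery study), 50 seeds for the count-recovery sweep, 100
seeded replicates for null calibration of the rank-sum test and 20 per
offset for power; these sizes make the whole suite run in about a minute
while keeping Monte-Carlo margins comfortable.  Observed recovery on these
fixtures: emergence angle within ±1° (mean ≈ 0.3°), base–tip law deviation
≈ 0.5° mean, MR length < 1% error, LR counts exact on all seeds, κ
recovered within ~7%, null false-flag rate ≈ 0.04–0.055 against α = 0.05,
and 100% power for a 20° offset at n = 15 per group.

## Known limitations

* One plant per mask region; no disambiguation of touching neighbours.
* No track splitting/merging repair and no occlusion reasoning.
* Emergence timing is right-censored by the visibility threshold.
* Relative LR length error grows as LRs approach the minimum length.
* The hull "width/height" are axis-aligned extents, not rotated calipers.
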