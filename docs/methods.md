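# Methods

This note documents the models, algorithms, and numerical choices behind
`octaquant`, in the order the pipeline applies them, together with what the
synthetic phantoms do and do not establish about real data.

## Angiography reconstruction (eigen-decomposition clutter filter)

OCT angiography derives flow contrast from N repeated frames at each
location: red blood cells decorrelate the signal between repeats while
static tissue does not. The reconstruction treats the repeats as N vectors
(one per frame) over the voxels of a local window, forms the N x N
inter-frame covariance of the mean-frame-removed vectors, and projects out
the `n_static` leading eigenvectors — the subspace where coherent (static)
energy concentrates. The per-voxel mean square of the residual across frames
is the angiography signal.

Choices that matter:

- **Mean-frame removal** (subtracting the per-frame mean over the window's
  voxels) rather than a scalar or per-voxel temporal mean. A per-voxel
  temporal mean would remove all static signal before the eigen-step and the
  leading eigenvector would then be the *flow* signal, inverting the filter's
  meaning. Mean-frame removal keeps a rank-k static pattern exactly rank k
  (so removing k components cancels it to machine precision) and makes the
  output exactly invariant to a global intensity offset.
- **Windowing**: the filter runs in overlapping `window_z x window_x x
  full-Y` blocks (defaults 32 x 32) with 50% stride, blended with strictly
  positive triangular weights. Overlap-plus-blending prevents block seams
  that would otherwise bias the downstream global threshold. A single window
  covering the volume reproduces the unwindowed filter exactly.
- **`n_static` = 1** by default: with N = 4 repeats the covariance has four
  eigenvalues and removing more than one clutter component leaves too little
  signal subspace to be robust.
- **Display/quantification scale**: the residual energy is converted to
  amplitude (square root) before projection and thresholding, optionally to
  decibels with a 30 dB floor (`amplitude_db`). Energy spans the square of
  the signal's dynamic range and defeats histogram-based thresholding; the
  amplitude/dB scale is the field's display convention.

The filter is a windowed-eigendecomposition *variant* ("wED-like" in the run
log): published wED filters differ in window geometry and regularization
details, and this implementation documents its own. A per-voxel temporal
variance baseline (`reconstruct_variance`) is provided for comparison.

## Depth-of-interest selection

Oral mucosa shows no sharp epithelium boundary under OCT, so depth layers
are chosen from the signal itself. The depth profile is the mean OCTA
intensity per axial slice (averaging ~10^4–10^5 lateral pixels, so its noise
is negligible). Two landmarks are detected on a 5-slice moving average of
the profile:

- **end depth** — the deepest slice whose smoothed intensity still reaches
  the mean over all depths, read as the last down-crossing of the mean level
  (exact equality almost never occurs on sampled data). Below it only the
  noise floor remains.
- **separation depth** — the global maximum of the smoothed profile between
  a surface guard (`z_min`, by default the first slice exceeding 10% of the
  profile maximum, which skips specular surface reflections) and the end
  depth. Ties break toward the surface. The maximum marks the depth where
  the superficial vascular plexus is densest.

DOI 1 = slices `[0, separation)`, DOI 2 = `[separation, end)`, both
half-open and 0-based; slices at or below the end depth belong to neither.
Splits with the separation within 2 slices of the top or the end are
rejected as degenerate. The 5-slice smoothing window is deliberately shorter
than a typical plexus band: a window wider than the band makes every window
containing the band sum to the same value, and the tie-break then
systematically parks the peak at the plateau's shallow edge.

Each DOI is collapsed to an en face image by maximum intensity projection.

## Vessel mask, skeleton, and segments

The binary angiography mask (BAM) combines three standard ingredients:

1. **Multi-scale Hessian vesselness** (Frangi filter, bright ridges, scales
   2/4/6/8 px spanning ~40–200 µm vessels at 13.125 µm/px), normalized to
   [0, 1] and compressed by a cube root before thresholding. The compression
   matters: the ridge response decays steeply toward vessel edges, and
   thresholding the raw response against a local mean erodes a ~1 px rim off
   every vessel (≈4 VAD points on tube phantoms).
2. **Adaptive threshold**: pixel above the local mean in a 101 px
   edge-replicated window (offset 0 on the compressed scale).
3. **Global Otsu gate**: pixel intensity above 0.6 x the 256-bin Otsu
   threshold. The gate suppresses the ridges the Hessian filter hallucinates
   in background noise; the 0.6 relaxation keeps dimmer distal vessels.

The mask is the AND of (1–2) with (3), followed by removal of objects under
30 px and filling of holes under 20 px.

The skeleton (BVS) is the topology-preserving medial axis of the BAM with
terminal spurs shorter than 5 px pruned, and any fully set 2 x 2 block
broken (the thinner of redundancy). Segments are obtained by cutting the
skeleton at junctions and keeping branch-free chains of length >= 5 px.
**Junctions are pixels with >= 3 connected runs of set neighbors in the
circular 8-neighborhood** (crossing number), not pixels with >= 3 set
neighbors: the raw count misclassifies pixels adjacent to a simple corner,
where two neighbors touch diagonally, and would cut every right-angle bend.
Branch pixels belong to no segment. Closed loops (capillary loops seen en
face) have no endpoints and a zero chord; they are cut at their
topmost-leftmost pixel, kept as one open segment, and flagged in the log.

**Chain length** is measured on the Douglas–Peucker simplification of the
pixel chain (tolerance 1 px), not by summing 1/sqrt(2) step weights. The
step metric overestimates the length of oblique digital curves by up to
8.2% (≈5.5% direction-averaged), which would bias every tortuosity value
upward by several points. The simplified polyline is exact on straight and
right-angled chains, reproduces 3 diagonal steps as 3·sqrt(2), and is ~1%
accurate on smooth curves; the 1 px tolerance absorbs rasterization jitter
without rounding genuine corners.

**Diameters** come from the Euclidean distance transform of the BAM:
`diameter = 2·(EDT − 0.5)` at each skeleton pixel. The half-pixel correction
accounts for the EDT measuring to the nearest background pixel *center*,
half a pixel beyond the vessel edge; without it an integer-radius tube reads
2r + 2 instead of ≈2r + 1.

## Metrics

Per DOI, from the maps above (X·Y = field-of-view pixels):

- **VAD** = 100 · ΣBAM / (X·Y) — vessel area density, %.
- **VSD** = 100 · ΣBVS / (X·Y) — vessel skeleton density, %.
- **VDI** = Σ_skel 2·disEu / ΣBVS · pixel_um — mean vessel diameter over
  skeleton pixels, reported in micrometers (13.125 µm/px default: 5.25 mm
  field sampled at 400 px).
- **TI** = (length/chord − 1) · 100 per segment — 0 for a straight vessel,
  ≈41.4 for a right angle, ≈57.1 for a semicircle.
- **WTI** = Σ_n d_n·TI_n / Σ_n d_n — segment TIs averaged with the
  segment's mean diameter as weight, so a tortuous arteriole counts more
  than an equally tortuous capillary. Unitless; equals the plain mean TI
  when all diameters are equal, and always lies within [min TI, max TI].

Local heatmaps use a moving square kernel (default 51 px, edge-replicated):
plain mean for density; for diameter and TI the mean over *non-zero* map
values only, since background zeros would dilute the local statistic, with 0
where the window contains no skeleton pixel.

**Repeatability** between repeated scans is the coefficient of variation per
metric, computed with the population SD (divisor n) — the convention that
reproduces the published per-metric values for the density and diameter
metrics; it is applied uniformly to all four metrics. **Cohort summaries**
report mean, sample SD (divisor n−1), and a Student-t confidence interval
`mean ± t(1−α/2, n−1)·SD/√n`; t rather than normal quantiles is what
reproduces published 95% bounds at n as small as 8.

## Synthetic phantoms

Phantoms provide analytic ground truth for every stage. Vessels are tubes
of known radius swept along analytic centerlines (straight, sinusoid, arc,
polyline); sinusoid arc lengths come from adaptive quadrature (relative
error ≤ 1e−9), so each vessel's TI is known exactly. Rasterization sets a
pixel when its center lies within the radius of the sampled curve, with a
`sqrt(r² + (s/2)²)` threshold correcting for the sample spacing s (otherwise
boundary pixels appear only near exact samples and the tube edge ripples).
Within a layer, vessels occupy disjoint lanes so every skeleton chain maps
to one vessel.

The two-layer volume phantom emulates the structure the depth segmentation
expects: a superficial plexus of uniform radius-2 px tubes at a single depth
(0.25·Z), a deeper plexus of radius 2–3 px tubes (0.55·Z) at 0.4 relative
amplitude under exponential attenuation (1/150 per px), and a Gaussian axial
envelope per vessel. The uniform superficial band gives the depth profile a
unique peak at the plexus center; the ground-truth layer boundary is defined
as the first gap slice below the superficial tubes (center + 3). The
vessel count is drawn once and shared by both layers, which keeps the
superficial peak dominant for every random draw.

The temporal phantom adds an N-frame dimension: tissue voxels carry a smooth
static texture identical across frames up to additive Gaussian read noise
(SD 0.02); vessel voxels fluctuate about their clean intensity following an
AR(1) sequence with frame-to-frame correlation ρ (default 0, fully
decorrelated flow; ρ = 1 degenerates to static). Noise for en face and
structural phantoms is multiplicative unit-mean Rayleigh speckle blended at
0.5 plus the same additive term — chosen to emulate a *reconstructed*
angiogram rather than raw interferograms, since projection and filtering
average much of the raw speckle.

What the phantoms do not emulate: vessel crossings within a layer, bulk
motion, shadowing below large vessels, depth-dependent speckle statistics,
and anatomical layer boundaries that are not intensity peaks. Passing the
phantom suites therefore demonstrates correctness of the measurement chain
under controlled geometry, not clinical validity on tissue.

## Problem sizes and tolerances

Test and acceptance runs use desk-scale volumes — 2D phantoms at 256²,
structural volumes at 128 x 160 x 160, temporal volumes at 96 x 128 x 128 x 4 —
chosen so the full suite completes in well under a minute while every
stage still operates far from degenerate sizes; the pipeline itself is
size-agnostic and handles the native 950 x 400 x 400 x 4 acquisitions.
Recovery tolerances on noise-free phantoms: VAD within 3 points, VDI within
1.5 px-equivalents, WTI within 3 points, layer boundary within 5 slices
(measured: ≤1, ≤1.3, ≤1, and ≤4 respectively). Oracle-equivalence checks
(Otsu vs exhaustive histogram search, heatmaps and depth profiles vs brute
force loops, the eigen-filter vs a direct 4 x 4 eigendecomposition) hold to
1e−9 relative. A full pipeline run with a fixed phantom and seed is
byte-identical across runs; the run log is written without timestamps for
that reason.

## Known limitations

- The windowed eigen-filter's window geometry is a design choice, not a
  reproduction of any specific published parameterization.
- The depth segmentation is intensity-based; it tracks the superficial
  plexus peak, not the anatomical epithelium–lamina propria boundary, and
  vessels straddling the separation depth contribute to both DOIs.
- Segment tortuosity near junction-dense regions depends on where the
  skeleton is cut; heavily fragmented skeletons bias TI toward 0.
- Loops cut at an arbitrary pixel get a chord close to one pixel and hence
  a very large TI; they are rare in the phantoms but flagged in the log so
  real-data runs can audit them.
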