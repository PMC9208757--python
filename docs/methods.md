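# Methods

This note documents the models, conventions and numerical choices behind
`hcmotion`, in the order data flows through the pipeline.

## Coordinate and unit conventions

Image coordinates have their origin at the top-left, x rightward (columns)
and y downward (rows). After calibration, the single internal length unit
is the micrometre and the single time unit the minute; speeds are µm/min.
Frames are 0-based internally; MTrackJ-style 1-based track tables are
shifted on read via an explicit `frames_one_based` flag (the shift is never
guessed from the data, because a silent off-by-one is the classic tracking
bug). The apico-basal tissue axis maps to image y by default, with basal =
+y; a geometry table can override the sign. Pixel size and frame interval
are always required inputs — light-sheet TIFF exports do not carry them
reliably, so the package never defaults calibration.

## Synthetic time-lapse generator (`simgen`)

The generator emulates the statistical structure of single-cell migration
movies in a crowded neuroepithelium, with full ground truth. It is the
substrate of every recovery test, so its construction is documented in
detail.

**Centroid path.** A correlated random walk: the step direction is the
normalized blend `d_t = norm(p·d_{t−1} + (1−p)·u_t)` of the previous
direction with a fresh uniform unit vector, where `p = path_persistence`
(default 0.7, giving the frequent direction changes of amoeboid migration
while retaining short-range persistence). Per-step speeds are
gamma-distributed with shape 2 around `mean_speed_um_min` (default
0.7 µm/min), chosen so that the realized 25th/75th percentiles of a typical
run land near 0.35/0.95 µm/min — the regime in which low/high-speed
stratification of real migrating cells operates. A soft reflection at a
two-cell-radius margin keeps the cell in the field. With
`mean_speed_um_min = 0` the path is exactly stationary.

**Cell contour.** A star-convex polygon (100 vertices): an area-preserving
ellipse with axis ratio `elongation` (default 2) oriented along the
instantaneous movement direction, multiplied by a low-order Fourier radius
perturbation (harmonics 2–4, amplitude ≤ 0.06, random phase per frame) that
models ongoing cortical deformation. Harmonics ≥ 2 leave the polygon
centroid at the track position, preserving the centroid-on-track invariant
(0.5 px). At `rounding_frame` the contour is an exact circle with no
perturbation — the mitotic rounding event.

**Protrusion tips.** Tip counts per frame are Poisson(`protrusion_rate`).
Angular offsets from the movement direction are drawn from a von Mises
distribution centred at 0 — symmetric and unimodal, matching the mirror
symmetry of observed protrusion rose plots — with concentration κ
interpolated linearly in speed from `kappa_low` below the cell's 25th
realized-speed percentile to `kappa_high` above the 75th. κ = 0 degenerates
to the uniform distribution. Offsets keep their sign for tip placement;
the recorded true angle is the unsigned fold to [0°, 180°]. The constraint
`kappa_low ≤ kappa_high` encodes the biological asymmetry being emulated:
protrusions are more front-biased the faster the cell moves.

**Rendering.** Three channels: the filled cell contour; a cortical band
(contour minus a 3-px erosion — wider than the 3-px line scan so the scan
never straddles the band) whose intensity rises linearly from front to
back by the factor `rear_polarity_strength`; and static neighbor nuclei
(random ellipses placed to never overlap the cell's path — visual crowding
context only, not a mechanical model, since tissue mechanics are
observational here). Everything is rasterized at 2× resolution and
block-averaged: the antialiased edges keep downstream subpixel sampling
unbiased at object boundaries. Cumulative drift `t · drift_per_frame_px`
(zero at the reference frame 0) shifts all channels; a frame whose drifted
contour leaves the field is flagged `out_of_field`, never silently cropped.
Additive Gaussian noise (`noise_sd`) is clipped at zero. Frames are
rendered in float32, the on-disk dtype, so TIFF round-trips are exact. A
single integer seed drives four independent child generators (path, tips,
shape, render), so identical (config, seed) pairs are bit-identical. An
optional 3-plane z mode (dimmed flanking planes) exercises the polarity
module's central-plane max-projection contract.

The generator emulates the *statistical* structure the analyses assume —
speed-conditioned angular bias, rear-enriched cortex, drifting crowded
background — not microscope optics: there is no PSF, photobleaching,
z-dependent blur or tissue deformation. Passing recovery tests therefore
demonstrates that the estimators are correct and unbiased on data that
satisfies their assumptions, not that segmentation will survive arbitrary
real-world contrast.

## Drift correction (`register`)

Translation between *consecutive* frames is estimated by upsampled-DFT
cross-correlation (subpixel factor 1/20 px) and composed cumulatively,
then re-referenced to the chosen reference frame. Consecutive pairing is
robust to slow content change over tens of hours, where all-to-reference
correlation decays. A flat (zero-variance) frame inherits the previous
cumulative drift with a warning. Correction resamples stacks by the
inverse translation (linear interpolation, constant-zero padding) but
shifts point tracks exactly — no interpolation — so correcting a track
with the drift that corrupted it restores it to numerical precision. Only
XY translation is modelled; rotation and scale are out of scope.

## Segmentation (`segment`)

Region-based boundary evolution (morphological Chan–Vese, foreground/
background mean separation) seeded at a point, run in a 128-px crop window
— fluorescent soma have much stronger region than edge contrast, so
gradient snakes were rejected. The evolution compares squared deviations
from the inside/outside means, making the result invariant to positive
intensity scaling; the seed-brightness check is likewise percentile-based.
The boundary is extracted from a lightly Gaussian-smoothed (σ = 1 px) mask
at level 0.5 — a symmetric kernel shifts a straight edge by zero, so this
removes the pixel staircase without biasing the contour — and resampled to
~1 vertex per 2 px of perimeter, stabilizing perimeter estimates across
cell sizes. No further smoothing happens at measurement time: the
segmentation-stage regularization is the single smoothing knob.

Failure flags: `low_contrast` (seed on background, vanished or tiny
region), `merged_with_neighbor` (area jumped past 1.6× the previous
frame's area — the region leaked into a touching object), `lost` (more
than `max_gap` = 2 consecutive failures). Series propagate frame-to-frame
by centroid reseeding rather than contour warping, tolerating the large
shape changes of amoeboid cells; per-frame segmentations are otherwise
independent.

## Shape descriptors (`shape`)

Perimeter is the polygon arc length as segmented; area is the shoelace
formula. **Sphericity** is realized as 2D circularity, `100 · 4πA/P²` —
the analysis operates on 2D projections, where 100% for a circle and the
isoperimetric bound make circularity the natural roundness measure; this
realization is a documented package decision, not a claim about any other
tool's internal formula. **Elongation** is the square-rooted eigenvalue
ratio of the polygon's exact second central moments (Green's-theorem edge
sums, no rasterization), i.e. the major/minor diameter ratio of the
equivalent ellipse; moment-degenerate shapes (circles) give exactly 1.

Rounding detection: the sphericity argmax is reported as the mitosis frame
when the elongation argmin falls within a 5-frame window of it and
sphericity reaches the 95% threshold; a persistently elongated cell
reports no event.

## Kinematics (`kinematics`)

Velocities are raw finite differences of consecutive centroid positions —
no smoothing, mirroring per-frame manual tracking; frame gaps split the
sequence and no velocity spans a gap. Displacements below 0.04 µm (0.1 px
at the generator's 0.4 µm/px default) are flagged invalid: the direction
is undefined at rest. Speed percentiles use linear interpolation between
order statistics (stated explicitly, and recorded in the manifest, because
percentile conventions differ across tools); a frame is `low` strictly
below the 25th percentile and `high` strictly above the 75th. Layer depth
is the signed distance to a per-frame layer — a scalar y (horizontal line)
or a polyline (point-to-polyline distance, sign from the apico-basal
convention); the per-track summary reports final and maximum basal depth.
The centrosome offset is the per-frame Euclidean distance to the cell
centre with a front/back label from the sign of the projection onto the
movement direction.

## Protrusion angles (`protrusion`)

One sample per (tip, frame): `θ = arccos(v̂ · û)` in degrees, unsigned in
[0°, 180°]; tips at frames without a valid velocity are dropped and
counted. Histograms use half-open 20° bins (9 bins, configurable; bin
width is surfaced in config and manifest since the choice is a display
convention) with the last bin closed at 180°. The emitted
`normalized_frequency` divides by the number of samples, so every
non-empty histogram sums to 1 and merging the low/mid/high sample sets
reproduces the all-condition histogram exactly; the number of frames per
condition is emitted alongside, so the alternative frames-denominator
normalization (relevant when several protrusions coexist in one frame) can
be recomputed from the same table. Empty conditions yield a flagged
all-zero histogram, never a fabricated distribution.

## Polarity profiling (`polarity`)

The cell axis is the line through the contour centroid along the
instantaneous movement direction — front and back are defined by motion,
not by shape (an `axis="shape"` variant via the equivalent-ellipse major
axis exists for sensitivity analysis at the library level by passing a
different direction). The line is clipped to the contour, oriented
front→back, and sampled at 50 equally spaced positions, each averaged over
3 perpendicular 1-px offsets with bilinear interpolation. Given a z-stack,
exactly the three central planes are max-projected first. Frames with an
invalid direction or a clipped line under 4 px are skipped and counted.
Per-frame profiles are length-normalized to s ∈ [0, 1] before averaging
(cell length changes frame to frame); both raw and per-frame
mean-normalized averages are available since brightness normalization
conventions vary. The rear-enrichment index is the back-third over
front-third mean of the averaged profile; with a cortical marker the scan
crosses the band only near the two cell poles, so the index is dominated
by the pole intensities and fluctuates a few percent per frame with cap
geometry — it is a property of the *averaged* profile, and the package's
own checks average ≥ 60 frames (200 for the tight unpolarized-control
bound). Bootstrap confidence intervals resample frames (200 replicates,
percentile 95% CI). No background subtraction by default; a constant
offset flag is recorded in the manifest when used.

## Problem sizes in the checks

The test-suite and acceptance-script runs use: 200×200 px fields at
0.4 µm/px and 1 min/frame; 12–40-frame rendered movies for segmentation,
drift and end-to-end runs; 500–800-frame kinematics-only simulations
(~1,500–2,000 protrusion tips) for angular statistics; 60 and 200 rendered
frames for the polarized and unpolarized polarity checks; and 100 random
convex polygons against brute-force perimeter/elongation oracles. These
sizes give each stochastic check comfortable statistical power while the
whole suite runs on a single CPU in well under half an hour.

## Known limitations

* Strictly 2D: depths, speeds and angles are projections; no 3D surface
  segmentation or 3D sphericity.
* No multi-cell instance segmentation or track linking — tracks arrive
  identified, as in manual MTrackJ workflows.
* No automated protrusion-tip detection from images; the angle statistic
  consumes tracked tips.
* Drift correction handles translation only.
* The rounding detector assumes a single dominant rounding event per
  series.
* Group-level statistical comparisons between experimental conditions are
  outside the package's scope; it produces per-cell metrics.
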