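# Methods

## Geometry and imaging model

The specimen rolls with uniform angular velocity about the
image-horizontal axis (x) through its volume centroid; frame *i* shows
it rotated by θᵢ = 2π·i / P (counter-clockwise viewed from +x, frame 0
defining θ = 0), orthographically projected along the optical axis.
Orthographic projection is appropriate for low-NA widefield imaging at
4×–20×; perspective is out of scope.  Uniform rotation is justified by
the very small timing spread of fluidically rotated animals; the period
P (frames per turn) may be non-integer.

Because the rotation axis is parallel to the image rows, axial slices
decouple: column *x* of every silhouette constrains only cross-section
*x* of the body.  The carver exploits this — each slice is the
intersection of half-open strips

    lo_i(x) ≤ y·cos θᵢ − z·sin θᵢ < hi_i(x)

where [lo, hi) is frame *i*'s silhouette row interval at column *x*
(expanded by half a pixel on each side so the hull remains a superset
of the body; columns with several disjoint runs use the full min–max
span for the same reason).  The result is the visual hull: a guaranteed
superset of the true body, exact for convex bodies as the number of
orientations grows (N uniform strips of half-width r intersect in the
regular 2N-gon, area 2N·r²·tan(π/2N) → πr²).

### Confidence gating (feature completion)

A frame constrains slice *x* only if *x* lies inside its *confident
extent* — the longest run of columns whose foreground/background
contrast exceeds `c_min = 0.3` of the frame's robust contrast range.
Columns the segmentation could not see (the faint adult tail at
unfavourable orientations) impose no constraint, so tail slices are
carved solely by the orientations that detected them.  Disabling the
gating makes every frame veto the columns it missed and truncates the
tail; the ablation in `examples/03_tail_completion.py` degrades the
length error from ≈ −2% to ≈ −16%.  Slices inside no frame's extent
stay empty; the largest 6-connected component is kept.

### Resolution

Carving uses voxels of half the mask pixel (`sub = 2`): strip bounds
are known to sub-pixel precision (half-pixel offsets plus the stored
sub-pixel alignment residuals), so a finer grid recovers real accuracy
that voxel-centre sampling at pixel pitch would quantise away.
Reprojection splats voxel centres onto `sub` fine bins per image row
and calls a row foreground when at least half its bins are occupied,
which makes the single-frame carve→reproject round trip exact.

## Stage notes

**Enhancement** — background flattening (subtract a Gaussian estimate
with σ = min(rows, cols)/4, restore the median), total-variation
denoising (weight 0.08), bicubic ×2 upsampling with unsharp masking
(amount 0.5).  Deterministic; a classical stand-in for learned
super-resolution with the same contract (cleaner frames, finer raster).

**Segmentation** — Otsu threshold on the flattened frame (dark
specimen by default), morphological closing (disk radius 2), hole
filling, largest connected component.  Frames whose foreground is
smaller than 64 px, larger than 90% of the frame, or weaker than
4 background standard deviations are flagged as failed and excluded —
never silently zero-filled.

**Period estimation** — the similarity curve is the mean NCC between
frame pairs at each lag (≤ 16 pairs per lag), computed on enhanced
intensity frames cropped to the silhouette bounding box.  Masks alone
are degenerate for near-symmetric specimens; intensity works because
real bodies carry internal landmarks (gonad, intestinal granules, the
embryo's transparent inclusion), which the phantom generator emulates.
The fundamental is chosen by a harmonic-comb score — worst similarity
at a candidate's integer multiples minus best similarity at its
half-integer multiples — which rejects both the 2P harmonic and the
subharmonic peaks of residual rotational symmetry (an m-lobed surface
repeats at 1/m turn; any centrally symmetric cross-section repeats at
half a turn).  The chosen peak is refined by 3-point parabolic
interpolation at every visible multiple and the per-multiple estimates
averaged (weights ∝ multiple: longer lags resolve finer fractions).
Failure modes raise "no reliable rotation detected": a flat curve
(static or rotation-symmetric specimen, range < 5·10⁻³) or a peak below
`s_min = 0.6`.

**Alignment** — drift is the per-axis least-squares line through the
silhouette-centroid trace plus a period-length rolling mean of the
residual (periodic padding).  Steady drift passes through the line
exactly; the oscillation a bent body imprints on its centroid repeats
every period and averages out, so it is preserved in the aligned masks
(it encodes shape, not drift).  Masks shift by integer pixels; the
sub-pixel remainder is applied by the carver as a real-valued strip
shift.  The rotation-axis row is the mean smoothed y-centroid.  One
period of frames starting at the reference frame is angle-stamped
(θᵢ = 2π(i − ref)/P; ceil(P) frames, so a non-integer period keeps the
frame just short of a full turn); fewer than 12 usable frames abort.

**Meshing** — the occupancy field is Gaussian-smoothed with σ of one
*mask pixel* (the information scale; the grid itself is finer), with
occupied voxels floored just above the iso-level so thin tails cannot
evaporate, then marching cubes at 0.5 and 10 iterations of Taubin
smoothing (volume-preserving: < 1% volume change).  Non-watertight
output is repaired or rejected.

**Morphometrics** — volume is the voxel count × voxel³ (the mesh
divergence-theorem volume is reported as QC; they agree to ~2%).
Surface area is the triangle-area sum.  Length is the arc length of the
centreline: 3-D skeletonisation, longest geodesic between the
extreme-x endpoints (the farthest-pair diameter is the fallback; a path
exceeding 1.8× the bounding-box diagonal falls back to the per-slice
centroid chain), cubic smoothing spline, two rounds of medial
refinement (each sample snapped to its normal-plane cross-section
centroid — thinning artifacts on the faceted hull otherwise pull the
geodesic sideways), then each end extended to the farthest occupied
voxel within a 2.5-voxel tube around the terminal tangent.  Blob-like
volumes with degenerate skeletons fall back to the principal-axis
extent (a sphere reports its diameter).  Maximum width is the largest
Feret (caliper) diameter over ≥ 40 cross-sections normal to the
centreline, excluding the terminal 5% of arc at each end (cap
artifacts); the caliper is taken over voxel centres, whose half-covered
boundary cells make it an unbiased estimate of the continuous caliper.
Length uses the centreline rather than an axis-aligned extent because
the bodies are curved; both interpretations were considered and the
centreline is canonical here.

**Statistics** — pooled-variance two-tailed Student's *t* (named
choice; Welch behind a flag), α = 0.05, data summarised as mean ± SD,
no multiple-testing correction by default (a Benjamini–Hochberg option
exists but raw p-values are the reference behaviour).  Classification
z-scores the five metrics, projects onto 2 principal components (the
decision-region plots are 2-D; the retained-component count is
configurable) and fits logistic regression (2 classes) or an
RBF-kernel SVM (multi-class; linear kernel behind a flag, fixed seed).
Accuracy is reported both by stratified cross-validation (5 folds,
reduced with a warning when a class is smaller) and by resubstitution
(the in-sample region counts that decision-boundary figures show).

## The phantom generator

Every phantom is a swept solid: cross-sections perpendicular to the
body axis, each a circle (worms: radius profile
r(u) = r_max·(1 − taper·(2u−1)²)·caps(u) with sine head/tail caps) or
an ellipse (embryos: semi-axes a, b, c), whose centre may be displaced
in the co-rotating plane by a sinusoidal bend.  A helical surface
corrugation (relative amplitude ã·cos(mφ + 2πx/pitch) plus a one-lobed
asymmetry term 0.6·ã·cos(φ + …)) makes the surface lumpy; the
asymmetry term exists because a perfectly m-fold-symmetric surface
would make the rotation period genuinely ambiguous at 1/m turn,
whereas real specimens are visibly irregular.  Internal "landmark"
inclusions (alternating transparent/opaque ellipsoidal blobs, strictly
interior — their edge stays inside 0.65 of the local radius so the
silhouette rim keeps clean contrast) modulate intensity only, mimicking
the organelles that real recordings show.

Brightfield intensity is background (level 0.75, 6% lateral shading)
minus contrast (0.55) times a saturating function of projected
thickness (saturation 4 µm — edges are sharp while interiors stay
textured), plus the landmark term, blurred by a Gaussian PSF (σ = 1 px;
the true optics' PSF is not specified anywhere usable, so this is a
documented free parameter), plus Gaussian noise (fraction of dynamic
range).  The adult tail fade multiplies contrast by an
orientation-dependent factor: depth (1 + cos θ)/2 times a ramp over the
tail fraction (default fraction 0.25, floor 0.03, full depth reached at
60% of the faded region) — at the worst orientation the deep tail is
essentially invisible, half a turn later it is fully visible, which is
precisely the situation confidence gating exploits.  Fading and
landmarks never touch the geometric ground truth.

Ground-truth metrics come from dense quadrature of the continuous
parametric surface (2001 cosine-spaced stations × 512 angles: shoelace
areas for volume, |p_x × p_φ| for surface, centreline arc for length,
antipodal chords for width), with closed forms substituted where exact
(sphere, bump-free ellipsoid, cylinder).  Voxelisation is anti-aliased
via the signed radial distance to the boundary; rendering projects the
fractional occupancy with mass-conserving linear splatting (two small
matrix products per frame), so silhouette edges are sub-voxel accurate.

### Standard study conditions

* **Adult**: L = 1000 µm, r_max = 25 µm (the ~1 mm × ~50 µm adult),
  taper 0.2, bend 30 µm at wavelength 900 µm, bumps 1 µm (m = 5),
  4 landmarks; imaged at 4 µm/px (4× objective scale), 48 × 288 frames,
  64 frames/turn, 104 frames (1.6 turns), 2% noise.
* **Embryo**: a = 25, b = c = 15 µm (the ~50 × 30 µm ovoid), bumps
  0.75 µm (5% of the minor radius, m = 5, pitch 40 µm), 3 landmarks;
  0.6 µm/px (20× scale), 72 × 112 frames, 48 frames/turn, 80 frames.
* **Cohorts** (12 specimens each, seeds 1–12): adults draw
  L ∈ [850, 1150], r_max ∈ [21, 28], taper ∈ [0.1, 0.3],
  bend ∈ [10, 45] µm, wavelength ∈ [700, 1200] µm, bumps ∈ [0.6, 1.4] µm;
  embryos draw a ∈ [22, 28], b, c ∈ [13.5, 16.5], bumps ∈ [0.8, 1.5] µm —
  the visibly irregular shapes real gastrulation embryos have.
* **Recovery battery** (20 seeds): down-scaled worms, L ∈ [300, 480] µm,
  r_max ∈ [15, 22] µm, imaged at 2 µm/px with 40 frames/turn — chosen so
  the full 20-specimen sweep (render → reconstruct → measure) completes
  in a few minutes while the specimens keep ≥ 150 pixels of body length.

## What the phantoms do and do not establish

The generator reproduces the features the algorithms must cope with —
non-integer periods, drift, blur, noise, shading, internal texture,
near-symmetric shapes, an orientation-dependent invisible tail — with
exactly known geometry, so accuracy statements (reprojection IoU above
95% per viewpoint, metric recovery within a few percent) are measured
against real ground truth.  They do not capture: non-rigid wriggling
during rotation (animals are anaesthetised in the real protocol, and
uniform rigid rotation is assumed throughout), non-uniform rotation
rate, focus drift or depth-dependent blur, multiple specimens per
field, or the concavities a visual hull fundamentally cannot recover
(our phantoms' per-slice sections are star-convex, so the hull bound
is tight; deeply concave real anatomy would be overestimated).
Reported p-values and classification accuracies on simulated cohorts
characterise the statistics layer, not any real strain.

## Numerical choices and limitations

* Pixel coordinates are 0-based (row, col), row 0 at top; extents are
  half-open; angles are radians internally, degrees at the validation
  interface.
* The slicewise and brute-force carvers share one geometry helper but
  take independent routes (strip intersection vs per-voxel mask
  lookup); half-open interval conventions make them agree voxel for
  voxel, which the suite asserts on five phantom types.
* Viewpoint↔frame pairing is nearest-angle (no interpolation); the
  projection is rendered at the matched frame's actual angle so model
  and silhouette are compared at truly corresponding orientations.  A
  viewpoint with no frame within half an inter-frame step is skipped
  with a warning.
* Identical seeds give bit-identical stacks, masks and metric rows; all
  randomness flows through `numpy.random.default_rng` seeds carried in
  the specs.
* Known biases: measured length is ~2–3% short (the faintest tip
  columns fall below the confidence floor, and strong bends add ~1%
  from residual corner-cutting); widths inherit up to half a pixel of
  mask quantisation; the hull is a superset, so volume errors are
  positive for convex bodies.  All are documented at the resolution of
  the standard conditions and shrink with finer pixels.
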