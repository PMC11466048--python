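# Methods

## Problem and model

Arteriosclerosis on kidney biopsies is graded by how much the intima
thickens and narrows the lumen. Area-based metrics (compartment areas and
their ratios) blur focal disease and are confounded by sectioning
artifacts, so this package measures wall thickness *radially*: media and
intima thickness are expressed as functions of polar angle along the
entire arterial perimeter, turning each artery into a circular signal
that standard signal-processing tools can clean and summarize.

Inputs are the outer contours of the media (`C_m`), intima (`C_i`) and
lumen (`C_l`) of one artery, as polygons (QuPath-style GeoJSON) or as a
4-class label mask. Coordinates are 0-based pixel centers, x right /
y down; polar angles are measured from +x toward +y. All geometry is in
pixels; the physical scale (`pixel_size_um`, default 0.25 µm/px at x40)
enters only in the area features.

### Radial measurement

1. The luminal center of mass is computed from the vertex spatial
   moments of `C_l`: `CoM = (M10/M00, M01/M00)` with
   `M_ij = Σ_(x,y)∈C_l x^i y^j` summed over contour points. Because a
   vertex sum is sensitive to digitization density, contours are
   arc-length resampled to 1 px vertex spacing first; this removes the
   main discretization artifact while keeping the vertex-moment
   definition. (Whether moments should instead be taken over the filled
   region is a judgment call; for convex lumens the difference is small.
   The vertex reading is implemented and documented.)
2. For each sampling angle α (default 360 angles at 1° spacing), three
   rays at α−β, α, α+β (β default 5°) are cast from the CoM and
   intersected with `C_i`, keeping the **farthest** intersection each
   (this matters for folded or re-entrant intimal contours).
3. The measurement line `L_α` passes through the central intimal point
   perpendicular to the chord joining the two auxiliary points — i.e.
   locally perpendicular to the intimal boundary rather than naively
   radial. `L_α` is searched in both senses: media thickness is the
   distance to the **closest** crossing of `C_m` in the outward sense,
   intima thickness the distance to the **closest** crossing of `C_l`
   in the inward sense.
4. A missing crossing produces a missing sample (NaN), never a zero.

Ray–edge intersection uses the half-open edge convention (edge parameter
in [0, 1)) so a crossing exactly at a shared polygon vertex counts once;
coincident double-hits from rounding are deduplicated by parameter
proximity (1e-7 px).

### Irregular appearances

Sectioning produces two irregular artery presentations that corrupt
subsets of angles:

* **Open lumen** (edge cuts): samples whose media *and* intima thickness
  fall below `open_lumen_threshold` (default 2 px) are marked; then any
  circular window of `window_size` samples (default 15) containing more
  than `window_count_limit` marked samples (default 3) is discarded
  entirely. The AND-reading of the threshold rule is deliberate: a
  single thin compartment is plausible disease, both thin at once is an
  edge artifact.
* **Multiple lumens/intimas** (tangential cuts): the lumen–intima pair
  with the largest combined area (among pairs whose lumen lies inside
  the intima, overlap fraction ≥ 0.95) is measured; every other lumen
  and intima contour is an obstacle. Angles whose central ray crosses an
  obstacle — the full half-line, not truncated at `C_i` — are discarded
  together with half a window of neighbors on each side.

The threshold, window size, and count limit are exposed in the
configuration; their defaults are this package's choices, documented
here rather than inherited from any external calibration. Flagged
samples keep their raw values but are excluded from every downstream
statistic.

### Conditioning

Applied strictly in the order filtering → imputation → normalization:

1. circular moving **median** (window 9 samples) — outlier suppression;
2. circular moving **average** (same window) — smoothing;
3. **imputation** of plainly missing samples by inverse-distance
   weighting of the nearest valid neighbors on each side:
   `l_i = (w_l·l_left + w_r·l_right)/(w_l + w_r)` with `w = 1/distance`,
   distances being circular index distances (first and last samples are
   adjacent). Appearance-flagged samples are treated as missing during
   filtering (they contribute nothing to window statistics) but are
   *not* imputed back into validity;
4. **normalization** by the median of the per-angle wall thickness
   (media + intima) over valid angles, making profiles dimensionless,
   resolution independent, and comparable across arteries (median wall
   = 1 afterwards).

Both filters skip missing entries rather than propagating them, so gaps
do not widen by the window size.

### Features

Three circular series are summarized per artery: media thickness, intima
thickness, and the per-angle intima–media ratio
`R_α = T_intima / (T_intima + T_media)` ∈ [0, 1]. Per series:

* global — average, median, **population** variance (divide by n; the
  convention is fixed and dimensionless after normalization);
* local — peaks are local maxima with width above `theta_w` (default 10
  samples = 10°); the features are the maximum peak height and maximum
  topographic prominence, taken independently (they may come from
  different peaks). The no-peak sentinel is 0 ("no local excursion"),
  which keeps score-0 arteries rankable. Peak detection runs on the
  three-fold tiled series so a bump straddling 0°/359° is found exactly
  once; a prominence floor of 1e-6 (the series is of order 1) keeps
  floating-point jitter on flat profiles from registering as peaks.
  Invalid arcs are bridged by the same inverse-distance imputation for
  detection continuity, and peaks whose apex falls on an invalid angle
  are dropped.

Three baseline area features come directly from the polygons (shoelace
areas, multi-part intima summed): media band area (media outer minus
intima outer), intima band area (intima outer minus lumens), and their
ratio. Band areas are reported in µm²; the ratio is dimensionless.

### Synthetic validation

`simulate.make_artery` builds the three appearances with analytic
ground truth: concentric circles (default radii 150/105/60 px on a
512 px canvas, scaled with the canvas); concentric half-discs whose flat
cut edges are staggered by 1 px per compartment (annotated cut
boundaries of an edge-cut artery nearly, but not exactly, coincide —
this is what makes open-lumen samples *small* rather than absent, which
is the signal the flagging mechanism keys on); and a four-circle
tangential-cut geometry (primary lumen 45 px at center, secondary lumen
25 px at offset 75 px, default bearing 280°). The open arc and the
angular extent of the secondary lumen (`asin(r₂/d)` around its bearing)
are computed in closed form, independently of the measurement code.

Elastic deformation: i.i.d. uniform[−1, 1] displacements per pixel and
direction are Gaussian-smoothed (σ = 30 px) and scaled by the distortion
order λ (grid 0–3000 in steps of 500); contour vertices move by the
bilinearly interpolated field value. The raw-field distribution is a
choice (only "random" is prescribed by the construction); the
monotonicity of roughness in λ is distribution robust, and smoothing and
scaling commute so their order is immaterial. Deformation displaces
annotation vertices rather than warping an image, which is equivalent
for a pipeline that consumes contours.

`validation_sweep` reports two roughness statistics of the conditioned
series — variance over valid samples and the mean absolute first
difference over circularly *adjacent* valid samples (so flagged arcs
contribute no spurious jumps).

### Synthetic cohort

`make_cohort` generates graded arteries for the evaluation layer: the
score (balanced over 0–3) drives a latent severity that narrows the
lumen both diffusely and through a focal intimal bump (Gaussian dent in
the lumen radius, width 25°); overall artery size varies log-normally as
a nuisance; all contours share smooth low-order Fourier shape noise.
This realizes a cohort in which thickness-based features carry the full
signal (diffuse + focal) while raw area features are diluted by the size
nuisance and blind to focal narrowing — the qualitative structure the
feature comparison is meant to probe. Cohort measurement runs at 120
angles on 240-vertex contours, sizes chosen so cohort-scale experiments
remain interactive; features are resolution robust at this scale.

### Evaluation layer

Dice overlap for masks (both-empty defined as 1, with a warning);
Kendall τ-b with tie correction and asymptotic two-sided p-values
(scipy) — continuous features are treated as ordinal by rank; ridge
regression R² (α = 1.0, standardized features, in-sample fit) over three
feature subsets (area-based, thickness-based, combined) — the evaluation
protocol is configurable, and with ~18 features against 40+ arteries the
in-sample optimism is shared across subsets being compared; Cohen's κ
with the full confusion matrix. Cohort-level analyses pool arteries
plainly, without clustering corrections.

## What the synthetic data does and does not show

The simulator emulates geometry — nesting, edge cuts, tangential cuts,
elastic deformation, graded narrowing — with exact ground truth, which
is what validates the measurement, exclusion, conditioning, and feature
machinery. It does not emulate stain variation, annotation subjectivity,
segmentation errors, adventitial ambiguity, or the biological
covariance structure of real cohorts. Passing tests therefore establish
the correctness of the computation, not clinical performance; headline
cohort statistics from real biopsies are not reproducible from synthetic
geometry and are not claimed.

## Numerical choices and degenerate inputs

* Contours are normalized to counter-clockwise orientation on
  construction; duplicated closing vertices are dropped; fewer than 3
  distinct points is an error. Invalid (self-intersecting) polygons are
  repaired via a zero-width buffer when converted for area/containment.
* Annotations with no lumen (occluded arteries) or no
  containment-consistent lumen–intima pair are rejected with a specific
  error rather than measured.
* A zero median wall thickness, an empty series, or fewer than two valid
  entries for imputation are hard errors.
* Mask cleaning removes per-class components and holes below 5% of that
  class's positive pixel count and iterates the pass to a fixed point,
  making it idempotent by construction.
* Windows must be odd; configuration objects validate on construction
  and reject unknown keys.

## Known limitations

* The measurement assumes the lumen CoM sees the intima in every
  direction; extremely non-star-shaped arteries can yield large missing
  arcs (reported as missing, then imputed — the imputation is a
  two-point interpolation, not a shape model).
* Cross-intersection checking uses the central ray only; an obstacle
  clipped solely by an auxiliary ray is not flagged (its window margin
  usually covers this).
* Circular prominence is computed on the tiled series, which matches
  the topographic definition for every peak whose base fits within one
  period.
* Adventitia is not measured; its outer boundary is not histologically
  separable.
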