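# Methods

## Measurement model

posturekit measures three axial postural abnormalities as *external
angles* at reconstructed vertebral landmarks: 180° minus the interior
angle at the apex, so a straight upright posture scores 0° and the
consensus cut-offs (PS > 10°, lCC > 30°, tCC > 45°, strict comparisons)
apply directly. This is the only reading of "external angle" consistent
with cut-offs like >10° for a visible lateral lean. Angles are reported
to 0.1°; equality with a cut-off is classified negative. The lumbar
camptocormia definition additionally requires hip flexion, which a
single photograph cannot assess; reports therefore always carry
`hip_flexion_assessed = False` and the lCC flag covers the angle clause
only.

All coordinates are image pixels, origin top-left, y down, 0-based,
sub-pixel valued. A keypoint with confidence 0 is missing; any
operation needing it raises a typed error naming the keypoint — no
imputation, because a silently guessed joint would corrupt a clinical
angle. Multi-person pose files are resolved to the person with the
largest bounding box of present keypoints (single-subject protocol;
ties keep the lowest index).

## Landmark construction

**Frontal (posterior) view.** C7 is the intersection of the
*contralateral* shoulder–ear diagonals (left shoulder→right ear ×
right shoulder→left ear): ipsilateral segments generally do not cross
between shoulder and ear level, while the diagonals cross at the neck
base. The crossing is accepted with 25 % slack beyond the segment
endpoints, absorbing detector jitter; parallel or far-out
configurations raise a geometry error. L5 lies on the image-vertical
through the hip mid-point MH, displaced *toward the head* by K1 % of
the mean hip–knee distance — the offset direction is forced by anatomy
(L5 sits above the hip joints, below the iliac-crest line).
"Vertical" is image-vertical, matching the upright acquisition
protocol. MA is the component-wise ankle mid-point.

**Sagittal view.** The visible side is the one whose complete
ear–shoulder–hip–knee–ankle chain has the higher summed confidence
(left-side keypoints substitute mirrored formulas on left-facing
images), and the posterior direction is the horizontal unit vector from
the nose/eye centroid toward the ear. Landmarks sit on the back
contour, so the silhouette is needed: anchor A is placed K2 % of the
way from shoulder to ear; C7 is the last silhouette point marching from
A perpendicular to the shoulder–ear segment, toward the back (C7 is a
spinous process on the back contour, which fixes the direction the
original description leaves open). L5′ repeats the frontal L5 (one leg
when only one side is visible); L5 is the last silhouette point
marching horizontally backwards from L5′. FC is the silhouette point
farthest behind the infinite C7–L5 line, computed as a maximum over all
boundary pixels strictly posterior of the line (ties: smaller y, then
smaller x) — equivalent to perpendicular ray-marching from the segment
but with a simpler exhaustive oracle; the ray-marching variant is kept
behind `fc_search(..., method="ray")`. When no boundary pixel is
strictly posterior (perfectly straight back) the fulcrum degenerates
onto the C7–L5 segment and tCC is 0.

Marches step at 0.5 px with nearest-pixel mask lookup, then refine by
bisection between the last in-mask and first out-of-mask samples; the
FC boundary pixel is refined the same way along the posterior normal.
Using one localisation convention for every boundary landmark makes
their half-pixel offsets cancel in the angles; without it the angle
error carries a resolution-dependent bias. A march that would leave the
image while still inside the mask raises a landmark error (the caller
should re-segment with a larger box) — as does a C7 search whose anchor
falls outside the silhouette, e.g. under arm occlusion.

### Parameters

| parameter | default | units | meaning |
|---|---|---|---|
| K1 | 20 | % | MH→L5 offset as a fraction of mean hip–knee length |
| K2 | 40 | % | shoulder→A as a fraction of shoulder–ear distance |
| band_thickness_scale | 0.15 | – | band half-thickness / joint-segment length |
| box_margin_frac | 0.15 | – | subject-box expansion per side |
| min_width_frac | 0.45 | – | box-width floor as a fraction of the stature estimate |
| graphcut_iters | 5 | – | colour-model re-estimation rounds |
| thresholds | 10/30/45 | deg | PS / lCC / tCC cut-offs (strict >) |

K1 and K2 were calibrated against ground truth in the original clinical
study; they are exposed but not re-tuned here.

## Silhouette extraction

A three-class trimap is seeded from the keypoints alone: pixels outside
a subject box are certain background; pixels inside bands — joint
segments (ear–shoulder, shoulder–hip, hip–knee, knee–ankle; the visible
side on sagittal views, both sides on frontal views by symmetry)
isotropically expanded by τ = 0.15 × segment length, clamped to
[2 px, half the length] — are certain foreground; the rest is probable
background. The box height spans ear to ankle; its width is the
keypoint spread, floored at 0.45 × a bend-invariant stature estimate
(the ear–shoulder–hip–knee–ankle chain length): on a true sagittal view
the keypoints hug the body axis while the back contour lies a body
depth behind them, so a pure keypoint-spread width would clip the very
contour the landmark searches need. Both extents are expanded by the
margin fraction and clipped to the image. `min_width_frac=0` restores
the tight keypoint-only rule.

Segmentation is a seeded iterative colour-model graph cut: foreground
and background Gaussian-mixture colour models (3 full-covariance
components, fitted on ≤4000 subsampled pixels per side) give per-pixel
data terms; a contrast-sensitive 4-neighbour smoothness term
(γ = 50, β = 1/(2·mean‖Δz‖²)) couples neighbours; certain trimap
classes get infinite terminal links. The exact min cut is solved by
sparse max-flow on integer-scaled capacities, and models are re-fitted
on the new labelling for up to 5 rounds or until labels stop changing.
The raw cut is post-processed: only the connected component with the
largest certain-foreground overlap is kept and its holes are filled, so
the later boundary searches never hit speckle; the hard seeds are then
re-imposed. Post-processing is a deliberate addition to the plain cut.

## Statistics

The robustness analysis correlates, per abnormality, the measured angle
(or the error, measured − ground truth) against: BMI; image width,
height and area; cover factors (tight mask-bounding-box width/height/
area over image width/height/area — the bounding box, not the pixel
count, keeps the width and height ratios well defined); and colour
summaries in hue–saturation–value space (circular mean for hue,
reported in degrees; arithmetic means for S and V; circular hue
variance and S/V variances are additionally emitted). Pearson's R is
computed from centred cross-moments and its two-sided p value from
t = R√((n−2)/(1−R²)) on n−2 degrees of freedom. Records missing a
covariate are excluded pairwise (counts logged). Raw p values are
compared to 0.05 per correlation; a Bonferroni switch exists but is off
by default, mirroring standard practice for this analysis.

## Synthetic mannequin generator

The generator emulates the acquisition protocol the measurement
assumes: one undressed standing subject, neutral uniform background,
frontal(posterior) or sagittal framing, with controllable
subject/background colours, pixel noise, lighting gradient, image size,
subject cover, trunk width (a BMI proxy mapped around 25 kg/m²) and
keypoint jitter (default σ = 2 px, emulating pose-estimator noise;
pixel noise default σ = 4 channel units). All randomness is seeded and
reproducible bit-for-bit.

The body is capsules and polygons, not an anatomical mesh — the
pipeline only consumes contours and keypoints, and this is the simplest
geometry with closed-form truth:

* **Sagittal**: the back contour is an exact polyline — straight lumbar
  edge, bend vertex at the flexion fulcrum (a settable fraction of
  trunk length), straight thoracic edge, with the neck's posterior edge
  *collinear* with the thoracic edge. True C7, L5 and FC all lie on
  this polyline, so the true thoracic angle equals the requested bend
  exactly. The true lumbar angle follows from the true landmarks (the
  ankle keypoint sits on the leg axis, a fixed body depth in front of
  the back contour, so true lCC at zero flexion is a small positive
  offset rather than exactly 0 — the same offset the measurement
  produces, and independent of the trunk-width covariate by
  construction). The whole figure gets a random sub-pixel placement
  phase per fixture: photographs are never aligned to the pixel grid,
  and a shared phase would make rasterisation error common-mode across
  a batch.
* **Frontal**: the upper body leans rigidly about L5; shoulders and
  ears sit symmetrically about the trunk axis at spans chosen so the
  contralateral diagonals cross exactly on the axis — the true Pisa
  angle equals the requested lean exactly.

Every joint band the trimap will draw is covered by a slightly larger
body capsule (band radius + 3σ_jitter + 3 px), so keypoint-seeded
foreground stays inside the true silhouette even under jitter. Stored
true angles are recomputable from the stored true landmarks through the
same angle module to 1e−9.

The full-factorial battery sweeps image size, background colour,
subject cover (optionally drawn per fixture, emulating uncontrolled
camera–subject distance) and trunk angle (fixed, listed, or drawn
i.i.d.), with trunk width always drawn independently — giving the
null-structure data the robustness analysis should flag nothing on.

**What the mannequin does not model:** clothing, hair, limb occlusion
of the trunk, arms (omitted entirely; elbow/wrist keypoints are
missing), perspective foreshortening, shadows, textured backgrounds,
multi-person scenes, and anatomical spine curvature between landmarks.
Passing tests therefore demonstrate the geometric and algorithmic
correctness of the pipeline under the stated acquisition protocol, not
clinical performance on photographs of real patients.

## Validation problem sizes

The test suite and the acceptance script run the full pipeline on
mannequins at the generator's default 480×640 resolution for angle
recovery (sweeps of 0–70° in both views, clean and with 2 px jitter +
channel noise; noisy recovery is held to the minimal-detectable-change
bounds of the reference manual method: PS 2.1°, lCC 3.7°, tCC 6.7°),
segmentation checks at 360×480, the fulcrum-search oracle on 100 random
64×64 blob masks, and ten seeded robustness runs of 30 fixtures per
abnormality at 360×480–600×800. These sizes were chosen as the smallest
at which rasterisation effects are comfortably below the tolerances
being asserted.

## Known limitations

* The sagittal search directions assume the subject's back is visible
  and the posterior direction is horizontal in the image (upright
  protocol); heavily rotated or supine framings are out of scope.
* An arm occluding the neck can make the C7 march exit through the arm;
  this surfaces as a landmark error rather than a silent mis-measure.
* Cover factors use the silhouette bounding box, so a failed
  segmentation propagates to the covariates (guarded by the
  segmentation error paths).
* The graph cut assumes the subject and background are colour-separable;
  at near-zero contrast the silhouette degrades (the monotone-contrast
  property test documents this), and landmark quality degrades with it.
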