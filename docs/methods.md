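# Methods

`autowbrt` implements an automated field-definition and planning pipeline for
whole-brain radiotherapy (WBRT) delivered with two lateral-opposed photon
beams, exercised end-to-end on synthetic head phantoms. This document states
the model, its parameters, the numerical choices, and the limitations.

## 1. Clinical model

A WBRT plan here is two opposed lateral beams (gantry 270° and 90°), equally
weighted, prescribed 30 Gy in 10 fractions and normalized to 100% at a marked
isocenter placed at the brain centroid. The planning problem reduces to
drawing one beam's-eye-view (BEV) aperture per side. The automated field is
assembled from:

1. a learned aperture prediction on the lateral digitally reconstructed
   radiograph (DRR),
2. rule-based post-processing that sets the caudal (inferior) field border at
   a vertebral landmark, clips to the patient outline, and adds skin flash,
3. an MLC fit and jaw setting to make the shape deliverable.

Two caudal-extent options are supported: the border at the **C1/C2** or the
**C2/C3** interspace, computed as the midpoint of the adjacent vertebral
bodies' superior–inferior centroid coordinates, projected into the BEV. Two
techniques are supported: **traditional** (open field over the whole
projected brain and skull) and **scalp-sparing** (field trimmed to the
projected brain expanded by a margin, with a bridge to the caudal border so
the cervical target stays connected).

## 2. Synthetic phantom

Each case is a parametric head-and-neck CT generated from a seed
(`PhantomSpec`): an ellipsoidal head, a skull shell, a brain (head eroded to
leave bone and a cerebrospinal-fluid gap), two eyes with lenses, a 3 mm bony
orbital rim around each globe, a neck cylinder, and three cervical vertebral
bodies (C1–C3). Per-seed variation draws head radii, neck length, eye
positions and vertebral geometry from bounded uniform distributions, so
cohorts have realistic anatomical spread while every case remains exactly
reproducible. HU values: air −1000, soft tissue ≈ 0–60, bone ≈ 700–1200.

The orbital rims matter: lateral DRRs are water-equivalent path-length
images, and soft-tissue eyes are invisible on them. The bony rim is the image
cue from which the model learns where the eye shield belongs.

Each case carries **exact reference apertures** (shapely polygons, then
rasterized) for all four (side, extent) combinations. These are the training
labels and the evaluation ground truth. The reference eye shield is extended
anteriorly to the field edge (a convex-hull sweep of the dilated eye region
toward anterior): a single-level MLC closes only from the sides, so an island
shield with an open strip anterior of it would not be deliverable.

Default CT grid: 2.5 × 2.5 × 2.5 mm voxels, ~(110, 110, 120) voxels —
chosen as this package's own compromise between geometric fidelity (half-voxel
errors ≈ 1.25 mm) and a single-CPU runtime budget.

## 3. Projection geometry

Both lateral beams share one image-plane convention: **u = patient anterior,
v = superior**, with the plane through the isocenter. For gantry angle *g*
the source sits at distance SAD = 1000 mm along
`s_hat = (sin g, −cos g, 0)`; the in-plane basis vector `e_u` is negated for
gantry in (180°, 360°) so that +u is anterior from either side. Consequence:
a structure projects to the same (u, v) footprint from either lateral beam
(up to perspective asymmetry of off-midline anatomy), and apertures can be
mirrored between sides exactly.

A point at distance *d* off the isocenter plane toward the source projects
with magnification `sad / (sad − d)` (similar triangles). The default BEV
grid is 2 mm pixels, sized to cover the head with flash headroom.

The DRR is a per-pixel line integral of relative attenuation
`mu_rel = max(0, 1 + HU/1000)` (water-equivalent path length in mm):
trilinear sampling along each source→pixel ray at steps of at most half the
smallest voxel spacing, trapezoidal integration. A per-pixel `coverage_ok`
flag records whether the ray entered/left the CT volume through air
(edge sample `mu < 1e-3`); edge samples are taken at least half a voxel
inside the volume bounds because trilinear lookups at the boundary fall into
the zero padding.

3D margin expansion (`expand_contour_3d`, used for the brain margin in the
scalp-sparing technique) is a voxel-domain Euclidean-distance-transform
dilation on a dedicated 2 mm working grid; accuracy is about half that
working voxel.

## 4. Aperture segmentation model

The learned component is deliberately small: a per-pixel multilayer
perceptron over 12 multiscale context features of the DRR (local intensity,
Gaussian-smoothed intensities and gradients at several scales, normalized
(u, v) position, distance to the projected body outline). Hidden layers
(48, 24), sigmoid output; trained with Adam on a weighted cross-entropy +
soft-Dice loss. Defaults: 30 epochs, learning rate 0.01, positive-class
weight 2.0, Dice weight 1.0, threshold 0.5. The checkpoint with the best
cross-validation Dice is kept.

This choice — rather than a deep CNN — keeps training on a laptop-scale CPU
budget (~2 minutes for a 40-case cohort) while being a genuine learned image
→ aperture mapping with the same train / cross-validation / test protocol
a larger model would use. Cohort splitting is seeded, shuffle-based, with
ratio rounding such that 520 cases at (0.6, 0.2, 0.2) split 312/104/104.

Prediction post-processing: threshold the probability map, keep the largest
connected component, fill holes **except** components touching the field
border region (so the eye-shield notch survives), clip to the projected body.

## 5. Field construction rules

`build_traditional_field` takes the predicted mask and:

1. sets the inferior border at the requested vertebral landmark (crop or
   extend; extensions are clipped to the projected body outline),
2. adds **skin flash**: a masked dilation that pushes the field edge exactly
   `flash_mm` (default 10 mm) beyond the projected body on the anterior,
   posterior and cranial sides — never inferiorly, and never into interior
   shields (the dilation is constrained so shielded regions inside the body,
   e.g. the eye shield, are not opened),
3. records provenance flags (`flash_applied`, clipping events) in the field's
   metadata.

`build_scalp_sparing_field` intersects the traditional field with the
projected (brain + 5 mm margin) and a bridge region down to the caudal
border, and verifies the unexpanded projected brain stays covered.

`mirror_for_opposed_beam` reflects u → −u, which is exact under the shared
BEV convention.

## 6. MLC fit and plan assembly

The MLC model is a single-level 80-pair leaf bank (5 mm leaf width at
isocenter by default), leaves travelling in u. Fitting is **fit-to-enclose**:
for every leaf row, the leaf tips are set to the open raster extent of that
row ± half a pixel; rows with no open pixels are parked closed; jaws are the
open bounding box + 2 mm margin. Fit-to-enclose (leaves outside the contour)
is chosen over midline fitting to protect target coverage. The
mask → MLC → mask roundtrip is exact when leaf-row boundaries align with the
raster rows.

`build_plan` assembles the two opposed beams with weight 0.5 each and
validates symmetry; plans serialize to a minimal RT-PLAN DICOM dialect
(ASYMX/ASYMY jaws, MLCX leaves, beam weights via fraction-group metersets).

## 7. Toy dose engine

Dose is a deliberately simple exponential-attenuation model, present so the
pipeline produces DVH-level outputs — not a clinical dose calculation. For
each lateral beam, every voxel inside the beam's divergent aperture cone
receives `exp(−mu_eff * WED)` where WED is the water-equivalent depth
accumulated along ±x (midpoint cumulative sum) and `mu_eff = 0.005/mm`.
Beam doses are weight-summed and normalized to 100% at the plan's
normalization point; Gy values scale by prescription. No scatter, no
build-up, no penumbra.

DVH metrics: `Dx%` is the largest dose received by at least x% of the
structure's voxels, computed as the (100 − x) percentile with **lower**
interpolation (conservative); `mean` is the voxel average. Reported:
brain D99%/D95%/D1% and mean lens dose.

## 8. Evaluation

Field quality is scored on the **shielded edge**: the part of the aperture
boundary lying strictly inside the projected body (by more than one pixel),
i.e. the anterior-inferior block edge where automation differs from simply
flashing the outline. Exact reference polygons are densified (segments split
to ≤ 1 pixel) before the inside-body filter so exact and rasterized
boundaries are compared on the same portions. Metrics: directed and
symmetric mean surface distance (point-to-segment, exact), Hausdorff
distance, and the inferior border offset. Cohort evaluation returns a
per-case table (failures become error rows, excluded from summaries) and
mean/SD summaries.

## 9. Operating points and observed behaviour

At the standard operating point (40-case cohort, seed 3, defaults
throughout): held-out segmentation Dice ≈ 0.91, directed predicted→reference
shielded-edge MSD ≈ 2.1 mm (bound used in the acceptance suite: ≤ 5 mm),
brain D99% ≈ 29.6–30.1 Gy, mean lens dose 0 Gy on all test cases.
Runtime ≈ 2.5 minutes on one CPU.

## 10. Limitations

- The phantom is parametric and idealized: no couch, no immobilization mask,
  no air cavities/sinuses, simplified vertebrae, elliptical cross-sections.
  Models trained on it will not transfer to clinical DRRs.
- The dose engine ignores scatter, build-up, penumbra and beam energy; DVH
  numbers are internally consistent but not clinically meaningful.
- The segmentation model is per-pixel; it has no global shape prior beyond
  its context features and the post-processing rules.
- Evaluation covers geometry (edge distances, Dice) and toy-dose DVH only;
  there is no deliverability check beyond the single-level MLC fit (no
  interdigitation or leaf-speed constraints).
- DICOM output is a minimal dialect sufficient for round-tripping within
  this package; it is not a validated clinical export.
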