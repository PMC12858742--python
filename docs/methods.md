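# Methods

This note documents the models, conventions and numerical choices behind
`bedsynth`, and what its synthetic fixtures do and do not emulate.

## Body model and kinematics

The articulated body is a fixed kinematic tree shipped as a versioned
plain-text asset (`src/bedsynth/assets/kinematic_tree.txt`): 22 body joints
compatible with the SMPL-X body hierarchy plus 5 face markers (nose, eyes,
ears) attached to the head, so the 17 COCO person keypoints are a strict
subset of the joint set. The world frame is right-handed with +z up; the
rest pose is supine along +x (head towards +x, feet towards −x, left side
towards +y), pelvis at the origin. Left/right rest offsets are
mirror-symmetric about the sagittal plane, and the loader enforces this.

**Shape.** Ten dimensionless coefficients, each drawn from N(0, σ) and
re-drawn until inside [−1, 1]. Rejection rather than clipping avoids
probability spikes at ±1. σ defaults to 0.5 (exposed in the API): at that
spread roughly 95 % of draws land inside the interval directly, so the
truncation bias is negligible while the full interval remains reachable.
`β₀` scales bone lengths (±5 % at the extremes); the mean of all ten scales
segment radii (±8 %), making mesh volume monotone in every coefficient.

**Pose.** Joint-wise axis-angle vectors (norm = angle ≤ π) composed down the
tree: `R_g(j) = R_g(parent) · R_l(j)`. The inverse problem — recovering a
pose from Cartesian joint positions — maps each joint's rest-pose child
offsets onto the observed child directions in the parent's accumulated
frame. Twist about a bone axis is unobservable from positions alone: for
single-child joints the minimal (twist-free) rotation is used, while
multi-child joints (pelvis, spine3, head) are solved by least-squares
rotation alignment, which does recover their full orientation. The
composition `positions → pose → forward kinematics` therefore reproduces
joint positions (tested to 1e-6 m) but not necessarily the original twist
components; this is documented behaviour, not a defect.

**Surface.** Each bone carries a capsule (apex-capped tube) with an
anthropometric base radius; the head is an ellipsoid. Tessellation density
is a single even integer (`n_seg`, default 8), and vertex/face counts are a
pure function of it. Capsule ring frames are built deterministically from
the bone axis, which makes the rest mesh exactly mirror-symmetric. This
surface is a deliberate simplification: it supports blanket draping,
occlusion reasoning and silhouette-accurate boxes, not photorealistic skin.
Anything producing joint positions over the same tree (e.g. a statistical
body model) can be slotted in above the mesh builder.

## Scene sampling

All per-scene randomness is explicit and interval-bounded; sampled values
are never clipped after the fact.

* **Appearance** — uniform draw from an 8-tone RGB skin palette; independent
  coin flips (default probability 0.5 each) for clothing overlay, hair and
  eyewear. Clothing is a flat-colour relabelling of torso/limb capsule
  faces; hair and eyewear recolour head-face bands. No garment mesh is
  constructed.
* **Blanket** — a heightfield drape: a rectangular grid (default 40
  cells/m) over a covered span of the body's long axis (coverage fraction
  default U(0.3, 0.9), anchor uniform), each cell taking the maximum body
  height beneath it plus an offset (default 3 cm), then i.i.d. Gaussian
  noise (default 1 cm) and `smoothing_iters` rounds of Laplacian diffusion
  with step λ = 0.2. The diffusion matrix `I − λL` is symmetric,
  non-negative for λ ≤ 0.25 and row-stochastic, hence doubly stochastic:
  grid variance is non-increasing and the mean is conserved exactly — the
  smoothing can only flatten. After smoothing, heights are clamped back to
  the draped surface so the cloth never penetrates the body.
* **Camera** — positioned on a sphere about the pelvis: distance
  U(0.3, 0.6) scene units, elevation U(−54°, 18°) above the horizontal,
  azimuth from the scenario preset measured about a named zero-reference
  axis ("bed right side" for preset B, "bed front" for C and D), then
  rolled about the optical axis by U(−115°, −30°). The asymmetric roll
  range is kept verbatim from the scenario definition; a `flip_elevation`
  switch covers the opposite elevation sign convention. Scene units convert
  to metres via `distance_scale` (default 3.0 → 0.9–1.8 m); with the
  default focal length (0.45 × image height) the body spans roughly 40–90 %
  of frame height.
* **Lights** — exactly five directional lights toward the mesh (front,
  back, left, right, above) with i.i.d. U(0.3, 3.0) intensities.
* **Plan** — `n_configs` (default 2,700) base configurations, each rendered
  `renders_per_config` (default 4) times. Shape, pose, appearance, blanket
  and camera are fixed within a configuration; lights and background are
  redrawn per render. This is the one free choice in "rendered several
  times under varied lighting": it maximises annotation reuse while still
  varying every render. Backgrounds are redrawn per render rather than per
  configuration.

## Rendering and annotation exactness

The built-in rasterizer trades realism for contract: pinhole projection
(principal point at the image centre, pixel centres at half-integers),
z-buffered per-face flat Lambertian shading summed over the five lights
(two-sided cosine so winding cannot darken a face; radiance is exactly
linear in the intensities before the display clamp), RGBA output whose
alpha is 255 exactly where geometry projects, and a tight half-open
`[x, y, w, h]` box over opaque pixels. Keypoint visibility follows COCO:
0 outside the image or behind the camera, 1 when z-occluded (by body or
blanket, resolved against the z-buffer with a 0.18 m depth slack ≈ one
torso radius, since joints sit inside the body), 2 when visible. The
renderer interface (scene in, RGBA layer + ground truth out) is the seam
for higher-fidelity backends; everything downstream depends only on it.

Compositing applies one similarity transform (uniform scale + integer
translation) to sprite pixels, keypoints and box alike, and stores it in
the provenance, so placements are exactly invertible. "Near or on the bed"
is quantified as: the placed human box must overlap the bed box (dilated by
20 %) by at least 30 % of its own area, with the scale chosen so the
human's long axis is 50–90 % of the bed's long axis; all four numbers are
configurable, as the scenario definition gives no values. The rotation
augmentation draws angles from [70°, 110°] ∪ [−110°, −70°] with equal mass
per interval, expands the canvas so no source pixel or annotation is lost
(exposed canvas is black), and resamples by nearest-neighbour inverse
mapping — exact at multiples of 90°.

## Dataset files and splitting

Ground truth is standard COCO object-keypoint JSON with two namespaced
extension keys (`x_joints3d` for 3D joints, `x_config_id` for provenance);
serialisation is canonical (sorted keys, fixed separators, id-ordered
records), so a fixed dataset yields byte-identical files. The 10,000/800
split is drawn uniformly over *configurations*, not images: all renders of
one configuration land on the same side. This is stricter than a plain
image split and prevents near-duplicate leakage between train and
validation; with 4 renders per configuration the default sizes are exactly
representable (2,500 + 200 configurations).

## Evaluation

Detection evaluation follows the COCO protocol: confidence filtering at
0.001 (0.2 for pose tasks), greedy per-image NMS at IoU 0.65 (ties broken
by input order), then per IoU threshold 0.50:0.05:0.95 a global
confidence-ranked greedy matching, 101-point interpolated AP and final
recall as AR (single category, up to 100 detections per image), averaged
over the ten thresholds and reported in percent. OKS uses the standard 17
per-keypoint falloff constants (kernel width k = 2σ) with the box area as
the scale.

The per-person score underlying all statistics is: match ground truths and
detections one-to-one, globally greedy by IoU (ties: higher confidence,
then lower ground-truth id); a person scores its matched IoU if that
reaches 0.75 and 0 otherwise. The source formula line for this score is
truncated in the scenario definition; matched-IoU-or-zero is the reading
consistent with "improvements averaged across instances" and with the
stated intent of capturing both sensitivity and localisation accuracy. A
binary 1/0 variant ships behind `EvalConfig(binary_score=True)`.

## Statistics

Improvements are analysed on index-aligned per-person score vectors:
two-sided paired t; Wilcoxon signed-rank with zero differences dropped
(classic treatment — a flag reports when dropped zeros exceed 10 % of
pairs), exact null for ≤ 25 non-zero pairs without rank ties, tie-corrected
normal approximation otherwise; percentile bootstrap (default 10,000
replicates, seeded) for the CI of the mean improvement. BCa was considered
and rejected: the percentile interval is the simplest defensible reading
and is what the coverage calibration tests check. The 0.75-thresholded
score is distinctly non-normal, so the Wilcoxon p-value is the primary
significance criterion; the t-test is reported as supplementary. The
default comparison grid — all unordered pairs of {pretrained, A, B, D} per
scenario-1 validation and {pretrained, C, D} per scenario-2 validation,
across 5 architectures — has 5 × (6 + 3) = 45 cells (a contrast present in
both scenarios is tested once per scenario), giving a Bonferroni-corrected
per-test α of 0.05/45 = 0.00111…, reported rounded to 0.0011.

## Aspect diagnostic

`ln(w/h)` of a person box separates upright (< 0) from lying (> 0)
instances. Dataset-vs-target closeness is scored by Jensen–Shannon
divergence (nats, bounded by ln 2) between histograms on 50 shared bins
spanning the pooled range — a scalar stand-in for a visual density
comparison; the histogram estimator and bin count are choices, exposed as
parameters.

## Synthetic fixtures: what they do and do not show

The fixtures module replaces every external asset so the full pipeline runs
offline: flat-shaded ward backgrounds with exactly known bed boxes
(substituting harvested photographs and a bed detector), joint-limited
reflected-random-walk pose sequences from the supine rest pose
(substituting a motion-capture archive; limits are coarse anthropometric
ranges shipped as an editable asset), and bisection-constructed detections
at prescribed IoU for exercising the scoring boundary. Passing tests on
these fixtures certify the *machinery* — geometry, annotation exactness,
metric and statistical correctness, determinism — not photorealism, pose
naturalism, or transfer of any specific detector: reproducing real-data
fine-tuning gains would require trained detector weights and clinical
validation videos, which are outside this package's scope.

## Problem sizes and determinism

Default problem sizes used by the test suite and `scripts/acceptance.py`:
plans and splits are exercised at the full 10,800/10,000/800 scale
(bookkeeping only); fully rasterised end-to-end runs use 120–200 images at
320×240; statistical calibrations use 2,000 simulations (Wilcoxon type-I at
the corrected α; bootstrap coverage with 600 replicates per interval —
the replicate count trades precision for runtime, while `bootstrap_ci`'s
own default remains 10,000). One integer seed drives everything through
CRC-keyed `SeedSequence` sub-streams (`bedsynth._rng`), so adding a
subsystem never perturbs another's draws, and identical seeds produce
byte-identical manifests, annotation files and rasters.

## Known limitations

* No physically based cloth: the blanket is a noisy, smoothed heightfield.
* No shadows, textures, anti-aliasing or specular shading; flat per-face
  colour only.
* Clothing is a colour overlay, not geometry; hair/eyewear are face-band
  recolourings.
* Pose sequences have no activity semantics or dynamics.
* Area-stratified AP breakdowns and multi-class evaluation are out of
  scope; AR uses the 100-detection variant only.
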