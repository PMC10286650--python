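# Methods

This note records the models, conventions and numerical choices behind
`pancparts`, in the spirit of a methods appendix: what the pipeline
assumes, which knobs matter, what the synthetic phantoms do and do not
emulate, and where the design was genuinely open.

## Geometry conventions

All volumes carry a per-axis voxel spacing (mm) and a 4×4 affine mapping
0-based voxel indices to world coordinates (mm), voxel-center convention.
The affine is authoritative for world mapping; the spacing is used for
voxel volumes and anisotropy-aware distances. Masks read from files are
thresholded at > 0.5 so 0/255 and interpolated encodings survive. Labels
are stored on disk as uint8, probabilistic templates as 32-bit floats.
2D PDFF maps may come from single-slice NIfTI or from DICOM, where the
pixel-to-world mapping is assembled from ImagePositionPatient,
ImageOrientationPatient, PixelSpacing and SliceThickness; the package
does not convert between DICOM (LPS) and NIfTI (RAS) frames — callers
must supply the 3D labels and the 2D map in one common frame.

## Preprocessing

Masks are resampled to isotropic resolution (2 mm default, matching the
abdominal Dixon protocol the pipeline targets) by linear interpolation of
the binary volume followed by a 0.5 threshold — approximately
volume-preserving, which a nearest-neighbor scheme is not. Labels
resampled jointly use the nearest-label rule and are then reconciled with
the resampled mask (clipped to it; uncovered mask voxels take the nearest
label in mm) so the partition property survives resampling exactly.

Centroid alignment translates every mask so its foreground centroid
matches an arbitrary reference subject. Shifts are rounded to whole
voxels: masks stay binary, the operation is idempotent, and the ≤ half-
voxel-per-axis residual is absorbed by the nonlinear registration. No
rotational or affine pre-alignment is applied.

## Registration

The downstream method only needs an invertible, overlap-improving warp,
so the registration is specified as a contract — forward field on the
fixed grid, inverse field on the moving grid, forward∘inverse within one
voxel on foreground, positive Jacobian determinants, Dice never worse
than unregistered — and implemented as compositive diffeomorphic demons:

* inputs are smoothed with a Gaussian of σ = 1 voxel, giving smooth
  gradients on binary masks; similarity is mean squared difference;
* three pyramid levels (downsampling 4, 2, 1) with iteration budgets
  (60, 30, 8); a level stops early when the relative similarity change
  stays below 1e−4 for 3 iterations;
* each iteration computes a Thirion demons force from the fixed-image
  gradient, smooths it with a fluid-like Gaussian (σ = 1.5 voxels),
  caps the step at 1.2 voxels, exponentiates it by scaling-and-squaring
  (largest sub-step 0.4 voxels) and composes it onto the running forward
  map, composing the negated exponential onto the running inverse;
* after the pyramid, 12 damped fixed-point sweeps
  inv(x) ← ½ inv(x) − ½ fwd(x + inv(x)) tighten the inverse; the refined
  field is kept only if it reduces the maximum round trip. Measured
  round trips on phantom pairs are ≲ 0.1 voxel;
* if the final warped Dice is below the unregistered Dice the identity
  transform is returned with a convergence flag — registration can only
  help or do nothing;
* demons forces vanish away from both shapes, so the solve is restricted
  to the joint bounding box plus a 10-voxel margin and the fields are
  embedded back into the full grid (identity outside).

Field resampling and composition run through fused trilinear kernels
(numba-jitted, with a scipy fallback) — one registration of a 64³ mask
pair takes ~0.3 s on one CPU.

These hyperparameters are this package's defaults; they were chosen for
smooth organ-scale masks, not gray-scale images, and are exposed in
`RegistrationConfig`.

## Template construction and annotation

Groupwise averaging follows the classical scheme: the initial average is
the voxelwise mean of the centroid-aligned masks; each iteration
registers every mask to the current average and re-averages the warped
(fractional) masks. Four iterations are the default; identical inputs are
a fixed point. The probabilistic template is binarized at 0.5,
**inclusive** (≥), making the printed threshold deterministic at ties.

Annotation uses two planes whose normals point head→tail. Head is the
foreground strictly on the negative side of the head–body plane; tail is
the foreground on the non-negative side of the body–tail plane (so a
voxel exactly on a plane belongs to the part downstream of it); body is
the remainder. Overlapping head and tail regions raise an error rather
than silently relabeling; so does any empty part.

### Centerline

The centerline supports the midpoint rule for the body–tail boundary
(s_bt = s_hb + (L − s_hb)/2) and plane placement orthogonal to the organ
axis. It is computed as a **medial geodesic on the foreground voxel
graph**: a double Dijkstra sweep with physical edge lengths finds the
mask's two geodesic extremities; the path between them is recomputed
with every edge multiplied by a centrality factor
0.02 + 0.98·(1 − EDT/EDT_max), which pins it to the distance-transform
ridge. The off-axis ramp near each extremity is trimmed by one local
radius, the path is smoothed with a moving average (window 5), and both
ends are extended along their tangents to the mask surface so the
polyline runs tip to tip. Thinning-based skeletonization was rejected
because discrete thinning degenerates on even-width symmetric tubes
(it can return an empty skeleton), whereas the EDT-ridge geodesic is
defined for every connected elongated mask. Masks with a principal-axis
elongation ratio √(λ₁/λ₂) < 1.5 are rejected as degenerate, as are
multi-component masks.

The head end is identified as the end with the larger distance-transform
radius (the anatomical head is bulkier); a user orientation vector
overrides this.

`annotate_by_fraction` emulates a human annotator on phantom-like shapes
whose head is defined as a fraction of the medial length: the head–body
plane is placed at `r_head + f·(L − r_head − r_tail)` along the tip-to-tip
centerline — the end-cap radii are trimmed because the generative
centerline of a capsule-like organ starts one local radius inside the
tip — and the body–tail plane follows the midpoint rule.

## Inference

`subsegment_template` requires the subject on the template grid,
centroid-initializes with a whole-voxel shift, registers subject →
template, warps the parts template back through the inverse with
nearest-label interpolation (which can never invent label values), and
propagates: foreground voxels under a warped label take it; uncovered
foreground voxels take the label of the nearest labeled voxel in mm,
ties broken toward the lowest label id (head < body < tail), implemented
with per-label Euclidean distance transforms so the tie-break is exact
and deterministic. The result exactly partitions the input mask; the
fraction covered directly by the warped template is reported as a
diagnostic. The whole procedure is deterministic for fixed settings.

`subsegment_kmeans` clusters foreground world coordinates only (the
input is a shape, not an image) with k = 3, k-means++ seeding under the
given integer seed, and Lloyd iterations to convergence (10 restarts,
tolerance 1e−10, ≤ 300 iterations). Clusters become head/body/tail by
ascending projection of their centroids on the head→tail axis — the
principal axis of the foreground, signed so that the quarter of the
projection range holding more voxels is the head, or a user-supplied
vector.

## Metrics

* Dice: 2|A∩B|/(|A|+|B|); two empty masks score 1 with a warning
  (perfect agreement on absence; avoids NaNs in batch tables).
* 95% Hausdorff: boundary voxels are the 6-connectivity erosion
  difference; directed nearest-boundary distances are computed in world
  mm in both directions, **pooled**, and the 95th percentile is taken
  with linear interpolation between order statistics. (A max-of-directed-
  percentiles variant exists in the literature; the pooled symmetric
  form is this package's documented choice.)
* Volumes: foreground count × voxel volume, in mL.
* Bland–Altman: bias = mean(a−b), limits of agreement bias ± 1.96 × SD
  with the n−1 denominator.
* Per-part comparisons score only parts non-empty in both inputs; parts
  empty in either are flagged absent, not scored as zero.
* Wilcoxon signed-rank and Mann–Whitney U tests are re-exported from
  scipy.stats unchanged; they are evaluation plumbing, not part of the
  bespoke surface.

## Regional PDFF

Reslicing maps each 2D pixel center through the slice affine into the 3D
label volume and samples the nearest voxel's label; pixels outside the
volume are background. Slice thickness is deliberately ignored — the
operation is plane sampling, not slab averaging.

QC follows a fixed order per segment: (1) a raw resliced area of ≤ 30
pixels excludes the segment (`small_segment`); (2) pixels with PDFF
strictly above 50% — exactly 50.0% is retained — or non-finite (treated
as missing) are removed; (3) the surviving mask is opened with the
discrete disk of 3-pixel diameter, realized as the 3×3 four-connected
cross; a segment emptied by the opening is excluded (`emptied_by_qc`).
Otherwise the median PDFF over the opened mask is reported, with even
counts averaged over the two central order statistics. The area test is
not re-applied after the opening — emptiness is the only post-opening
exclusion. The whole-pancreas value merges all part labels into one
label first and then applies the identical cascade, so segments too
small on their own can still contribute to a reportable whole.

## Synthetic phantoms

A phantom is a tube around a cubic-spline centerline through five
control points: a gentle C-shaped bow (curvature amplitude 12 mm) with
Gaussian control-point jitter (σ = 2 mm), radius linearly interpolating
head → body → tail (9 / 7 / 5 mm), head spanning the first 40% of the
arc length and the body–tail boundary at the midpoint of the remainder —
the conventional anatomical definition. Ground-truth labels are assigned
by nearest-centerline-sample arc length, so they are exact even on
curved tubes. Cohorts jitter radii by ±15% and redraw (deterministically)
the rare draws whose tube would leave the grid. The defaults fit a 64³
grid of 2 mm voxels; a real pancreas is about 1.5× larger, with the same
proportions.

The phantoms emulate the elongated, curved, single-component,
bulky-head geometry of whole-pancreas masks and their inter-subject
variation. They do **not** emulate surface roughness from manual
delineation, the flattened (non-circular) cross-section of a real
pancreas, duodenal indentation, segmentation errors, or any image
intensities. Passing phantom suites therefore demonstrates the
correctness and internal consistency of the machinery — partitions,
invertibility, metric values, label propagation — not clinical accuracy
on patient data.

## Validation study sizes

The self-validation run (`scripts/acceptance.py`) uses: a 20-phantom
leave-one-out study (each fold builds a 4-iteration template from the
other 19 and subsegments the held-out phantom), a 50-phantom partition
suite for both methods (template built from 10 cohort members with 2
groupwise iterations), 20 random 16³ mask pairs against brute-force
metric oracles, 10 registered phantom pairs for the invertibility
contract, and the closed-form k-means / PDFF / Bland–Altman cases. On
one CPU the study takes ~10 minutes; the pytest suite runs a smaller
4-fold variant of the leave-one-out study.

## Known limitations

* The registration is tuned for smooth organ-scale binary masks; it is
  not a gray-scale image registration tool and does not reproduce any
  particular LDDMM energy.
* Centroid alignment is translation-only; cohorts with large rotational
  variation would need an orientation step before template construction.
* The annotation helpers assume an elongated single-component organ; the
  plane-based annotation itself is generic but planes must be supplied
  in world coordinates.
* PDFF reslicing assumes the 3D segmentation and the 2D map share a
  world frame; breath-hold misalignment between the two acquisitions is
  not corrected.
* Both-empty Dice = 1 and the pooled 95%HD variant are deliberate,
  documented conventions; other packages may differ.
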