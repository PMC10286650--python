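# pancparts

Automated subsegmentation of the pancreas into its three anatomical
segments — head, body and tail — from a whole-organ binary segmentation,
with downstream regional quantification of proton density fat fraction
(PDFF).

Quantitative MRI biomarkers of the pancreas (PDFF, T1) vary regionally:
fat infiltration, fibro-inflammation and cancer are all spatially
inhomogeneous, and whole-organ averages can wash out clinically relevant
contrasts. `pancparts` is aimed at imaging scientists who already have
whole-pancreas segmentations (manual or from a segmentation network) and
want reproducible head/body/tail labels plus per-segment biomarker values.

## Method

The core is a **template (atlas) approach built by groupwise
registration** of whole-organ masks:

1. **Template construction (offline).** A cohort of masks is resampled to
   2 mm isotropic resolution and translated so foreground centroids
   coincide. Starting from the voxelwise mean, each groupwise iteration
   registers every mask to the current average with a diffeomorphic
   transform φᵢ and re-averages the warped masks; after a few iterations
   this yields a probabilistic template p(x) ∈ [0, 1], binarized at 0.5.
2. **Parts annotation (once).** Two boundary planes — head–body and
   body–tail, normals pointing head→tail — partition the binarized
   template T into labels: head = {x : d_hb(x) < 0}, tail =
   {x : d_bt(x) ≥ 0}, body = the rest. The body–tail plane can be placed
   by the centerline midpoint rule: s_bt = s_hb + (L − s_hb)/2, i.e. the
   midpoint between the head–body boundary and the tail tip.
3. **Inference.** A new subject mask S is centroid-initialized and
   registered to the template (S → T, a diffeomorphic transform with an
   explicit inverse). The inverse warp carries the parts template into
   subject space with nearest-label interpolation, and every foreground
   voxel of S takes the warped label at its location (or the nearest
   labeled voxel in mm), so the labels exactly partition S.

Registration is a compositive diffeomorphic demons scheme on smoothed
masks: invertible by construction (forward and inverse displacement
fields, positive Jacobians, sub-voxel round trip), multi-resolution, with
mean-squared difference as the similarity.

Also included:

* the **k-means baseline** (k = 3 on foreground voxel coordinates,
  k-means++ seeding, clusters ordered along the organ axis);
* the **validation metric suite**: Dice similarity coefficient
  DSC = 2|A∩B|/(|A|+|B|), 95th-percentile Hausdorff distance (pooled
  symmetric, in mm), per-part volumes, and Bland–Altman bias ± 1.96·SD
  limits of agreement;
* **regional PDFF quantification**: the 3D labels are resliced onto a 2D
  PDFF map through scanner coordinates, then each segment passes QC —
  raw area must exceed 30 pixels, pixels above 50% PDFF are excluded, and
  the mask is opened with a 3-pixel-diameter disk — before its median
  PDFF is reported;
* a **phantom generator** producing curved, tapering, pancreas-like tubes
  with exact ground-truth head/body/tail labels, so the whole pipeline is
  testable without access-controlled imaging data.

## Worked example

Build a template from a synthetic cohort, annotate it, and subsegment a
held-out-style subject:

```python
import pancparts as pp
from pancparts.template import annotate_by_fraction

spec = pp.PhantomSpec()                      # 80 mm curved, tapering organ
cohort = pp.generate_cohort(spec, 10, seed=7)
masks = [m for m, _ in cohort]

aligned, _ = pp.centroid_align(masks, reference_index=0)
template, _ = pp.build_template(aligned, n_iterations=4)
parts_template = annotate_by_fraction(pp.binarize(template, 0.5),
                                      head_fraction=0.40)

subject, ground_truth = cohort[3]
result = pp.subsegment_template(subject, parts_template)
agreement = pp.compare_parts(result.parts, ground_truth)
print(f"coverage by warped template: {result.warped_parts_coverage:.3f}")
for part in ("head", "body", "tail"):
    print(f"{part:>5}: DSC {agreement.dsc[part]:.3f}   "
          f"95%HD {agreement.hd95_mm[part]:.2f} mm   "
          f"dV {agreement.volume_delta_ml[part]:+.2f} mL")
```

prints

```
coverage by warped template: 0.903
 head: DSC 0.989   95%HD 0.00 mm   dV +0.17 mL
 body: DSC 0.957   95%HD 2.00 mm   dV -0.11 mL
 tail: DSC 0.983   95%HD 0.00 mm   dV -0.06 mL
```

i.e. 90% of the subject's voxels were covered directly by the warped
parts template (the rest filled by nearest label), and the recovered
segments agree with the phantom's generative ground truth to DSC ≥ 0.95
per part with volume errors well under a millilitre.

The same pipeline is available from the shell:

```sh
pancparts make-phantoms --n 10 --seed 7 --out-dir phantoms/
pancparts build-template --masks phantoms/ --iterations 4 --out template.nii.gz
pancparts annotate --template template.nii.gz \
    --plane-hb 50,60,64,1,0,0 --plane-bt 80,66,63,1,0,0 --out parts.nii.gz
pancparts subsegment --template parts.nii.gz --in subject.nii.gz --out out.nii.gz
pancparts pdff-quant --parts out.nii.gz --pdff slice.nii.gz --report pdff.json
```

## Layout

| module | contents |
| --- | --- |
| `pancparts.geometry` | mask/label/template/PDFF containers, NIfTI and DICOM I/O |
| `pancparts.phantom` | synthetic pancreas cohorts with ground-truth parts |
| `pancparts.preprocess` | isotropic resampling, centroid alignment |
| `pancparts.registration` | diffeomorphic demons, forward/inverse warps |
| `pancparts.template` | groupwise template, plane annotation, centerline |
| `pancparts.inference` | template subsegmentation, k-means baseline |
| `pancparts.metrics` | DSC, 95%HD, volumes, Bland–Altman, per-part tables |
| `pancparts.pdff` | 3D→2D label reslicing and QC'd median PDFF |

See `docs/methods.md` for the modelling assumptions, parameter defaults
and known limitations.
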