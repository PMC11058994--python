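# Methods

## Problem and model

After endovascular thrombectomy for ischemic stroke, hemorrhagic
transformation (HT) appears on follow-up non-contrast CT as regions of
elevated attenuation — acute blood sits at roughly 50–90 HU against
brain parenchyma at 25–40 HU. `htseg` segments such regions
semi-automatically: the user supplies a box around the suspected bleed,
and the algorithm selects voxels inside it whose Hounsfield value falls
in an intensity window that *adapts to the patient*.

The adaptation is a single-pass rule system. An initial pass thresholds
at the nominal acute-blood window 50–80 HU. The population standard
deviation (SD) of the selected voxels' intensities then diagnoses the
segmentation quality: a narrow spread means the window clipped the
lesion's density range (under-segmentation), a wide spread means
background leaked in (over-segmentation). The SD picks the final
window from a fixed table; every window is 30 HU wide:

| initial-region SD (HU) | classification  | final window (HU) |
|---|---|---|
| SD = 0        | under-segmented | 35–65 |
| 0 < SD ≤ 2.3  | under-segmented | 40–70 |
| 2.3 < SD ≤ 6  | under-segmented | 45–75 |
| 6 < SD ≤ 11   | well-segmented  | 50–80 |
| SD > 11       | over-segmented  | 55–85 |

Boundaries are inclusive on the upper end, window bounds inclusive at
both ends. An *empty* initial mask has SD defined as 0 and routes to
the 35–65 row: it is the extreme of under-segmentation, and lowering
the window is the only move that can recover a faint lesion. The table
is data (`RuleTable`, YAML-overridable): the cut-offs were calibrated
on one scanner fleet and may need adjustment elsewhere.

Only one adaptation pass is performed — threshold, classify, re-threshold.
The rule table is a finished artifact; iterating it further has no
defined fixed point and is not part of the procedure.

## Pipeline stages

**Skull stripping.** K-Means (k = 3, deterministic k-means++ from a
fixed seed) clusters voxel intensities into air / soft tissue / bone;
the soft-tissue class is reduced to its largest connected component,
holes are filled per slice, and the surface is refined by a
morphological geodesic active contour (smoothing 1, no balloon force),
run in 10-iteration batches up to 200 iterations, stopping when the
mask changes by < 0.1 % of voxels. Because curvature smoothing can
drift across the thin skull line, the refined mask is clamped to
soft-tissue density (−200 to 300 HU) and reduced again to its dominant
component. Voxels ≥ 300 HU are never brain.

**Filtering.** Gaussian denoising (σ = 1 voxel) followed by unsharp
masking, `v + amount · (v − G_σ v)` with gain 1 by default. σ is
interpreted in voxels and both filters run per axial slice: with
4–5 mm slices over ~0.5 mm in-plane pitch, a 3-D kernel at one voxel
would mix slices asymmetrically. When a brain mask is available the
kernels are renormalised over in-mask voxels so skull density never
bleeds into edge-of-brain values. Without a mask the two filters
compose to a linear shift-invariant operator (tested property).

**ROI.** A single in-plane rectangle replicated over a slice range —
six integers `z0 z1 y0 y1 x0 x1`, half-open, 0-based. The lesion is
3-D but the user draws in 2-D; a box is the minimal extension.

**Post-processing.** Per-slice binary closing with a 4 × 4 square
element, computed on the ROI crop so the mask never crosses ROI
bounds, then re-intersected with the brain mask. Closing is
implemented through the identity *closing = complement of the opening
of the complement* (via `scipy.ndimage.binary_opening`): opening is
anchor-free, so the even-sized element introduces no half-pixel shift,
and the result is the exact mathematical closing against an empty
background (verified against a placement-enumeration oracle). Element
shape and dimensionality were open choices; 2-D in-plane closing was
chosen because 4–5 mm slices make a 3-D element severely anisotropic.
No connected-component filtering follows: scattered petechial (HI2)
bleeds are legitimately multi-component.

**Volume.** `true-voxel count × dz·dy·dx / 1000` mL.

## Evaluation

Metrics are computed over the domain **ROI ∩ brain**, not the whole
scan; whole-volume true-negative counts would pin specificity at ≈ 1
regardless of quality.

* **DSC** = 2·TP / (2·TP + FP + FN), with the conventional six verbal
  bands at cuts 0, 0.2, 0.4, 0.6, 0.8. Two empty masks give DSC 1.0
  with a degenerate-case flag (agreement of two empty segmentations is
  perfect; 0/0 is otherwise undefined).
* **Sensitivity / specificity** = TP/(TP+FN), TN/(TN+FP); undefined
  denominators yield flagged NaN.
* **ROC-AUC.** A hard thresholder exposes no voxel score, so the ROC
  is built from the method's one scalar dial: the window lower bound L
  is swept over −20…120 HU (step 1) at fixed 30 HU width, giving one
  (FPR, TPR) operating point per L. The points are not monotone in
  FPR — very low windows select only background — so the curve is
  defined as the monotone upper envelope of the point cloud anchored
  at (0,0) and (1,1), integrated by trapezoid. A naive sort-by-FPR
  polyline would credit a perfectly separable image with area 0.5,
  which no reasonable reading of an ROC supports; the envelope gives
  it 1.0 and stays at chance (±sampling error) when intensities are
  independent of the reference labels (both tested).
* **Lin's CCC** on paired per-case volumes (mL):
  `2·cov(x,y) / (var x + var y + (mean x − mean y)²)` with population
  moments. The 95 % CI uses the Fisher z-transform with Lin's
  asymptotic variance; n ≥ 3 and non-zero total variance required.

## Synthetic phantoms

The generator emulates the acquisition the method targets: an
ellipsoidal brain (default 30 HU) inside a 1000 HU skull shell and
−1000 HU air, on an anisotropic grid of (24, 128, 128) voxels at
(5, 0.5, 0.5) mm — ~4–5 mm slices with sub-millimetre in-plane pitch.
Two lesion morphologies: *PH-like*, one confluent high-contrast blob
(default mean 65 HU, SD 8); *HI2-like*, 3–10 scattered blobs at 10 HU
lower mean — smaller, lower contrast, more varied shape. Lesion masks
take exactly the required number of nearest voxels under a random
ellipsoidal metric, so the achieved volume matches the target to
within one voxel even for sub-slice lesions. Intensities are drawn
iid Normal *before* blur, making the region statistics that drive the
rule table analytically known; in-plane Gaussian blur (σ = 1 voxel,
partial-volume mimicry) and global additive noise (SD 2 HU) then
degrade the image. Ground truth is the pre-blur support.

Cohorts draw per-case volumes from lognormals moment-matched to
(mean 17.28, SD 12.44) mL for PH and (6.81, 9.59) mL for HI2 — the
right skew matches observed min–max ranges — with mild per-case jitter
of lesion mean (±3 HU) and SD (±1 HU).

What the phantoms do **not** emulate: real skull geometry and bone
texture, beam hardening and streak artifacts, calcification, motion,
and — most importantly — contrast extravasation after thrombectomy,
which mimics blood density and is the method's known clinical
confound. Passing phantom tests therefore demonstrates correctness of
the algorithmic pipeline under controlled intensity statistics, not
clinical-grade accuracy on patient scans.

## Problem sizes and numerical choices

Default test/benchmark sizes are (12–24, 64–128, 64–128) voxel grids,
40-case cohorts for the adaptive-vs-global comparison and 200-spec
draws for distributional checks; these sizes make every property
observable while keeping the suite quick on one CPU. HU is held as
float32 after rescale (preserves slope/intercept arithmetic). The
DICOM reader tolerates 10 % slice-gap jitter before raising; silent
resampling is out of scope, as are multi-series studies, registration,
MRI, and hemorrhage-type classification. Whether the rule-table SD
should be computed on raw or filtered HU is not externally specified;
it is computed here on the volume handed to the thresholder, i.e.
after preprocessing.

## Known limitations

* The ROI is user-supplied; no automatic lesion proposal.
* The SD heuristic can misfire on lesions with genuinely indistinct
  boundaries (a low SD need not mean under-segmentation).
* Skull stripping is intensity-driven; it assumes CT-calibrated HU and
  a closed skull, and recovers ≥ 99 % of brain only on clean geometry
  (partial-volume boundary voxels are excluded on blurred data).
* The window-sweep ROC is an operationalisation for a binary
  segmenter, not a property of any underlying probabilistic score.
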