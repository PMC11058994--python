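# htseg

Semi-automatic segmentation of **hemorrhagic transformation (HT)** on
follow-up non-contrast head CT after stroke reperfusion therapy.

Acute blood attenuates at roughly 50–90 HU against brain parenchyma at
25–40 HU, but the right intensity window varies from patient to
patient. `htseg` implements an adaptive Hounsfield-unit thresholding
pipeline for clinicians and imaging researchers who need fast,
CPU-only hemorrhage volumetry: skull stripping (K-Means + geodesic
level set), Gaussian denoising and unsharp edge enhancement, then
ROI-restricted thresholding whose window adapts to the patient, and
morphological closing. The user supplies only a box around the bleed.

## The adaptive rule

An initial pass thresholds the ROI at the nominal window 50–80 HU.
The population SD of the selected intensities diagnoses the result —
narrow spread ⇒ the window clipped the lesion (under-segmented), wide
spread ⇒ background leaked in (over-segmented) — and picks the final
30-HU-wide window:

| SD (HU) | classification | final window |
|---|---|---|
| SD = 0 | under-segmented | 35–65 |
| 0 < SD ≤ 2.3 | under-segmented | 40–70 |
| 2.3 < SD ≤ 6 | under-segmented | 45–75 |
| 6 < SD ≤ 11 | well-segmented | 50–80 |
| SD > 11 | over-segmented | 55–85 |

The final mask is re-thresholded at that window, closed per slice
(4 × 4 square), and converted to millilitres. Evaluation against a
reference mask reports Dice (DSC = 2·TP/(2·TP+FP+FN) with the six
verbal agreement bands), sensitivity/specificity and a window-sweep
ROC-AUC within ROI ∩ brain, and Lin's concordance correlation
coefficient of paired volumes across a cohort. A synthetic
head-phantom generator (ellipsoidal brain in a 1000 HU skull shell,
confluent "PH-like" or scattered "HI2-like" lesions with controllable
intensity statistics) makes the whole pipeline testable without
patient data. See `docs/methods.md` for the model details.

## Worked example

Generate a 17.28 mL high-contrast phantom, segment it, evaluate:

```sh
htseg phantom --out case --kind PH --target-ml 17.28 --seed 7
# -> INFO wrote phantom to case (gt volume 17.28 mL); ROI in case/phantom.json
htseg segment --input case/volume.nii.gz --brain case/brain.nii.gz \
              --roi 12 20 23 104 39 103 --out seg
htseg evaluate --pred seg/mask.nii.gz --gt case/gt.nii.gz \
               --roi 12 20 23 104 39 103 --out metrics.json
```

`seg/result.json` records the adaptation:

```json
{
  "initial_window": [50.0, 80.0],
  "initial_sd_hu": 3.9194,
  "label": "under-segmented",
  "final_window": [45.0, 75.0],
  "volume_ml": 18.02
}
```

The initial 50–80 HU pass selected 13 932 voxels whose SD (3.9 HU)
falls in the 2.3–6 band: the case is under-segmented (partial-volume
blur pulled boundary voxels below 50 HU), so the window drops to
45–75 HU and the recovered volume is 18.02 mL against 17.28 mL of
ground truth. `metrics.json` then reports

```json
{"dsc": 0.978895, "agreement_band": "almost-perfect",
 "sensitivity": 0.99986, "specificity": 0.97852}
```

— near-perfect spatial overlap, with the small specificity deficit
coming from the blurred rim outside the true lesion.

`htseg benchmark --n 40 --mean-shift -10 --seed 11 --out bench.csv`
reproduces the adaptive-vs-global comparison on a synthetic cohort
whose lesions sit 10 HU below nominal density: the adaptive rule beats
the fixed 50–80 HU threshold by ~0.07 mean DSC there.

## Library surface

```python
from htseg import (PhantomSpec, make_head_phantom, preprocess,
                   adaptive_segment, evaluate_case, lins_ccc)
case = make_head_phantom(PhantomSpec(seed=7))
vol, brain = preprocess(case.volume, seed=0)
result = adaptive_segment(vol, case.roi, brain)
print(result.label, result.final_window, result.volume_ml)
```

Not in scope: automatic ROI proposal, hemorrhage-type classification,
separation of contrast extravasation from blood, extra-axial
hemorrhage (IVH/SAH/SDH/EDH), registration/resampling, and MRI.
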