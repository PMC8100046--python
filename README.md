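# hrfcount

Semi-automatic counting of **hyperreflective retinal foci (HRF)** in OCT
B-scans.

Solitary, small (<30 µm) intraretinal hyperreflective foci with medium
reflectivity (similar to the retinal nerve fiber layer, RNFL) and no
back-shadowing are an OCT biomarker of retinal inflammation — they are
thought to be aggregates of activated microglia — and are of particular
interest in diabetic retinopathy. Counting them by hand is slow and
requires a trained grader. `hrfcount` implements a reproducible
semi-automatic counting pipeline for single B-scans, together with the
statistical machinery needed to validate any such counter against a manual
reference (ICC, Bland–Altman), and a synthetic B-scan generator with
planted ground truth so the whole chain is testable without clinical data.

The tool is *semi*-automatic by design: the user supplies the region of
interest (the retinal band from the RNFL/GCL boundary down to the external
limiting membrane, drawn freehand in practice) and the physical pixel
scale; everything else is automatic.

## Pipeline

For a B-scan `I` (8-bit, cropped to ±1,500 µm around the fovea):

1. **À-trous wavelet denoising.** Stationary B3-spline decomposition
   `I = A_5 + Σ_{i=1..5} w_i`, with per-plane hard thresholds
   `|w_i| ≥ k_i σ_i`, `k = (4, 3, 3, 0, 0)` and robust (MAD-based) noise
   scaled by σ = 1.50. Coarse planes and the residual are dropped, so the
   "denoised image" is a spot-enhanced detail mask.
2. **Masked CLAHE.** Contrast-limited adaptive histogram equalization
   (blocksize 127, 256 bins, max slope 3.00) applied through the denoised
   image as a per-pixel blend weight: enhancement acts where spot-scale
   structure exists and leaves the rest of the scan untouched.
3. **Spot detection.** Optional Gaussian pre-filter (σ = 1.5), then
   ImageJ-style noise-tolerance (prominence) local maxima; each maximum is
   measured as the mean intensity in a 5×5 box (box size 2).
4. **Filtering.** Maxima outside the user ROI are discarded; any spot with
   measured intensity greater than **2× the image mean** is excluded as a
   hard exudate / bright confounder.

Four built-in method profiles share steps 1–2 and differ in step 3:

| method | pre-filter   | box size | noise tolerance |
|--------|--------------|----------|-----------------|
| 1      | Gaussian 1.5 | 2        | 15              |
| 2      | Gaussian 1.5 | 2        | 20              |
| 3      | none         | 2        | 20              |
| 4      | none         | 2        | 15              |

Per scan and method the tool records `n` (retained spot count),
`spot_mean`, `image_mean` and the list of per-spot intensities.

The agreement layer compares paired manual/semi-automatic counts with the
two-way absolute-agreement single-measures ICC (ICC(A,1)) and Bland–Altman
analysis (`d = manual − semi`; bias = mean d; limits of agreement =
bias ± 1.96·SD(d)), plus point-cloud diagnostics (trend of d on the pair
means; homogeneity of the difference variability between count halves).

## Worked example

```python
from hrfcount import SceneParams, generate_bscan, builtin_profile, run_method

scan, truth = generate_bscan(SceneParams(seed=42, n_foci=30))  # speckled scan
for m in (1, 2, 3, 4):
    rec = run_method(scan, truth.roi, builtin_profile(m))
    print(f"method {m}: n={rec.n}  spot_mean={rec.spot_mean:.2f}  "
          f"image_mean={rec.image_mean:.2f}")
```

prints

```
method 1: n=27  spot_mean=96.50  image_mean=72.15
method 2: n=27  spot_mean=96.50  image_mean=72.15
method 3: n=69  spot_mean=88.82  image_mean=72.15
method 4: n=200  spot_mean=78.22  image_mean=72.15
```

The scene contains 30 planted foci; some sit under vessel shadows or are
masked by speckle. The pre-filtered methods (1–2) count close to the truth,
while the unfiltered methods (3–4) also pick up speckle maxima and
overcount — the same qualitative ordering that motivates preferring a
pre-filtered profile, and lower tolerance overcounts more (method 4 vs 3).
`image_mean` is the post-enhancement mean on which the 2×-mean exclusion
operates, and `spot_mean` averages the retained per-spot box intensities.

Command-line equivalents:

```sh
hrfcount simulate --n 5 --seed 42 -o scenes/        # scans + truth + ROIs
hrfcount count --image scenes/scene_0042.tif --roi scenes/scene_0042_roi.json \
         --method 2 --no-crop -o counts.csv
hrfcount agree --pairs pairs.csv --col-manual manual --col-semi semi
```

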