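# Methods

This note documents the models, conventions and design choices behind
`hrfcount`, in the order data flows through the tool.

## Input model and conventions

A B-scan is an 8-bit grayscale raster; rows are axial depth (row 0 =
vitreous side), columns lateral position, indices 0-based, crops half-open
`[lo, hi)`. 16-bit input is mapped linearly over the **full dtype range**
(`v·255/65535`), never per-image min–max: per-image stretching would change
the meaning of the 2×-image-mean brightness exclusion from scan to scan.
Wherever a real value becomes an 8-bit intensity or a pixel index, rounding
is half-up (`floor(x + 0.5)`) — one documented convention, no
round-to-even surprises at `.5` boundaries. Physical scale (µm/px lateral
and axial) and the fovea column are required user inputs; scans are
centered at acquisition time and the exporter's pixel pitch varies by
device, so the tool refuses to guess either. The fovea-centered crop keeps
`±round(1500/lateral_scale)` columns, i.e. the central 3 mm.

## À-trous decomposition and denoising

The stationary ("with holes") wavelet transform uses the separable
B3-spline kernel (1, 4, 6, 4, 1)/16, dilated by `2^(i−1)` at level *i*,
mirror boundary; `w_i = A_{i−1} − A_i`, residual `A_J`. Reconstruction is
exact by construction (telescoping sum), which the tests assert to 1e-9 per
pixel. Five levels require a minimum image dimension of 64 px
(`4·2^(levels−1)`); the decomposition of a 64×64 image is supported.

Denoising hard-thresholds each plane at `k_i σ_i` and **sums only the
surviving detail planes**; the residual is never added back. Two σ
semantics are available:

* `robust_noise=True` (default): `σ_i = 1.50 · MAD(w_i)/0.6745`, a robust
  per-plane noise estimate — our reading of a "non-Gaussian noise removal"
  option combined with a standard-deviation setting of 1.50;
* `robust_noise=False`: `σ_i = 1.50 · c_i`, where `c_i` is the L2 norm of
  the level's equivalent detail filter, obtained by decomposing a discrete
  delta (Gaussian noise propagation through the filter bank).

`k_i = 0` *drops* plane *i* entirely rather than keeping it untouched.
With `k = (4, 3, 3, 0, 0)` this removes the two coarsest planes — the
smooth anatomy — so the output is a sparse spot/detail image. That is what
makes the next stage meaningful: the denoised image is used as a mask, and
a mask that contained the full background would enhance everything.

## Masked CLAHE

Classical tiled CLAHE: tiles of side `blocksize` (127) anchored at the
origin, edge tiles smaller; per-tile histogram on `bins` (256) bins;
clipping at `max_slope · n_pixels/bins` with the excess redistributed
uniformly in a single pass (no iteration — deterministic and standard);
per-tile mapping `255·cdf/N`; per-pixel bilinear interpolation between the
four surrounding tile mappings (clamped beyond the outer tile centers).
A tile with a single occupied bin maps to itself (identity), so constant
regions are preserved. CLAHE is implemented in-package: the available
library implementations parameterize clipping as a float fraction and
normalize mappings differently, so they cannot express the
blocksize/bins/max-slope contract this tool documents. Only the tiled
variant is provided; a per-pixel sliding-window variant would be
prohibitively slow and changes none of the semantics the tests pin down.

Masked application is a per-pixel convex blend,
`out = original + (mask/255)·(enhanced − original)`: weight 255 applies
full enhancement, 0 leaves the pixel untouched. A binarize-at-threshold
variant is available (`binarize_threshold`) for all-or-nothing masking.

## Spot detection

Detection follows the ImageJ "find maxima" prominence convention. The
documented contract: candidate local maxima (≥ all 8 neighbours) are
processed in descending value; from each candidate a flood fill expands
over 8-connected pixels with `value > peak − tolerance` **or
`value == peak`** (the second clause keeps equal-valued plateaus together
even at tolerance 0); the candidate is rejected when the flood reaches a
pixel brighter than the peak or one claimed by a previously accepted
maximum. Accepted plateaus yield one maximum at the plateau centroid
(half-up rounding; tie order row-then-column). A globally constant image
yields no maxima — a counter reporting one spot on a blank scan would be
meaningless. Output order is descending peak value, ties by (row, col).
The implementation dismisses equal-valued pixels of a rejected flood
region without re-flooding them; this is an exact shortcut (the flood
component and its rejection verdict depend only on the peak value), and
the test suite checks equivalence against an independent brute-force
implementation with no such shortcut.

The Gaussian pre-filter (σ = 1.5, kernel truncated at ⌈4σ⌉, mirror
boundary, float output) applies to *detection only*; spot intensities are
measured on the processed but unfiltered image, as the mean of the
`(2·box_size+1)²` box clipped at the borders (mean-in-box; the historical
plugin does not document its box statistic, so the simplest one is used
and documented).

## Pipeline assembly and exclusions

`run_method` executes crop (optional) → denoise → masked CLAHE →
pre-filter → maxima → box measurement → ROI filter → brightness exclusion.
All four built-in profiles share the preprocessing and differ only in the
spot-counter settings; every stage can also be switched off in custom
profiles, so a variant that skips denoising for the unfiltered methods is
expressible if a user wants it.

The ROI is an input polygon (≥3 vertices, row/col coordinates), never a
computed segmentation — supplying it is the "semi" in semi-automatic.
Inclusion uses the even-odd (ray-casting) rule with boundary points
counted inside, implemented in-package because that boundary convention is
part of the contract.

`image_mean` is taken on the cropped, post-CLAHE image — the same image on
which spot intensities are measured, making the comparison
`intensity > 2·image_mean` internally consistent; the pre-enhancement mean
is recorded alongside for transparency. The inequality is strict:
intensity exactly equal to twice the mean is retained. `spot_mean` is NaN
(never 0) when no spots survive, so empty scans cannot contaminate
downstream agreement statistics.

The sub-30-µm criterion is enforced implicitly by the detection
parameters, which is how the original procedure prevents vessels and hard
exudates from being counted. An explicit gate is available
(`max_diameter_um`): it measures the Feret diameter of the flood region
above `peak − tolerance` on the detection image. That region is wider than
the physical focus (pre-filter blur plus the tolerance margin), so the
gate is off in the built-in profiles and its threshold should be chosen
relative to region size, not to the 30 µm definition.

## Agreement statistics

Differences are `d = manual − semi` throughout: an overcounting
semi-automatic method therefore shows a *negative* bias. ICC defaults to
ICC(A,1) (two-way, absolute agreement, single measures) because absolute
agreement between modalities is the clinical question; the consistency
form is available by flag. All-identical tables return ICC 1.0 with a
warning rather than 0/0. Limits of agreement use the 1.96·SD(d) half-width
with the n−1 sample SD. Cloud diagnostics: OLS of `d` on the pair means
(slope + two-sided p) and a Brown–Forsythe/Levene test (absolute
deviations from group medians) of `d` between the halves below and above
the median pair mean — with two groups this F-test is identical to the
two-sample t on those deviations. Diagnostics require ≥4 pairs and are
refused (NaN + note) below that. Correlation between two eyes of the same
patient is not modelled; counts are treated as independent pairs.

## Synthetic scenes

The generator renders the three entity classes the pipeline must separate
on a layered background constant along the lateral direction:

* **Background**: an axial step profile (vitreous floor 28–30, RNFL 150,
  GCL/IPL 90, INL/OPL 60, ONL 45, thin ELM 150, RPE 180, choroid tapering
  110→40) with short linear transitions. Intensities follow an 8-bit
  clinical export: the vitreous has a noise floor rather than true black,
  and band boundaries are sharp at the ~10 µm scale. Within the counting
  band the profile decreases monotonically with depth; a thin bright ridge
  band (e.g. a high-contrast OPL) is deliberately not modelled, since on a
  noiseless scan such a ridge forms a legitimate plateau maximum of its
  own and has no ground-truth count.
* **Foci**: Gaussian bumps, amplitude 100–140 above the local band,
  σ 0.9–1.25 px (FWHM 21–29 µm at the default 10 µm/px — under the 30 µm
  definition, validated at construction). In *well-separated* mode foci
  keep ≥12 px mutual distance and are placed only on locally flat
  background (no value within ±8 rows more than 5 levels brighter): a
  focus on a band flank merges into the band's flood region and is not a
  countable isolated object, for the same reason manual counting excludes
  the RNFL.
* **Vessels**: bright ellipses at the inner retina with a multiplicative
  back-shadow column (factor ≈0.5) underneath.
* **Exudates**: large (≥50 µm) disks with a bright core (245–255) and a
  20% radial falloff, far above twice the expected image mean, so the
  brightness correction must reject them.

Speckle is multiplicative gamma noise with shape 100 (≈10% contrast),
matching the residual speckle of a ~100-frame averaged acquisition; raw
single-frame speckle would be far harsher and is not what this class of
scan shows. All randomness flows from the single scene seed.

What passing tests show — and what they do not: the synthetic background
has no anatomical curvature, no intra-layer texture, no foveal pit, and
foci are isotropic Gaussians. Recovery of planted foci at 100% therefore
validates the pipeline's mechanics (detection, masking, exclusion logic,
coordinate bookkeeping), not clinical accuracy on real scans, which only a
reader study can establish.

`generate_paired_counts` draws manual counts from a truncated-at-zero
normal (default mean 58.9, SD 36.9 — the scale of a typical validation
series) and subtracts normal differences (default bias −0.2, SD 8.3, so
1.96·SD ≈ 16.3 foci), rounding to integers and flooring at zero. Because
the estimator of the bias from one n = 140 study has standard error
8.3/√140 ≈ 0.70, recovery is asserted on the pooled mean over 20
replicate studies (within 2·SE/√20), with each study's limits half-width
within 15% — per-study ±2·SE bounds would fail ~5% of replicates by
construction, which is sampling noise, not an implementation defect.

## Problem sizes and runtime choices

Default scenes are 256×360 px (≈1 mm axial × 3.6 mm lateral at 4 and
10 µm/px); the validation study in `scripts/acceptance.py` uses 12 speckled
scans with 10–75 foci each, enough to estimate ICC/bias/limits on the
count scale while keeping a full run in seconds. Oracle-equivalence checks
use 32×32 images (exhaustive flood enumeration is quadratic) and
reconstruction checks 64×64 (the 5-level minimum).

## Known limitations

* Not a bit-exact reimplementation of the historical ImageJ plugins; the
  contracts above are the specification, and the plugin's undocumented
  choices (box statistic, noise-removal semantics) are resolved explicitly.
* Single B-scans only: no stacks, no proprietary container formats
  (.e2e/.vol), no automatic layer segmentation, no fovea detection.
* The brightness exclusion threshold (2× whole-crop post-CLAHE mean) is
  crude on scans whose composition differs strongly from the usual crop;
  alternatives (pre-enhancement mean, ROI-restricted mean) are simple to
  compute from the recorded fields but are not wired into the profiles.
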