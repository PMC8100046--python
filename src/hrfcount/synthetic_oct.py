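"""Seed-deterministic synthetic OCT B-scans and paired count tables.

The generator renders the three entity classes the counting pipeline has to
separate:

* **foci** — the objects being counted: Gaussian bumps of sub-30-µm extent
  and medium reflectivity (contrast comparable to the nerve-fiber layer),
  placed inside the retinal counting band;
* **vessels** — larger bright ellipses near the inner retina with a
  back-shadowing column underneath (reduced signal below the vessel);
* **exudates** — large (>= 40 µm) near-saturated bright disks, brighter
  than twice the expected image mean so the pipeline's brightness
  correction must reject them.

The background is a smooth axial layer profile (vitreous, RNFL, inner
plexiform/nuclear layers, ELM/ellipsoid, RPE, choroid) constant along the
lateral direction; optional multiplicative gamma speckle emulates the
first-order noise character of coherent imaging.  All randomness flows from
the single ``seed`` in :class:`SceneParams`.

``generate_paired_counts`` separately draws manual/semi-automatic count
pairs with a prescribed bias and difference SD, for exercising the
agreement statistics at the scale of a clinical validation study.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np

from ._util import round_half_up
from .agreement_stats import PairedCounts
from .hrf_pipeline import ROIPolygon
from .oct_image import BScanImage

__all__ = ["SceneParams", "SyntheticTruth", "generate_bscan",
           "generate_paired_counts", "save_scene"]

# Axial layer profile: (depth fraction, base intensity).  Chosen to mimic a
# macular B-scan: dark vitreous, bright RNFL band, alternating inner layers,
# dark outer nuclear layer, bright ELM/ellipsoid and RPE, dim choroid.
_DEFAULT_LAYERS = (
    (0.000, 28), (0.140, 30),                 # vitreous floor
    (0.165, 150), (0.210, 150),               # RNFL band
    (0.235, 90), (0.310, 90),                 # GCL/IPL
    (0.330, 60), (0.460, 60),                 # INL/OPL
    (0.480, 45), (0.705, 45),                 # ONL
    (0.720, 150), (0.735, 150),               # ELM
    (0.750, 95),                              # EZ gap
    (0.775, 180), (0.800, 180),               # RPE
    (0.815, 110), (0.920, 70), (1.000, 40),   # choroid taper
)


@dataclass(frozen=True)
class SceneParams:
    """Scene description for one synthetic B-scan.

    The defaults describe a cropped central-3-mm macular scan at 10 µm/px
    lateral and 4 µm/px axial sampling: 20 foci of 100-140 amplitude and
    0.9-1.25 px sigma (FWHM 21-29 µm, under the 30 µm focus ceiling), two
    vessels with back-shadowing, two exudates, moderate speckle.
    """

    height: int = 256
    width: int = 360
    lateral_scale_um: float = 10.0
    axial_scale_um: float = 4.0
    fovea_col: int | None = None          # default: image center
    n_foci: int = 20
    focus_amplitude_range: tuple = (100.0, 140.0)
    focus_sigma_px_range: tuple = (0.9, 1.25)
    n_vessels: int = 2
    n_exudates: int = 2
    speckle: bool = True
    speckle_shape: float = 100.0   # ~10% contrast, as after ~100-frame averaging
    layer_profile: tuple = _DEFAULT_LAYERS
    roi_top_frac: float = 0.26            # RNFL/GCL boundary
    roi_bottom_frac: float = 0.72         # just inner to the ELM
    well_separated: bool = True
    min_separation_px: float = 12.0
    seed: int = 0

    def __post_init__(self):
        if min(self.n_foci, self.n_vessels, self.n_exudates) < 0:
            raise ValueError("entity counts must be >= 0")
        sig_hi = self.focus_sigma_px_range[1]
        # Rendered focus diameter (FWHM) must stay under 30 µm.
        fwhm_um = 2.0 * math.sqrt(2.0 * math.log(2.0)) * sig_hi \
            * self.lateral_scale_um
        if fwhm_um >= 30.0:
            raise ValueError(
                f"focus sigma up to {sig_hi} px renders {fwhm_um:.1f} um "
                "FWHM; foci must stay below 30 um")
        if not 0 < self.roi_top_frac < self.roi_bottom_frac < 1:
            raise ValueError("ROI fractions must satisfy 0 < top < bottom < 1")


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth for one generated scene."""

    foci: tuple          # (row, col, amplitude, sigma)
    vessels: tuple       # (row, col, radius_px, shadow_factor)
    exudates: tuple      # (row, col, radius_px, value)
    roi: ROIPolygon
    seed: int

    @property
    def n_foci(self) -> int:
        return len(self.foci)


def _background(params: SceneParams) -> np.ndarray:
    fracs, vals = zip(*params.layer_profile)
    depth = np.arange(params.height) / max(params.height - 1, 1)
    profile = np.interp(depth, fracs, vals)
    return np.repeat(profile[:, None], params.width, axis=1)


def _place(rng, n, row_range, col_range, keep_away, min_sep, what,
           allowed_rows=None):
    """Rejection-sample n points, each >= min_sep from previous + keep_away.

    ``allowed_rows`` optionally restricts the row coordinate to a discrete
    set (used to keep well-separated foci off bright-band flanks).
    """
    pts = []
    existing = list(keep_away)
    for _ in range(n):
        for _attempt in range(10000):
            if allowed_rows is not None:
                r = float(rng.choice(allowed_rows)) + rng.uniform(-0.5, 0.5)
            else:
                r = rng.uniform(*row_range)
            c = rng.uniform(*col_range)
            if all((r - er) ** 2 + (c - ec) ** 2 >= min_sep ** 2
                   for er, ec in existing):
                pts.append((r, c))
                existing.append((r, c))
                break
        else:
            raise ValueError(
                f"infeasible packing: could not place {n} {what} with "
                f"minimum separation {min_sep} px in the ROI band")
    return pts


def _flat_rows(profile: np.ndarray, row_lo: float, row_hi: float,
               window: int = 8, margin: float = 5.0) -> np.ndarray:
    """Rows in [row_lo, row_hi] whose background is locally flat.

    A row qualifies when no background value within ``window`` rows exceeds
    its own by more than ``margin``: a focus planted there sits on a plateau
    and cannot be flooded into a brighter neighboring band, so it is a
    well-defined isolated object.  On band flanks even a human grader could
    not call the focus boundary, which is why the counting band excludes the
    RNFL in the first place.
    """
    rows = np.arange(int(math.ceil(row_lo)), int(math.floor(row_hi)) + 1)
    keep = []
    for r in rows:
        lo, hi = max(0, r - window), min(len(profile), r + window + 1)
        if profile[lo:hi].max() <= profile[r] + margin:
            keep.append(r)
    return np.asarray(keep)


def _add_gaussian(img, r0, c0, amplitude, sigma):
    rad = int(math.ceil(4 * sigma))
    h, w = img.shape
    r_lo, r_hi = max(0, int(r0) - rad), min(h, int(r0) + rad + 1)
    c_lo, c_hi = max(0, int(c0) - rad), min(w, int(c0) + rad + 1)
    rr = np.arange(r_lo, r_hi)[:, None]
    cc = np.arange(c_lo, c_hi)[None, :]
    img[r_lo:r_hi, c_lo:c_hi] += amplitude * np.exp(
        -((rr - r0) ** 2 + (cc - c0) ** 2) / (2 * sigma ** 2))


def generate_bscan(params: SceneParams | None = None
                   ) -> tuple[BScanImage, SyntheticTruth]:
    """Render one synthetic B-scan and its ground truth."""
    if params is None:
        params = SceneParams()
    rng = np.random.default_rng(params.seed)
    h, w = params.height, params.width
    img = _background(params)

    roi_top = params.roi_top_frac * (h - 1)
    roi_bottom = params.roi_bottom_frac * (h - 1)
    margin = 6.0
    roi = ROIPolygon(np.array([
        [roi_top, 2.0], [roi_top, w - 3.0],
        [roi_bottom, w - 3.0], [roi_bottom, 2.0]]))

    min_sep = params.min_separation_px if params.well_separated else 0.0
    sig_hi = params.focus_sigma_px_range[1]
    if params.well_separated and min_sep < 4 * sig_hi:
        min_sep = 4 * sig_hi

    # Exudates first (they are large): bright saturated disks in the band.
    ex_pts = _place(rng, params.n_exudates,
                    (roi_top + 8, roi_bottom - 8), (8, w - 9),
                    [], max(min_sep, 10.0), "exudates")
    exudates = []
    for r0, c0 in ex_pts:
        radius = rng.uniform(2.5, 4.0)       # 50-80 um at 10 um/px
        value = rng.uniform(245.0, 255.0)
        exudates.append((r0, c0, radius, value))

    # Foci inside the counting band, away from borders and exudates; in
    # well-separated mode they are additionally restricted to locally flat
    # background so each planted focus is an unambiguous isolated object.
    allowed = None
    if params.well_separated:
        allowed = _flat_rows(img[:, 0], roi_top + margin,
                             roi_bottom - margin)
        if len(allowed) == 0:
            raise ValueError(
                "infeasible packing: no locally flat background rows in "
                "the ROI band for well-separated foci")
    focus_pts = _place(rng, params.n_foci,
                       (roi_top + margin, roi_bottom - margin),
                       (margin, w - 1 - margin),
                       [(r, c) for r, c, *_ in exudates], min_sep, "foci",
                       allowed_rows=allowed)
    foci = []
    for r0, c0 in focus_pts:
        amp = rng.uniform(*params.focus_amplitude_range)
        sig = rng.uniform(*params.focus_sigma_px_range)
        foci.append((r0, c0, amp, sig))
        _add_gaussian(img, r0, c0, amp, sig)

    # Vessels: bright ellipses at the inner retina with back-shadowing.
    vessels = []
    vessel_row = roi_top - 6.0
    for _ in range(params.n_vessels):
        c0 = rng.uniform(15, w - 16)
        radius = rng.uniform(3.0, 5.0)
        shadow = rng.uniform(0.45, 0.6)
        vessels.append((vessel_row, c0, radius, shadow))
    for r0, c0, radius, shadow in vessels:
        rad_ax = radius * params.lateral_scale_um / params.axial_scale_um
        rr = np.arange(h)[:, None]
        cc = np.arange(w)[None, :]
        inside = (((rr - r0) / rad_ax) ** 2
                  + ((cc - c0) / radius) ** 2) <= 1.0
        img[inside] = np.maximum(img[inside], 190.0)
        col_lo = int(max(0, math.floor(c0 - radius)))
        col_hi = int(min(w, math.ceil(c0 + radius) + 1))
        row_lo = int(min(h, math.ceil(r0 + rad_ax)))
        img[row_lo:, col_lo:col_hi] *= shadow

    # Exudates rendered last so nothing dilutes their core.  A mild radial
    # falloff (bright core, ~20% dimmer rim) keeps the maximum at the core.
    for r0, c0, radius, value in exudates:
        rr = np.arange(h)[:, None]
        cc = np.arange(w)[None, :]
        d2 = ((rr - r0) ** 2 + (cc - c0) ** 2) / radius ** 2
        inside = d2 <= 1.0
        img[inside] = (value * (1.0 - 0.2 * d2))[inside]

    if params.speckle:
        img *= rng.gamma(params.speckle_shape,
                         1.0 / params.speckle_shape, size=img.shape)

    pixels = round_half_up(np.clip(img, 0, 255)).astype(np.uint8)
    fovea = params.fovea_col if params.fovea_col is not None else w // 2
    scan = BScanImage(pixels, params.lateral_scale_um, params.axial_scale_um,
                      fovea, source_id=f"synthetic-{params.seed}")
    truth = SyntheticTruth(
        foci=tuple(foci), vessels=tuple(vessels), exudates=tuple(exudates),
        roi=roi, seed=params.seed)
    return scan, truth


def generate_paired_counts(n_pairs: int, true_bias: float = -0.2,
                           sd_diff: float = 8.3, manual_mean: float = 58.9,
                           manual_sd: float = 36.9,
                           seed: int = 0) -> PairedCounts:
    """Draw manual/semi-automatic count pairs with a prescribed difference
    structure.

    Manual counts come from a truncated-at-zero normal, rounded to integers;
    the semi-automatic count of each pair is ``manual - d`` with
    ``d ~ N(true_bias, sd_diff)``, rounded and floored at 0.  The defaults
    describe the count scale of a typical clinical validation set (mean
    about 59 foci, SD about 37, sub-focus bias, difference SD near 8.3 so
    that the 1.96·SD limits are about ±16 foci).
    """
    if n_pairs < 2:
        raise ValueError("need at least 2 pairs")
    if sd_diff < 0 or manual_sd < 0:
        raise ValueError("standard deviations must be >= 0")
    rng = np.random.default_rng(seed)
    manual = np.empty(n_pairs)
    filled = 0
    while filled < n_pairs:   # redraw negatives: truncation at zero
        draw = rng.normal(manual_mean, manual_sd, size=n_pairs - filled)
        keep = draw[draw >= 0]
        manual[filled:filled + len(keep)] = keep
        filled += len(keep)
    manual = round_half_up(manual)
    d = rng.normal(true_bias, sd_diff, size=n_pairs)
    semi = np.maximum(round_half_up(manual - d), 0.0)
    return PairedCounts(manual=manual, semi=semi)


def save_scene(outdir, scan: BScanImage, truth: SyntheticTruth,
               stem: str = "scene"):
    """Write a scene as TIFF image + truth CSV + ROI JSON + metadata JSON."""
    import pathlib

    import pandas as pd
    import tifffile

    outdir = pathlib.Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(outdir / f"{stem}.tif", scan.pixels)
    pd.DataFrame(list(truth.foci),
                 columns=["row", "col", "amplitude", "sigma"]).to_csv(
        outdir / f"{stem}_foci.csv", index=False)
    with open(outdir / f"{stem}_roi.json", "w") as fh:
        json.dump({"vertices": truth.roi.vertices.tolist()}, fh)
    with open(outdir / f"{stem}.json", "w") as fh:
        json.dump({"lateral_um_per_px": scan.lateral_scale_um,
                   "axial_um_per_px": scan.axial_scale_um,
                   "fovea_col": scan.fovea_col}, fh)
    return outdir / f"{stem}.tif"
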