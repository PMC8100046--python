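"""End-to-end semi-automatic HRF counting pipeline.

Orchestrates the full procedure on one B-scan: fovea-centered crop,
a-trous wavelet denoising, CLAHE applied through the denoised-image mask,
per-method spot detection (optional Gaussian pre-filter, noise-tolerance
maxima, box intensity measurement), restriction to the user-drawn retinal
region of interest (RNFL/GCL boundary down to the ELM), and the brightness
correction that excludes any spot whose measured intensity exceeds twice
the image mean — large hard exudates are far brighter than the
medium-reflectivity foci the count is after.

Four built-in method profiles share the preprocessing and differ only in
the spot-detection settings:

====== =========== ======== ===============
method pre-filter  box size noise tolerance
====== =========== ======== ===============
1      Gaussian 1.5    2         15
2      Gaussian 1.5    2         20
3      none            2         20
4      none            2         15
====== =========== ======== ===============
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .clahe_enhance import ClaheParams, apply_with_mask, clahe
from .oct_image import BScanImage, crop_central, image_mean
from .spot_counter import (SpotCounterParams, SpotSet, find_maxima,
                           gaussian_prefilter, measure_spots)
from .wavelet_denoise import DenoiseParams, atrous_decompose, denoise

__all__ = ["MethodProfile", "ROIPolygon", "CountRecord", "PipelineError",
           "builtin_profile", "filter_spots_in_roi", "exclude_bright",
           "run_method", "point_in_polygon"]


class PipelineError(RuntimeError):
    """Stage failure with the stage name attached."""


@dataclass(frozen=True)
class MethodProfile:
    """One parameter set: denoise + CLAHE settings and spot-counter settings.

    ``denoise`` or ``clahe`` may be ``None`` to switch the stage off in a
    custom profile; the four built-ins share both stages and differ only in
    ``spot``.
    """

    id: object                              # 1..4 or "custom"/free text
    denoise: DenoiseParams | None
    clahe: ClaheParams | None
    spot: SpotCounterParams


_SPOT_SETTINGS = {
    1: dict(prefilter="gaussian", gaussian_sigma=1.5, box_size=2,
            noise_tolerance=15.0),
    2: dict(prefilter="gaussian", gaussian_sigma=1.5, box_size=2,
            noise_tolerance=20.0),
    3: dict(prefilter="none", box_size=2, noise_tolerance=20.0),
    4: dict(prefilter="none", box_size=2, noise_tolerance=15.0),
}


def builtin_profile(method_id: int) -> MethodProfile:
    """Return built-in method profile 1-4 (a fresh, immutable instance)."""
    if method_id not in _SPOT_SETTINGS:
        raise ValueError(f"method_id must be 1..4, got {method_id!r}")
    return MethodProfile(
        id=method_id,
        denoise=DenoiseParams(),
        clahe=ClaheParams(),
        spot=SpotCounterParams(**_SPOT_SETTINGS[method_id]),
    )


@dataclass(frozen=True)
class ROIPolygon:
    """Closed polygon (>= 3 vertices, (row, col) coordinates) delimiting the
    retinal band in which foci are counted."""

    vertices: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.vertices, dtype=np.float64)
        if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 3:
            raise ValueError("ROI polygon needs >= 3 (row, col) vertices")
        v = v.copy()
        v.setflags(write=False)
        object.__setattr__(self, "vertices", v)


def _on_segment(pr, pc, ar, ac, br, bc, eps=1e-9) -> bool:
    cross = (br - ar) * (pc - ac) - (bc - ac) * (pr - ar)
    if abs(cross) > eps * max(1.0, abs(br - ar), abs(bc - ac)):
        return False
    dot = (pr - ar) * (br - ar) + (pc - ac) * (bc - ac)
    sq = (br - ar) ** 2 + (bc - ac) ** 2
    return -eps <= dot <= sq + eps


def point_in_polygon(point, vertices) -> bool:
    """Even-odd (ray casting) point-in-polygon; boundary points are inside."""
    pr, pc = float(point[0]), float(point[1])
    verts = np.asarray(vertices, dtype=np.float64)
    n = len(verts)
    for i in range(n):
        ar, ac = verts[i]
        br, bc = verts[(i + 1) % n]
        if _on_segment(pr, pc, ar, ac, br, bc):
            return True
    inside = False
    for i in range(n):
        ar, ac = verts[i]
        br, bc = verts[(i + 1) % n]
        # Horizontal ray in +col direction; half-open rule on row spans.
        if (ar > pr) != (br > pr):
            c_cross = ac + (pr - ar) * (bc - ac) / (br - ar)
            if c_cross > pc:
                inside = not inside
    return inside


def filter_spots_in_roi(spots: SpotSet, roi: ROIPolygon) -> SpotSet:
    """Flag spots outside the ROI polygon with ``excluded_by = 'roi'``."""
    verts = roi.vertices
    for s in spots:
        if s.excluded_by == "none" and not point_in_polygon((s.row, s.col),
                                                            verts):
            s.excluded_by = "roi"
    return spots


def exclude_bright(spots: SpotSet, image_mean_value: float) -> SpotSet:
    """Flag spots brighter than twice the image mean.

    The inequality is strict: intensity exactly equal to 2x the mean is
    retained.
    """
    if image_mean_value < 0:
        raise ValueError("image mean must be >= 0")
    threshold = 2.0 * image_mean_value
    for s in spots:
        if s.excluded_by == "none" and s.intensity > threshold:
            s.excluded_by = "brightness"
    return spots


@dataclass(frozen=True)
class CountRecord:
    """Result of one method on one scan.

    ``n`` counts the spots surviving the ROI and brightness filters;
    ``spot_mean`` is NaN when ``n`` = 0 (never 0, which would corrupt
    downstream agreement statistics).  ``image_mean`` is taken on the
    cropped, post-enhancement image — the same image on which spot
    intensities are measured; ``raw_image_mean`` (pre-enhancement) is kept
    for transparency.
    """

    source_id: str
    method_id: object
    n: int
    spot_mean: float
    image_mean: float
    raw_image_mean: float
    intensities: tuple
    spots: SpotSet = field(repr=False, default=None)

    def __post_init__(self):
        if self.n != len(self.intensities):
            raise ValueError("n must equal len(intensities)")


def _feret_diameter_um(region, lateral_um, axial_um) -> float:
    pts = np.asarray(region, dtype=np.float64)
    pts = pts * np.array([axial_um, lateral_um])
    if len(pts) == 1:
        return 0.0
    d2 = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1)
    return float(np.sqrt(d2.max()))


def _spot_region(image, r, c, tolerance):
    """8-connected component around (r, c) above image[r, c] - tolerance."""
    from collections import deque
    a = np.asarray(image, dtype=np.float64)
    h, w = a.shape
    v = a[r, c]
    seen = {(r, c)}
    queue = deque(seen)
    while queue:
        rr, cc = queue.popleft()
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                q = (rr + dr, cc + dc)
                if (q not in seen and 0 <= q[0] < h and 0 <= q[1] < w
                        and a[q] > v - tolerance):
                    seen.add(q)
                    queue.append(q)
    return list(seen)


def run_method(scan: BScanImage, roi: ROIPolygon, profile: MethodProfile,
               *, crop: bool = False, half_width_um: float = 1500.0,
               max_diameter_um: float | None = None) -> CountRecord:
    """Run the full counting pipeline for one scan and one method profile.

    ``crop=True`` applies the fovea-centered crop first (ROI coordinates are
    then interpreted in the cropped frame).  ``max_diameter_um`` optionally
    enables an explicit size gate (max Feret diameter of the connected
    region above peak - tolerance); it is off in the built-in profiles,
    whose detection parameters implicitly enforce the sub-30-µm criterion.
    """
    def _stage(name, fn, *args, **kw):
        try:
            return fn(*args, **kw)
        except Exception as exc:
            raise PipelineError(f"stage '{name}': {exc}") from exc

    if crop:
        scan = _stage("crop", crop_central, scan, half_width_um)
    img8 = scan.pixels
    raw_mean = _stage("image_mean", image_mean, img8)

    mask = None
    if profile.denoise is not None:
        decomp = _stage("wavelet", atrous_decompose, img8)
        mask = _stage("denoise", denoise, decomp, profile.denoise)

    if profile.clahe is not None:
        enhanced = _stage("clahe", clahe, img8, profile.clahe)
        if mask is not None:
            processed = _stage("mask_blend", apply_with_mask, img8, enhanced,
                               mask)
        else:
            processed = enhanced
    else:
        processed = img8

    proc_mean = _stage("image_mean", image_mean, processed)

    if profile.spot.prefilter == "gaussian":
        detection_img = _stage("prefilter", gaussian_prefilter, processed,
                               profile.spot.gaussian_sigma)
    else:
        detection_img = np.asarray(processed, dtype=np.float64)

    maxima = _stage("find_maxima", find_maxima, detection_img,
                    profile.spot.noise_tolerance)
    spots = _stage("measure", measure_spots, processed, maxima,
                   profile.spot.box_size)
    spots = _stage("roi_filter", filter_spots_in_roi, spots, roi)
    spots = _stage("brightness_filter", exclude_bright, spots, proc_mean)

    if max_diameter_um is not None:
        for s in spots:
            if s.excluded_by != "none":
                continue
            region = _spot_region(detection_img, s.row, s.col,
                                  profile.spot.noise_tolerance)
            if _feret_diameter_um(region, scan.lateral_scale_um,
                                  scan.axial_scale_um) > max_diameter_um:
                s.excluded_by = "diameter"

    retained = spots.retained
    intensities = tuple(s.intensity for s in retained)
    spot_mean = float(np.mean(intensities)) if intensities else math.nan
    return CountRecord(
        source_id=scan.source_id,
        method_id=profile.id,
        n=len(intensities),
        spot_mean=spot_mean,
        image_mean=proc_mean,
        raw_image_mean=raw_mean,
        intensities=intensities,
        spots=spots,
    )
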