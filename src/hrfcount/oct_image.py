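"""B-scan raster I/O, bit-depth normalization and fovea-centered cropping.

An OCT B-scan is handled as an 8-bit grayscale raster with explicit physical
scale (µm per pixel, lateral and axial) and the lateral pixel index of the
foveal center.  Rows are axial depth (row 0 = inner / vitreous side), columns
are lateral position.  All downstream processing operates on the central
3 mm of the retina, obtained by cropping at a fixed distance (default
1,500 µm) on either side of the fovea.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import imageio.v3 as iio
import numpy as np

from ._util import round_half_up, round_half_up_int

__all__ = ["BScanImage", "load_bscan", "to_8bit", "crop_central", "image_mean"]

# Rec. 601 luma weights, the convention ImageJ uses for RGB -> grayscale.
_LUMA = np.array([0.299, 0.587, 0.114])


@dataclass(frozen=True)
class BScanImage:
    """A single 8-bit B-scan raster plus its physical metadata.

    Attributes
    ----------
    pixels : ndarray of uint8, shape (rows, cols)
        Intensities in [0, 255]; rows = axial depth, cols = lateral position.
    lateral_scale_um : float
        Micrometers per pixel laterally (> 0).
    axial_scale_um : float
        Micrometers per pixel axially (> 0).
    fovea_col : int
        Lateral pixel index of the foveal center (0-based).
    source_id : str
        Free-text identifier carried through to output tables.
    """

    pixels: np.ndarray
    lateral_scale_um: float
    axial_scale_um: float
    fovea_col: int
    source_id: str = ""

    def __post_init__(self):
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.size == 0:
            raise ValueError("pixels must be a non-empty 2-D array")
        if px.dtype != np.uint8:
            if not (np.issubdtype(px.dtype, np.integer)
                    and px.min() >= 0 and px.max() <= 255):
                raise ValueError("pixels must be integers in [0, 255]")
            px = px.astype(np.uint8)
        object.__setattr__(self, "pixels", px)
        if not (self.lateral_scale_um > 0 and self.axial_scale_um > 0):
            raise ValueError("pixel scales must be strictly positive")
        if not (0 <= self.fovea_col < px.shape[1]):
            raise ValueError(
                f"fovea_col {self.fovea_col} outside image width {px.shape[1]}")

    @property
    def shape(self) -> tuple:
        return self.pixels.shape


def to_8bit(raw, source_depth) -> np.ndarray:
    """Linearly map a raster onto [0, 255] using the full source dtype range.

    Parameters
    ----------
    raw : 2-D array
    source_depth : 8, 16, or a ``(lo, hi)`` tuple
        Declared input range.  8-bit input is passed through unchanged;
        16-bit input is mapped by ``v * 255 / 65535``; floating-point input
        must declare its range explicitly as ``(lo, hi)``.

    The full dtype range is used, never a per-image min-max stretch: per-image
    stretching would change the meaning of the downstream 2x-image-mean
    brightness exclusion from image to image.  Rounding is half-up.
    """
    raw = np.asarray(raw)
    if source_depth == 8:
        out = np.asarray(raw)
        if out.min() < 0 or out.max() > 255:
            raise ValueError("8-bit input has values outside [0, 255]")
        return out.astype(np.uint8)
    if source_depth == 16:
        scaled = round_half_up(raw.astype(np.float64) * (255.0 / 65535.0))
        return scaled.astype(np.uint8)
    if isinstance(source_depth, (tuple, list)) and len(source_depth) == 2:
        lo, hi = map(float, source_depth)
        if not hi > lo:
            raise ValueError("declared range must satisfy hi > lo")
        scaled = (raw.astype(np.float64) - lo) * (255.0 / (hi - lo))
        return round_half_up(np.clip(scaled, 0, 255)).astype(np.uint8)
    raise ValueError(
        "source_depth must be 8, 16, or an explicit (lo, hi) range for "
        "floating-point input")


def load_bscan(path, lateral_scale_um: float, axial_scale_um: float,
               fovea_col: int, source_id: str | None = None) -> BScanImage:
    """Read a grayscale (or RGB) TIFF/PNG B-scan and normalize it to 8 bit.

    RGB inputs are collapsed to Rec. 601 luminance before bit-depth
    conversion.  Multi-frame stacks are rejected: the tool operates on single
    B-scans.
    """
    try:
        raw = iio.imread(path)
    except FileNotFoundError:
        raise
    except Exception as exc:  # decoder errors vary by backend
        raise IOError(f"could not read image {path!r}: {exc}") from exc
    if raw.ndim == 3 and raw.shape[-1] in (3, 4):
        rgb = raw[..., :3].astype(np.float64)
        raw = round_half_up(rgb @ _LUMA).astype(raw.dtype)
    if raw.ndim != 2:
        n_frames = raw.shape[0] if raw.ndim > 2 else 0
        raise ValueError(
            f"{path!r} is a multi-frame stack ({n_frames} frames); "
            "this tool operates on single B-scans")
    if raw.dtype == np.uint8:
        px = to_8bit(raw, 8)
    elif raw.dtype == np.uint16:
        px = to_8bit(raw, 16)
    else:
        raise ValueError(
            f"unsupported pixel type {raw.dtype}; supply 8- or 16-bit "
            "grayscale input")
    return BScanImage(px, lateral_scale_um, axial_scale_um, fovea_col,
                      source_id if source_id is not None else str(path))


def crop_central(scan: BScanImage, half_width_um: float = 1500.0) -> BScanImage:
    """Crop the scan to ± ``half_width_um`` around the fovea column.

    The crop keeps columns ``[fovea_col - w, fovea_col + w)`` with
    ``w = round(half_width_um / lateral_scale_um)`` (half-open, 0-based);
    rows are unchanged and ``fovea_col`` is re-expressed in the new frame.
    """
    if half_width_um <= 0:
        raise ValueError("half_width_um must be > 0 (zero-width crop rejected)")
    w = round_half_up_int(half_width_um / scan.lateral_scale_um)
    if w < 1:
        raise ValueError("half_width_um smaller than one pixel")
    lo = scan.fovea_col - w
    hi = scan.fovea_col + w
    width = scan.pixels.shape[1]
    if lo < 0 or hi > width:
        missing_px = max(0, -lo) + max(0, hi - width)
        raise ValueError(
            f"crop window [{lo}, {hi}) exceeds image width {width}: missing "
            f"margin of {missing_px * scan.lateral_scale_um:.1f} um")
    return dataclasses.replace(scan, pixels=scan.pixels[:, lo:hi],
                               fovea_col=w)


def image_mean(image) -> float:
    """Arithmetic mean intensity of a non-empty image."""
    image = np.asarray(image)
    if image.size == 0:
        raise ValueError("cannot take the mean of an empty image")
    return float(image.mean(dtype=np.float64))
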