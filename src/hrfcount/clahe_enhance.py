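"""Contrast-limited adaptive histogram equalization with masked application.

Classical tiled CLAHE: the image is partitioned into tiles of side
``blocksize`` (edge tiles may be smaller), each tile's histogram is clipped
at a slope limit and the clipped excess redistributed uniformly in a single
pass, the tile's cumulative mapping is scaled to [0, 255], and every pixel
is remapped by bilinear interpolation of the four surrounding tile mappings.

``apply_with_mask`` then blends the enhanced image into the original with a
per-pixel weight in [0, 255] — here the wavelet-denoised detail image, so
that contrast enhancement is concentrated where the image actually carries
spot-scale structure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._util import round_half_up

__all__ = ["ClaheParams", "clahe", "apply_with_mask"]


@dataclass(frozen=True)
class ClaheParams:
    """CLAHE settings: tile side, histogram bins, contrast slope limit.

    ``blocksize`` is normalized to the next odd value >= 3; ``bins`` must be
    in [2, 256]; ``max_slope`` >= 1 (1 disables enhancement on
    uniform-histogram tiles).
    """

    blocksize: int = 127
    bins: int = 256
    max_slope: float = 3.00

    def __post_init__(self):
        bs = int(self.blocksize)
        if bs < 3:
            raise ValueError("blocksize must be >= 3")
        if bs % 2 == 0:
            bs += 1
        object.__setattr__(self, "blocksize", bs)
        if not 2 <= int(self.bins) <= 256:
            raise ValueError("bins must be in [2, 256]")
        object.__setattr__(self, "bins", int(self.bins))
        if not self.max_slope >= 1:
            raise ValueError("max_slope must be >= 1")


def _tile_edges(n: int, block: int) -> np.ndarray:
    edges = list(range(0, n, block)) + [n]
    return np.asarray(edges)


def _tile_mapping(tile: np.ndarray, bins: int, max_slope: float) -> np.ndarray:
    """Per-bin output values (float, in [0, 255]) for one tile."""
    if tile.min() == tile.max():
        # Degenerate histogram: map each bin to its own center so that the
        # single occupied bin maps (for bins = 256, exactly) to itself.
        return (np.arange(bins) + 0.5) * (256.0 / bins) - 0.5
    bin_idx = (tile.astype(np.int64) * bins) // 256
    hist = np.bincount(bin_idx.ravel(), minlength=bins).astype(np.float64)
    npix = tile.size
    clip = max_slope * npix / bins
    excess = np.maximum(hist - clip, 0.0).sum()
    hist = np.minimum(hist, clip) + excess / bins   # single uniform pass
    cdf = np.cumsum(hist)
    return 255.0 * cdf / cdf[-1]


def clahe(image, params: ClaheParams | None = None) -> np.ndarray:
    """Apply tiled CLAHE to an 8-bit image; returns uint8."""
    if params is None:
        params = ClaheParams()
    img = np.asarray(image)
    if img.min() < 0 or img.max() > 255:
        raise ValueError("image values must lie in [0, 255]")
    img = img.astype(np.uint8)
    h, w = img.shape
    bs, bins = params.blocksize, params.bins
    r_edges = _tile_edges(h, bs)
    c_edges = _tile_edges(w, bs)
    n_tr, n_tc = len(r_edges) - 1, len(c_edges) - 1

    maps = np.empty((n_tr, n_tc, bins))
    r_centers = np.empty(n_tr)
    c_centers = np.empty(n_tc)
    for i in range(n_tr):
        r0, r1 = r_edges[i], r_edges[i + 1]
        r_centers[i] = (r0 + r1 - 1) / 2.0
        for j in range(n_tc):
            c0, c1 = c_edges[j], c_edges[j + 1]
            c_centers[j] = (c0 + c1 - 1) / 2.0
            maps[i, j] = _tile_mapping(img[r0:r1, c0:c1], bins,
                                       params.max_slope)

    bin_idx = (img.astype(np.int64) * bins) // 256

    def _bracket(coords: np.ndarray, centers: np.ndarray):
        """Indices of the two bracketing tile centers and the upper weight."""
        hi = np.searchsorted(centers, coords)
        lo = np.clip(hi - 1, 0, len(centers) - 1)
        hi = np.clip(hi, 0, len(centers) - 1)
        span = centers[hi] - centers[lo]
        with np.errstate(invalid="ignore", divide="ignore"):
            t = np.where(span > 0, (coords - centers[lo]) / np.where(
                span > 0, span, 1.0), 0.0)
        return lo, hi, t

    ri0, ri1, tr = _bracket(np.arange(h, dtype=float), r_centers)
    ci0, ci1, tc = _bracket(np.arange(w, dtype=float), c_centers)

    def _gather(ri, ci):
        return maps[ri[:, None], ci[None, :], bin_idx]

    out = ((1 - tr)[:, None] * (1 - tc)[None, :] * _gather(ri0, ci0)
           + (1 - tr)[:, None] * tc[None, :] * _gather(ri0, ci1)
           + tr[:, None] * (1 - tc)[None, :] * _gather(ri1, ci0)
           + tr[:, None] * tc[None, :] * _gather(ri1, ci1))
    return round_half_up(np.clip(out, 0, 255)).astype(np.uint8)


def apply_with_mask(original, enhanced, mask,
                    binarize_threshold: float | None = None) -> np.ndarray:
    """Blend ``enhanced`` into ``original`` with per-pixel weight ``mask``/255.

    Mask 255 gives the enhanced pixel exactly, mask 0 leaves the original
    untouched.  With ``binarize_threshold`` set, the mask is first binarized
    (>= threshold -> 255, else 0) for all-or-nothing application.
    """
    original = np.asarray(original)
    enhanced = np.asarray(enhanced)
    mask = np.asarray(mask)
    if not (original.shape == enhanced.shape == mask.shape):
        raise ValueError(
            f"shape mismatch: original {original.shape}, enhanced "
            f"{enhanced.shape}, mask {mask.shape}")
    if mask.min() < 0 or mask.max() > 255:
        raise ValueError("mask values must lie in [0, 255]")
    if binarize_threshold is not None:
        mask = np.where(mask >= binarize_threshold, 255, 0)
    w = mask.astype(np.float64) / 255.0
    out = original.astype(np.float64) + w * (
        enhanced.astype(np.float64) - original.astype(np.float64))
    return round_half_up(out).astype(np.uint8)
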