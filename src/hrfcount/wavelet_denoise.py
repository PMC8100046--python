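"""B3-spline a-trous stationary wavelet decomposition and denoising.

The a-trous ("with holes") transform decomposes an image into a sequence of
same-size detail planes w1..wJ plus a smooth residual A_J such that

    input = A_J + w1 + ... + wJ        (exact, additive)

where A_0 is the input, A_i is A_{i-1} smoothed with the separable B3-spline
kernel (1, 4, 6, 4, 1)/16 dilated with 2^(i-1) - 1 zeros between taps
(mirror boundary), and w_i = A_{i-1} - A_i.  Because the transform is
undecimated it is shift-equivariant, which makes the detail planes usable
for spot detection.

Denoising hard-thresholds each detail plane at k_i * sigma_i and sums the
surviving planes; planes with k_i = 0 are dropped entirely, so with the
default coefficients k = (4, 3, 3, 0, 0) the two coarsest planes and the
residual background are removed and the output is a spot-enhanced detail
image, suitable as a per-pixel mask for local contrast enhancement.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy import ndimage

from ._util import round_half_up

__all__ = ["DenoiseParams", "WaveletDecomposition", "atrous_decompose",
           "plane_noise_sigma", "denoise"]

_B3 = np.array([1.0, 4.0, 6.0, 4.0, 1.0]) / 16.0


@dataclass(frozen=True)
class DenoiseParams:
    """Thresholding parameters for the a-trous denoiser.

    ``k`` are the per-plane threshold multipliers (k_i = 0 drops plane i),
    ``base_sigma`` the plugin-style noise standard-deviation setting, and
    ``robust_noise`` selects robust (MAD-based) per-plane noise estimation
    instead of propagating ``base_sigma`` through the filter-bank norms.
    """

    k: tuple = (4.0, 3.0, 3.0, 0.0, 0.0)
    base_sigma: float = 1.50
    robust_noise: bool = True

    def __post_init__(self):
        object.__setattr__(self, "k", tuple(float(v) for v in self.k))
        if any(v < 0 for v in self.k):
            raise ValueError("k values must be non-negative")
        if not self.base_sigma > 0:
            raise ValueError("base_sigma must be > 0")


@dataclass(frozen=True)
class WaveletDecomposition:
    """Detail planes w1..wJ and residual A_J of an a-trous decomposition."""

    detail_planes: tuple          # J signed float planes, input shape
    residual: np.ndarray          # A_J
    base_sigma: float = 1.50

    @property
    def levels(self) -> int:
        return len(self.detail_planes)

    def reconstruct(self) -> np.ndarray:
        """residual + sum of detail planes (equals the input exactly)."""
        return self.residual + np.sum(self.detail_planes, axis=0)


def _holey_kernel(level: int) -> np.ndarray:
    """The B3 kernel with 2^(level-1) - 1 zeros inserted between taps."""
    step = 2 ** (level - 1)
    kern = np.zeros(4 * step + 1)
    kern[::step] = _B3
    return kern


def _smooth(plane: np.ndarray, level: int) -> np.ndarray:
    kern = _holey_kernel(level)
    out = ndimage.correlate1d(plane, kern, axis=0, mode="mirror")
    return ndimage.correlate1d(out, kern, axis=1, mode="mirror")


def atrous_decompose(image, levels: int = 5) -> WaveletDecomposition:
    """Decompose ``image`` into ``levels`` detail planes plus a residual."""
    a = np.asarray(image, dtype=np.float64)
    if a.ndim != 2 or a.size == 0:
        raise ValueError("image must be a non-empty 2-D array")
    if levels < 1:
        raise ValueError("levels must be >= 1")
    min_size = 4 * 2 ** (levels - 1)
    if min(a.shape) < min_size:
        raise ValueError(
            f"image {a.shape} too small for {levels} levels; minimum "
            f"dimension is {min_size} pixels")
    planes = []
    current = a
    for i in range(1, levels + 1):
        smoothed = _smooth(current, i)
        planes.append(current - smoothed)
        current = smoothed
    return WaveletDecomposition(tuple(planes), current)


@lru_cache(maxsize=8)
def _detail_filter_norms(levels: int) -> tuple:
    """L2 norms of the equivalent per-level detail filters.

    Obtained by decomposing a discrete delta on a grid large enough that the
    mirrored boundary cannot reach the impulse response support.
    """
    half_support = 2 * (2 ** levels - 1)
    size = 2 * half_support + 5
    delta = np.zeros((size, size))
    delta[size // 2, size // 2] = 1.0
    dec = atrous_decompose(delta, levels)
    return tuple(float(np.sqrt((w ** 2).sum())) for w in dec.detail_planes)


def plane_noise_sigma(decomp: WaveletDecomposition, level: int,
                      params: DenoiseParams) -> float:
    """Noise scale for one detail plane.

    With ``robust_noise`` the per-plane noise is estimated from the plane
    itself as MAD/0.6745 and scaled by ``base_sigma``; otherwise
    ``base_sigma`` is propagated through the filter bank via the L2 norm of
    the level's equivalent detail filter.
    """
    if not 1 <= level <= decomp.levels:
        raise ValueError(f"level must be in [1, {decomp.levels}]")
    w = decomp.detail_planes[level - 1]
    if params.robust_noise:
        mad = float(np.median(np.abs(w - np.median(w))))
        return params.base_sigma * mad / 0.6745
    return params.base_sigma * _detail_filter_norms(decomp.levels)[level - 1]


def denoise(decomp: WaveletDecomposition, params: DenoiseParams) -> np.ndarray:
    """Hard-threshold the detail planes and sum the survivors.

    For each level with k > 0 a coefficient survives when
    ``|w| >= k * sigma_level``; levels with k = 0 are dropped.  The smooth
    residual is never added back: the output is a detail/spot image.
    Negative sums are clipped to 0, values capped at 255, rounded half-up,
    returned as uint8.
    """
    if len(params.k) < decomp.levels:
        raise ValueError(
            f"need {decomp.levels} k values, got {len(params.k)}")
    out = np.zeros_like(decomp.residual)
    for i, w in enumerate(decomp.detail_planes, start=1):
        k = params.k[i - 1]
        if k == 0:
            continue
        sigma = plane_noise_sigma(decomp, i, params)
        out += np.where(np.abs(w) >= k * sigma, w, 0.0)
    out = np.minimum(np.maximum(out, 0.0), 255.0)
    return round_half_up(out).astype(np.uint8)
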