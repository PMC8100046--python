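"""Noise-tolerance local-maxima spot detection and box intensity measurement.

Detection follows the prominence ("noise tolerance") convention of the
classical ImageJ maximum finder: candidate local maxima are processed in
descending intensity; from each candidate a flood fill expands over
8-connected pixels whose value exceeds ``peak - tolerance`` (equal-valued
plateau pixels are always included); the candidate is rejected if the flood
reaches a pixel brighter than the peak or a pixel already claimed by a
higher accepted maximum — it is then "within tolerance" of that maximum.
Equal-valued plateaus yield a single maximum at the plateau centroid.  An
image with no structure at all (globally constant) yields no maxima: the
whole-image plateau is background, not a spot.

Measurement is separate from detection: each accepted maximum is assigned
the mean intensity of the (2*box_size+1)^2 box around it, clipped at the
image borders, evaluated on the processed-but-unprefiltered image.
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from ._util import round_half_up_int

__all__ = ["SpotCounterParams", "Spot", "SpotSet", "gaussian_prefilter",
           "find_maxima", "measure_spots"]

_NEIGHBORS = ((-1, -1), (-1, 0), (-1, 1), (0, -1),
              (0, 1), (1, -1), (1, 0), (1, 1))


@dataclass(frozen=True)
class SpotCounterParams:
    """Spot-detection settings: optional Gaussian pre-filter, measurement
    box half-size, and the noise tolerance (prominence) of maxima."""

    prefilter: str = "gaussian"        # "none" or "gaussian"
    gaussian_sigma: float = 1.5
    box_size: int = 2
    noise_tolerance: float = 15.0

    def __post_init__(self):
        if self.prefilter not in ("none", "gaussian"):
            raise ValueError("prefilter must be 'none' or 'gaussian'")
        if self.prefilter == "gaussian" and not self.gaussian_sigma > 0:
            raise ValueError("gaussian_sigma must be > 0")
        if self.box_size < 0:
            raise ValueError("box_size must be >= 0")
        if self.noise_tolerance < 0:
            raise ValueError("noise_tolerance must be >= 0")


@dataclass
class Spot:
    """One accepted maximum with its box-measured intensity and, after the
    pipeline filters have run, the reason it was excluded (if any)."""

    row: int
    col: int
    intensity: float
    excluded_by: str = "none"          # "none" | "roi" | "brightness" | "diameter"


@dataclass
class SpotSet:
    """Ordered collection of spots from one image and method."""

    spots: list = field(default_factory=list)

    def __len__(self):
        return len(self.spots)

    def __iter__(self):
        return iter(self.spots)

    @property
    def retained(self) -> list:
        return [s for s in self.spots if s.excluded_by == "none"]

    @property
    def n_retained(self) -> int:
        return len(self.retained)


def gaussian_prefilter(image, sigma: float) -> np.ndarray:
    """Separable Gaussian smoothing (kernel truncated at ceil(4*sigma),
    mirror boundary), kept in float for maxima detection."""
    if not sigma > 0:
        raise ValueError("sigma must be > 0")
    return ndimage.gaussian_filter(np.asarray(image, dtype=np.float64),
                                   sigma, mode="mirror",
                                   radius=math.ceil(4 * sigma))


def find_maxima(image, tolerance: float) -> list:
    """Detect prominence maxima; returns [(row, col), ...].

    Output ordering is deterministic: descending peak intensity, ties broken
    by (row, col).
    """
    if tolerance < 0:
        raise ValueError("tolerance must be >= 0")
    a = np.asarray(image, dtype=np.float64)
    if a.ndim != 2 or a.size == 0:
        raise ValueError("image must be a non-empty 2-D array")
    if a.min() == a.max():
        return []
    h, w = a.shape
    # Local-maximum candidates: >= all in-bounds 8-neighbors (plateaus count).
    neigh_max = ndimage.maximum_filter(a, size=3, mode="constant",
                                       cval=-np.inf)
    cand_r, cand_c = np.nonzero(a >= neigh_max)
    vals = a[cand_r, cand_c]
    order = np.lexsort((cand_c, cand_r, -vals))

    claimed = np.zeros((h, w), dtype=bool)
    # Candidates whose flood is already known to fail: a rejected flood
    # dismisses every equal-valued pixel it reached, since a flood started
    # from any of them covers the same connected component and meets the
    # same brighter/claimed pixel.  Pure shortcut, identical results.
    dismissed = np.zeros((h, w), dtype=bool)
    visited = np.zeros((h, w), dtype=np.int32)
    gen = 0
    results = []  # (peak value, centroid row, centroid col)

    for idx in order:
        r0, c0 = int(cand_r[idx]), int(cand_c[idx])
        if claimed[r0, c0] or dismissed[r0, c0]:
            continue
        v = a[r0, c0]
        gen += 1
        region = [(r0, c0)]
        visited[r0, c0] = gen
        queue = deque(region)
        rejected = False
        while queue and not rejected:
            r, c = queue.popleft()
            for dr, dc in _NEIGHBORS:
                rr, cc = r + dr, c + dc
                if not (0 <= rr < h and 0 <= cc < w):
                    continue
                if visited[rr, cc] == gen:
                    continue
                av = a[rr, cc]
                if av > v - tolerance or av == v:
                    if av > v or claimed[rr, cc]:
                        rejected = True
                        break
                    visited[rr, cc] = gen
                    region.append((rr, cc))
                    queue.append((rr, cc))
        rows = np.fromiter((p[0] for p in region), dtype=np.intp)
        cols = np.fromiter((p[1] for p in region), dtype=np.intp)
        if rejected:
            eq = a[rows, cols] == v
            dismissed[rows[eq], cols[eq]] = True
            continue
        claimed[rows, cols] = True
        # Plateau = equal-valued pixels connected to the seed within region.
        plateau = _plateau_component(a, region, r0, c0, v)
        pr = round_half_up_int(np.mean([p[0] for p in plateau]))
        pc = round_half_up_int(np.mean([p[1] for p in plateau]))
        results.append((v, pr, pc))

    results.sort(key=lambda t: (-t[0], t[1], t[2]))
    return [(r, c) for _, r, c in results]


def _plateau_component(a, region, r0, c0, v):
    members = set(region)
    plateau = [(r0, c0)]
    seen = {(r0, c0)}
    queue = deque(plateau)
    while queue:
        r, c = queue.popleft()
        for dr, dc in _NEIGHBORS:
            q = (r + dr, c + dc)
            if q in members and q not in seen and a[q] == v:
                seen.add(q)
                plateau.append(q)
                queue.append(q)
    return plateau


def measure_spots(image, maxima, box_size: int = 2) -> SpotSet:
    """Assign each maximum the mean intensity of the box around it.

    The box is (2*box_size+1) pixels square, clipped at image borders (the
    mean is taken over the in-bounds subset).
    """
    a = np.asarray(image, dtype=np.float64)
    h, w = a.shape
    spots = []
    for r, c in maxima:
        if not (0 <= r < h and 0 <= c < w):
            raise ValueError(f"maximum ({r}, {c}) outside image {a.shape}")
        r0, r1 = max(0, r - box_size), min(h, r + box_size + 1)
        c0, c1 = max(0, c - box_size), min(w, c + box_size + 1)
        spots.append(Spot(int(r), int(c), float(a[r0:r1, c0:c1].mean())))
    return SpotSet(spots)
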