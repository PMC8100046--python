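"""Independent brute-force reference implementations used only by tests.

These deliberately share no code with the package: plain-Python data
structures, full (non-early-exit) floods, and explicit sums of squares, so
that agreement with the package is evidence, not tautology.
"""

import numpy as np


def find_maxima_bruteforce(image, tolerance):
    """Reference prominence-maxima finder.

    Same documented contract as the package (descending candidates, flood
    over value > peak - tolerance or == peak, reject on brighter/claimed,
    plateau centroid, no maxima on a constant image) but implemented with
    python sets and full component enumeration, no shortcuts.
    """
    a = np.asarray(image, dtype=float)
    h, w = a.shape
    if a.min() == a.max():
        return []

    def neighbors(p):
        r, c = p
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if (dr or dc) and 0 <= r + dr < h and 0 <= c + dc < w:
                    yield (r + dr, c + dc)

    candidates = [
        (r, c) for r in range(h) for c in range(w)
        if all(a[q] <= a[r, c] for q in neighbors((r, c)))
    ]
    candidates.sort(key=lambda p: (-a[p], p[0], p[1]))

    claimed = set()
    out = []
    for seed in candidates:
        if seed in claimed:
            continue
        v = a[seed]
        # Full connected component under the inclusion predicate.
        comp = {seed}
        frontier = [seed]
        while frontier:
            p = frontier.pop()
            for q in neighbors(p):
                if q not in comp and (a[q] > v - tolerance or a[q] == v):
                    comp.add(q)
                    frontier.append(q)
        if any(a[q] > v for q in comp) or comp & claimed:
            continue
        claimed |= comp
        plateau = {seed}
        frontier = [seed]
        while frontier:
            p = frontier.pop()
            for q in neighbors(p):
                if q in comp and q not in plateau and a[q] == v:
                    plateau.add(q)
                    frontier.append(q)
        pr = int(np.floor(np.mean([p[0] for p in plateau]) + 0.5))
        pc = int(np.floor(np.mean([p[1] for p in plateau]) + 0.5))
        out.append((v, pr, pc))
    out.sort(key=lambda t: (-t[0], t[1], t[2]))
    return [(r, c) for _, r, c in out]


def icc_absolute_bruteforce(manual, semi):
    """ICC(A,1) from explicitly enumerated two-way ANOVA sums of squares."""
    x = np.column_stack([np.asarray(manual, float), np.asarray(semi, float)])
    n, k = x.shape
    grand = x.sum() / (n * k)
    ss_rows = sum(k * (x[i].mean() - grand) ** 2 for i in range(n))
    ss_cols = sum(n * (x[:, j].mean() - grand) ** 2 for j in range(k))
    ss_tot = sum((x[i, j] - grand) ** 2 for i in range(n) for j in range(k))
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = (ss_tot - ss_rows - ss_cols) / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)


def point_in_polygon_bruteforce(point, vertices, eps=1e-9):
    """Crossing-number test written independently (angle-sum free)."""
    pr, pc = point
    verts = [tuple(map(float, v)) for v in vertices]
    n = len(verts)
    for i in range(n):
        (ar, ac), (br, bc) = verts[i], verts[(i + 1) % n]
        cross = (br - ar) * (pc - ac) - (bc - ac) * (pr - ar)
        dot = (pr - ar) * (br - ar) + (pc - ac) * (bc - ac)
        if (abs(cross) <= eps * max(1.0, abs(br - ar) + abs(bc - ac))
                and -eps <= dot <= (br - ar) ** 2 + (bc - ac) ** 2 + eps):
            return True
    count = 0
    for i in range(n):
        (ar, ac), (br, bc) = verts[i], verts[(i + 1) % n]
        if (ar > pr) != (br > pr):
            if ac + (pr - ar) * (bc - ac) / (br - ar) > pc:
                count += 1
    return count % 2 == 1


def histogram_equalize_bruteforce(image):
    """Classical global 8-bit histogram equalization: v -> 255*P(X <= v)."""
    img = np.asarray(image).astype(int)
    out = np.empty_like(img)
    npix = img.size
    for v in np.unique(img):
        out[img == v] = int(np.floor(255.0 * (img <= v).sum() / npix + 0.5))
    return out
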