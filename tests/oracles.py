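"""Independent brute-force oracles used to validate the library paths.

These deliberately avoid scipy.spatial.Voronoi and the package's own
membership code: adjacency comes from explicit half-plane clipping of
each cell, densities from per-pixel loops, lattice counts from direct
index enumeration.
"""

from __future__ import annotations

import math

import numpy as np


def lattice_count_loop(width_px, height_px, um_per_px, spacing_um) -> int:
    """Count triangular-lattice sites inside the image extent by direct
    enumeration over (row, column) indices."""
    spacing = spacing_um / um_per_px
    row_h = spacing * math.sqrt(3.0) / 2.0
    count = 0
    j = 0
    while True:
        y = row_h / 2.0 + j * row_h
        if y > height_px - 0.5:
            break
        x0 = spacing / 2.0 + (spacing / 2.0 if j % 2 else 0.0)
        # walk columns in both directions from the anchor
        i = 0
        while x0 + i * spacing <= width_px - 0.5:
            count += 1
            i += 1
        i = -1
        while x0 + i * spacing >= -0.5:
            count += 1
            i -= 1
        j += 1
    return count


def _clip_halfplane(poly, a, b):
    """Clip polygon to the half-plane of points closer to site a than b
    (Sutherland-Hodgman)."""
    mid = (a + b) / 2.0
    normal = b - a  # f(p) = (p - mid) . normal; keep f <= 0
    out = []
    n = len(poly)
    for k in range(n):
        p, q = poly[k], poly[(k + 1) % n]
        fp = float(np.dot(p - mid, normal))
        fq = float(np.dot(q - mid, normal))
        if fp <= 0:
            out.append(p)
        if (fp < 0 < fq) or (fq < 0 < fp):
            t = fp / (fp - fq)
            out.append(p + t * (q - p))
    return out


def voronoi_adjacency_bruteforce(points: np.ndarray) -> list[set[int]]:
    """O(n^2) Voronoi adjacency via perpendicular-bisector clipping.

    For each site, its cell is the intersection of half-planes against
    every other site (inside a large bounding box); two sites are
    adjacent when the clipped cell retains a positive-length edge on
    their bisector.
    """
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    lo = pts.min(axis=0)
    hi = pts.max(axis=0)
    span = float(max(hi[0] - lo[0], hi[1] - lo[1], 1.0))
    # ridges between hull-adjacent sites may only begin far beyond the
    # point cloud (near-collinear hull triples push Voronoi vertices
    # out); the box must comfortably contain every Voronoi vertex
    m = 1e4 * span
    box = np.array(
        [
            [lo[0] - m, lo[1] - m],
            [hi[0] + m, lo[1] - m],
            [hi[0] + m, hi[1] + m],
            [lo[0] - m, hi[1] + m],
        ]
    )
    edge_tol = 1e-9 * span
    adjacency: list[set[int]] = [set() for _ in range(n)]
    for i in range(n):
        poly = [box[k] for k in range(4)]
        for j in range(n):
            if j == i or not poly:
                continue
            poly = _clip_halfplane(poly, pts[i], pts[j])
        if not poly:
            continue
        arr = np.array(poly)
        others = np.delete(np.arange(n), i)
        for k in range(len(arr)):
            p, q = arr[k], arr[(k + 1) % len(arr)]
            if float(np.hypot(*(p - q))) <= edge_tol:
                continue
            mid = (p + q) / 2.0
            d_i = float(np.hypot(*(mid - pts[i])))
            # every positive-length cell edge lies on exactly one
            # bisector (or on the clipping box); take the unique nearest
            # candidate, with a tolerance scaled for far-out midpoints
            d_all = np.hypot(mid[0] - pts[others, 0], mid[1] - pts[others, 1])
            k_min = int(np.argmin(np.abs(d_all - d_i)))
            if abs(d_all[k_min] - d_i) < 1e-9 * d_i + 1e-7 * span:
                adjacency[i].add(int(others[k_min]))
    return adjacency


def annulus_density_loop(mask, center, inner_um, outer_um, um_per_px):
    """Per-pixel membership loop for the annulus vessel density."""
    h, w = mask.shape
    cx, cy = center
    vessel = 0
    total = 0
    for r in range(h):
        for c in range(w):
            d_um = math.hypot(c - cx, r - cy) * um_per_px
            if inner_um / 2.0 <= d_um <= outer_um / 2.0:
                total += 1
                if mask[r, c]:
                    vessel += 1
    return 100.0 * vessel / total


def disk_pixel_count(shape, cx_px, cy_px, radius_px) -> int:
    """Pixels whose centers fall inside the disk, by direct loop."""
    h, w = shape
    count = 0
    for r in range(h):
        for c in range(w):
            if (c - cx_px) ** 2 + (r - cy_px) ** 2 <= radius_px**2:
                count += 1
    return count


def spearman_hand(x, y):
    """Spearman r via explicit average ranks and the Pearson formula."""

    def ranks(v):
        v = np.asarray(v, dtype=float)
        order = np.argsort(v, kind="stable")
        r = np.empty(len(v))
        pos = 0
        while pos < len(v):
            end = pos
            while end + 1 < len(v) and v[order[end + 1]] == v[order[pos]]:
                end += 1
            avg = (pos + end) / 2.0 + 1.0
            for k in range(pos, end + 1):
                r[order[k]] = avg
            pos = end + 1
        return r

    rx, ry = ranks(x), ranks(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float((rx @ ry) / math.sqrt((rx @ rx) * (ry @ ry)))
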