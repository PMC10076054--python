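"""Independent brute-force oracles shared by the unit and acceptance tests.

These deliberately avoid the implementation's code paths: explicit loops,
pairwise enumeration, and direct slicing instead of cumulative sums or
separable convolutions.
"""

import itertools
import math

import numpy as np


def exhaustive_best_line(pts, t):
    """Best line over all point pairs by inlier count (perpendicular
    residual < t, refit-and-recollect convention), ties to lower mean
    residual.  Returns the inlier index set."""
    best = None
    for i, j in itertools.combinations(range(len(pts)), 2):
        if pts[i][0] == pts[j][0]:
            continue
        a = (pts[j][1] - pts[i][1]) / (pts[j][0] - pts[i][0])
        b = pts[i][1] - a * pts[i][0]
        dist = np.abs(a * pts[:, 0] - pts[:, 1] + b) / math.hypot(a, 1.0)
        inliers = frozenset(np.flatnonzero(dist < t)) | {i, j}
        err = float(dist[list(inliers)].mean())
        if best is None or (len(inliers), -err) > (len(best[0]), -best[1]):
            best = (inliers, err)
    return best[0]


def brute_force_moving_sum(counts, window):
    """Per-pixel window sum with boundary truncation and coverage
    renormalization, via explicit slicing."""
    h, w = counts.shape
    out = np.zeros((h, w))
    half = window // 2
    for i in range(h):
        for j in range(w):
            i0, i1 = max(0, i - half), min(h, i + (window - half))
            j0, j1 = max(0, j - half), min(w, j + (window - half))
            s = counts[i0:i1, j0:j1].sum()
            frac = (i1 - i0) * (j1 - j0) / window**2
            out[i, j] = s / frac
    return out


def brute_force_convolve(img, kernel):
    """Direct zero-padded 2-D convolution (kernel is symmetric)."""
    kh, kw = kernel.shape
    ph, pw = kh // 2, kw // 2
    padded = np.zeros((img.shape[0] + 2 * ph, img.shape[1] + 2 * pw))
    padded[ph:ph + img.shape[0], pw:pw + img.shape[1]] = img
    out = np.zeros_like(img, dtype=float)
    for i in range(img.shape[0]):
        for j in range(img.shape[1]):
            out[i, j] = np.sum(padded[i:i + kh, j:j + kw] * kernel)
    return out


def nearest_covering_assignment(grid, cams, footprints):
    """Exhaustive nearest-covering-image search over every cell.

    ``cams``: image_id -> (x, y); ``footprints``: image_id ->
    (xmin, ymin, xmax, ymax) axis-aligned in the grid frame.
    """
    assignment = {}
    for i in range(grid.n_cols):
        for j in range(grid.n_rows):
            x0, y0, x1, y1 = grid.cell_bounds(i, j)
            cx, cy = grid.cell_center(i, j)
            best, best_d = None, math.inf
            for image_id in sorted(cams):
                fx0, fy0, fx1, fy1 = footprints[image_id]
                if not (fx0 <= x0 and x1 <= fx1 and fy0 <= y0 and y1 <= fy1):
                    continue
                e, n = cams[image_id]
                d = math.hypot(e - cx, n - cy)
                if d < best_d:
                    best, best_d = image_id, d
            if best is not None:
                assignment[(i, j)] = best
    return assignment
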