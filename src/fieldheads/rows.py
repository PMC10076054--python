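"""Planting-row detection by iterative RANSAC on head-detection centers.

Each planting row is modeled as a line ``y = a*x + b`` in the image pixel
frame (y down), fitted robustly to the center points of head bounding
boxes.  The generic RANSAC loop is applied repeatedly: once a row model is
accepted, its inliers are removed and the search continues on the
remaining points until too few points remain or no candidate reaches the
minimum inlier count.

The inlier residual is the perpendicular point-to-line distance rather
than the vertical offset — robust to steep slopes before the image is
rotated row-horizontal.  Near-vertical point sets are handled by swapping
the x/y axes before fitting and converting the result back.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from fieldheads.geo_io import Detection, ImageRecord, detections_to_array

__all__ = [
    "RowModel",
    "RansacParams",
    "RotationRecord",
    "DegenerateFitError",
    "InsufficientDataError",
    "fit_line",
    "ransac_single",
    "detect_rows",
    "dominant_direction",
    "filter_rows_by_direction",
    "rotate_to_horizontal",
    "assign_to_nearest_row",
]


class DegenerateFitError(ValueError):
    """Line fit attempted on <2 points or points with identical x."""


class InsufficientDataError(ValueError):
    """Too few points to run the requested estimation."""


@dataclass(frozen=True)
class RowModel:
    """One fitted planting-row line ``y = a*x + b`` with its inliers.

    ``b`` is the line's intersection with the left image edge (y at x=0);
    ``inlier_ids`` index into the point set the model was fitted on;
    ``x_span`` is the inlier extent along x in pixels.
    """

    a: float
    b: float
    inlier_ids: tuple[int, ...]
    x_span: tuple[float, float]
    mean_residual: float = 0.0

    @property
    def angle_deg(self) -> float:
        """Slope angle atan(a) in degrees, in (-90, 90]."""
        return math.degrees(math.atan(self.a))

    def perpendicular_distance(self, points: np.ndarray) -> np.ndarray:
        """Unsigned perpendicular distance of (n,2) points to the line."""
        pts = np.atleast_2d(points)
        return np.abs(self.a * pts[:, 0] - pts[:, 1] + self.b) / math.hypot(self.a, 1.0)


@dataclass(frozen=True)
class RansacParams:
    """RANSAC knobs: ``n`` points per minimal sample, ``k`` iterations per
    row, ``t`` inlier residual threshold (px), ``d`` minimum extra inliers
    to accept a candidate.

    With 75 cm row spacing at 0.25 cm/px a row is 300 px from its
    neighbors; ``t`` defaults to 0.35 x the spacing in pixels when the
    spacing is known, else 10 px.
    """

    n: int = 2
    k: int = 500
    t: float = 10.0
    d: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("n must be >= 2")
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if not self.t > 0:
            raise ValueError("t must be positive")
        if self.d < self.n:
            raise ValueError("d must be >= n")

    @classmethod
    def for_spacing(cls, row_spacing_px: float, **kw) -> "RansacParams":
        """Threshold scaled to the known row spacing in pixels."""
        return cls(t=0.35 * row_spacing_px, **kw)


@dataclass(frozen=True)
class RotationRecord:
    """In-plane rotation applied to bring planting rows horizontal."""

    theta_deg: float
    center_xy: tuple[float, float]


def fit_line(points: np.ndarray | Sequence[tuple[float, float]]) -> tuple[float, float]:
    """Ordinary least squares of y on x; returns (slope, intercept).

    Raises :class:`DegenerateFitError` on fewer than 2 points or a vertical
    point set (caller resamples).
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.shape[0] < 2:
        raise DegenerateFitError("need at least 2 points")
    x, y = pts[:, 0], pts[:, 1]
    if np.ptp(x) == 0:
        raise DegenerateFitError("all points share the same x (vertical line)")
    a, b = np.polyfit(x, y, 1)
    return float(a), float(b)


def ransac_single(
    points: np.ndarray | Sequence[tuple[float, float]],
    params: RansacParams,
    rng: np.random.Generator,
) -> RowModel | None:
    """One round of generic RANSAC: fit a single line to the point set.

    Runs up to ``k`` iterations.  Each iteration samples ``n`` points,
    fits a line, and collects the remaining points within perpendicular
    distance ``t`` as consensus inliers.  When sample and consensus
    together exceed ``d``, the line is refitted to their union and scored
    by its mean perpendicular residual over the refit's own inliers; the
    lowest-scoring candidate wins, ties broken toward the larger inlier
    set.  Returns ``None`` if no iteration met ``d``: the absence of a
    row is a valid outcome, not an error.

    After the refit, inliers are re-collected against the refitted line —
    so a minimal sample that only grazed part of a row still ends up
    owning the whole row — and the sampled points are kept as inliers
    even if they drift outside ``t``, so iterative removal always shrinks
    the data.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    m = pts.shape[0]
    if m < params.n:
        return None
    x, y = pts[:, 0], pts[:, 1]
    best: RowModel | None = None
    best_err = math.inf
    best_count = -1
    for _ in range(params.k):
        sample = rng.choice(m, size=params.n, replace=False)
        sx, sy = x[sample], y[sample]
        if np.ptp(sx) == 0:
            continue
        if params.n == 2:
            a = (sy[1] - sy[0]) / (sx[1] - sx[0])
            b = sy[0] - a * sx[0]
        else:
            a, b = fit_line(pts[sample])
        dist = np.abs(a * x - y + b) / math.hypot(a, 1.0)
        inlier = dist < params.t
        inlier[sample] = True
        if int(inlier.sum()) <= params.d:
            continue
        union = np.flatnonzero(inlier)
        try:
            a2, b2 = fit_line(pts[union])
        except DegenerateFitError:
            continue
        dist2 = np.abs(a2 * x - y + b2) / math.hypot(a2, 1.0)
        final = dist2 < params.t
        final[sample] = True
        ids = np.flatnonzero(final)
        err = float(dist2[ids].mean())
        count = ids.size
        # errors equal to within numerical noise tie-break on inlier count
        if err < best_err - 1e-9 or (err < best_err + 1e-9 and count > best_count):
            best = RowModel(
                a=float(a2),
                b=float(b2),
                inlier_ids=tuple(int(i) for i in ids),
                x_span=(float(x[ids].min()), float(x[ids].max())),
                mean_residual=err,
            )
            best_err = err
            best_count = count
    return best


def detect_rows(
    points: np.ndarray | Sequence[tuple[float, float]],
    params: RansacParams,
    rng: np.random.Generator | None = None,
) -> list[RowModel]:
    """Iteratively extract all planting-row lines from a point set.

    Calls :func:`ransac_single`, removes the accepted model's inliers
    (sample and consensus alike) from the data, and repeats until fewer
    than ``n`` points remain or no candidate reaches ``d`` inliers.
    Inlier ids in the returned models index the *original* point set, and
    no point belongs to two rows.  Rows are sorted by intercept ``b``.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.size == 0:
        return []
    remaining = np.arange(pts.shape[0])
    rows: list[RowModel] = []
    while remaining.size > params.n:
        model = ransac_single(pts[remaining], params, rng)
        if model is None:
            break
        original_ids = remaining[np.array(model.inlier_ids, dtype=int)]
        rows.append(replace(model, inlier_ids=tuple(int(i) for i in np.sort(original_ids))))
        keep = np.ones(remaining.size, dtype=bool)
        keep[np.array(model.inlier_ids, dtype=int)] = False
        remaining = remaining[keep]
    rows.sort(key=lambda r: r.b)
    return rows


def _densest_window(centers: np.ndarray, width: int, height: int) -> np.ndarray:
    """Mask of centers inside the densest ceil(W/3) x ceil(H/3) window.

    The window slides on a stride-W/10 (resp. H/10) lattice; ties go to
    the first window in scan order.
    """
    win_w = math.ceil(width / 3)
    win_h = math.ceil(height / 3)
    stride_x = max(1, width // 10)
    stride_y = max(1, height // 10)
    xs = np.arange(0, max(width - win_w, 0) + 1, stride_x)
    ys = np.arange(0, max(height - win_h, 0) + 1, stride_y)
    best_mask = np.ones(centers.shape[0], dtype=bool)
    best_count = -1
    for y0 in ys:
        in_y = (centers[:, 1] >= y0) & (centers[:, 1] < y0 + win_h)
        for x0 in xs:
            mask = in_y & (centers[:, 0] >= x0) & (centers[:, 0] < x0 + win_w)
            count = int(mask.sum())
            if count > best_count:
                best_count = count
                best_mask = mask
    return best_mask


def dominant_direction(
    dets: Sequence[Detection] | np.ndarray,
    rec: ImageRecord,
    params: RansacParams,
    rng: np.random.Generator | None = None,
) -> float:
    """Estimate the prevailing planting-row orientation of one image.

    RANSAC is run on the densest third-of-the-image window first — a dense
    patch almost surely contains a full row segment, making the direction
    estimate robust on scattered images.  The fit is attempted in both
    axis orders (y-on-x and x-on-y) and the better consensus wins, so
    near-vertical rows do not blow up the slope.  Returns the angle
    ``atan(a)`` in degrees, in (-90, 90].

    Raises :class:`InsufficientDataError` when fewer than ``n`` points are
    available or no candidate line reaches ``d`` inliers.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    centers = dets if isinstance(dets, np.ndarray) else detections_to_array(dets)
    if centers.shape[0] < params.n:
        raise InsufficientDataError(
            f"{centers.shape[0]} detections < minimum sample size {params.n}"
        )
    mask = _densest_window(centers, rec.width, rec.height)
    sub = centers[mask]
    if sub.shape[0] < params.n:
        sub = centers
    direct = ransac_single(sub, params, rng)
    swapped = ransac_single(sub[:, ::-1], params, rng)
    if direct is None and swapped is None:
        raise InsufficientDataError("no line with the required consensus found")
    use_swapped = (
        direct is None
        or (swapped is not None
            and len(swapped.inlier_ids) > len(direct.inlier_ids))
    )
    if use_swapped:
        assert swapped is not None
        theta = 90.0 - math.degrees(math.atan(swapped.a))
    else:
        assert direct is not None
        theta = math.degrees(math.atan(direct.a))
    if theta > 90.0:
        theta -= 180.0
    elif theta <= -90.0:
        theta += 180.0
    return theta


def _angle_difference_deg(alpha: float, beta: float) -> float:
    """Acute difference between two undirected line angles in degrees."""
    diff = abs(alpha - beta) % 180.0
    return min(diff, 180.0 - diff)


def filter_rows_by_direction(
    rows: Sequence[RowModel],
    theta_deg: float,
    tol_deg: float = 10.0,
    points: np.ndarray | None = None,
    params: RansacParams | None = None,
    rng: np.random.Generator | None = None,
) -> list[RowModel]:
    """Discard rows deviating from the dominant direction by more than ``tol_deg``.

    Spurious "rows" arise when RANSAC strings together collinear points
    across several true rows; these run diagonally and are rejected here.
    When ``points`` and ``params`` are given, the discarded rows' points
    are pooled and refit once, and any refit row that now agrees with the
    dominant direction is appended.
    """
    kept = [r for r in rows if _angle_difference_deg(r.angle_deg, theta_deg) <= tol_deg]
    dropped = [r for r in rows if _angle_difference_deg(r.angle_deg, theta_deg) > tol_deg]
    if dropped and points is not None and params is not None:
        pool_ids = np.sort(np.concatenate(
            [np.array(r.inlier_ids, dtype=int) for r in dropped]
        ))
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        refit = detect_rows(pts[pool_ids], params,
                            rng if rng is not None else np.random.default_rng(params.seed))
        for r in refit:
            if _angle_difference_deg(r.angle_deg, theta_deg) <= tol_deg:
                kept.append(replace(
                    r,
                    inlier_ids=tuple(int(pool_ids[i]) for i in r.inlier_ids),
                ))
    kept.sort(key=lambda r: r.b)
    return kept


def rotate_to_horizontal(
    dets: Sequence[Detection],
    rec: ImageRecord,
    theta_deg: float,
) -> tuple[list[Detection], RotationRecord]:
    """Rotate detection centers by ``-theta`` about the image center.

    Brings lines of slope ``tan(theta)`` horizontal in the y-down pixel
    frame.  Boxes stay axis-aligned with their original width/height,
    re-centered on the rotated center (heads are roughly isotropic, so
    shearing the box would add nothing).  The applied rotation is recorded
    for the mosaic stage.
    """
    cx, cy = rec.width / 2.0, rec.height / 2.0
    th = math.radians(theta_deg)
    cos_t, sin_t = math.cos(th), math.sin(th)
    out: list[Detection] = []
    for d in dets:
        x, y = d.center
        dx, dy = x - cx, y - cy
        nx = cos_t * dx + sin_t * dy + cx
        ny = -sin_t * dx + cos_t * dy + cy
        out.append(replace(
            d,
            x_min=nx - d.width / 2.0,
            x_max=nx + d.width / 2.0,
            y_min=ny - d.height / 2.0,
            y_max=ny + d.height / 2.0,
        ))
    return out, RotationRecord(theta_deg=theta_deg, center_xy=(cx, cy))


def assign_to_nearest_row(
    dets: Sequence[Detection] | np.ndarray,
    rows: Sequence[RowModel],
) -> tuple[np.ndarray, np.ndarray]:
    """Assign each detection center to the perpendicular-nearest row line.

    Returns ``(assignment, positions)`` where ``assignment[i]`` is the
    index into ``rows`` of detection ``i``'s nearest line (ties broken by
    the lower row index) and ``positions[i]`` is the scalar projection of
    the center onto that line, in pixels from the row's ``x_span`` minimum.
    """
    if not rows:
        raise ValueError("no rows to assign to")
    centers = dets if isinstance(dets, np.ndarray) else detections_to_array(dets)
    centers = np.atleast_2d(np.asarray(centers, dtype=float))
    dist = np.stack([r.perpendicular_distance(centers) for r in rows], axis=1)
    assignment = np.argmin(dist, axis=1)  # argmin takes the first minimum: lower index wins ties
    positions = np.empty(centers.shape[0], dtype=float)
    for j, r in enumerate(rows):
        mask = assignment == j
        if not mask.any():
            continue
        x0 = r.x_span[0]
        y0 = r.a * x0 + r.b
        ux, uy = 1.0 / math.hypot(r.a, 1.0), r.a / math.hypot(r.a, 1.0)
        positions[mask] = (centers[mask, 0] - x0) * ux + (centers[mask, 1] - y0) * uy
    return assignment, positions
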