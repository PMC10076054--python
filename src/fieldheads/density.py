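"""Head-density statistics: row/image densities, gaps, profiles, field maps.

With planting rows horizontal in the image and the ground sampling
distance G (cm/px) known for a W x H image, head counts convert to
physical densities as

    D_r = C_r / (W * G)          heads per cm of row, reported as heads/m
    D_i = C_i / (W * H * G^2)    heads per cm^2,      reported as heads/m^2

where C_r counts the heads assigned to one row and C_i counts all heads
in the image.  Planting gaps are along-row spans longer than a threshold
(default 50 cm) containing no heads.  Field-wide density is a moving-sum
map over the quasi-mosaic at 1 cm/px: a 100 x 100 px window is one square
meter, so the window sum is already heads/m^2; a sum-one Gaussian kernel
then smooths the map without changing its physical meaning.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import convolve1d

from fieldheads.geo_io import Detection, ImageRecord
from fieldheads.rows import RowModel, assign_to_nearest_row

__all__ = [
    "GapRecord",
    "RowStats",
    "ImageStats",
    "DensityMap",
    "row_density",
    "image_density",
    "detect_gaps",
    "row_profile",
    "field_density_map",
    "compute_image_stats",
    "gaussian_kernel_1d",
]


@dataclass(frozen=True)
class GapRecord:
    """An along-row span with no heads, longer than the gap threshold."""

    row_id: int
    start_cm: float
    end_cm: float

    @property
    def length_cm(self) -> float:
        return self.end_cm - self.start_cm


@dataclass(frozen=True)
class RowStats:
    row_id: int
    count: int
    length_m: float
    density_per_m: float
    gaps: tuple[GapRecord, ...] = ()


@dataclass(frozen=True)
class ImageStats:
    """Per-image head statistics: per-row counts/densities and the
    whole-image count and areal density."""

    image_id: str
    rows: tuple[RowStats, ...]
    count: int
    density_per_m2: float
    length_basis: str = "row_span"  # or "image_width"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "image_id": self.image_id,
                    "row_id": r.row_id,
                    "row_count": r.count,
                    "row_length_m": r.length_m,
                    "row_density_per_m": r.density_per_m,
                    "n_gaps": len(r.gaps),
                    "image_count": self.count,
                    "image_density_per_m2": self.density_per_m2,
                }
                for r in self.rows
            ]
        )


def row_density(c_r: int, width_px: float, gsd_cm_px: float) -> float:
    """Heads per meter of planting row: ``C_r / (W * G) * 100``."""
    if width_px <= 0 or gsd_cm_px <= 0:
        raise ValueError("width and GSD must be positive")
    if c_r < 0:
        raise ValueError("count must be non-negative")
    return c_r / (width_px * gsd_cm_px) * 100.0


def image_density(c_i: int, width_px: float, height_px: float,
                  gsd_cm_px: float) -> float:
    """Heads per square meter of ground: ``C_i / (W * H * G^2) * 10^4``."""
    if width_px <= 0 or height_px <= 0 or gsd_cm_px <= 0:
        raise ValueError("dimensions and GSD must be positive")
    if c_i < 0:
        raise ValueError("count must be non-negative")
    return c_i / (width_px * height_px * gsd_cm_px**2) * 1.0e4


def detect_gaps(
    positions_cm: Sequence[float] | np.ndarray,
    span_cm: tuple[float, float],
    threshold_cm: float = 50.0,
    row_id: int = 0,
) -> list[GapRecord]:
    """Find head-free along-row spans longer than ``threshold_cm``.

    Scans consecutive differences of the sorted positions, including the
    distances from the span edges to the first and last head.  An empty
    row whose span exceeds the threshold is one whole-span gap.
    """
    lo, hi = span_cm
    pos = np.asarray(positions_cm, dtype=float)
    if pos.size and np.any(np.diff(pos) < 0):
        raise ValueError("positions must be sorted non-decreasing")
    edges = np.concatenate([[lo], pos, [hi]])
    gaps = []
    for a, b in zip(edges[:-1], edges[1:]):
        if b - a > threshold_cm:
            gaps.append(GapRecord(row_id=row_id, start_cm=float(a), end_cm=float(b)))
    return gaps


def gaussian_kernel_1d(sigma: float, radius: int | None = None) -> np.ndarray:
    """Discrete Gaussian normalized to sum exactly one."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if radius is None:
        radius = int(math.ceil(3.0 * sigma))
    x = np.arange(-radius, radius + 1, dtype=float)
    k = np.exp(-(x**2) / (2.0 * sigma**2))
    return k / k.sum()


def _moving_sum_1d(counts: np.ndarray, window: int) -> tuple[np.ndarray, np.ndarray]:
    """Centered moving-window sum ([i - w//2, i + w//2)) and the in-bounds
    covered fraction of each window, via a cumulative sum."""
    n = counts.size
    csum = np.concatenate([[0.0], np.cumsum(counts)])
    idx = np.arange(n)
    lo = np.clip(idx - window // 2, 0, n)
    hi = np.clip(idx + (window - window // 2), 0, n)
    sums = csum[hi] - csum[lo]
    covered = (hi - lo) / float(window)
    return sums, covered


def row_profile(
    positions_cm: Sequence[float] | np.ndarray,
    span_cm: tuple[float, float],
    window_cm: int = 100,
    sigma_cm: float = 25.0,
) -> np.ndarray:
    """One-dimensional moving-sum head-count profile along a row, smoothed.

    Heads are binned at 1 cm; a ``window_cm`` moving sum with stride 1,
    truncated at the row ends and renormalized by the covered fraction,
    gives heads per window; dividing by the window length in meters gives
    heads/m.  A sum-one Gaussian (``sigma_cm``) then smooths the profile
    without changing its mean.  Returns one value per cm of span.
    """
    if window_cm <= 0:
        raise ValueError("window must be positive")
    lo, hi = span_cm
    n = int(math.ceil(hi - lo))
    if n <= 0:
        return np.zeros(0, dtype=float)
    pos = np.asarray(positions_cm, dtype=float)
    counts, _ = np.histogram(pos, bins=n, range=(lo, lo + n))
    sums, covered = _moving_sum_1d(counts.astype(float), window_cm)
    with np.errstate(invalid="ignore"):
        per_window = np.where(covered > 0, sums / covered, 0.0)
    profile = per_window / (window_cm / 100.0)
    kernel = gaussian_kernel_1d(sigma_cm)
    return convolve1d(profile, kernel, mode="nearest")


@dataclass(frozen=True)
class DensityMap:
    """Field-frame head-density raster in heads/m^2.

    ``raw`` is the edge-renormalized moving-window sum (integer counts
    over interior windows); ``smoothed`` is ``raw`` convolved with the
    sum-one Gaussian kernel; both are indexed [row, col] with row 0 at the
    field's north edge, at ``scale_cm_px`` per pixel.
    """

    raw: np.ndarray
    smoothed: np.ndarray
    extent_m: tuple[float, float, float, float]
    scale_cm_px: float
    window_px: int
    kernel: np.ndarray = dc_field(repr=False, default=None)

    @property
    def interior(self) -> tuple[slice, slice]:
        """Slices selecting pixels unaffected by any boundary handling:
        margin of one window (raw truncation) plus the kernel radius."""
        m = self.window_px + self.window_px // 2
        return (slice(m, max(self.raw.shape[0] - m, m)),
                slice(m, max(self.raw.shape[1] - m, m)))


def moving_window_sum(counts: np.ndarray, window: int) -> tuple[np.ndarray, np.ndarray]:
    """2-D centered moving-window sum and covered fraction, separably."""
    _, cov_y = _moving_sum_1d(np.ones(counts.shape[0]), window)
    csum = np.concatenate([np.zeros((1, counts.shape[1])),
                           np.cumsum(counts, axis=0)], axis=0)
    idx = np.arange(counts.shape[0])
    lo = np.clip(idx - window // 2, 0, counts.shape[0])
    hi = np.clip(idx + (window - window // 2), 0, counts.shape[0])
    sums_y = csum[hi] - csum[lo]
    csum_x = np.concatenate([np.zeros((counts.shape[0], 1)),
                             np.cumsum(sums_y, axis=1)], axis=1)
    idx_x = np.arange(counts.shape[1])
    lo_x = np.clip(idx_x - window // 2, 0, counts.shape[1])
    hi_x = np.clip(idx_x + (window - window // 2), 0, counts.shape[1])
    sums = csum_x[:, hi_x] - csum_x[:, lo_x]
    _, cov_x = _moving_sum_1d(np.ones(counts.shape[1]), window)
    coverage = np.outer(cov_y, cov_x)
    return sums, coverage


def field_density_map(
    field_dets: pd.DataFrame | np.ndarray,
    extent_m: tuple[float, float, float, float] | None = None,
    window_px: int = 100,
    scale_cm_px: float = 1.0,
    sigma_px: float | None = None,
) -> DensityMap:
    """Field-wide head-density map from field-frame detection positions.

    Detection centers are rasterized onto a ``scale_cm_px`` lattice (1 cm
    by default, so 100 x 100 px is 1 m x 1 m); a ``window_px`` moving sum
    with stride one counts heads around every pixel, windows at the field
    boundary being truncated and renormalized by their covered fraction;
    at the default scales the result is directly heads/m^2.  Smoothing
    uses a separable Gaussian whose 2-D kernel sums to one (sigma
    defaults to window/6, matching a window-sized kernel support), which
    preserves the map's physical unit.
    """
    if scale_cm_px <= 0 or window_px <= 0:
        raise ValueError("scale and window must be positive")
    if isinstance(field_dets, pd.DataFrame):
        pts = field_dets[["east_m", "north_m"]].to_numpy(dtype=float)
    else:
        pts = np.atleast_2d(np.asarray(field_dets, dtype=float))
        if pts.size == 0:
            pts = np.empty((0, 2))
    if extent_m is None:
        if pts.shape[0] == 0:
            raise ValueError("need an extent for an empty detection set")
        extent_m = (pts[:, 0].min(), pts[:, 1].min(),
                    pts[:, 0].max(), pts[:, 1].max())
    x0, y0, x1, y1 = extent_m
    scale_m = scale_cm_px / 100.0
    n_cols = max(1, int(math.ceil((x1 - x0) / scale_m)))
    n_rows = max(1, int(math.ceil((y1 - y0) / scale_m)))
    cols = np.floor((pts[:, 0] - x0) / scale_m).astype(int)
    rows_ = np.floor((y1 - pts[:, 1]) / scale_m).astype(int)
    ok = (cols >= 0) & (cols < n_cols) & (rows_ >= 0) & (rows_ < n_rows)
    counts = np.zeros((n_rows, n_cols), dtype=float)
    np.add.at(counts, (rows_[ok], cols[ok]), 1.0)

    sums, coverage = moving_window_sum(counts, window_px)
    raw = np.where(coverage > 0, sums / coverage, 0.0)
    # window area in m^2: at 1 cm/px and window 100 this is exactly 1
    window_area_m2 = (window_px * scale_m) ** 2
    raw = raw / window_area_m2

    if sigma_px is None:
        sigma_px = window_px / 6.0
    k1 = gaussian_kernel_1d(sigma_px, radius=window_px // 2)
    smoothed = convolve1d(convolve1d(raw, k1, axis=0, mode="constant"),
                          k1, axis=1, mode="constant")
    return DensityMap(
        raw=raw,
        smoothed=smoothed,
        extent_m=extent_m,
        scale_cm_px=scale_cm_px,
        window_px=window_px,
        kernel=np.outer(k1, k1),
    )


def compute_image_stats(
    rec: ImageRecord,
    dets: Sequence[Detection],
    rows: Sequence[RowModel],
    gap_threshold_cm: float = 50.0,
    length_basis: str = "row_span",
) -> ImageStats:
    """Per-image statistics from rotated (row-horizontal) detections and rows.

    Each detection is assigned to its perpendicular-nearest row; per-row
    density uses the row's inlier x-span as its length when rows do not
    traverse the full image (``length_basis='row_span'``), or the image
    width (``'image_width'``, the textbook form).  Gaps are detected on
    the projected along-row positions in cm.
    """
    c_i = len(dets)
    d_i = image_density(c_i, rec.width, rec.height, rec.gsd_cm_px)
    row_stats: list[RowStats] = []
    if rows and dets:
        assignment, positions = assign_to_nearest_row(dets, rows)
    else:
        assignment = np.zeros(0, dtype=int)
        positions = np.zeros(0, dtype=float)
    for ridx, row in enumerate(rows):
        mask = assignment == ridx
        c_r = int(mask.sum())
        if length_basis == "image_width":
            length_px = float(rec.width)
            span_lo_px = 0.0
        else:
            length_px = max(row.x_span[1] - row.x_span[0], 1.0)
            span_lo_px = 0.0  # positions are already measured from x_span min
        dens = row_density(c_r, length_px, rec.gsd_cm_px)
        pos_cm = np.sort(positions[mask]) * rec.gsd_cm_px
        gaps = detect_gaps(
            pos_cm,
            (span_lo_px, length_px * rec.gsd_cm_px),
            threshold_cm=gap_threshold_cm,
            row_id=ridx,
        )
        row_stats.append(RowStats(
            row_id=ridx, count=c_r,
            length_m=length_px * rec.gsd_cm_px / 100.0,
            density_per_m=dens, gaps=tuple(gaps),
        ))
    return ImageStats(
        image_id=rec.image_id,
        rows=tuple(row_stats),
        count=c_i,
        density_per_m2=d_i,
        length_basis=length_basis,
    )
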