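"""Quasi-mosaic composition: GPS grid, nearest-image assignment, field detections.

A quasi-mosaic is a composite of the whole field built by placing rotated
crops of the raw UAV images into a GPS-anchored grid of cells — rough
stitching by camera position alone, with no feature matching or bundle
adjustment.  Overlap between consecutive captures is removed purely by
cell-exclusive cropping: each cell shows (and counts) content from exactly
one image, the one whose camera was nearest the cell center among those
whose footprint covers the cell.

Frames
------
``mosaic frame``: the field-local east/north frame rotated by
``-rotation_deg`` so that planting rows run horizontal (x axis).  A single
global rotation — the mean of the per-image dominant row directions — is
used for every image, so the pixel-to-field transform is shared and each
head falls in exactly one cell.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field as dc_field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from shapely import affinity
from shapely.geometry import box as shapely_box

from fieldheads.geo_io import Detection, ImageRecord, latlon_to_local

__all__ = [
    "FieldGrid",
    "build_grid",
    "assign_images",
    "compose_field_detections",
    "compose_mosaic_raster",
    "camera_positions_local",
    "mosaic_rotation_from_image_thetas",
    "footprint_extent",
]


@dataclass(frozen=True)
class FieldGrid:
    """GPS-anchored lattice of ``m_x x m_y`` meter cells in the mosaic frame.

    ``extent`` is (xmin, ymin, xmax, ymax) in mosaic meters; cell (i, j)
    is column i (west to east), row j (south to north); its center is
    ``origin + ((i + 0.5) m_x, (j + 0.5) m_y)``.  ``cell_assignment`` maps
    (i, j) to the image chosen to fill that cell; cells with no covering
    footprint are absent.
    """

    m_x: float
    m_y: float
    extent: tuple[float, float, float, float]
    n_cols: int
    n_rows: int
    ref_lat: float
    ref_lon: float
    rotation_deg: float = 0.0
    cell_assignment: dict[tuple[int, int], str] = dc_field(default_factory=dict)

    def cell_center(self, i: int, j: int) -> tuple[float, float]:
        x0, y0, _, _ = self.extent
        return (x0 + (i + 0.5) * self.m_x, y0 + (j + 0.5) * self.m_y)

    def cell_bounds(self, i: int, j: int) -> tuple[float, float, float, float]:
        cx, cy = self.cell_center(i, j)
        return (cx - self.m_x / 2, cy - self.m_y / 2,
                cx + self.m_x / 2, cy + self.m_y / 2)

    def cell_of(self, x: float, y: float) -> tuple[int, int]:
        x0, y0, _, _ = self.extent
        return (int(math.floor((x - x0) / self.m_x)),
                int(math.floor((y - y0) / self.m_y)))


def _rotate_to_mosaic(x: np.ndarray, y: np.ndarray, rotation_deg: float
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Apply R(-rotation) to east/north coordinates."""
    th = math.radians(rotation_deg)
    c, s = math.cos(th), math.sin(th)
    return c * x + s * y, -s * x + c * y


def mosaic_rotation_from_image_thetas(thetas_deg: Sequence[float]) -> float:
    """Global field rotation from per-image dominant row directions.

    An image-frame row angle theta (pixel frame, y down) corresponds to a
    field orientation of ``-theta`` (y flips between the frames); the
    mosaic frame is rotated by the circular mean of those orientations so
    rows run horizontal.  Angles are averaged as undirected lines (mod
    180 degrees).
    """
    if len(thetas_deg) == 0:
        return 0.0
    doubled = np.radians(2.0 * np.asarray(thetas_deg, dtype=float))
    mean = math.degrees(math.atan2(np.sin(doubled).mean(), np.cos(doubled).mean())) / 2.0
    return -mean


def camera_positions_local(
    images: Sequence[ImageRecord], ref_lat: float, ref_lon: float,
    rotation_deg: float = 0.0,
) -> np.ndarray:
    """(n, 2) camera positions in the mosaic frame."""
    lats = np.array([r.lat for r in images], dtype=float)
    lons = np.array([r.lon for r in images], dtype=float)
    if np.isnan(lats).any() or np.isnan(lons).any():
        raise ValueError("every image needs camera GPS for mosaic composition")
    x, y = latlon_to_local(lats, lons, ref_lat, ref_lon)
    xm, ym = _rotate_to_mosaic(x, y, rotation_deg)
    return np.stack([np.atleast_1d(xm), np.atleast_1d(ym)], axis=1)


def _footprint_polygon(rec: ImageRecord, cam_xy: tuple[float, float],
                       rotation_deg: float):
    """Footprint rectangle in the mosaic frame (axis-aligned in east/north,
    then rotated into the mosaic frame; camera yaw additionally rotates it)."""
    fw, fh = rec.footprint_m
    poly = shapely_box(cam_xy[0] - fw / 2, cam_xy[1] - fh / 2,
                       cam_xy[0] + fw / 2, cam_xy[1] + fh / 2)
    total = (rec.yaw_deg or 0.0) - rotation_deg
    if total:
        poly = affinity.rotate(poly, total, origin=cam_xy)
    return poly


def footprint_extent(
    images: Sequence[ImageRecord], ref_lat: float, ref_lon: float,
    rotation_deg: float = 0.0,
) -> tuple[float, float, float, float]:
    """Bounding box of all image footprints in the mosaic frame."""
    cams = camera_positions_local(images, ref_lat, ref_lon, rotation_deg)
    xs, ys = [], []
    for rec, cam in zip(images, cams):
        poly = _footprint_polygon(rec, tuple(cam), rotation_deg)
        x0, y0, x1, y1 = poly.bounds
        xs += [x0, x1]
        ys += [y0, y1]
    return (min(xs), min(ys), max(xs), max(ys))


def build_grid(
    extent: tuple[float, float, float, float],
    m_x: float,
    m_y: float,
    ref_lat: float = float("nan"),
    ref_lon: float = float("nan"),
    rotation_deg: float = 0.0,
) -> FieldGrid:
    """Lay a ceil(width/m_x) x ceil(height/m_y) cell lattice over the extent."""
    if m_x <= 0 or m_y <= 0:
        raise ValueError("cell sizes must be positive")
    x0, y0, x1, y1 = extent
    if not (x1 > x0 and y1 > y0):
        raise ValueError("degenerate extent")
    n_cols = math.ceil((x1 - x0) / m_x)
    n_rows = math.ceil((y1 - y0) / m_y)
    if n_cols == 1 and (x1 - x0) < m_x or n_rows == 1 and (y1 - y0) < m_y:
        warnings.warn("cell size exceeds field extent; grid collapses to one cell",
                      stacklevel=2)
    return FieldGrid(
        m_x=m_x, m_y=m_y, extent=extent, n_cols=n_cols, n_rows=n_rows,
        ref_lat=ref_lat, ref_lon=ref_lon, rotation_deg=rotation_deg,
    )


def assign_images(grid: FieldGrid, images: Sequence[ImageRecord]) -> FieldGrid:
    """Assign to each cell the nearest camera whose footprint covers the cell.

    "Covers" means the whole cell rectangle lies inside the image
    footprint, so the cell can be filled without blank corners.  Distance
    is camera-to-cell-center in the mosaic frame; ties go to the
    lexicographically lower image id.  Cells no footprint covers stay
    unassigned.
    """
    if not images:
        raise ValueError("need at least one image")
    order = np.argsort([r.image_id for r in images], kind="stable")
    images = [images[i] for i in order]
    cams = camera_positions_local(images, grid.ref_lat, grid.ref_lon,
                                  grid.rotation_deg)
    polys = [_footprint_polygon(rec, tuple(cam), grid.rotation_deg)
             for rec, cam in zip(images, cams)]
    assignment: dict[tuple[int, int], str] = {}
    for i in range(grid.n_cols):
        for j in range(grid.n_rows):
            cell = shapely_box(*grid.cell_bounds(i, j))
            cx, cy = grid.cell_center(i, j)
            best_id: str | None = None
            best_d = math.inf
            for rec, cam, poly in zip(images, cams, polys):
                if not poly.covers(cell):
                    continue
                d = math.hypot(cam[0] - cx, cam[1] - cy)
                if d < best_d:  # sorted by id, so strict < gives the tie rule
                    best_d = d
                    best_id = rec.image_id
            if best_id is not None:
                assignment[(i, j)] = best_id
    return replace(grid, cell_assignment=assignment)


def detection_field_positions(
    dets: Sequence[Detection], rec: ImageRecord, cam_xy: tuple[float, float],
    rotation_deg: float,
) -> np.ndarray:
    """Map detection centers from image pixels to mosaic-frame meters.

    Exact inverse of the nadir camera model: pixel offsets from the
    principal point scale by the GSD, camera yaw rotates them into
    east/north, and the global mosaic rotation is applied last.
    """
    if not dets:
        return np.empty((0, 2), dtype=float)
    centers = np.array([d.center for d in dets], dtype=float)
    gsd_m = rec.gsd_cm_px / 100.0
    fe = (centers[:, 0] - rec.width / 2.0) * gsd_m
    fn = -(centers[:, 1] - rec.height / 2.0) * gsd_m
    yaw = math.radians(rec.yaw_deg or 0.0)
    c, s = math.cos(yaw), math.sin(yaw)
    de = c * fe - s * fn
    dn = s * fe + c * fn
    # camera position is already in the mosaic frame; rotate only the offsets
    ox, oy = _rotate_to_mosaic(de, dn, rotation_deg)
    return np.stack([cam_xy[0] + ox, cam_xy[1] + oy], axis=1)


def compose_field_detections(
    grid: FieldGrid,
    dets_by_image: Mapping[str, Sequence[Detection]],
    images: Sequence[ImageRecord],
) -> pd.DataFrame:
    """Compose the field-frame detection set, one cell at a time.

    For each assigned cell, the assigned image's detections are projected
    into mosaic meters and kept only if they fall inside the cell
    (half-open bounds, so a detection on a shared edge belongs to exactly
    one cell).  Because every cell draws from a single image, heads seen
    by several overlapping captures are counted once — overlap removal by
    construction, with no cross-image box merging.

    Returns a DataFrame with columns ``east_m, north_m, cell_i, cell_j,
    source_image, confidence`` (plus ``head_id`` where the detections
    carry ground-truth provenance).
    """
    rec_by_id = {r.image_id: r for r in images}
    missing = [img for img in grid.cell_assignment.values() if img not in rec_by_id]
    if missing:
        raise KeyError(f"assigned images missing metadata: {sorted(set(missing))}")
    cams = camera_positions_local(
        [rec_by_id[i] for i in sorted(rec_by_id)], grid.ref_lat, grid.ref_lon,
        grid.rotation_deg)
    cam_by_id = dict(zip(sorted(rec_by_id), (tuple(c) for c in cams)))
    rows: list[dict] = []
    for (i, j), image_id in sorted(grid.cell_assignment.items()):
        rec = rec_by_id[image_id]
        dets = list(dets_by_image.get(image_id, ()))
        if not dets:
            continue
        pos = detection_field_positions(dets, rec, cam_by_id[image_id],
                                        grid.rotation_deg)
        x0, y0, x1, y1 = grid.cell_bounds(i, j)
        inside = (pos[:, 0] >= x0) & (pos[:, 0] < x1) & \
                 (pos[:, 1] >= y0) & (pos[:, 1] < y1)
        for k in np.flatnonzero(inside):
            d = dets[k]
            row = {
                "east_m": pos[k, 0],
                "north_m": pos[k, 1],
                "cell_i": i,
                "cell_j": j,
                "source_image": image_id,
                "confidence": d.confidence,
            }
            if "head_id" in d.extra:
                row["head_id"] = d.extra["head_id"]
            rows.append(row)
    columns = ["east_m", "north_m", "cell_i", "cell_j", "source_image", "confidence"]
    if any("head_id" in r for r in rows):
        columns.append("head_id")
    return pd.DataFrame(rows, columns=columns)


def compose_mosaic_raster(
    grid: FieldGrid,
    rasters: Mapping[str, np.ndarray],
    images: Sequence[ImageRecord],
    out_gsd_cm_px: float = 1.0,
) -> np.ndarray:
    """Render the quasi-mosaic raster: each cell is the rotated, cropped
    patch of its assigned image, sampled at ``out_gsd_cm_px``.

    The canvas row 0 is the field's north edge (image convention).  Cells
    whose image has no raster are left blank with a warning.
    """
    from scipy.ndimage import map_coordinates

    rec_by_id = {r.image_id: r for r in images}
    cams = camera_positions_local(
        [rec_by_id[i] for i in sorted(rec_by_id)], grid.ref_lat, grid.ref_lon,
        grid.rotation_deg)
    cam_by_id = dict(zip(sorted(rec_by_id), (tuple(c) for c in cams)))
    x0, y0, x1, y1 = grid.extent
    scale_m = out_gsd_cm_px / 100.0
    out_w = int(math.ceil((x1 - x0) / scale_m))
    out_h = int(math.ceil((y1 - y0) / scale_m))
    canvas = np.zeros((out_h, out_w), dtype=float)
    th = math.radians(grid.rotation_deg)
    c_r, s_r = math.cos(th), math.sin(th)
    for (i, j), image_id in sorted(grid.cell_assignment.items()):
        if image_id not in rasters:
            warnings.warn(f"no raster for {image_id}; cell ({i},{j}) left blank",
                          stacklevel=2)
            continue
        rec = rec_by_id[image_id]
        cam = cam_by_id[image_id]
        bx0, by0, bx1, by1 = grid.cell_bounds(i, j)
        px0 = max(0, int(math.floor((bx0 - x0) / scale_m)))
        px1 = min(out_w, int(math.ceil((bx1 - x0) / scale_m)))
        py0 = max(0, int(math.floor((y1 - by1) / scale_m)))
        py1 = min(out_h, int(math.ceil((y1 - by0) / scale_m)))
        if px0 >= px1 or py0 >= py1:
            continue
        jj, ii = np.mgrid[py0:py1, px0:px1]
        mx = x0 + (ii + 0.5) * scale_m
        my = y1 - (jj + 0.5) * scale_m
        # mosaic -> east/north (inverse of R(-rotation)), minus camera
        dx, dy = mx - cam[0], my - cam[1]
        de = c_r * dx - s_r * dy
        dn = s_r * dx + c_r * dy
        yaw = math.radians(rec.yaw_deg or 0.0)
        cy_, sy_ = math.cos(yaw), math.sin(yaw)
        fe = cy_ * de + sy_ * dn
        fn = -sy_ * de + cy_ * dn
        gsd_m = rec.gsd_cm_px / 100.0
        src_x = fe / gsd_m + rec.width / 2.0
        src_y = -fn / gsd_m + rec.height / 2.0
        patch = map_coordinates(np.asarray(rasters[image_id], dtype=float),
                                [src_y, src_x], order=1, mode="constant", cval=0.0)
        canvas[py0:py1, px0:px1] = patch
    return canvas


def write_grid_manifest(grid: FieldGrid, path: str | Path) -> None:
    doc = {
        "m_x": grid.m_x,
        "m_y": grid.m_y,
        "extent": list(grid.extent),
        "n_cols": grid.n_cols,
        "n_rows": grid.n_rows,
        "ref_lat": grid.ref_lat,
        "ref_lon": grid.ref_lon,
        "rotation_deg": grid.rotation_deg,
        "cell_assignment": {f"{i},{j}": img
                            for (i, j), img in sorted(grid.cell_assignment.items())},
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)
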