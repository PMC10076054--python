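"""Detection and geo-metadata I/O, GSD calibration, and image-frame preprocessing.

Conventions
-----------
Pixel frame: 0-based, origin at the top-left corner, x to the right, y
downward.  Bounding boxes are half-open, ``[x_min, x_max) x [y_min, y_max)``.
Field-local frame: meters, x east, y north, anchored at a reference
latitude/longitude via an equirectangular projection (fields span well under
a kilometer, so projection curvature is negligible).

Ground sampling distance (GSD) is expressed in cm per pixel throughout.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

EARTH_RADIUS_M = 6_371_000.0

__all__ = [
    "Detection",
    "ImageRecord",
    "compute_gsd",
    "center_crop",
    "rescale_to_gsd",
    "latlon_to_local",
    "local_to_latlon",
    "read_detections",
    "write_detections",
    "read_image_records",
    "write_image_records",
    "detections_to_array",
    "gaussian_blur_match",
    "DetectionParseError",
]


class DetectionParseError(ValueError):
    """Raised when a detection file is malformed; names the offending record."""


@dataclass(frozen=True)
class Detection:
    """One bounding box with confidence, in image pixel coordinates."""

    image_id: str
    x_min: float
    y_min: float
    x_max: float
    y_max: float
    confidence: float = 1.0
    extra: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        if not (self.x_max > self.x_min and self.y_max > self.y_min):
            raise ValueError(
                f"degenerate box for image {self.image_id!r}: "
                f"({self.x_min},{self.y_min},{self.x_max},{self.y_max})"
            )
        if not 0.0 <= self.confidence <= 1.0:
            raise ValueError(f"confidence {self.confidence} outside [0,1]")

    @property
    def center(self) -> tuple[float, float]:
        return ((self.x_min + self.x_max) / 2.0, (self.y_min + self.y_max) / 2.0)

    @property
    def width(self) -> float:
        return self.x_max - self.x_min

    @property
    def height(self) -> float:
        return self.y_max - self.y_min


@dataclass(frozen=True)
class ImageRecord:
    """Image geometry, GSD and camera GPS for one capture.

    ``lat``/``lon`` locate the camera (principal point at nadir) in WGS84
    degrees; ``yaw_deg`` is an optional camera heading.
    """

    image_id: str
    width: int
    height: int
    gsd_cm_px: float
    lat: float = float("nan")
    lon: float = float("nan")
    yaw_deg: float | None = None

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValueError("image dimensions must be positive")
        if not self.gsd_cm_px > 0:
            raise ValueError("GSD must be positive")

    @property
    def footprint_m(self) -> tuple[float, float]:
        """Ground footprint (east, north extent) in meters."""
        return (self.width * self.gsd_cm_px / 100.0,
                self.height * self.gsd_cm_px / 100.0)


def compute_gsd(ref_width_px: float, ref_width_cm: float) -> float:
    """Calibrate ground sampling distance from a reference object of known size.

    A flat reference marker of known physical width (e.g. a 30 x 15 cm board
    laid in the field) measured in the image gives the cm-per-pixel scale.

    Parameters
    ----------
    ref_width_px : measured width of the reference object in pixels.
    ref_width_cm : physical width of the reference object in cm.

    Returns
    -------
    GSD in cm per pixel.
    """
    if ref_width_px <= 0 or ref_width_cm <= 0:
        raise ValueError("reference measurements must be positive")
    return ref_width_cm / ref_width_px


def center_crop(
    rec: ImageRecord,
    dets: Sequence[Detection],
    edge_fraction: float = 0.10,
) -> tuple[ImageRecord, list[Detection]]:
    """Remove an ``edge_fraction`` margin from each side of the image.

    Retains the central ``1 - 2*edge_fraction`` of each dimension.  A
    detection survives iff its center lies inside the retained window; the
    surviving boxes are clipped to the window and shifted to the new origin.
    UAV imagery is most distorted near frame edges, hence the crop.
    """
    if not 0.0 <= edge_fraction < 0.5:
        raise ValueError("edge_fraction must be in [0, 0.5)")
    x0 = edge_fraction * rec.width
    y0 = edge_fraction * rec.height
    x1 = rec.width - x0
    y1 = rec.height - y0
    new_rec = replace(
        rec,
        width=int(round(x1 - x0)),
        height=int(round(y1 - y0)),
    )
    kept: list[Detection] = []
    for d in dets:
        cx, cy = d.center
        if not (x0 <= cx < x1 and y0 <= cy < y1):
            continue
        kept.append(
            replace(
                d,
                x_min=max(d.x_min, x0) - x0,
                y_min=max(d.y_min, y0) - y0,
                x_max=min(d.x_max, x1) - x0,
                y_max=min(d.y_max, y1) - y0,
            )
        )
    return new_rec, kept


def rescale_to_gsd(
    rec: ImageRecord,
    dets: Sequence[Detection],
    target_gsd_cm_px: float,
) -> tuple[ImageRecord, list[Detection]]:
    """Rescale pixel coordinates so the image has the target GSD.

    The scale factor is ``s = G / target_G``; physical positions
    (pixels x GSD) are preserved exactly.  Used to match a deployment
    image's resolution to the resolution a detector was trained at.
    """
    if target_gsd_cm_px <= 0:
        raise ValueError("target GSD must be positive")
    s = rec.gsd_cm_px / target_gsd_cm_px
    new_rec = replace(
        rec,
        width=int(round(rec.width * s)),
        height=int(round(rec.height * s)),
        gsd_cm_px=target_gsd_cm_px,
    )
    scaled = [
        replace(d, x_min=d.x_min * s, y_min=d.y_min * s,
                x_max=d.x_max * s, y_max=d.y_max * s)
        for d in dets
    ]
    return new_rec, scaled


# ---------------------------------------------------------------------------
# Local planar projection

def latlon_to_local(
    lat: float | np.ndarray,
    lon: float | np.ndarray,
    ref_lat: float,
    ref_lon: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Project WGS84 degrees to local planar meters (x east, y north).

    Equirectangular about the reference point: ``x = R cos(ref_lat) dlon``,
    ``y = R dlat`` with R = 6,371,000 m.  Accurate to well under a
    centimeter over the sub-kilometer extents of a single field.
    """
    lat = np.asarray(lat, dtype=float)
    lon = np.asarray(lon, dtype=float)
    if np.any(np.abs(lat) > 90.0) or abs(ref_lat) > 90.0:
        raise ValueError("latitude outside [-90, 90]")
    x = EARTH_RADIUS_M * math.cos(math.radians(ref_lat)) * np.radians(lon - ref_lon)
    y = EARTH_RADIUS_M * np.radians(lat - ref_lat)
    return x, y


def local_to_latlon(
    x_east_m: float | np.ndarray,
    y_north_m: float | np.ndarray,
    ref_lat: float,
    ref_lon: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Inverse of :func:`latlon_to_local`."""
    x = np.asarray(x_east_m, dtype=float)
    y = np.asarray(y_north_m, dtype=float)
    lat = ref_lat + np.degrees(y / EARTH_RADIUS_M)
    lon = ref_lon + np.degrees(
        x / (EARTH_RADIUS_M * math.cos(math.radians(ref_lat)))
    )
    return lat, lon


# ---------------------------------------------------------------------------
# Detection file I/O

_CSV_HEADER = ["image_id", "x_min", "y_min", "x_max", "y_max", "confidence"]


def _detect_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        return fmt
    return "coco_json" if path.suffix.lower() == ".json" else "csv"


def read_detections(path: str | Path, fmt: str | None = None) -> list[Detection]:
    """Read detections from COCO-style JSON or flat CSV.

    COCO dialect: top-level ``images`` (id, file_name, width, height),
    ``annotations`` (image_id, bbox as ``[x, y, w, h]``, score) and
    ``categories``.  CSV dialect: header
    ``image_id,x_min,y_min,x_max,y_max,confidence``.
    """
    path = Path(path)
    fmt = _detect_format(path, fmt)
    if fmt == "coco_json":
        return _read_coco(path)
    if fmt == "csv":
        return _read_csv(path)
    raise ValueError(f"unknown detection format {fmt!r}")


def _read_coco(path: Path) -> list[Detection]:
    with open(path) as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as exc:
            raise DetectionParseError(f"{path}: invalid JSON: {exc}") from exc
    id_to_name = {img["id"]: str(img.get("file_name", img["id"]))
                  for img in doc.get("images", [])}
    out: list[Detection] = []
    for k, ann in enumerate(doc.get("annotations", [])):
        try:
            x, y, w, h = ann["bbox"]
            image_id = id_to_name.get(ann["image_id"], str(ann["image_id"]))
            out.append(
                Detection(
                    image_id=image_id,
                    x_min=float(x),
                    y_min=float(y),
                    x_max=float(x) + float(w),
                    y_max=float(y) + float(h),
                    confidence=float(ann.get("score", 1.0)),
                    extra={key: v for key, v in ann.items()
                           if key not in ("bbox", "image_id", "score", "id",
                                          "category_id")},
                )
            )
        except (KeyError, TypeError, ValueError) as exc:
            raise DetectionParseError(
                f"{path}: annotation {k}: {exc}"
            ) from exc
    return out


def _read_csv(path: Path) -> list[Detection]:
    out: list[Detection] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        missing = set(_CSV_HEADER[:-1]) - set(reader.fieldnames or [])
        if missing:
            raise DetectionParseError(f"{path}: missing columns {sorted(missing)}")
        for k, row in enumerate(reader):
            try:
                extra_keys = set(row) - set(_CSV_HEADER)
                out.append(
                    Detection(
                        image_id=row["image_id"],
                        x_min=float(row["x_min"]),
                        y_min=float(row["y_min"]),
                        x_max=float(row["x_max"]),
                        y_max=float(row["y_max"]),
                        confidence=float(row.get("confidence") or 1.0),
                        extra={k2: row[k2] for k2 in sorted(extra_keys)},
                    )
                )
            except ValueError as exc:
                raise DetectionParseError(f"{path}: record {k}: {exc}") from exc
    return out


def write_detections(
    dets: Iterable[Detection], path: str | Path, fmt: str | None = None
) -> None:
    """Write detections; the written file round-trips through
    :func:`read_detections` losslessly."""
    path = Path(path)
    fmt = _detect_format(path, fmt)
    dets = list(dets)
    if fmt == "csv":
        extra_keys = sorted({k for d in dets for k in d.extra})
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(_CSV_HEADER + extra_keys)
            for d in dets:
                writer.writerow(
                    [d.image_id, repr(float(d.x_min)), repr(float(d.y_min)),
                     repr(float(d.x_max)), repr(float(d.y_max)),
                     repr(float(d.confidence))]
                    + [d.extra.get(k, "") for k in extra_keys]
                )
        return
    if fmt == "coco_json":
        names = sorted({d.image_id for d in dets})
        name_to_id = {n: i + 1 for i, n in enumerate(names)}
        doc = {
            "images": [{"id": i, "file_name": n} for n, i in name_to_id.items()],
            "categories": [{"id": 1, "name": "head"}],
            "annotations": [
                {
                    "id": k + 1,
                    "image_id": name_to_id[d.image_id],
                    "category_id": 1,
                    "bbox": [d.x_min, d.y_min, d.width, d.height],
                    "score": d.confidence,
                    **d.extra,
                }
                for k, d in enumerate(dets)
            ],
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=1)
        return
    raise ValueError(f"unknown detection format {fmt!r}")


_META_HEADER = ["image_id", "width", "height", "gsd_cm_px", "lat", "lon", "yaw_deg"]


def read_image_records(path: str | Path) -> list[ImageRecord]:
    """Read the metadata CSV (image_id,width,height,gsd_cm_px,lat,lon[,yaw_deg])."""
    out: list[ImageRecord] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        missing = set(_META_HEADER[:4]) - set(reader.fieldnames or [])
        if missing:
            raise DetectionParseError(f"{path}: missing columns {sorted(missing)}")
        for k, row in enumerate(reader):
            try:
                yaw = row.get("yaw_deg")
                out.append(
                    ImageRecord(
                        image_id=row["image_id"],
                        width=int(row["width"]),
                        height=int(row["height"]),
                        gsd_cm_px=float(row["gsd_cm_px"]),
                        lat=float(row.get("lat") or "nan"),
                        lon=float(row.get("lon") or "nan"),
                        yaw_deg=float(yaw) if yaw not in (None, "") else None,
                    )
                )
            except ValueError as exc:
                raise DetectionParseError(f"{path}: record {k}: {exc}") from exc
    return out


def write_image_records(recs: Iterable[ImageRecord], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_META_HEADER)
        for r in recs:
            writer.writerow(
                [r.image_id, r.width, r.height, repr(float(r.gsd_cm_px)),
                 repr(float(r.lat)), repr(float(r.lon)),
                 "" if r.yaw_deg is None else repr(float(r.yaw_deg))]
            )


def detections_to_array(dets: Sequence[Detection]) -> np.ndarray:
    """Stack detection centers into an (n, 2) float array of (x, y) pixels."""
    if not dets:
        return np.empty((0, 2), dtype=float)
    return np.array([d.center for d in dets], dtype=float)


def gaussian_blur_match(
    raster: np.ndarray, source_gsd_cm_px: float, target_gsd_cm_px: float
) -> np.ndarray:
    """Blur a higher-resolution raster to emulate a coarser GSD.

    Heuristic resolution matching: sigma = target_G / source_G pixels.  A
    no-op when the target is not coarser than the source.  Operates on
    rasters only; detections are unaffected.
    """
    from scipy.ndimage import gaussian_filter

    if source_gsd_cm_px <= 0 or target_gsd_cm_px <= 0:
        raise ValueError("GSDs must be positive")
    if target_gsd_cm_px <= source_gsd_cm_px:
        return np.asarray(raster, dtype=float)
    sigma = target_gsd_cm_px / source_gsd_cm_px
    return gaussian_filter(np.asarray(raster, dtype=float), sigma=sigma)
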