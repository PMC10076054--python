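"""Synthetic sorghum-field simulator: ground truth, captures, detector noise.

Generates a field of parallel planting rows (default 75 cm spacing, the
standard sorghum sowing configuration), places grain heads along each row
by a homogeneous 1-D Poisson process with Gaussian cross-row jitter,
carves out planting gaps, simulates overlapping nadir camera captures
with GPS, and corrupts the resulting ground-truth boxes with configurable
detector noise (misses, false positives, box jitter).  It stands in for a
trained deep detector so every downstream stage has a known-answer test
bed.

Field-local coordinates are meters, x east, y north.  GPS is synthesized
by anchoring the field origin at a reference latitude/longitude and
converting with the same equirectangular projection used everywhere else
in the package.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.stats import truncnorm

from fieldheads.geo_io import Detection, ImageRecord, local_to_latlon, latlon_to_local

__all__ = [
    "RowSpec",
    "FieldConfig",
    "FieldTruth",
    "CaptureConfig",
    "DetectorNoise",
    "generate_field",
    "capture_images",
    "corrupt_detections",
    "render_image",
    "write_truth",
    "read_truth",
]


@dataclass(frozen=True)
class RowSpec:
    """One planting row: a sown line segment in field-local meters."""

    index: int
    origin_x_m: float
    origin_y_m: float
    orientation_deg: float
    length_m: float

    @property
    def direction(self) -> tuple[float, float]:
        th = math.radians(self.orientation_deg)
        return (math.cos(th), math.sin(th))

    @property
    def normal(self) -> tuple[float, float]:
        th = math.radians(self.orientation_deg)
        return (-math.sin(th), math.cos(th))

    def point_at(self, along_m: float, cross_m: float = 0.0) -> tuple[float, float]:
        ux, uy = self.direction
        nx, ny = self.normal
        return (
            self.origin_x_m + along_m * ux + cross_m * nx,
            self.origin_y_m + along_m * uy + cross_m * ny,
        )


@dataclass(frozen=True)
class FieldConfig:
    """Parameters of the simulated field.

    Defaults emulate a commercial sorghum trial: 75 cm row spacing, rows a
    few tens of meters long, 4-8 heads per meter of row (about 5-10 heads
    per square meter, consistent with ~80 k plants/ha sowing density), and
    2 cm of cross-row scatter.  ``gap_spans`` lists (row_index, start_m,
    end_m) intervals with no plants, emulating sowing skips.
    """

    n_rows: int = 8
    row_spacing_m: float = 0.75
    row_length_m: float = 20.0
    orientation_deg: float = 0.0
    heads_per_m: float = 5.0
    cross_jitter_sd_m: float = 0.02
    gap_spans: tuple[tuple[int, float, float], ...] = ()
    head_diameter_cm: float = 8.0
    ref_lat: float = -27.45
    ref_lon: float = 151.53
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.row_spacing_m <= 0 or self.row_length_m <= 0:
            raise ValueError("field geometry must be positive")
        if self.heads_per_m < 0:
            raise ValueError("head density must be non-negative")
        if self.head_diameter_cm <= 0:
            raise ValueError("head diameter must be positive")


@dataclass(frozen=True)
class FieldTruth:
    """Ground truth for one simulated field.

    ``head_positions`` holds (row_index, along_row_m, cross_jitter_m)
    triples; field coordinates follow from the row geometry.
    """

    row_specs: tuple[RowSpec, ...]
    row_spacing_m: float
    head_positions: tuple[tuple[int, float, float], ...]
    gap_spans: tuple[tuple[int, float, float], ...]
    head_diameter_cm: float
    ref_lat: float
    ref_lon: float
    seed: int

    @property
    def n_heads(self) -> int:
        return len(self.head_positions)

    def row_counts(self) -> dict[int, int]:
        counts = {spec.index: 0 for spec in self.row_specs}
        for row_idx, _, _ in self.head_positions:
            counts[row_idx] += 1
        return counts

    def head_coords(self) -> np.ndarray:
        """(n, 2) array of head field-local (east, north) meters."""
        specs = {s.index: s for s in self.row_specs}
        if not self.head_positions:
            return np.empty((0, 2), dtype=float)
        return np.array(
            [specs[r].point_at(along, cross) for r, along, cross in self.head_positions],
            dtype=float,
        )

    def extent(self, margin_m: float = 0.5) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) bounding the rows, padded by ``margin_m``."""
        pts = []
        for s in self.row_specs:
            pts.append(s.point_at(0.0))
            pts.append(s.point_at(s.length_m))
        arr = np.array(pts, dtype=float)
        return (
            float(arr[:, 0].min() - margin_m),
            float(arr[:, 1].min() - margin_m),
            float(arr[:, 0].max() + margin_m),
            float(arr[:, 1].max() + margin_m),
        )


@dataclass(frozen=True)
class CaptureConfig:
    """Camera and flight parameters for simulated nadir captures.

    Footprint side lengths in meters are ``image dimension x GSD / 100``.
    When ``flight_path`` (a tuple of (lat, lon) camera positions) is not
    given, a serpentine path covering the field with the requested forward
    and side ``overlap_fraction`` is planned automatically.
    """

    gsd_cm_px: float = 0.25
    image_w_px: int = 2000
    image_h_px: int = 1500
    overlap_fraction: float = 0.2
    flight_path: tuple[tuple[float, float], ...] | None = None
    camera_yaw_deg: float = 0.0
    margin_m: float = 1.5

    def __post_init__(self) -> None:
        if self.gsd_cm_px <= 0:
            raise ValueError("GSD must be positive")
        if self.image_w_px <= 0 or self.image_h_px <= 0:
            raise ValueError("zero-area footprint: image dimensions must be positive")
        if not 0.0 <= self.overlap_fraction < 1.0:
            raise ValueError("overlap_fraction must be in [0, 1)")

    @property
    def footprint_m(self) -> tuple[float, float]:
        return (
            self.image_w_px * self.gsd_cm_px / 100.0,
            self.image_h_px * self.gsd_cm_px / 100.0,
        )


@dataclass(frozen=True)
class DetectorNoise:
    """Error model for a simulated head detector.

    ``fn_prob`` drops each true box independently; ``fp_rate_per_m2`` adds
    spurious boxes by a Poisson process over the footprint area; survivors'
    centers are jittered by an isotropic Gaussian.  Confidence scores are
    truncated-normal in [0, 1], false positives drawn with a lower mean so
    precision-recall sweeps are non-degenerate.
    """

    fp_rate_per_m2: float = 0.0
    fn_prob: float = 0.0
    box_jitter_px_sd: float = 0.0
    tp_confidence: tuple[float, float] = (0.85, 0.08)
    fp_confidence: tuple[float, float] = (0.45, 0.15)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fp_rate_per_m2 < 0 or self.box_jitter_px_sd < 0:
            raise ValueError("rates must be non-negative")
        if not 0.0 <= self.fn_prob <= 1.0:
            raise ValueError("fn_prob must be in [0, 1]")


def generate_field(config: FieldConfig) -> FieldTruth:
    """Simulate a field: parallel rows, Poisson head placement, gaps.

    Row ``i`` is offset ``i * row_spacing_m`` along the shared row normal
    from the field origin.  Head counts per row are Poisson with intensity
    ``heads_per_m x row_length_m``; positions are uniform along the row,
    then any head falling inside one of that row's gap spans is removed
    (thinning, so the retained process is Poisson on the planted span).
    Deterministic and bit-identical for a fixed config.
    """
    rng = np.random.default_rng(config.seed)
    th = math.radians(config.orientation_deg)
    nx, ny = -math.sin(th), math.cos(th)
    specs = tuple(
        RowSpec(
            index=i,
            origin_x_m=i * config.row_spacing_m * nx,
            origin_y_m=i * config.row_spacing_m * ny,
            orientation_deg=config.orientation_deg,
            length_m=config.row_length_m,
        )
        for i in range(config.n_rows)
    )
    gaps_by_row: dict[int, list[tuple[float, float]]] = {}
    for row_idx, start, end in config.gap_spans:
        gaps_by_row.setdefault(row_idx, []).append((start, end))
    heads: list[tuple[int, float, float]] = []
    for spec in specs:
        count = rng.poisson(config.heads_per_m * spec.length_m)
        along = np.sort(rng.uniform(0.0, spec.length_m, size=count))
        cross = rng.normal(0.0, config.cross_jitter_sd_m, size=count)
        for a, c in zip(along, cross):
            if any(lo < a < hi for lo, hi in gaps_by_row.get(spec.index, [])):
                continue
            heads.append((spec.index, float(a), float(c)))
    return FieldTruth(
        row_specs=specs,
        row_spacing_m=config.row_spacing_m,
        head_positions=tuple(heads),
        gap_spans=config.gap_spans,
        head_diameter_cm=config.head_diameter_cm,
        ref_lat=config.ref_lat,
        ref_lon=config.ref_lon,
        seed=config.seed,
    )


def _plan_camera_positions(truth: FieldTruth, cap: CaptureConfig) -> np.ndarray:
    """Serpentine grid of camera centers covering the field extent.

    The planned coverage extends ``margin_m`` beyond the outermost rows so
    that, even after center-cropping, every grid cell containing a head
    can fall fully inside at least one footprint."""
    fw, fh = cap.footprint_m
    xmin, ymin, xmax, ymax = truth.extent(cap.margin_m)
    step_x = fw * (1.0 - cap.overlap_fraction)
    step_y = fh * (1.0 - cap.overlap_fraction)
    n_x = max(1, math.ceil((xmax - xmin - fw) / step_x) + 1) if xmax - xmin > fw else 1
    n_y = max(1, math.ceil((ymax - ymin - fh) / step_y) + 1) if ymax - ymin > fh else 1
    xs = xmin + fw / 2.0 + step_x * np.arange(n_x)
    ys = ymin + fh / 2.0 + step_y * np.arange(n_y)
    positions = []
    for j, y in enumerate(ys):
        order = xs if j % 2 == 0 else xs[::-1]  # serpentine, as a UAV flies it
        positions.extend((x, y) for x in order)
    return np.array(positions, dtype=float)


def capture_images(
    truth: FieldTruth, cap: CaptureConfig
) -> list[tuple[ImageRecord, list[Detection]]]:
    """Simulate nadir captures; each head inside a footprint yields one box.

    Boxes are squares of side ``head_diameter_cm / GSD`` pixels centered
    on the head, in the capturing image's pixel frame (origin top-left, x
    right, y down; north maps to -y).  Heads inside overlap regions appear
    in every covering image.  Each detection carries its ground-truth head
    index in ``extra['head_id']``.
    """
    if cap.flight_path is not None:
        lats = np.array([p[0] for p in cap.flight_path])
        lons = np.array([p[1] for p in cap.flight_path])
        ex, ny_ = latlon_to_local(lats, lons, truth.ref_lat, truth.ref_lon)
        cams = np.stack([ex, ny_], axis=1)
    else:
        cams = _plan_camera_positions(truth, cap)
    fw, fh = cap.footprint_m
    if fw <= 0 or fh <= 0:
        raise ValueError("zero-area footprint")
    coords = truth.head_coords()
    box_px = truth.head_diameter_cm / cap.gsd_cm_px
    gsd_m = cap.gsd_cm_px / 100.0
    yaw = math.radians(cap.camera_yaw_deg)
    cos_y, sin_y = math.cos(yaw), math.sin(yaw)
    out: list[tuple[ImageRecord, list[Detection]]] = []
    for k, (ce, cn) in enumerate(cams):
        image_id = f"img_{k:03d}"
        lat, lon = local_to_latlon(ce, cn, truth.ref_lat, truth.ref_lon)
        rec = ImageRecord(
            image_id=image_id,
            width=cap.image_w_px,
            height=cap.image_h_px,
            gsd_cm_px=cap.gsd_cm_px,
            lat=float(lat),
            lon=float(lon),
            yaw_deg=cap.camera_yaw_deg if cap.camera_yaw_deg else None,
        )
        dets: list[Detection] = []
        for head_id in range(coords.shape[0]):
            de = coords[head_id, 0] - ce
            dn = coords[head_id, 1] - cn
            # rotate world offsets into the camera frame (yaw), then to pixels
            fe = cos_y * de + sin_y * dn
            fn_ = -sin_y * de + cos_y * dn
            px = fe / gsd_m + cap.image_w_px / 2.0
            py = -fn_ / gsd_m + cap.image_h_px / 2.0
            if 0.0 <= px < cap.image_w_px and 0.0 <= py < cap.image_h_px:
                dets.append(
                    Detection(
                        image_id=image_id,
                        x_min=px - box_px / 2.0,
                        y_min=py - box_px / 2.0,
                        x_max=px + box_px / 2.0,
                        y_max=py + box_px / 2.0,
                        confidence=1.0,
                        extra={"head_id": head_id},
                    )
                )
        out.append((rec, dets))
    return out


def corrupt_detections(
    gt: Sequence[Detection],
    noise: DetectorNoise,
    rec: ImageRecord,
    rng: np.random.Generator | None = None,
) -> list[Detection]:
    """Apply the detector error model to a ground-truth detection set.

    Each true box survives with probability ``1 - fn_prob``; survivors'
    centers are jittered.  False positives are added at
    ``fp_rate_per_m2 x footprint area`` with box sizes matching the median
    true box (falling back to 20 px for an empty input).  Deterministic
    given the noise seed; pass ``rng`` to share a stream across images.
    """
    if rng is None:
        rng = np.random.default_rng(noise.seed)
    out: list[Detection] = []

    def _confidence(mean: float, sd: float, n: int) -> np.ndarray:
        if sd == 0:
            return np.full(n, mean)
        a, b = (0.0 - mean) / sd, (1.0 - mean) / sd
        return truncnorm.rvs(a, b, loc=mean, scale=sd, size=n, random_state=rng)

    keep = rng.random(len(gt)) >= noise.fn_prob
    survivors = [d for d, k in zip(gt, keep) if k]
    conf = _confidence(*noise.tp_confidence, len(survivors))
    for d, c in zip(survivors, conf):
        jx, jy = (rng.normal(0.0, noise.box_jitter_px_sd, size=2)
                  if noise.box_jitter_px_sd > 0 else (0.0, 0.0))
        out.append(
            Detection(
                image_id=d.image_id,
                x_min=d.x_min + jx,
                y_min=d.y_min + jy,
                x_max=d.x_max + jx,
                y_max=d.y_max + jy,
                confidence=float(np.clip(c, 0.0, 1.0)),
                extra=dict(d.extra),
            )
        )
    fw, fh = rec.footprint_m
    n_fp = rng.poisson(noise.fp_rate_per_m2 * fw * fh)
    if n_fp > 0:
        if gt:
            size = float(np.median([d.width for d in gt]))
        else:
            size = 20.0
        cx = rng.uniform(0.0, rec.width, size=n_fp)
        cy = rng.uniform(0.0, rec.height, size=n_fp)
        conf_fp = _confidence(*noise.fp_confidence, n_fp)
        for x, y, c in zip(cx, cy, conf_fp):
            out.append(
                Detection(
                    image_id=rec.image_id,
                    x_min=x - size / 2.0,
                    y_min=y - size / 2.0,
                    x_max=x + size / 2.0,
                    y_max=y + size / 2.0,
                    confidence=float(np.clip(c, 0.0, 1.0)),
                    extra={"is_fp": True},
                )
            )
    return out


def render_image(
    rec: ImageRecord,
    truth: FieldTruth,
    background: float = 0.1,
    peak: float = 1.0,
) -> np.ndarray:
    """Render a simple grayscale raster of the heads seen by one capture.

    Heads are drawn as Gaussian blobs (sigma = a quarter of the head
    diameter in pixels) on a uniform background.  Intended for
    documentation figures and for exercising blob-counting oracles, not
    for photorealism.
    """
    ce, cn = latlon_to_local(rec.lat, rec.lon, truth.ref_lat, truth.ref_lon)
    ce, cn = float(ce), float(cn)
    gsd_m = rec.gsd_cm_px / 100.0
    img = np.full((rec.height, rec.width), background, dtype=float)
    coords = truth.head_coords()
    sigma_px = truth.head_diameter_cm / rec.gsd_cm_px / 4.0
    half = int(math.ceil(3 * sigma_px))
    yaw = math.radians(rec.yaw_deg or 0.0)
    cos_y, sin_y = math.cos(yaw), math.sin(yaw)
    for e, n in coords:
        de, dn = e - ce, n - cn
        fe = cos_y * de + sin_y * dn
        fn_ = -sin_y * de + cos_y * dn
        px = fe / gsd_m + rec.width / 2.0
        py = -fn_ / gsd_m + rec.height / 2.0
        if not (-half <= px < rec.width + half and -half <= py < rec.height + half):
            continue
        x0, x1 = max(0, int(px) - half), min(rec.width, int(px) + half + 1)
        y0, y1 = max(0, int(py) - half), min(rec.height, int(py) + half + 1)
        if x0 >= x1 or y0 >= y1:
            continue
        yy, xx = np.mgrid[y0:y1, x0:x1]
        img[y0:y1, x0:x1] += peak * np.exp(
            -((xx - px) ** 2 + (yy - py) ** 2) / (2.0 * sigma_px**2)
        )
    return img


# ---------------------------------------------------------------------------
# Truth manifest

def write_truth(truth: FieldTruth, path: str | Path) -> None:
    """Serialize the ground-truth manifest to JSON (row lines, head field
    coordinates, gaps)."""
    doc = {
        "row_spacing_m": truth.row_spacing_m,
        "head_diameter_cm": truth.head_diameter_cm,
        "ref_lat": truth.ref_lat,
        "ref_lon": truth.ref_lon,
        "seed": truth.seed,
        "row_specs": [asdict(s) for s in truth.row_specs],
        "head_positions": [list(h) for h in truth.head_positions],
        "gap_spans": [list(g) for g in truth.gap_spans],
        "head_coords_m": [[float(e), float(n)] for e, n in truth.head_coords()],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


def read_truth(path: str | Path) -> FieldTruth:
    with open(path) as fh:
        doc = json.load(fh)
    return FieldTruth(
        row_specs=tuple(RowSpec(**s) for s in doc["row_specs"]),
        row_spacing_m=doc["row_spacing_m"],
        head_positions=tuple((int(r), float(a), float(c))
                             for r, a, c in doc["head_positions"]),
        gap_spans=tuple((int(r), float(s), float(e))
                        for r, s, e in doc["gap_spans"]),
        head_diameter_cm=doc["head_diameter_cm"],
        ref_lat=doc["ref_lat"],
        ref_lon=doc["ref_lon"],
        seed=doc["seed"],
    )
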