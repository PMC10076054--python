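"""End-to-end orchestration: simulate -> preprocess -> rows -> mosaic -> stats -> eval.

Each stage reads and writes plain files (CSV/JSON/NPY) under the run
directory, so any stage can be resumed from a previous run's outputs and
every artifact is inspectable and diffable.  A run manifest records the
config hash, seeds, and per-stage record counts; identical configs give
byte-identical statistics outputs.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from fieldheads import config as config_mod
from fieldheads import density, evaluation, geo_io, mosaic, rows as rows_mod, synthetic

log = logging.getLogger("fieldheads")

STAGES = ["simulate", "preprocess", "rows", "mosaic", "stats", "eval"]

__all__ = ["run_pipeline", "StageError", "STAGES"]


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _ransac_params(cfg: dict) -> rows_mod.RansacParams:
    r = cfg["ransac"]
    t = r.get("t")
    if t is None:
        spacing_px = cfg["field"]["row_spacing_m"] * 100.0 / cfg["preprocess"]["target_gsd_cm_px"]
        t = 0.35 * spacing_px
    return rows_mod.RansacParams(n=r["n"], k=r["k"], t=float(t), d=r["d"],
                                 seed=cfg["seed"])


def stage_simulate(cfg: dict, out: Path) -> dict:
    field_cfg = dict(cfg["field"])
    field_cfg["gap_spans"] = tuple(tuple(g) for g in field_cfg.get("gap_spans", []))
    field_cfg["seed"] = cfg["seed"]
    truth = synthetic.generate_field(synthetic.FieldConfig(**field_cfg))
    cap = synthetic.CaptureConfig(**cfg["capture"])
    captures = synthetic.capture_images(truth, cap)
    noise_cfg = dict(cfg["noise"])
    noise_cfg["seed"] = cfg["seed"] + 1
    noise = synthetic.DetectorNoise(**noise_cfg)
    rng = np.random.default_rng(noise.seed)
    recs, gt_all, noisy_all = [], [], []
    for rec, gt in captures:
        recs.append(rec)
        gt_all.extend(gt)
        noisy_all.extend(synthetic.corrupt_detections(gt, noise, rec, rng=rng))
    synthetic.write_truth(truth, out / "truth.json")
    geo_io.write_image_records(recs, out / "meta.csv")
    geo_io.write_detections(gt_all, out / "detections_gt.csv")
    geo_io.write_detections(noisy_all, out / "detections.csv")
    log.info("simulate: %d heads, %d images, %d gt boxes, %d noisy boxes",
             truth.n_heads, len(recs), len(gt_all), len(noisy_all))
    return {"heads": truth.n_heads, "images": len(recs),
            "gt_boxes": len(gt_all), "noisy_boxes": len(noisy_all)}


def stage_preprocess(cfg: dict, out: Path) -> dict:
    recs = geo_io.read_image_records(out / "meta.csv")
    dets = geo_io.read_detections(out / "detections.csv")
    by_image: dict[str, list] = {r.image_id: [] for r in recs}
    for d in dets:
        by_image.setdefault(d.image_id, []).append(d)
    new_recs, new_dets = [], []
    for rec in recs:
        r2, d2 = geo_io.center_crop(rec, by_image.get(rec.image_id, []),
                                    cfg["preprocess"]["edge_fraction"])
        r3, d3 = geo_io.rescale_to_gsd(r2, d2, cfg["preprocess"]["target_gsd_cm_px"])
        new_recs.append(r3)
        new_dets.extend(d3)
    geo_io.write_image_records(new_recs, out / "meta_pre.csv")
    geo_io.write_detections(new_dets, out / "detections_pre.csv")
    log.info("preprocess: kept %d/%d boxes", len(new_dets), len(dets))
    return {"images": len(new_recs), "boxes": len(new_dets)}


def stage_rows(cfg: dict, out: Path) -> dict:
    recs = geo_io.read_image_records(out / "meta_pre.csv")
    dets = geo_io.read_detections(out / "detections_pre.csv")
    by_image: dict[str, list] = {r.image_id: [] for r in recs}
    for d in dets:
        by_image.setdefault(d.image_id, []).append(d)
    params = _ransac_params(cfg)
    rng = np.random.default_rng(params.seed)
    tol = cfg["rows"]["direction_tol_deg"]
    doc: dict = {"params": {"n": params.n, "k": params.k, "t": params.t,
                            "d": params.d, "seed": params.seed},
                 "images": {}}
    n_rows_total = 0
    for rec in recs:
        img_dets = by_image.get(rec.image_id, [])
        centers = geo_io.detections_to_array(img_dets)
        entry: dict = {"theta_deg": None, "rows": []}
        if centers.shape[0] >= params.n:
            try:
                theta = rows_mod.dominant_direction(centers, rec, params, rng)
            except rows_mod.InsufficientDataError:
                theta = None
            if theta is not None:
                detected = rows_mod.detect_rows(centers, params, rng)
                detected = rows_mod.filter_rows_by_direction(
                    detected, theta, tol, points=centers, params=params, rng=rng)
                rotated, rot = rows_mod.rotate_to_horizontal(img_dets, rec, theta)
                entry = {
                    "theta_deg": theta,
                    "rotation_center": list(rot.center_xy),
                    "rows": [
                        {"a": r.a, "b": r.b, "x_span": list(r.x_span),
                         "inlier_ids": list(r.inlier_ids)}
                        for r in detected
                    ],
                }
                n_rows_total += len(detected)
        doc["images"][rec.image_id] = entry
    with open(out / "rows.json", "w") as fh:
        json.dump(doc, fh, indent=1)
    log.info("rows: %d rows across %d images", n_rows_total, len(recs))
    return {"images": len(recs), "rows": n_rows_total}


def stage_mosaic(cfg: dict, out: Path) -> dict:
    recs = geo_io.read_image_records(out / "meta_pre.csv")
    dets = geo_io.read_detections(out / "detections_pre.csv")
    with open(out / "rows.json") as fh:
        rows_doc = json.load(fh)
    thetas = [e["theta_deg"] for e in rows_doc["images"].values()
              if e["theta_deg"] is not None]
    rotation = mosaic.mosaic_rotation_from_image_thetas(thetas)
    ref_lat = cfg["field"]["ref_lat"]
    ref_lon = cfg["field"]["ref_lon"]
    extent = mosaic.footprint_extent(recs, ref_lat, ref_lon, rotation)
    smallest = min(min(r.footprint_m) for r in recs)
    cell = cfg["mosaic"]["cell_fraction"] * smallest
    grid = mosaic.build_grid(extent, cell, cell, ref_lat, ref_lon, rotation)
    grid = mosaic.assign_images(grid, recs)
    by_image: dict[str, list] = {r.image_id: [] for r in recs}
    for d in dets:
        by_image.setdefault(d.image_id, []).append(d)
    field_dets = mosaic.compose_field_detections(grid, by_image, recs)
    field_dets.to_csv(out / "field_detections.csv", index=False)
    mosaic.write_grid_manifest(grid, out / "grid.json")
    log.info("mosaic: %d x %d cells (%d assigned), %d field detections",
             grid.n_cols, grid.n_rows, len(grid.cell_assignment), len(field_dets))
    return {"cells": grid.n_cols * grid.n_rows,
            "assigned_cells": len(grid.cell_assignment),
            "field_detections": len(field_dets)}


def stage_stats(cfg: dict, out: Path) -> dict:
    recs = geo_io.read_image_records(out / "meta_pre.csv")
    dets = geo_io.read_detections(out / "detections_pre.csv")
    with open(out / "rows.json") as fh:
        rows_doc = json.load(fh)
    s = cfg["stats"]
    by_image: dict[str, list] = {r.image_id: [] for r in recs}
    for d in dets:
        by_image.setdefault(d.image_id, []).append(d)
    frames, gap_rows = [], []
    for rec in recs:
        entry = rows_doc["images"][rec.image_id]
        if entry["theta_deg"] is None:
            continue
        rotated, _ = rows_mod.rotate_to_horizontal(
            by_image.get(rec.image_id, []), rec, entry["theta_deg"])
        # refit rows in the rotated frame so projections are along-row
        centers = geo_io.detections_to_array(rotated)
        params = _ransac_params(cfg)
        detected = rows_mod.detect_rows(centers, params,
                                        np.random.default_rng(params.seed))
        stats = density.compute_image_stats(
            rec, rotated, detected,
            gap_threshold_cm=s["gap_threshold_cm"],
            length_basis=s["length_basis"],
        )
        frames.append(stats.to_frame())
        for r in stats.rows:
            for g in r.gaps:
                gap_rows.append({"image_id": rec.image_id, "row_id": g.row_id,
                                 "start_cm": g.start_cm, "end_cm": g.end_cm,
                                 "length_cm": g.length_cm})
    image_stats = (pd.concat(frames, ignore_index=True) if frames
                   else pd.DataFrame())
    image_stats.to_csv(out / "image_stats.csv", index=False)
    pd.DataFrame(gap_rows, columns=["image_id", "row_id", "start_cm",
                                    "end_cm", "length_cm"]
                 ).to_csv(out / "gaps.csv", index=False)
    field_dets = pd.read_csv(out / "field_detections.csv")
    with open(out / "grid.json") as fh:
        grid_doc = json.load(fh)
    dmap = density.field_density_map(
        field_dets, tuple(grid_doc["extent"]),
        window_px=s["window_px"], scale_cm_px=s["scale_cm_px"])
    np.save(out / "density_map.npy", dmap.smoothed)
    with open(out / "density_map_meta.json", "w") as fh:
        json.dump({"extent_m": list(dmap.extent_m),
                   "scale_cm_px": dmap.scale_cm_px,
                   "window_px": dmap.window_px,
                   "max_heads_m2": float(dmap.smoothed.max()),
                   "length_basis": s["length_basis"]}, fh, indent=1)
    _render_heatmap(dmap, out / "density_map.png")
    log.info("stats: %d image-rows, %d gaps, density max %.2f heads/m2",
             len(image_stats), len(gap_rows), float(dmap.smoothed.max()))
    return {"image_rows": len(image_stats), "gaps": len(gap_rows),
            "density_max": float(dmap.smoothed.max())}


def _render_heatmap(dmap: density.DensityMap, path: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 5))
    x0, y0, x1, y1 = dmap.extent_m
    im = ax.imshow(dmap.smoothed, extent=(x0, x1, y0, y1), cmap="viridis")
    fig.colorbar(im, ax=ax, label="heads / m$^2$")
    ax.set_xlabel("east (m)")
    ax.set_ylabel("north (m)")
    ax.set_title("Field head density")
    fig.savefig(path, dpi=100, bbox_inches="tight")
    plt.close(fig)


def stage_eval(cfg: dict, out: Path) -> dict:
    recs = geo_io.read_image_records(out / "meta.csv")
    gt = geo_io.read_detections(out / "detections_gt.csv")
    pred = geo_io.read_detections(out / "detections.csv")
    gt_by, pred_by = {}, {}
    for d in gt:
        gt_by.setdefault(d.image_id, []).append(d)
    for d in pred:
        pred_by.setdefault(d.image_id, []).append(d)
    results, pred_counts, true_counts, rows_csv = [], [], [], []
    for rec in recs:
        g = gt_by.get(rec.image_id, [])
        p = pred_by.get(rec.image_id, [])
        pred_counts.append(len(p))
        true_counts.append(len(g))
        if g:
            results.append(evaluation.match(p, g, cfg["eval"]["iou_thresh"]))
        rows_csv.append({"image_id": rec.image_id, "pred": len(p), "true": len(g)})
    mae, rmse = evaluation.count_errors(pred_counts, true_counts)
    # pool matches across images for one field-level PR curve
    if results:
        pooled = evaluation.MatchResult(
            order=np.arange(sum(r.is_tp.size for r in results)),
            confidence=np.concatenate([r.confidence for r in results]),
            is_tp=np.concatenate([r.is_tp for r in results]),
            matched_gt=np.concatenate([r.matched_gt for r in results]),
            iou_value=np.concatenate([r.iou_value for r in results]),
            n_gt=sum(r.n_gt for r in results),
        )
        order = np.argsort(-pooled.confidence, kind="stable")
        pooled = replace_fields(pooled, order)
        ap, pr = evaluation.average_precision(pooled)
    else:
        ap, pr = float("nan"), np.zeros((0, 2))
    metrics = {"ap": ap, "mae": mae, "rmse": rmse,
               "iou_thresh": cfg["eval"]["iou_thresh"],
               "n_images": len(recs),
               "ap_interpolation": "all_point"}
    with open(out / "metrics.json", "w") as fh:
        json.dump(metrics, fh, indent=1)
    pd.DataFrame(rows_csv).to_csv(out / "per_image_counts.csv", index=False)
    np.savetxt(out / "pr_curve.csv", pr, delimiter=",",
               header="recall,precision", comments="")
    log.info("eval: AP=%.4f MAE=%.3f RMSE=%.3f", ap, mae, rmse)
    return {"ap": ap, "mae": mae, "rmse": rmse}


def replace_fields(result: evaluation.MatchResult, order: np.ndarray
                   ) -> evaluation.MatchResult:
    """Re-sort a pooled MatchResult by descending confidence."""
    return evaluation.MatchResult(
        order=order,
        confidence=result.confidence[order],
        is_tp=result.is_tp[order],
        matched_gt=result.matched_gt[order],
        iou_value=result.iou_value[order],
        n_gt=result.n_gt,
    )


_STAGE_FN = {
    "simulate": stage_simulate,
    "preprocess": stage_preprocess,
    "rows": stage_rows,
    "mosaic": stage_mosaic,
    "stats": stage_stats,
    "eval": stage_eval,
}


def run_pipeline(cfg: dict, out_dir: str | Path,
                 stages: list[str] | None = None) -> dict:
    """Execute the requested stages in order; returns the run manifest.

    Raises :class:`StageError` naming the failing stage; outputs of
    completed stages are retained.
    """
    errors, warns = config_mod.validate_config(cfg)
    for w in warns:
        log.warning("config: %s", w)
    if errors:
        raise ValueError("invalid config: " + "; ".join(errors))
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages = stages or STAGES
    unknown = [s for s in stages if s not in _STAGE_FN]
    if unknown:
        raise ValueError(f"unknown stages: {unknown}")
    manifest: dict = {
        "config_hash": config_mod.config_hash(cfg),
        "seed": cfg["seed"],
        "stages": {},
    }
    config_mod.save_config(cfg, out / "config.yaml")
    for stage in STAGES:
        if stage not in stages:
            continue
        try:
            manifest["stages"][stage] = _STAGE_FN[stage](cfg, out)
        except Exception as exc:  # noqa: BLE001 - report the failing stage
            with open(out / "manifest.json", "w") as fh:
                json.dump(manifest, fh, indent=1)
            raise StageError(stage, exc) from exc
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest
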