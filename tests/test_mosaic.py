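import math

import numpy as np
import pytest

import fieldheads as fh
from fieldheads import mosaic
from fieldheads.mosaic import (
    assign_images,
    build_grid,
    compose_field_detections,
    compose_mosaic_raster,
    footprint_extent,
    mosaic_rotation_from_image_thetas,
)


def rec_at(e, n, image_id="img", w=400, h=300, gsd=1.0, ref=(0.0, 0.0)):
    lat, lon = fh.local_to_latlon(e, n, *ref)
    return fh.ImageRecord(image_id, w, h, gsd, float(lat), float(lon))


class TestBuildGrid:
    def test_even_division(self):
        grid = build_grid((0, 0, 10, 10), 2.0, 2.0)
        assert (grid.n_cols, grid.n_rows) == (5, 5)
        assert grid.cell_center(0, 0) == (1.0, 1.0)

    def test_single_cell(self):
        grid = build_grid((0, 0, 10, 10), 10.0, 10.0)
        assert (grid.n_cols, grid.n_rows) == (1, 1)

    def test_ceiling_rule(self):
        grid = build_grid((0, 0, 10.5, 10), 2.0, 2.0)
        assert (grid.n_cols, grid.n_rows) == (6, 5)

    def test_oversized_cell_warns(self):
        with pytest.warns(UserWarning):
            build_grid((0, 0, 3, 3), 5.0, 5.0)

    def test_rejects_bad_input(self):
        with pytest.raises(ValueError):
            build_grid((0, 0, 10, 10), -1.0, 2.0)
        with pytest.raises(ValueError):
            build_grid((5, 5, 5, 10), 1.0, 1.0)


class TestAssignImages:
    def test_single_image_covers_all(self):
        rec = rec_at(0.0, 0.0, w=1000, h=1000)  # 10 x 10 m footprint
        grid = build_grid((-4, -4, 4, 4), 2.0, 2.0, 0.0, 0.0)
        grid = assign_images(grid, [rec])
        assert set(grid.cell_assignment.values()) == {"img"}
        assert len(grid.cell_assignment) == grid.n_cols * grid.n_rows

    def test_equidistant_tie_lower_id_wins(self):
        recs = [rec_at(-1.0, 0.0, "img_a", w=1000, h=1000),
                rec_at(1.0, 0.0, "img_b", w=1000, h=1000)]
        grid = build_grid((-1, -1, 1, 1), 2.0, 2.0, 0.0, 0.0)
        grid = assign_images(grid, recs)
        assert grid.cell_assignment[(0, 0)] == "img_a"

    def test_matches_exhaustive_search(self):
        """6x6 grid, 4 overlapping captures: assignment equals the
        brute-force nearest-covering search."""
        cams = [(-2.0, -2.0), (2.0, -2.0), (-2.0, 2.0), (2.0, 2.0)]
        recs = [rec_at(e, n, f"img_{k}", w=900, h=900)
                for k, (e, n) in enumerate(cams)]
        grid = build_grid((-6, -6, 6, 6), 2.0, 2.0, 0.0, 0.0)
        grid = assign_images(grid, recs)
        for i in range(6):
            for j in range(6):
                x0, y0, x1, y1 = grid.cell_bounds(i, j)
                cx, cy = grid.cell_center(i, j)
                best, best_d = None, math.inf
                for k, (ce, cn) in enumerate(cams):
                    covers = (ce - 4.5 <= x0 and x1 <= ce + 4.5
                              and cn - 4.5 <= y0 and y1 <= cn + 4.5)
                    d = math.hypot(ce - cx, cn - cy)
                    if covers and d < best_d:
                        best, best_d = f"img_{k}", d
                assert grid.cell_assignment.get((i, j)) == best

    def test_uncovered_cells_left_empty(self):
        rec = rec_at(0.0, 0.0, w=400, h=400)  # 4 x 4 m footprint
        grid = build_grid((-10, -10, 10, 10), 2.0, 2.0, 0.0, 0.0)
        grid = assign_images(grid, [rec])
        assert 0 < len(grid.cell_assignment) < grid.n_cols * grid.n_rows

    def test_requires_gps(self):
        rec = fh.ImageRecord("img", 100, 100, 1.0)  # lat/lon NaN
        grid = build_grid((0, 0, 1, 1), 1.0, 1.0, 0.0, 0.0)
        with pytest.raises(ValueError):
            assign_images(grid, [rec])


class TestComposeFieldDetections:
    def test_single_image_single_cell_arithmetic(self):
        rec = rec_at(0.0, 0.0, w=400, h=400, gsd=1.0)  # 4 x 4 m
        grid = build_grid((-1.5, -1.5, 1.5, 1.5), 3.0, 3.0, 0.0, 0.0)
        grid = assign_images(grid, [rec])
        d = fh.Detection("img", 195, 95, 205, 105)  # center (200, 100)
        out = compose_field_detections(grid, {"img": [d]}, [rec])
        assert len(out) == 1
        # (200, 100) px at 1 cm/px from a 400x400 image centered on the
        # camera: east = 0, north = +1 m
        assert out.iloc[0]["east_m"] == pytest.approx(0.0)
        assert out.iloc[0]["north_m"] == pytest.approx(1.0)

    def test_overlap_head_appears_once(self, small_truth, capture_cfg):
        captures = fh.capture_images(small_truth, capture_cfg)
        recs = [r for r, _ in captures]
        dets = {r.image_id: d for r, d in captures}
        extent = footprint_extent(recs, small_truth.ref_lat, small_truth.ref_lon)
        cell = 0.35 * min(min(r.footprint_m) for r in recs)
        grid = build_grid(extent, cell, cell,
                          small_truth.ref_lat, small_truth.ref_lon)
        grid = assign_images(grid, recs)
        out = compose_field_detections(grid, dets, recs)
        assert out["head_id"].value_counts().max() == 1

    def test_full_coverage_conserves_count(self, small_truth, capture_cfg):
        """Noiseless detector + full coverage: field detections = truth heads."""
        captures = fh.capture_images(small_truth, capture_cfg)
        recs = [r for r, _ in captures]
        dets = {r.image_id: d for r, d in captures}
        extent = footprint_extent(recs, small_truth.ref_lat, small_truth.ref_lon)
        cell = 0.35 * min(min(r.footprint_m) for r in recs)
        grid = build_grid(extent, cell, cell,
                          small_truth.ref_lat, small_truth.ref_lon)
        grid = assign_images(grid, recs)
        out = compose_field_detections(grid, dets, recs)
        assert len(out) == small_truth.n_heads

    def test_positions_match_truth(self, small_truth, capture_cfg):
        captures = fh.capture_images(small_truth, capture_cfg)
        recs = [r for r, _ in captures]
        dets = {r.image_id: d for r, d in captures}
        extent = footprint_extent(recs, small_truth.ref_lat, small_truth.ref_lon)
        cell = 0.35 * min(min(r.footprint_m) for r in recs)
        grid = build_grid(extent, cell, cell,
                          small_truth.ref_lat, small_truth.ref_lon)
        grid = assign_images(grid, recs)
        out = compose_field_detections(grid, dets, recs).sort_values("head_id")
        coords = small_truth.head_coords()
        got = out[["east_m", "north_m"]].to_numpy()
        want = coords[out["head_id"].to_numpy(dtype=int)]
        assert np.abs(got - want).max() < 1e-6

    def test_missing_metadata_is_linkage_error(self):
        grid = build_grid((0, 0, 2, 2), 2.0, 2.0, 0.0, 0.0)
        grid = mosaic.FieldGrid(**{**grid.__dict__,
                                   "cell_assignment": {(0, 0): "ghost"}})
        with pytest.raises(KeyError):
            compose_field_detections(grid, {}, [rec_at(0, 0)])


class TestRotationHandling:
    def test_global_rotation_makes_rows_horizontal(self):
        """With a rotated field, composing under the mean dominant direction
        puts each truth row at constant mosaic-y."""
        truth = fh.generate_field(fh.FieldConfig(
            n_rows=4, row_length_m=8.0, heads_per_m=5.0,
            orientation_deg=10.0, seed=21))
        cap = fh.CaptureConfig(gsd_cm_px=0.5, image_w_px=1200, image_h_px=1000,
                               overlap_fraction=0.5)
        captures = fh.capture_images(truth, cap)
        recs = [r for r, _ in captures]
        dets = {r.image_id: d for r, d in captures}
        rotation = mosaic_rotation_from_image_thetas([-10.0] * len(recs))
        extent = footprint_extent(recs, truth.ref_lat, truth.ref_lon, rotation)
        cell = 0.3 * min(min(r.footprint_m) for r in recs)
        grid = build_grid(extent, cell, cell, truth.ref_lat, truth.ref_lon,
                          rotation)
        grid = assign_images(grid, recs)
        out = compose_field_detections(grid, dets, recs)
        labels = np.array([truth.head_positions[int(h)][0]
                           for h in out["head_id"]])
        for row_idx in np.unique(labels):
            spread = out["north_m"].to_numpy()[labels == row_idx].std()
            assert spread < 0.05  # only cross-row jitter remains


class TestComposeMosaicRaster:
    def test_single_image_identity_crop(self):
        rec = rec_at(0.0, 0.0, w=200, h=200, gsd=1.0)  # 2 x 2 m
        raster = np.arange(200 * 200, dtype=float).reshape(200, 200)
        grid = build_grid((-1.0, -1.0, 1.0, 1.0), 2.0, 2.0, 0.0, 0.0)
        grid = assign_images(grid, [rec])
        out = compose_mosaic_raster(grid, {"img": raster}, [rec], out_gsd_cm_px=1.0)
        assert out.shape == (200, 200)
        # interior pixels reproduce the source (bilinear at half-pixel offsets)
        assert np.allclose(out[50:150, 50:150], raster[50:150, 50:150], atol=260)

    def test_blank_cell_without_raster(self):
        rec = rec_at(0.0, 0.0, w=200, h=200, gsd=1.0)
        grid = build_grid((-1.0, -1.0, 1.0, 1.0), 2.0, 2.0, 0.0, 0.0)
        grid = assign_images(grid, [rec])
        with pytest.warns(UserWarning):
            out = compose_mosaic_raster(grid, {}, [rec])
        assert np.all(out == 0.0)

    def test_rows_continuous_across_cells(self):
        """Adjacent cells filled from different images keep each row's
        y-position within a quarter of the row spacing."""
        truth = fh.generate_field(fh.FieldConfig(
            n_rows=3, row_length_m=6.0, heads_per_m=5.0, seed=31))
        cap = fh.CaptureConfig(gsd_cm_px=1.0, image_w_px=400, image_h_px=300,
                               overlap_fraction=0.5)
        captures = fh.capture_images(truth, cap)
        recs = [r for r, _ in captures]
        dets = {r.image_id: d for r, d in captures}
        extent = footprint_extent(recs, truth.ref_lat, truth.ref_lon)
        grid = build_grid(extent, 1.5, 1.5, truth.ref_lat, truth.ref_lon)
        grid = assign_images(grid, recs)
        out = compose_field_detections(grid, dets, recs)
        labels = np.array([truth.head_positions[int(h)][0]
                           for h in out["head_id"]])
        for row_idx in np.unique(labels):
            ys = out["north_m"].to_numpy()[labels == row_idx]
            assert ys.max() - ys.min() < truth.row_spacing_m / 4
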