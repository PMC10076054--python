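# Methods

This note documents the models, conventions, parameter choices, and known
limitations of the `fieldheads` pipeline.

## Coordinate conventions

Pixel frames are 0-based with the origin at the top-left corner, x right,
y down; boxes are half-open `[min, max)`. Field-local coordinates are
meters, x east, y north, obtained from WGS84 degrees by an
equirectangular projection about a field reference point
(`x = R·cos(ref_lat)·Δλ`, `y = R·Δφ`, R = 6,371,000 m). Over the
sub-kilometer extent of a single field the projection error is far below
the GPS noise the quasi-mosaic already tolerates, so no geodesic library
is needed. The same projection is the single source of truth for both
the simulator (meters → synthesized GPS) and the mosaic (GPS → meters),
which is what makes the round trip exact in tests.

Ground sampling distance (GSD) is cm per pixel throughout, calibrated in
the field by imaging a reference object of known width (a 30 × 15 cm
board: `GSD = width_cm / width_px`).

## Image normalization

Deployment images are center-cropped (default: 10% of each dimension
removed from **each side**, retaining the central 80%; the fraction is a
parameter since "removing 10% edges" admits either per-side or total
readings) and then rescaled to a common GSD (default 0.25 cm/px) so that
a detector sees heads at its training scale. Crop precedes rescaling.
Both operations are affine on detections; physical positions
(pixels × GSD) are preserved exactly by rescaling. An optional raster
utility applies Gaussian blur with sigma = target_G/source_G px to
emulate a coarser sensor; this is a documented heuristic and never
touches detections.

## Row detection

Rows are lines `y = a·x + b` fitted to detection centers by iterative
RANSAC. Numerical choices:

- **Residual**: perpendicular point-to-line distance, not vertical
  offset — stable for steep slopes before rotation.
- **Acceptance**: a candidate is accepted when its full consensus set
  (minimal sample plus points within `t`) exceeds `d`. Gating on the
  consensus-only count would make small noiseless fixtures (e.g. three
  collinear points with `d = n = 2`) unsolvable.
- **Refit and re-collect**: accepted candidates are refitted by ordinary
  least squares on the consensus union, and inliers are re-collected
  against the refitted line. Without re-collection, a minimal sample that
  grazes part of a row at a slight angle can claim only a fragment,
  leaving the remainder to be detected as a phantom second row. The
  sampled points always remain inliers so iterative removal terminates.
- **Score**: mean perpendicular residual over the final inlier set;
  ties within 1e-9 break toward the larger inlier count, which makes the
  noiseless case deterministic and equivalent to exhaustive search over
  all point pairs (verified against that oracle).
- **Defaults**: `n = 2`, `k = 500`, `d = 5`, `t = 0.35 ×` the row spacing
  in pixels when the spacing is known (105 px for 75 cm rows at
  0.25 cm/px), else 10 px. These solve the default synthetic field with
  a wide margin; all are exposed in config. One seeded generator is
  threaded through all RANSAC calls and recorded in output metadata.

The **dominant direction** of an image is estimated by running RANSAC on
the centers inside the densest ⌈W/3⌉ × ⌈H/3⌉ sliding window (stride
W/10, H/10) — a dense patch almost surely contains a complete row
segment. The fit is attempted in both axis orders and the larger
consensus wins, so near-vertical rows (|θ| > 45°) never produce unstable
slopes. Detected rows deviating from the dominant direction by more than
10° (default) are discarded and their points refitted once; rows that
still disagree are dropped. Detections are then rotated by −θ about the
image center (boxes re-centered, not sheared) and the rotation recorded
for the mosaic.

Row-count monotonicity in the RANSAC parameters holds in the operating
regime: more required inliers (larger `d`) never yields more rows; a
larger threshold `t` never yields fewer rows *provided* `d` is strict
enough to reject row fragments. With a permissive `d`, a threshold below
the cross-row scatter fragments each physical row into many small
collinear subsets — a misconfiguration, not a detection regime.

## Quasi-mosaic

The mosaic frame is the field-local frame rotated by a single global
angle — the circular mean (mod 180°) of the per-image dominant
directions — so planting rows run horizontal across the composite. Using
one global rotation rather than per-image rotations means every image
shares the same pixel→field transform, so the cell partition is exact
and no head can be double-counted or lost at a cell boundary from
rotation disagreements between neighboring images.

Cells default to a square grid; the pipeline sizes cells at 50% of the
smallest image footprint side. Any fraction below
`(footprint − camera spacing) / footprint` guarantees that every cell is
fully covered by at least one footprint; 50% leaves headroom for the
inscribed-rectangle loss when footprints are rotated into the mosaic
frame. Each cell is assigned the nearest camera among those whose
footprint covers the *entire* cell (ties to the lexicographically lower
image id); cells with no covering footprint are left empty rather than
interpolated. Camera position is taken as the image principal point at
nadir with no tilt model — the "quasi" in quasi-mosaic.

Detections are mapped to field meters by inverting the nadir camera
model (pixel offset × GSD, optional yaw, global rotation, camera
translation) and kept only when they fall inside their cell's half-open
bounds. With a noiseless detector and full coverage the composed field
detection set equals the ground truth exactly (a test asserts equality,
not a tolerance).

## Density statistics

- `D_r = C_r/(W·G)` heads/cm, reported ×100 as heads/m;
  `D_i = C_i/(W·H·G²)` heads/cm², reported ×10⁴ as heads/m².
- Per-row length uses the row's inlier x-span by default, falling back
  conceptually to the image width (`length_basis="image_width"`) when
  rows traverse the full frame; the basis is recorded in the output.
- **Gaps**: consecutive-difference scan over sorted along-row positions,
  including the span edges; spans strictly longer than 50 cm (default)
  are reported. An empty row whose span exceeds the threshold is one
  whole-span gap — agronomically, a fully failed row is the largest gap
  there is. Note that a homogeneous Poisson planting at λ heads/m
  produces natural head-free spans >τ at rate e^(−λτ) per inter-head
  interval (8.2% at λ=5, τ=0.5 m; 3.0% at λ=7): "spurious" gaps at the
  50 cm threshold are a property of the planting process, not a detector
  artifact.
- **Row profiles**: 1 cm binning, 100 cm moving sum (stride 1 cm)
  truncated at row ends and renormalized by the covered fraction,
  divided by the window in meters to give heads/m, then smoothed by a
  sum-one Gaussian (σ = 25 cm). Window and sigma are exposed in config.
- **Field map**: centers rasterized at 1 cm/px; 100 × 100 px moving sum
  with stride 1 (so each value is heads per m²), boundary windows
  truncated and renormalized by coverage; smoothing by a separable
  Gaussian with σ = window/6 whose 2-D kernel sums to one, preserving
  the unit. The `interior` accessor excludes a margin of one window plus
  the kernel radius, the region free of any boundary handling. Raw maps
  are integer window counts and match a brute-force double-loop oracle
  exactly; the smoothed map matches direct convolution to 1e-9.

## Evaluation metrics

Greedy confidence-ordered matching at a fixed IoU threshold (0.5); each
detection claims the unmatched ground truth of highest IoU, ties to the
lower index. AP uses all-point interpolation (the single-threshold COCO
form) — the choice is recorded in the metrics output since 11-point
interpolation would differ slightly. MAE/RMSE are computed over paired
per-image counts.

## Synthetic data: what it does and does not emulate

The generator produces parallel rows at 75 cm spacing (the standard
sorghum configuration; defaults approximate an 80k plants/ha trial),
heads placed by a homogeneous 1-D Poisson process along each row
(default 5 heads/m) with Gaussian cross-row jitter (default sd 2 cm),
optional sown gaps carved out by thinning, overlapping nadir captures on
a serpentine flight path with synthesized GPS, and a detector error
model: independent misses (`fn_prob`), Poisson false positives per m²,
center jitter, and truncated-normal confidences with false positives
drawn from a lower mean so precision–recall sweeps are non-degenerate.
The flight plan extends 1.5 m beyond the outermost rows so that, even
after the 10% center crop, every grid cell containing a head lies fully
inside some footprint.

It does **not** emulate: photorealistic canopy appearance, illumination
or motion blur, perspective/tilt distortion, genotype or growth-stage
variation in head size, spatially correlated detector errors, or GPS
error. Passing tests therefore demonstrate the geometric and statistical
correctness of the pipeline — not detector robustness on real imagery,
where detection quality dominates end-to-end accuracy.

## Problem sizes

The test suite and acceptance studies run at deliberately moderate
scales chosen to exercise every code path with tight statistical bounds:
20 randomized fields (5–12 rows, 20 m, 4–8 heads/m) for row recovery;
300×300 px fields for brute-force oracle comparisons; 100–200 seeds for
Poisson/binomial calibration checks; and a 3-row field imaged by ~40
captures for the end-to-end determinism run. All bounds are 4-sigma
confidence intervals computed from closed forms, not tuned constants.

## Known limitations

- Rows are straight lines; curved or contour planting is out of scope.
- The quasi-mosaic trusts camera GPS; with real RTK noise, cell-boundary
  heads can be attributed to the wrong (but adjacent) cell.
- `detect_rows` assumes a single dominant orientation per image; fields
  with intersecting row systems (e.g. headlands) will be filtered to the
  dominant one.
- The detector error model is uncalibrated — error rates are free
  parameters, not fitted to any particular CNN.
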