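import numpy as np
import pytest

import fieldheads as fh


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_truth():
    """5-row, 10 m field with moderate density; deterministic."""
    return fh.generate_field(
        fh.FieldConfig(n_rows=5, row_length_m=10.0, heads_per_m=5.0, seed=42)
    )


@pytest.fixture
def capture_cfg():
    return fh.CaptureConfig(
        gsd_cm_px=0.25, image_w_px=1600, image_h_px=1200, overlap_fraction=0.5
    )


def field_points_px(truth, gsd_cm_px=0.25):
    """Project truth head coordinates into a y-down pixel frame."""
    coords = truth.head_coords()
    scale = gsd_cm_px / 100.0
    return np.stack([coords[:, 0] / scale, -coords[:, 1] / scale], axis=1)
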