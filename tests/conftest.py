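"""Shared fixtures: analytic wedge phantoms and hand-built contours."""

from __future__ import annotations

import numpy as np
import pytest

from octangle.phantom import contours_from_truth, render_phantom, wedge_spec
from octangle.segmentation import (
    AngleContours,
    binarize_per_column,
    extract_angle_contours,
    fill_holes,
    preprocess,
)

SCALE = 31.3  # μm/pixel of the reference device


@pytest.fixture
def wedge():
    """Factory: noise-free analytic wedge phantom at a given opening angle."""

    def make(angle_deg: float, **kw):
        return render_phantom(wedge_spec(float(angle_deg), **kw))

    return make


@pytest.fixture
def truth_contours():
    """Factory: ground-truth contours wrapped for the metric layer."""

    def make(truth, scale=SCALE):
        return contours_from_truth(truth, scale)

    return make


@pytest.fixture
def segment():
    """Run the full segmentation chain on a scan."""

    def run(scan, spur_hint=None):
        pre = preprocess(scan)
        mask = fill_holes(binarize_per_column(pre))
        return extract_angle_contours(mask, pre, spur_hint=spur_hint)

    return run


def parallel_contours(d_px: float, length: int = 60, spur_at: int = 40,
                      scale: float = SCALE) -> AngleContours:
    """Two horizontal contours d_px apart; spur on the cornea at arc spur_at."""
    cols = np.arange(length, dtype=float)
    cornea = np.column_stack([np.full(length, 100.0), cols])
    iris = np.column_stack([np.full(length, 100.0 + d_px), cols])
    return AngleContours(
        cornea_contour=cornea,
        iris_contour=iris,
        apex_rc=(100, 0),
        spur_rc=(100, spur_at),
        sclera_poly_coeffs=None,
        sclera_polyline=None,
        scale_um_per_px=scale,
    )


def contour_rms(seg_poly, truth_poly) -> float:
    """RMS row error of a per-column contour against a per-column truth."""
    tr = {int(round(col)): r for r, col in np.asarray(truth_poly, float)}
    errs = [
        r - tr[int(round(col))]
        for r, col in np.asarray(seg_poly, float)
        if int(round(col)) in tr
    ]
    assert errs, "contours share no columns"
    return float(np.sqrt(np.mean(np.square(errs))))
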