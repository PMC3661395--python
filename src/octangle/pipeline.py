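"""End-to-end convenience wrapper: scan in, QC decision and metrics out.

This is the glue the CLI, the examples and batch evaluation share; each
stage remains individually importable from its own module.
"""

from __future__ import annotations

from . import angle_metrics as am
from . import qc_filters as qc
from . import segmentation as seg
from .errors import OctangleError
from .io_calibration import OctScan

__all__ = ["measure_scan", "measurement_record"]

_METRICS = {
    "aom": am.compute_aom,
    "aom2": am.compute_aom2,
    "aod": am.compute_aod,
    "tia": am.compute_tia,
    "tisa": am.compute_tisa,
}


def measurement_record(m: am.AngleMeasurement) -> dict:
    """JSON-ready record for one measurement."""
    rec = {
        "method": m.method,
        "range_um": m.range_um,
        "value": m.value,
        "units": m.units,
    }
    if m.value_px is not None:
        rec["value_px"] = m.value_px
    if m.argmin_pair is not None:
        rec["argmin_pair"] = [list(m.argmin_pair[0]), list(m.argmin_pair[1])]
    if m.sequence is not None:
        rec["sequence"] = m.sequence
    if m.notes:
        rec["notes"] = dict(m.notes)
    return rec


def measure_scan(
    scan: OctScan,
    spur: tuple[int, int] | None = None,
    methods: tuple[str, ...] = ("aom", "aod", "tia"),
    range_um: int = 500,
    median_mask_px: int = 3,
    short_px: int = qc.SHORT_PX,
    long_px: int = qc.LONG_PX,
    delta_px: float = qc.DELTA_PX,
    max_arc_px: float | None = 64.0,
):
    """Run preprocess → binarize → fill → contours → metrics on one scan.

    Returns ``(result_dict, contours)``; the dict carries the QC decision
    and one record per requested method (AOS is requested as ``"aos"``).
    Contours are traced over a 64 px (~2 mm) region of interest from the
    recess by default, matching the anatomical extent of usable iris
    visibility; pass ``max_arc_px=None`` for the whole wedge.
    """
    pre = seg.preprocess(scan, mask_px=median_mask_px)
    mask = seg.fill_holes(seg.binarize_per_column(pre))
    contours = seg.extract_angle_contours(
        mask, pre, spur_hint=spur, max_arc_px=max_arc_px
    )

    iris_len = int(len(contours.iris_contour))
    length_status = qc.filter_iris_length(iris_len, short_px, long_px)

    measurements, failed = [], []
    aod_px = aom_px = None
    for name in methods:
        try:
            if name == "aos":
                m = am.compute_aos(contours)
            else:
                m = _METRICS[name](contours, range_um)
        except OctangleError:
            if length_status == "ok":
                raise  # a metric failure on an eligible scan is an error
            failed.append(name)  # QC rejection takes precedence
            continue
        if name == "aod":
            aod_px = m.value_px
        if name == "aom":
            aom_px = m.value_px
        measurements.append(m)

    decision = qc.qc_decision(
        scan.frame_id, iris_len, aod_px=aod_px, aom_px=aom_px,
        short_threshold=short_px, long_threshold=long_px, delta_threshold=delta_px,
    )
    result = {
        "frame_id": scan.frame_id,
        "scale_um_per_px": scan.scale_um_per_px,
        "apex_rc": [int(contours.apex_rc[0]), int(contours.apex_rc[1])],
        "spur_rc": (
            [int(contours.spur_rc[0]), int(contours.spur_rc[1])]
            if contours.spur_rc is not None
            else None
        ),
        "closed": bool(contours.closed),
        "iris_len_px": iris_len,
        "qc": {
            "status": decision.status,
            "delta_aod_aom_px": decision.delta_aod_aom_px,
            "delta_class": decision.delta_class,
        },
        "measurements": [measurement_record(m) for m in measurements],
        "failed_methods": failed,
    }
    return result, contours
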