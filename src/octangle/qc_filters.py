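"""Eligibility and plausibility filters on measured scans.

Two screens are applied before any population-level comparison:

* iris-contour length bounds — contours shorter than 16 px (the 500 μm
  window at 31.3 μm/pixel) cannot support the windowed metrics, and
  contours longer than ~70 px (≈ 2.5 mm) do not occur anatomically and
  indicate a tracing failure;
* the AOD−AOM difference Δ — AOM searches a minimum so it undershoots AOD
  by definition, but only up to about 22 px on the most obtuse angles;
  larger differences flag an algorithm error rather than anatomy.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

__all__ = [
    "QcDecision",
    "filter_iris_length",
    "partition_delta",
    "qc_decision",
    "summarize_cohort",
    "summarize_counts",
    "round_half_up",
]

SHORT_PX = 16
LONG_PX = 70
DELTA_PX = 22.0

_STATUSES = ("ok", "too_short", "too_long", "no_contours")


@dataclass(frozen=True)
class QcDecision:
    frame_id: str
    iris_len_px: int
    status: str  # ok | too_short | too_long | no_contours
    delta_aod_aom_px: float | None = None
    delta_class: str | None = None  # definitional | algorithm_error


def round_half_up(x: float, decimals: int = 1) -> float:
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def filter_iris_length(
    iris_len_px: int, short_threshold: int = SHORT_PX, long_threshold: int = LONG_PX
) -> str:
    """too_short below the short bound, too_long strictly above the long
    bound, else ok.  16 px is acceptable; 71 px is not."""
    if iris_len_px < 0:
        raise ValueError(f"negative iris length: {iris_len_px}")
    if iris_len_px < short_threshold:
        return "too_short"
    if iris_len_px > long_threshold:
        return "too_long"
    return "ok"


def partition_delta(
    aod_px: float, aom_px: float, delta_threshold: float = DELTA_PX
) -> tuple[float, str]:
    """Δ = AOD − AOM in pixels; 'definitional' up to the threshold (the
    undershoot AOM's minimum search implies), 'algorithm_error' above it."""
    for name, v in (("aod_px", aod_px), ("aom_px", aom_px)):
        if not (v == v and v >= 0 and v != float("inf")):
            raise ValueError(f"{name} must be finite and >= 0, got {v}")
    delta = float(aod_px) - float(aom_px)
    return delta, ("definitional" if delta <= delta_threshold else "algorithm_error")


def qc_decision(
    frame_id: str,
    iris_len_px: int,
    aod_px: float | None = None,
    aom_px: float | None = None,
    short_threshold: int = SHORT_PX,
    long_threshold: int = LONG_PX,
    delta_threshold: float = DELTA_PX,
) -> QcDecision:
    """Combine both screens into one record for a frame."""
    status = filter_iris_length(iris_len_px, short_threshold, long_threshold)
    delta = cls = None
    if aod_px is not None and aom_px is not None:
        delta, cls = partition_delta(aod_px, aom_px, delta_threshold)
    return QcDecision(frame_id, int(iris_len_px), status, delta, cls)


def summarize_counts(
    total: int, too_short: int = 0, too_long: int = 0, no_contours: int = 0
) -> dict:
    """Cohort bookkeeping: per-status counts, percentages (one decimal,
    round half up) and the remaining count after exclusions."""
    if total <= 0:
        raise ValueError("empty cohort")
    excluded = too_short + too_long + no_contours
    counts = {
        "ok": total - excluded,
        "too_short": too_short,
        "too_long": too_long,
        "no_contours": no_contours,
    }
    percent = {k: round_half_up(100.0 * v / total, 1) for k, v in counts.items()}
    return {
        "total": total,
        "counts": counts,
        "percent": percent,
        "remaining": total - excluded,
    }


def summarize_cohort(decisions) -> dict:
    """Summarize a list of QcDecision records (see summarize_counts)."""
    decisions = list(decisions)
    if not decisions:
        raise ValueError("empty cohort")
    n = {s: 0 for s in _STATUSES}
    for d in decisions:
        if d.status not in n:
            raise ValueError(f"unknown status {d.status!r}")
        n[d.status] += 1
    return summarize_counts(
        len(decisions), n["too_short"], n["too_long"], n["no_contours"]
    )
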